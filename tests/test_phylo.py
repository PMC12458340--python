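import math
import random

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from strainbiogeo import (
    binary_trait_association,
    count_trait_genes,
    iqr_outlier_filter,
    midpoint_root,
    parse_newick,
    pic,
    pic_regression_origin,
    prune,
    trait_eligibility,
    write_newick,
)
from strainbiogeo.phylo import _leaf_distances_from, tip_labels


def random_tree(n_tips, seed):
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace([f"T{i}" for i in range(n_tips)])
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=random.Random(seed),
    )
    # the process stops at a birth event, leaving a zero-length cherry;
    # pad so strictly positive branch lengths are guaranteed
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 1e-8:
            edge.length = 0.05
    return tree


class TestNewickIO:
    def test_two_tip_parse(self):
        t = parse_newick("(A:1,B:1);")
        assert sorted(tip_labels(t)) == ["A", "B"]
        lengths = {l.taxon.label: l.edge.length for l in t.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0}

    def test_round_trip_preserves_paths(self):
        tree = random_tree(50, seed=4)
        before = oracles.allpairs_tip_paths(tree)
        back = parse_newick(write_newick(tree))
        after = oracles.allpairs_tip_paths(back)
        assert before.keys() == after.keys()
        for k in before:
            assert after[k] == pytest.approx(before[k], abs=1e-9)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="[Dd]uplicate"):
            parse_newick("((A:1,A:2):1,B:1);")

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValueError, match="parse"):
            parse_newick("((A:1,B:2;")


class TestMidpointRoot:
    def test_two_tip_midpoint(self):
        m = midpoint_root(parse_newick("(A:1,B:3);"))
        d = _leaf_distances_from(m, m.seed_node)
        depths = {l.taxon.label: d[l] for l in m.leaf_node_iter()}
        assert depths == pytest.approx({"A": 2.0, "B": 2.0})

    def test_idempotent_on_already_rooted_tree(self):
        m1 = midpoint_root(random_tree(12, seed=9))
        m2 = midpoint_root(m1)
        p1 = oracles.allpairs_tip_paths(m1)
        p2 = oracles.allpairs_tip_paths(m2)
        for k in p1:
            assert p2[k] == pytest.approx(p1[k], abs=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3, 17])
    def test_deepest_tips_equidistant_at_half_diameter(self, seed):
        tree = random_tree(20, seed=seed)
        paths = oracles.allpairs_tip_paths(tree)
        diameter = max(paths.values())
        m = midpoint_root(tree)
        d = _leaf_distances_from(m, m.seed_node)
        depths = sorted((d[l] for l in m.leaf_node_iter()), reverse=True)
        assert depths[0] == pytest.approx(diameter / 2, abs=1e-9)
        assert depths[1] == pytest.approx(diameter / 2, abs=1e-9)

    def test_zero_length_tree_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            midpoint_root(parse_newick("(A:0,B:0);"))


class TestPrune:
    def test_keep_all_preserves_paths(self):
        tree = random_tree(10, seed=5)
        out = prune(tree, tip_labels(tree))
        before = oracles.allpairs_tip_paths(tree)
        after = oracles.allpairs_tip_paths(out)
        for k in before:
            assert after[k] == pytest.approx(before[k], abs=1e-9)

    def test_unifurcation_merged_additively(self):
        out = prune(parse_newick("((A:1,B:1):1,C:2);"), {"A", "C"})
        paths = oracles.allpairs_tip_paths(out)
        assert paths[("A", "C")] == pytest.approx(4.0)

    @pytest.mark.parametrize("seed,n_keep", [(11, 5), (12, 10), (13, 17)])
    def test_random_subset_preserves_pairwise_paths(self, seed, n_keep):
        tree = random_tree(25, seed=seed)
        keep = sorted(tip_labels(tree))[:n_keep]
        out = prune(tree, keep)
        assert sorted(tip_labels(out)) == keep
        before = oracles.allpairs_tip_paths(tree)
        after = oracles.allpairs_tip_paths(out)
        for k in after:
            assert after[k] == pytest.approx(before[k], abs=1e-9)

    def test_unknown_tip_rejected(self):
        with pytest.raises(ValueError, match="not in tree"):
            prune(parse_newick("(A:1,B:1);"), {"A", "Z"})


class TestPIC:
    def test_two_tip_closed_form(self):
        t = parse_newick("(A:1,B:1);")
        cs = pic(t, {"A": 3.0, "B": 1.0})
        assert len(cs) == 1
        assert abs(cs.values[0]) == pytest.approx(2.0 / math.sqrt(2.0))

    def test_constant_tip_values_give_zero_contrasts(self):
        tree = random_tree(10, seed=21)
        cs = pic(tree, {t: 5.5 for t in tip_labels(tree)})
        assert np.allclose(cs.values, 0.0)

    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_matches_independent_recursive_oracle(self, seed, rng):
        tree = random_tree(16, seed=seed)
        values = {t: float(rng.normal()) for t in tip_labels(tree)}
        cs = pic(tree, values)
        expected = oracles.pic_recursive(tree, values)
        assert len(cs.values) == 15
        assert np.allclose(np.sort(np.abs(cs.values)), np.sort(np.abs(expected)), atol=1e-9)

    def test_linear_transform_scales_contrasts(self, rng):
        tree = random_tree(12, seed=41)
        values = {t: float(rng.normal()) for t in tip_labels(tree)}
        base = pic(tree, values).values
        scaled = pic(tree, {k: 3.0 * v - 7.0 for k, v in values.items()}).values
        assert np.allclose(scaled, 3.0 * base, atol=1e-9)

    def test_invariant_to_child_order(self):
        a = parse_newick("((A:1,B:2):1,C:3);")
        b = parse_newick("(C:3,(B:2,A:1):1);")
        vals = {"A": 1.0, "B": 4.0, "C": 2.0}
        ca = np.sort(np.abs(pic(a, vals).values))
        cb = np.sort(np.abs(pic(b, vals).values))
        assert np.allclose(ca, cb, atol=1e-12)

    def test_brownian_contrast_calibration(self, rng):
        """BM contrasts have mean 0 and variance sigma^2 (3 SE over 1000 sims)."""
        tree = midpoint_root(random_tree(16, seed=51))
        sigma = 0.7
        all_contrasts = []
        tips = tip_labels(tree)
        for _ in range(1000):
            state = {tree.seed_node: 0.0}
            for nd in tree.preorder_node_iter():
                if nd is tree.seed_node:
                    continue
                b = nd.edge.length or 0.0
                state[nd] = state[nd.parent_node] + rng.normal(0, sigma * math.sqrt(b))
            vals = {l.taxon.label: state[l] for l in tree.leaf_node_iter()}
            all_contrasts.append(pic(tree, vals).values)
        c = np.concatenate(all_contrasts)
        se_mean = c.std() / math.sqrt(len(c))
        assert abs(c.mean()) < 3 * se_mean
        var = c.var()
        se_var = sigma**2 * math.sqrt(2.0 / (len(c) - 1))
        assert abs(var - sigma**2) < 3 * se_var

    def test_polytomy_resolved_with_epsilon_policy(self):
        t = parse_newick("(A:1,B:1,C:1);")
        cs = pic(t, {"A": 1.0, "B": 2.0, "C": 3.0}, zero_branch_policy="epsilon")
        assert len(cs) == 2
        with pytest.raises(ValueError, match="zero"):
            pic(parse_newick("(A:0,B:0);"), {"A": 1.0, "B": 2.0})

    def test_missing_tip_value_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            pic(parse_newick("(A:1,B:1);"), {"A": 1.0})


class TestIQRFilter:
    def test_all_equal_values_kept(self):
        assert iqr_outlier_filter([2.0] * 6).all()

    def test_fixed_vector_extreme_removed(self):
        # 12 points: Q1 = 2.75, Q3 = 5.25 (linear interpolation), IQR = 2.5,
        # fences [-1.0, 9.0]; 50 is the only point outside
        v = [1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 50.0]
        mask = iqr_outlier_filter(v)
        assert mask.sum() == 11
        assert not mask[-1]

    def test_short_input_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            mask = iqr_outlier_filter([1.0, 2.0, 100.0])
        assert mask.all()


class TestOriginRegression:
    def test_exact_negative_relation(self):
        x = np.array([0.5, -1.2, 2.0, 0.7, -0.3, 1.1])
        res = pic_regression_origin(x, -2.0 * x, n_perm=1000)
        assert res.exhaustive and res.n_perm == 64
        assert res.slope == pytest.approx(-2.0, abs=1e-12)
        assert res.p_one_sided_negative == pytest.approx(1.0 / 64.0)

    def test_slope_matches_closed_form(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        res = pic_regression_origin(x, y, n_perm=100, seed=1)
        assert res.slope == pytest.approx(float(x @ y / (x @ x)), abs=1e-12)

    def test_exhaustive_matches_direct_enumeration(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        res = pic_regression_origin(x, y, n_perm=300)
        assert res.exhaustive
        count = 0
        slope = x @ y / (x @ x)
        for bits in range(2**8):
            s = np.array([1.0 if bits >> i & 1 == 0 else -1.0 for i in range(8)])
            if (x @ (s * y)) / (x @ x) <= slope + 1e-12:
                count += 1
        assert res.p_one_sided_negative == pytest.approx(count / 256)

    def test_type_i_error_calibrated(self, rng):
        from scipy.stats import binom

        reps = 400
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            res = pic_regression_origin(x, y, n_perm=199, seed=rng)
            rejections += res.p_one_sided_negative <= 0.05
        lo, hi = binom.ppf([0.025, 0.975], reps, 0.05)
        assert lo <= rejections <= hi

    def test_zero_x_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            pic_regression_origin(np.zeros(5), np.ones(5), n_perm=10)

    def test_negative_coupling_power(self, rng):
        """y = -0.5 x + noise on BM contrasts rejects in >= 80% of replicates."""
        tree = midpoint_root(random_tree(150, seed=61))
        tips = tip_labels(tree)
        hits = 0
        reps = 100
        for _ in range(reps):
            state = {tree.seed_node: 0.0}
            for nd in tree.preorder_node_iter():
                if nd is tree.seed_node:
                    continue
                b = nd.edge.length or 0.0
                state[nd] = state[nd.parent_node] + rng.normal(0, math.sqrt(b))
            xv = {l.taxon.label: state[l] for l in tree.leaf_node_iter()}
            x_c = pic(tree, xv).values
            noise = {t: float(rng.normal(0, 1.0)) for t in tips}
            yv = {t: -0.5 * xv[t] + noise[t] for t in tips}
            y_c = pic(tree, yv).values
            res = pic_regression_origin(x_c, y_c, n_perm=199, seed=rng)
            hits += res.p_one_sided_negative <= 0.05
        assert hits / reps >= 0.8


class TestTraitPrep:
    def test_count_trait_genes(self):
        table = {"g1": {"a", "b", "c"}, "g2": {"c"}, "g3": set()}
        assert count_trait_genes(table, set()) == {"g1": 0, "g2": 0, "g3": 0}
        assert count_trait_genes(table, {"a", "b", "c", "d"}) == {"g1": 3, "g2": 1, "g3": 0}

    @pytest.mark.parametrize(
        "comp,n,expected",
        [(0.90, 4, True), (0.95, 3, False), (0.89, 10, False)],
    )
    def test_trait_eligibility_boundaries(self, comp, n, expected):
        occ = {"g": [f"s{i}" for i in range(n)]}
        out = trait_eligibility({"g": comp}, occ)
        assert ("g" in out) is expected

    def test_binary_association_equals_group_mean_difference(self):
        trait = {"a": 1, "b": 1, "c": 0, "d": 0, "e": None}
        ibd = {"a": 0.2, "b": 0.2, "c": 0.5, "d": 0.5, "e": 99.0}
        slope, p, n = binary_trait_association(trait, ibd)
        assert slope == pytest.approx(-0.3)
        assert n == 4

    def test_binary_association_matches_t_test_oracle(self, rng):
        from scipy.stats import ttest_ind

        present = rng.normal(0.2, 0.1, 8)
        absent = rng.normal(0.4, 0.1, 10)
        trait = {f"p{i}": 1 for i in range(8)} | {f"a{i}": 0 for i in range(10)}
        ibd = {f"p{i}": present[i] for i in range(8)} | {
            f"a{i}": absent[i] for i in range(10)
        }
        slope, p, _ = binary_trait_association(trait, ibd)
        t_res = ttest_ind(present, absent, equal_var=True)
        assert slope == pytest.approx(present.mean() - absent.mean(), abs=1e-12)
        assert p == pytest.approx(t_res.pvalue, abs=1e-12)

    def test_single_trait_level_rejected(self):
        with pytest.raises(ValueError, match="one trait level"):
            binary_trait_association({"a": 1, "b": 1, "c": 1}, {"a": 1, "b": 2, "c": 3})
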