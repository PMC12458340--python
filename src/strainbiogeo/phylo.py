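"""Phylogenetic comparative analysis of dispersal traits and IBD strength.

Across bacterial species, does spore-forming ability (proxied by the number
of sporulation-associated genes in the genome) dampen the geographic
structuring of strain diversity? Because related bacteria share both traits
and biogeography, the association is tested on Felsenstein's phylogenetic
independent contrasts (PIC) computed over the bacterial phylogeny — midpoint
rooted and pruned to the analysed species — followed by a through-origin
permutation regression of gene-abundance contrasts on IBD-strength
contrasts. Binary trait calls (e.g. classifier-derived sporulation
presence/absence) are tested against IBD strength with a plain
identity-covariance least-squares fit.

Tree I/O, rooting and pruning are delegated to dendropy; the PIC recursion
and permutation machinery are implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

from ._rng import substream

__all__ = [
    "ContrastSet",
    "TraitRegressionResult",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "midpoint_root",
    "prune",
    "pic",
    "iqr_outlier_filter",
    "pic_regression_origin",
    "count_trait_genes",
    "trait_eligibility",
    "binary_trait_association",
]


@dataclass(frozen=True)
class ContrastSet:
    """Standardized independent contrasts, one per internal node."""

    values: np.ndarray
    node_ids: tuple

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TraitRegressionResult:
    slope: float
    p_one_sided_negative: float
    n_contrasts_used: int
    n_outliers_removed: int
    n_perm: int
    exhaustive: bool


# ---------------------------------------------------------------- tree io
def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a rooted dendropy tree.

    Raises on malformed input and on duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    if any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
        raise ValueError("unlabelled tip in newick input")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)


def read_newick_file(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree(tree)


def tip_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------- rooting
def _leaf_distances_from(tree: dendropy.Tree, start) -> dict:
    """Path lengths from ``start`` node to every node (undirected walk)."""
    dist = {start: 0.0}
    stack = [start]
    while stack:
        nd = stack.pop()
        nbrs = list(nd.child_nodes())
        if nd.parent_node is not None:
            nbrs.append(nd.parent_node)
        for nb in nbrs:
            if nb in dist:
                continue
            edge = nb.edge if nb.parent_node is nd else nd.edge
            dist[nb] = dist[nd] + (edge.length or 0.0)
            stack.append(nb)
    return dist


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest tip-to-tip path.

    The diameter is found with the standard two-sweep walk (farthest tip
    from an arbitrary tip, then farthest tip from that), which is exact on
    trees with non-negative branch lengths; the root is placed on the edge
    containing the path's midpoint.
    """
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs >= 2 tips")
    if all((e.length or 0.0) == 0.0 for e in tree.preorder_edge_iter()):
        raise ValueError("all branch lengths are zero; midpoint undefined")
    out = _clone(tree)
    out.seed_node.edge.length = None

    leaves = out.leaf_nodes()
    d0 = _leaf_distances_from(out, leaves[0])
    u = max((nd for nd in leaves), key=lambda nd: d0[nd])
    du = _leaf_distances_from(out, u)
    v = max((nd for nd in leaves), key=lambda nd: du[nd])
    half = du[v] / 2.0

    # u -> v path through their most recent common ancestor
    up_u = [u]
    while up_u[-1].parent_node is not None:
        up_u.append(up_u[-1].parent_node)
    up_v = [v]
    while up_v[-1].parent_node is not None:
        up_v.append(up_v[-1].parent_node)
    anc_u = set(id(x) for x in up_u)
    mrca_idx = next(i for i, x in enumerate(up_v) if id(x) in anc_u)
    mrca = up_v[mrca_idx]
    path = up_u[: up_u.index(mrca) + 1] + list(reversed(up_v[:mrca_idx]))
    cum = 0.0
    tol = 1e-12 * max(du[v], 1.0)
    for a, b in zip(path, path[1:]):
        edge = b.edge if b.parent_node is a else a.edge
        elen = edge.length or 0.0
        if cum + elen >= half - tol:
            rem = min(max(half - cum, 0.0), elen)
            if rem <= tol:  # midpoint sits exactly on node a
                out.reseed_at(a, update_bipartitions=True, suppress_unifurcations=True)
            elif elen - rem <= tol:  # midpoint sits exactly on node b
                out.reseed_at(b, update_bipartitions=True, suppress_unifurcations=True)
            else:
                # rem measured from the path-walk side; convert to the
                # edge's own (tail -> head) orientation
                if b.parent_node is a:
                    l_tail, l_head = rem, elen - rem
                else:
                    l_tail, l_head = elen - rem, rem
                out.reroot_at_edge(
                    edge, length1=l_tail, length2=l_head, update_bipartitions=True
                )
            break
        cum += elen
    out.seed_node.edge.length = None
    if len(out.seed_node.child_nodes()) != 2:
        out.resolve_polytomies(limit=2, update_bipartitions=True)
    return out


def prune(tree: dendropy.Tree, keep_tips) -> dendropy.Tree:
    """Induced subtree on ``keep_tips``; unifurcations merged additively."""
    keep = set(keep_tips)
    present = set(tip_labels(tree))
    unknown = keep - present
    if unknown:
        raise ValueError(f"tips not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need >= 2 tips to keep")
    out = tree.extract_tree_with_taxa_labels(labels=keep)
    out.purge_taxon_namespace()
    # collapse a degree-1 root edge so path lengths among tips are unchanged
    root = out.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        out.seed_node = child
        child.parent_node = None
        child.edge.length = None
        root = child
    return out


# -------------------------------------------------------------------- pic
def pic(
    tree: dendropy.Tree,
    tip_values: dict,
    zero_branch_policy: str = "error",
) -> ContrastSet:
    """Felsenstein's phylogenetic independent contrasts.

    At each internal node with child values x1, x2 on (extended) branch
    lengths b1, b2:

        contrast   = (x1 - x2) / sqrt(b1 + b2)
        node value = (x1/b1 + x2/b2) / (1/b1 + 1/b2)

    and the node's own branch is extended by b1*b2/(b1 + b2). Polytomies are
    resolved to arbitrary bifurcations with zero-length internal branches
    first; with ``zero_branch_policy="epsilon"`` any zero b1 + b2 is padded
    by 1e-8 x tree depth instead of raising.
    """
    work = _clone(tree)
    if any(len(nd.child_nodes()) > 2 for nd in work.preorder_internal_node_iter()):
        work.resolve_polytomies(limit=2, update_bipartitions=False)
    tips = tip_labels(work)
    missing = [t for t in tips if t not in tip_values]
    if missing:
        raise ValueError(f"tip values missing for: {missing[:10]}")
    depth = max(work.calc_node_root_distances(return_leaf_distances_only=True))
    eps = 1e-8 * (depth if depth > 0 else 1.0)

    contrasts = []
    node_ids = []
    counter = [0]
    state = {}  # node -> (value, working branch length)
    for nd in work.postorder_node_iter():
        edge_len = nd.edge.length if nd.edge.length is not None else 0.0
        if edge_len < 0:
            raise ValueError("negative branch length")
        if nd.is_leaf():
            state[nd] = (float(tip_values[nd.taxon.label]), float(edge_len))
            continue
        children = nd.child_nodes()
        if len(children) != 2:
            raise ValueError("internal node is not binary after polytomy resolution")
        (x1, b1), (x2, b2) = state[children[0]], state[children[1]]
        if b1 + b2 == 0.0:
            if zero_branch_policy == "epsilon":
                b1 += eps
                b2 += eps
            else:
                raise ValueError(
                    "zero-length branch pair at an internal node; rerun with "
                    "zero_branch_policy='epsilon' or fix the tree"
                )
        contrasts.append((x1 - x2) / math.sqrt(b1 + b2))
        value = (x1 / b1 + x2 / b2) / (1.0 / b1 + 1.0 / b2)
        counter[0] += 1
        node_id = nd.label if nd.label else f"node{counter[0]}"
        node_ids.append(node_id)
        state[nd] = (value, edge_len + b1 * b2 / (b1 + b2))
    values = np.array(contrasts, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite contrast computed")
    return ContrastSet(values, tuple(node_ids))


# ---------------------------------------------------------------- filter
def iqr_outlier_filter(values) -> np.ndarray:
    """Tukey fence mask: keep values within [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation between order statistics. With fewer
    than 4 values no filtering is applied (a warning is emitted).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        warnings.warn("fewer than 4 values: IQR outlier filter skipped", stacklevel=2)
        return np.ones(v.size, dtype=bool)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)


# ------------------------------------------------------------ regression
def pic_regression_origin(
    x_contrasts,
    y_contrasts,
    n_perm: int = 100000,
    seed: int | None = 0,
) -> TraitRegressionResult:
    """Through-origin regression of y on x contrasts with a sign-flip null.

    Contrast signs are arbitrary (they depend on child ordering), so under
    the null of no association the slope is symmetric under independent sign
    flips of the response contrasts. The test is one-sided for a *negative*
    slope: p = share of sign-flip patterns with slope <= observed. All 2^n
    patterns are enumerated when 2^n <= n_perm.

    Outlier handling is the caller's responsibility (see
    :func:`iqr_outlier_filter`); pairs must already be jointly masked.
    """
    x = np.asarray(x_contrasts, dtype=float)
    y = np.asarray(y_contrasts, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y contrasts must be equal-length 1-D vectors")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("sum of squared x contrasts is zero; slope undefined")
    slope = float(x @ y) / sxx
    n = len(x)

    if 2**n <= n_perm:
        # enumerate all sign patterns via bit masks
        patterns = np.arange(2**n, dtype=np.uint64)
        bits = ((patterns[:, None] >> np.arange(n, dtype=np.uint64)) & 1).astype(float)
        signs = 1.0 - 2.0 * bits
        slopes = (signs * y[None, :]) @ x / sxx
        count = int((slopes <= slope + 1e-12).sum())
        p = count / 2**n
        return TraitRegressionResult(slope, p, n, 0, 2**n, True)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    chunk = max(1, int(2e7 // max(1, n)))
    done = 0
    while done < n_perm:
        take = min(chunk, n_perm - done)
        signs = rng.choice((-1.0, 1.0), size=(take, n))
        slopes = (signs * y[None, :]) @ x / sxx
        count += int((slopes <= slope + 1e-12).sum())
        done += take
    p = (1.0 + count) / (n_perm + 1.0)
    return TraitRegressionResult(slope, p, n, 0, n_perm, False)


# ------------------------------------------------------------ trait prep
def count_trait_genes(annotation_table: dict, curated_list) -> dict:
    """Per-SGB abundance of curated trait genes: |annotations ∩ list|."""
    curated = set(curated_list)
    return {sgb: len(set(genes) & curated) for sgb, genes in annotation_table.items()}


def trait_eligibility(
    completeness: dict,
    occupancy: dict,
    min_completeness: float = 0.90,
    min_samples: int = 4,
) -> list:
    """SGBs complete enough (>= min_completeness) and common enough
    (present in >= min_samples samples) for trait annotation analyses.

    ``occupancy`` maps sgb_id -> iterable of samples (or (host, site) pairs).
    """
    eligible = []
    for sgb, comp in completeness.items():
        n = len(list(occupancy.get(sgb, ())))
        if comp >= min_completeness and n >= min_samples:
            eligible.append(sgb)
    return sorted(eligible)


def binary_trait_association(trait: dict, ibd_strength: dict):
    """Association of a binary trait with per-SGB IBD strength.

    Identity-covariance least squares of IBD strength on the trait
    indicator: the slope is the mean difference (trait present - absent) and
    the two-sided p comes from the t distribution — equivalent to a pooled
    two-sample t-test. SGBs with missing trait calls (None/NaN) are dropped.

    Returns ``(slope, two_sided_p, n_used)``.
    """
    pairs = []
    for sgb, call in trait.items():
        if call is None or (isinstance(call, float) and math.isnan(call)):
            continue
        if sgb not in ibd_strength:
            continue
        if call not in (0, 1):
            raise ValueError(f"trait call for {sgb} must be 0/1/missing, got {call!r}")
        pairs.append((int(call), float(ibd_strength[sgb])))
    if len(pairs) < 3:
        raise ValueError("need >= 3 SGBs with non-missing trait calls")
    t_arr = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs])
    if len(np.unique(t_arr)) < 2:
        raise ValueError("degenerate design: only one trait level present")
    X = np.column_stack([np.ones_like(t_arr), t_arr])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - 2
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(s2 * xtx_inv[1, 1])
    if se == 0.0:  # perfect separation of group means
        p = 0.0 if beta[1] != 0 else 1.0
    else:
        p = 2.0 * stats.t.sf(abs(beta[1] / se), dof)
    return float(beta[1]), float(p), len(y)


def trait_pipeline_regression(
    tree: dendropy.Tree,
    abundance: dict,
    ibd_strength: dict,
    n_perm: int = 100000,
    seed: int = 0,
    substream_key: str = "traits",
) -> TraitRegressionResult:
    """Full PIC trait analysis for one gene category.

    Midpoint-roots and prunes the tree to the SGBs present in both inputs,
    computes contrasts of gene abundance and IBD strength, removes jointly
    the contrast pairs where either member is a Tukey-fence outlier, and
    runs the through-origin sign-flip regression of abundance contrasts on
    IBD-strength contrasts (one-sided, negative slope).
    """
    shared = sorted(set(abundance) & set(ibd_strength) & set(tip_labels(tree)))
    if len(shared) < 3:
        raise ValueError("need >= 3 SGBs shared between tree, abundance and IBD strength")
    sub = prune(tree, shared) if set(tip_labels(tree)) != set(shared) else tree
    sub = midpoint_root(sub)
    y_c = pic(sub, {s: abundance[s] for s in shared}, zero_branch_policy="epsilon")
    x_c = pic(sub, {s: ibd_strength[s] for s in shared}, zero_branch_policy="epsilon")
    keep = iqr_outlier_filter(x_c.values) & iqr_outlier_filter(y_c.values)
    n_out = int((~keep).sum())
    rng = substream(seed, substream_key)
    res = pic_regression_origin(
        x_c.values[keep], y_c.values[keep], n_perm=n_perm, seed=rng
    )
    return TraitRegressionResult(
        res.slope, res.p_one_sided_negative, res.n_contrasts_used, n_out,
        res.n_perm, res.exhaustive,
    )
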