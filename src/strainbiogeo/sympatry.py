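"""Strain divergence between sympatric host species.

Where a focal host species co-occurs with congeneric and heterogeneric
rodents, each shared SGB's pairwise strain distances are partitioned into
conspecific (focal vs focal), congeneric and heterogeneric host pairings.
Per SGB, permutation t-tests compare conspecific vs congeneric and
congeneric vs heterogeneric distances (BH-FDR across SGBs within each
contrast); an across-SGB "mean of means" permutation test asks whether a
pairing systematically elevates divergence, respecting the paired structure
of SGBs observed in both pairings.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .matrixtests import bh_fdr

__all__ = [
    "PairingComparison",
    "PermTTestResult",
    "build_pairings",
    "perm_ttest",
    "sympatric_sgb_tests",
    "mean_of_means_test",
    "pairings_to_frame",
]

logger = logging.getLogger(__name__)

PAIRINGS = ("conspecific", "congeneric", "heterogeneric")


@dataclass
class PairingComparison:
    sgb_id: str
    pairing: str
    distances: np.ndarray
    n_pairs: int

    @property
    def mean_distance(self) -> float:
        return float(np.mean(self.distances))


@dataclass(frozen=True)
class PermTTestResult:
    mean_diff: float
    p_value: float
    n_perm_used: int
    exhaustive: bool


def build_pairings(
    strain_matrices: dict,
    samples: list,
    focal_species: str,
    comparator_species_map: dict,
    min_pairs: int = 2,
    conspecific_requires_comparator_site: bool = True,
) -> list:
    """Partition each SGB's pairwise distances into host pairings.

    Pairs are restricted to sympatric hosts (identical site_code). A
    focal-focal pair is conspecific; a focal-comparator pair takes the
    pairing named in ``comparator_species_map`` (species -> "congeneric" or
    "heterogeneric"); comparator-comparator pairs are excluded. With
    ``conspecific_requires_comparator_site`` (default), conspecific pairs
    only count at sites where some comparator species was sampled. SGB x
    pairing entries with fewer than ``min_pairs`` pairs are dropped.
    """
    by_id = {s.sample_id: s for s in samples}
    species = {s.host_species for s in samples}
    if focal_species not in species:
        raise ValueError(f"focal species {focal_species!r} absent from metadata")
    bad = set(comparator_species_map.values()) - {"congeneric", "heterogeneric"}
    if bad:
        raise ValueError(f"invalid pairing names: {sorted(bad)}")
    comparator_sites = {
        s.site_code for s in samples if s.host_species in comparator_species_map
    }

    out = []
    for sgb in sorted(strain_matrices):
        D = strain_matrices[sgb]
        buckets: dict = {p: [] for p in PAIRINGS}
        labels = [x for x in D.labels if x in by_id]
        for a, b in itertools.combinations(labels, 2):
            d = D[a, b]
            if math.isnan(d):
                continue
            sa, sb = by_id[a], by_id[b]
            if sa.site_code != sb.site_code:
                continue
            kinds = {sa.host_species, sb.host_species}
            if kinds == {focal_species}:
                if (
                    conspecific_requires_comparator_site
                    and sa.site_code not in comparator_sites
                ):
                    continue
                buckets["conspecific"].append(d)
            elif focal_species in kinds:
                other = (kinds - {focal_species}).pop()
                pairing = comparator_species_map.get(other)
                if pairing is not None:
                    buckets[pairing].append(d)
            # comparator-comparator pairs fall through (excluded)
        for pairing in PAIRINGS:
            vals = buckets[pairing]
            if len(vals) >= min_pairs:
                out.append(
                    PairingComparison(sgb, pairing, np.asarray(vals, float), len(vals))
                )
    return out


def perm_ttest(a, b, n_perm: int = 10000, seed: int | None = 0) -> PermTTestResult:
    """Two-sided permutation t-test on the difference of group means.

    The null reassigns the pooled values to groups of the original sizes;
    all C(na+nb, na) assignments are enumerated when that count <= n_perm.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    pooled = np.concatenate([a, b])
    na, n = a.size, a.size + b.size
    total = pooled.sum()
    obs = float(a.mean() - b.mean())
    # mean_a - mean_b is a monotone function of sum(a): d = s/na - (T-s)/nb
    def diff_from_suma(s):
        return s / na - (total - s) / (n - na)

    n_comb = math.comb(n, na)
    if n_comb <= n_perm:
        count = 0
        for idx in itertools.combinations(range(n), na):
            d = diff_from_suma(pooled[list(idx)].sum())
            if abs(d) >= abs(obs) - 1e-12:
                count += 1
        return PermTTestResult(obs, count / n_comb, n_comb, True)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    chunk = max(1, int(2e6 // n))
    done = 0
    while done < n_perm:
        take = min(chunk, n_perm - done)
        order = np.argsort(rng.random((take, n)), axis=1)[:, :na]
        sums = np.take(pooled, order).sum(axis=1)
        d = sums / na - (total - sums) / (n - na)
        count += int((np.abs(d) >= abs(obs) - 1e-12).sum())
        done += take
    return PermTTestResult(obs, (1.0 + count) / (n_perm + 1.0), n_perm, False)


CONTRASTS = (
    ("conspecific", "congeneric"),
    ("congeneric", "heterogeneric"),
)


def sympatric_sgb_tests(
    pairings: list,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-SGB permutation t-tests on the two host-pairing contrasts.

    BH-FDR is applied across SGBs within each contrast; ``flagged`` marks
    q < alpha. SGBs missing a category for a contrast are skipped with a
    warning.
    """
    table: dict = {}
    for pc in pairings:
        table.setdefault(pc.sgb_id, {})[pc.pairing] = pc.distances
    rows = []
    for sgb in sorted(table):
        cats = table[sgb]
        for pa, pb in CONTRASTS:
            if pa not in cats or pb not in cats:
                logger.warning(
                    "sympatry: SGB %s lacks %s or %s pairing; contrast skipped",
                    sgb, pa, pb,
                )
                continue
            rng = substream(seed, "sympatry", sgb, pa, pb)
            res = perm_ttest(cats[pa], cats[pb], n_perm=n_perm, seed=rng)
            rows.append(
                {
                    "sgb_id": sgb,
                    "contrast": f"{pa}_vs_{pb}",
                    "mean_diff": res.mean_diff,
                    "p": res.p_value,
                }
            )
    df = pd.DataFrame(rows, columns=["sgb_id", "contrast", "mean_diff", "p"])
    if df.empty:
        df["q"] = []
        df["flagged"] = []
        return df
    df["q"] = np.nan
    for contrast, grp in df.groupby("contrast"):
        df.loc[grp.index, "q"] = bh_fdr(grp["p"].to_numpy())
    df["flagged"] = df["q"] < alpha
    return df


def mean_of_means_test(
    pairings: list,
    contrast: tuple = ("congeneric", "heterogeneric"),
    n_perm: int = 10000,
    seed: int | None = 0,
    paired: bool = True,
):
    """Across-SGB test on per-SGB mean distances between two pairings.

    The unit of analysis is an SGB's mean distance in each pairing. With
    ``paired`` (default) the null flips the pairing labels within each SGB
    (lines connecting the same SGB across pairings), i.e. a sign-flip test
    on per-SGB differences; unpaired mode pools the per-SGB means and
    permutes group membership. Returns ``(p, mean_diff)``.
    """
    pa, pb = contrast
    means: dict = {}
    for pc in pairings:
        if pc.pairing in contrast:
            means.setdefault(pc.sgb_id, {})[pc.pairing] = pc.mean_distance
    shared = sorted(s for s, m in means.items() if pa in m and pb in m)
    if len(shared) < 2:
        raise ValueError(f"need >= 2 SGBs present in both {pa} and {pb}")
    ma = np.array([means[s][pa] for s in shared])
    mb = np.array([means[s][pb] for s in shared])
    obs = float(ma.mean() - mb.mean())

    if not paired:
        res = perm_ttest(ma, mb, n_perm=n_perm, seed=seed)
        return res.p_value, obs

    d = ma - mb
    n = len(d)
    if 2**n <= n_perm:
        patterns = np.arange(2**n, dtype=np.uint64)
        bits = ((patterns[:, None] >> np.arange(n, dtype=np.uint64)) & 1).astype(float)
        signs = 1.0 - 2.0 * bits
        diffs = (signs * d[None, :]).mean(axis=1)
        p = float((np.abs(diffs) >= abs(obs) - 1e-12).sum()) / 2**n
        return p, obs
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    diffs = (signs * d[None, :]).mean(axis=1)
    count = int((np.abs(diffs) >= abs(obs) - 1e-12).sum())
    return (1.0 + count) / (n_perm + 1.0), obs


def pairings_to_frame(pairings: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sgb_id": pc.sgb_id,
                "pairing": pc.pairing,
                "n_pairs": pc.n_pairs,
                "mean_distance": pc.mean_distance,
            }
            for pc in pairings
        ]
    )
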