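"""Distance-matrix statistics: Mantel tests, MRM, FDR and the IBD/IBH screen.

The central question — does strain genetic distance track geography after
controlling for host maternal (mitochondrial) relatedness, or vice versa? —
is answered per bacterial species (SGB) with multiple regression on distance
matrices (MRM):

    strain distance ~ host MT distance + geographic distance

on standardized vectorized lower triangles, with significance from a
permutation null that jointly permutes rows and columns of the response
matrix. A Spearman variant rank-transforms the vectorized distances first.
The Mantel test is the single-predictor correlation analogue with a
one-sided (positive association) permutation p-value.

Exact enumeration over all n! relabelings replaces sampling whenever
n! <= n_perm, so small-sample p-values are exact rationals.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .distmat import DistanceMatrix, common_labels

__all__ = [
    "MantelResult",
    "MRMResult",
    "SGBScreenResult",
    "vectorize",
    "mantel",
    "mrm",
    "bh_fdr",
    "screen_sgbs",
    "run_ibd_ibh_screen",
    "screen_to_frame",
    "residualize",
]

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12  # tolerance when comparing permuted vs observed statistics


# ----------------------------------------------------------------- results
@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_samples: int
    n_pairs: int
    n_perm_used: int
    exhaustive: bool
    method: str = "pearson"


@dataclass(frozen=True)
class MRMResult:
    """Standardized MRM fit for one response matrix.

    ``coefs`` are standardized partial regression coefficients (response and
    predictors z-scored on the vectorized scale); ``raw_coefs`` are on the
    original distance scale (with intercept, not reported).
    """

    method: str
    predictor_names: tuple
    coefs: tuple
    raw_coefs: tuple
    p_values: tuple
    r_squared: float
    n_samples: int
    n_pairs: int
    n_perm_used: int
    exhaustive: bool

    def coef(self, name: str) -> float:
        return self.coefs[self.predictor_names.index(name)]

    def p_value(self, name: str) -> float:
        return self.p_values[self.predictor_names.index(name)]

    # Convenience accessors for the canonical host-MT + geography formula.
    @property
    def coef_host(self) -> float:
        return self.coef("host_mt")

    @property
    def coef_geo(self) -> float:
        return self.coef("geo")

    @property
    def p_host(self) -> float:
        return self.p_value("host_mt")

    @property
    def p_geo(self) -> float:
        return self.p_value("geo")


@dataclass
class SGBScreenResult:
    sgb_id: str
    n_hosts: int
    n_populations: int
    pearson: MRMResult
    spearman: MRMResult
    q_geo_pearson: float = math.nan
    q_geo_spearman: float = math.nan
    q_host_pearson: float = math.nan
    q_host_spearman: float = math.nan
    ibd_call: str = "none"
    ibh_call: str = "none"


# -------------------------------------------------------------- vectorize
def tri_indices(n: int):
    """Row-major lower-triangle indices: (1,0), (2,0), (2,1), (3,0)..."""
    iu, ju = np.tril_indices(n, k=-1)
    return iu, ju


def vectorize(D: DistanceMatrix, mask: np.ndarray | None = None) -> np.ndarray:
    """Lower-triangle values in deterministic row-major order.

    ``mask`` (length n(n-1)/2, True = keep) drops pairs that are missing in
    any matrix participating in a joint analysis. Pairs missing in ``D``
    itself are dropped as well.
    """
    iu, ju = tri_indices(D.n)
    v = D.values[iu, ju]
    keep = ~np.isnan(v)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != v.shape:
            raise ValueError("mask length must be n(n-1)/2")
        keep &= mask
    if not keep.any():
        raise ValueError("all pairs are masked or missing")
    return v[keep]


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    return (v - v.mean()) / sd


def _rank_matrix(M: np.ndarray, iu, ju) -> np.ndarray:
    """Replace off-diagonal values by average ranks of the lower triangle."""
    v = M[iu, ju]
    ok = ~np.isnan(v)
    r = np.full_like(v, np.nan)
    r[ok] = rankdata(v[ok])
    R = np.zeros_like(M)
    R[iu, ju] = r
    R[ju, iu] = r
    return R


def _permutations(n: int, n_perm: int, seed: int | None):
    """(perms, exhaustive): all n! orderings if n! <= n_perm, else sampled."""
    if math.factorial(n) <= n_perm:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        return perms, True
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    return perms, False


def _align(Dy: DistanceMatrix, Dx_list: list):
    labels = common_labels(Dy, *Dx_list)
    if len(labels) < 3:
        raise ValueError(f"need >= 3 common labels, got {len(labels)}")
    return Dy.restrict(labels), [d.restrict(labels) for d in Dx_list], labels


def _check_collinear(X: np.ndarray, names) -> None:
    k = X.shape[1]
    if k < 2:
        return
    C = np.corrcoef(X, rowvar=False)
    for i in range(k):
        for j in range(i + 1, k):
            if abs(C[i, j]) > 1 - 1e-10:
                raise ValueError(
                    f"predictors {names[i]!r} and {names[j]!r} are collinear "
                    f"(|r| = {abs(C[i, j]):.12f})"
                )


# ------------------------------------------------------------------- mrm
def mrm(
    Dy: DistanceMatrix,
    Dx_list: list,
    method: str = "pearson",
    n_perm: int = 10000,
    seed: int | None = None,
    predictor_names: tuple | None = None,
) -> MRMResult:
    """Multiple regression on distance matrices with a matrix-permutation null.

    Coefficient p-values are two-sided: the fraction of response relabelings
    whose |coefficient| reaches the observed one (with the +1 small-sample
    correction in sampled mode; exact in exhaustive mode). ``n_perm = 0``
    skips the permutation test and returns NaN p-values (coefficients only).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    Dy, Dx_list, labels = _align(Dy, Dx_list)
    n = len(labels)
    k = len(Dx_list)
    if predictor_names is None:
        predictor_names = tuple(f"x{i + 1}" for i in range(k))
    predictor_names = tuple(predictor_names)
    iu, ju = tri_indices(n)

    My = Dy.values
    Xcols = np.column_stack([d.values[iu, ju] for d in Dx_list])
    y_raw = My[iu, ju]
    pair_ok = ~np.isnan(Xcols).any(axis=1)
    obs_ok = pair_ok & ~np.isnan(y_raw)
    if obs_ok.sum() < k + 2:
        raise ValueError("too few complete pairs for regression")

    if method == "spearman":
        My_s = _rank_matrix(My, iu, ju)
        Xc = np.column_stack(
            [_rank_matrix(d.values, iu, ju)[iu, ju] for d in Dx_list]
        )
    else:
        My_s = My
        Xc = Xcols

    def fit(yv, Xv):
        yz = _zscore(yv)
        Xz = np.column_stack([_zscore(Xv[:, j]) for j in range(Xv.shape[1])])
        XtX = Xz.T @ Xz
        beta = np.linalg.solve(XtX, Xz.T @ yz)
        resid = yz - Xz @ beta
        r2 = 1.0 - (resid @ resid) / (yz @ yz)
        return beta, r2

    ys = My_s[iu, ju]
    _check_collinear(Xc[obs_ok], predictor_names)
    beta_obs, r2 = fit(ys[obs_ok], Xc[obs_ok])

    # raw-scale coefficients (with intercept) for transparency
    Xraw = np.column_stack([np.ones(obs_ok.sum()), Xcols[obs_ok]])
    raw = np.linalg.lstsq(Xraw, y_raw[obs_ok], rcond=None)[0][1:]

    if n_perm <= 0:
        return MRMResult(
            method, predictor_names, tuple(beta_obs), tuple(raw),
            tuple(math.nan for _ in range(k)), float(r2), n, int(obs_ok.sum()),
            0, False,
        )

    perms, exhaustive = _permutations(n, n_perm, seed)
    P = len(perms)

    complete = obs_ok.all() and not np.isnan(My_s[iu, ju]).any()
    if complete:
        counts = np.zeros(k)
        yz = _zscore(ys)
        Xz = np.column_stack([_zscore(Xc[:, j]) for j in range(k)])
        H = np.linalg.solve(Xz.T @ Xz, Xz.T)  # (k, m)
        mu, sd = ys.mean(), ys.std(ddof=0)
        # chunk permutations to bound memory
        chunk = max(1, int(2e7 // max(1, len(ys))))
        for s in range(0, P, chunk):
            pp = perms[s : s + chunk]
            Yp = My_s[pp[:, iu], pp[:, ju]]  # (chunk, m)
            B = ((Yp - mu) / sd) @ H.T  # (chunk, k)
            counts += (np.abs(B) >= np.abs(beta_obs)[None, :] - _TIE_EPS).sum(axis=0)
        denom = P
    else:
        counts = np.zeros(k)
        denom = 0
        for pi in perms:
            yp_raw = My[pi[iu], pi[ju]]
            ok = pair_ok & ~np.isnan(yp_raw)
            if ok.sum() < k + 2:
                continue
            if method == "spearman":
                yp = np.full_like(yp_raw, np.nan)
                yp[ok] = rankdata(yp_raw[ok])
            else:
                yp = yp_raw
            try:
                b, _ = fit(yp[ok], Xc[ok])
            except (ValueError, np.linalg.LinAlgError):
                continue
            counts += np.abs(b) >= np.abs(beta_obs) - _TIE_EPS
            denom += 1

    if exhaustive:
        p = counts / denom  # identity relabeling is included in the count
    else:
        p = (1.0 + counts) / (denom + 1.0)
    return MRMResult(
        method, predictor_names, tuple(beta_obs), tuple(raw), tuple(p),
        float(r2), n, int(obs_ok.sum()), int(denom), exhaustive,
    )


def mantel(
    Dy: DistanceMatrix,
    Dx: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 10000,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test: one-sided (upper-tail) permutation test of matrix correlation."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    Dy_a, Dx_a, labels = _align(Dy, [Dx])
    Dx_a = Dx_a[0]
    n = len(labels)
    iu, ju = tri_indices(n)

    My, Mx = Dy_a.values, Dx_a.values
    if method == "spearman":
        My_s, Mx_s = _rank_matrix(My, iu, ju), _rank_matrix(Mx, iu, ju)
    else:
        My_s, Mx_s = My, Mx

    y = My_s[iu, ju]
    x = Mx_s[iu, ju]
    ok = ~np.isnan(y) & ~np.isnan(x)
    if ok.sum() < 3:
        raise ValueError("too few complete pairs")
    r_obs = float(np.corrcoef(_zscore(y[ok]), _zscore(x[ok]))[0, 1])

    perms, exhaustive = _permutations(n, n_perm, seed)
    P = len(perms)
    complete = ok.all()
    if complete:
        xz = _zscore(x)
        m = len(y)
        mu, sd = y.mean(), y.std(ddof=0)
        count = 0
        chunk = max(1, int(2e7 // m))
        for s in range(0, P, chunk):
            pp = perms[s : s + chunk]
            Yp = My_s[pp[:, iu], pp[:, ju]]
            rp = ((Yp - mu) / sd) @ xz / m
            count += int((rp >= r_obs - _TIE_EPS).sum())
        denom = P
    else:
        count = 0
        denom = 0
        for pi in perms:
            yp = My[pi[iu], pi[ju]]
            ok_p = ~np.isnan(yp) & ~np.isnan(x)
            if ok_p.sum() < 3:
                continue
            yv = rankdata(yp[ok_p]) if method == "spearman" else yp[ok_p]
            xv = rankdata(x[ok_p]) if method == "spearman" else x[ok_p]
            try:
                rp = float(np.corrcoef(_zscore(yv), _zscore(xv))[0, 1])
            except ValueError:
                continue
            count += rp >= r_obs - _TIE_EPS
            denom += 1

    p = count / denom if exhaustive else (1.0 + count) / (denom + 1.0)
    return MantelResult(r_obs, float(p), n, int(ok.sum()), int(denom), exhaustive, method)


# ------------------------------------------------------------------- fdr
def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------- screen
def screen_sgbs(occupancy: dict, min_hosts: int = 3, min_pops: int = 2) -> list:
    """SGBs detected in >= min_hosts hosts and >= min_pops populations.

    ``occupancy`` maps sgb_id -> iterable of (host_id, site_code).
    """
    eligible = []
    for sgb, pairs in occupancy.items():
        hosts = {h for h, _ in pairs}
        sites = {s for _, s in pairs}
        if len(hosts) >= min_hosts and len(sites) >= min_pops:
            eligible.append(sgb)
    return sorted(eligible)


def _call(q1: float, q2: float, alpha: float) -> str:
    hits = (q1 < alpha) + (q2 < alpha)
    return {2: "both", 1: "either", 0: "none"}[hits]


def run_ibd_ibh_screen(
    strain_matrices: dict,
    D_mt: DistanceMatrix,
    D_geo: DistanceMatrix,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
    fdr_family_mode: str = "per_family",
) -> list:
    """Per-SGB MRM screen for IBD and IBH with BH-FDR across SGBs.

    For each SGB the model is
    ``strain distance ~ host MT distance + geographic distance``
    under both Pearson and Spearman methods. FDR is applied across SGBs
    separately within each (method x predictor) family by default
    (``fdr_family_mode="per_family"``) or jointly over all four families
    (``"joint"``). An SGB earns ``ibd_call = "both"`` when its
    geography q-value clears ``alpha`` under both methods; analogously for
    ``ibh_call`` with the host-MT q-values.

    Per-SGB permutation substreams are derived by stable hashing of the SGB
    id, so adding or removing SGBs never perturbs the others' p-values.
    """
    if fdr_family_mode not in ("per_family", "joint"):
        raise ValueError(f"unknown fdr_family_mode {fdr_family_mode!r}")
    results = []
    for sgb in sorted(strain_matrices):
        Dy = strain_matrices[sgb]
        labels = common_labels(Dy, D_mt, D_geo)
        if len(labels) < 3:
            logger.warning(
                "screen: skipping %s (only %d samples shared with metadata)",
                sgb, len(labels),
            )
            continue
        fits = {}
        for method in ("pearson", "spearman"):
            rng = substream(seed, "screen", method, sgb)
            fits[method] = mrm(
                Dy, [D_mt, D_geo], method=method, n_perm=n_perm, seed=rng,
                predictor_names=("host_mt", "geo"),
            )
        sub = Dy.restrict(labels)
        results.append(
            SGBScreenResult(
                sgb_id=sgb,
                n_hosts=len(labels),
                n_populations=0,  # filled by callers that know site codes
                pearson=fits["pearson"],
                spearman=fits["spearman"],
            )
        )
    if not results:
        return results

    families = {
        ("geo", "pearson"): [r.pearson.p_geo for r in results],
        ("geo", "spearman"): [r.spearman.p_geo for r in results],
        ("host", "pearson"): [r.pearson.p_host for r in results],
        ("host", "spearman"): [r.spearman.p_host for r in results],
    }
    if fdr_family_mode == "per_family":
        q = {key: bh_fdr(ps) for key, ps in families.items()}
    else:
        keys = list(families)
        stacked = np.concatenate([families[k] for k in keys])
        adj = bh_fdr(stacked)
        m = len(results)
        q = {k: adj[i * m : (i + 1) * m] for i, k in enumerate(keys)}

    for i, r in enumerate(results):
        r.q_geo_pearson = float(q[("geo", "pearson")][i])
        r.q_geo_spearman = float(q[("geo", "spearman")][i])
        r.q_host_pearson = float(q[("host", "pearson")][i])
        r.q_host_spearman = float(q[("host", "spearman")][i])
        r.ibd_call = _call(r.q_geo_pearson, r.q_geo_spearman, alpha)
        r.ibh_call = _call(r.q_host_pearson, r.q_host_spearman, alpha)
    return results


def screen_to_frame(results: list, occupancy: dict | None = None) -> pd.DataFrame:
    """Flatten screen results to the tabular output schema."""
    rows = []
    for r in results:
        n_pops = r.n_populations
        if occupancy is not None and r.sgb_id in occupancy:
            n_pops = len({s for _, s in occupancy[r.sgb_id]})
        rows.append(
            {
                "sgb_id": r.sgb_id,
                "n_hosts": r.n_hosts,
                "n_populations": n_pops,
                "coef_geo_pearson": r.pearson.coef_geo,
                "p_geo_pearson": r.pearson.p_geo,
                "q_geo_pearson": r.q_geo_pearson,
                "coef_geo_spearman": r.spearman.coef_geo,
                "p_geo_spearman": r.spearman.p_geo,
                "q_geo_spearman": r.q_geo_spearman,
                "coef_host_pearson": r.pearson.coef_host,
                "p_host_pearson": r.pearson.p_host,
                "q_host_pearson": r.q_host_pearson,
                "coef_host_spearman": r.spearman.coef_host,
                "p_host_spearman": r.spearman.p_host,
                "q_host_spearman": r.q_host_spearman,
                "r_squared_pearson": r.pearson.r_squared,
                "r_squared_spearman": r.spearman.r_squared,
                "ibd_call": r.ibd_call,
                "ibh_call": r.ibh_call,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- residuals
def residualize(Dy: DistanceMatrix, Dx: DistanceMatrix):
    """OLS residuals of vectorized Dy on vectorized Dx (plus intercept).

    Identity-covariance least squares; used to visualise the partial
    geographic / host signal. Returns ``(pairs, residuals)`` where ``pairs``
    is the list of (label_i, label_j) in vectorize order.
    """
    Dy_a, Dx_a, labels = _align(Dy, [Dx])
    Dx_a = Dx_a[0]
    iu, ju = tri_indices(len(labels))
    y = Dy_a.values[iu, ju]
    x = Dx_a.values[iu, ju]
    ok = ~np.isnan(y) & ~np.isnan(x)
    if ok.sum() < 3:
        raise ValueError("too few complete pairs")
    if x[ok].std(ddof=0) == 0:
        raise ValueError("zero-variance predictor")
    X = np.column_stack([np.ones(ok.sum()), x[ok]])
    beta = np.linalg.lstsq(X, y[ok], rcond=None)[0]
    resid = y[ok] - X @ beta
    pairs = [
        (labels[i], labels[j]) for i, j, keep in zip(iu, ju, ok) if keep
    ]
    return pairs, resid
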