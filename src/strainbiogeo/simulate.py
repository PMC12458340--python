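"""Synthetic worlds with known IBD/IBH ground truth.

The generator emulates the statistical structure of a continental rodent
biogeography study so every pipeline stage can be validated against known
generating parameters:

* field sites scattered uniformly over a square of continental extent,
  mapped to latitude/longitude around a mid-continent origin;
* host mitochondrial distances that increase linearly with geography plus
  noise (host isolation by distance), symmetrized and clipped at zero;
* a pure-birth bacterial phylogeny whose tips carry a sporulation
  gene-abundance trait evolved by geometric Brownian motion;
* per-SGB strain distance matrices built as linear mixtures of the
  (rescaled) geographic and host-mitochondrial layers plus Gaussian pair
  noise, with the geographic effect attenuated exponentially by relative
  sporulation ability (spore-formers disperse, so their IBD is weaker);
* Bernoulli occupancy thinning (not every host carries every SGB) and an
  optional multi-species sympatric design in which heterogeneric host
  pairs are additively inflated.

Strain distances are simulated directly at the distance-matrix level; an
optional allele-profile mode exercises the conANI machinery end to end.
"""

from __future__ import annotations

import dataclasses
import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._rng import substream
from .distmat import DistanceMatrix
from .geodist import AlleleProfile, SampleRecord, geo_distance_matrix, write_samples_tsv
from .phylo import write_newick

__all__ = [
    "ScenarioConfig",
    "SyntheticWorld",
    "make_world",
    "make_null_world",
    "make_sympatric_world",
    "simulate_allele_profiles",
    "write_world",
]

FOCAL_SPECIES = "P_maniculatus"
COMPARATOR_SPECIES = {"P_leucopus": "congeneric", "R_megalotis": "heterogeneric"}

# ~km per degree of latitude on the mean-radius sphere
_KM_PER_DEG = 111.19492664455873
_ORIGIN_LAT = 39.0
_ORIGIN_LON = -98.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of a synthetic world.

    Defaults mirror the emulated study design: 13 field sites across a
    continental (4000 km) extent, 3 hosts per site, 200 SGBs with sparse
    occupancy, host mitochondrial IBD strong but noisy (Mantel r ~ 0.5),
    moderate geographic and host effects on strain divergence, and a
    sporulation-dispersal coupling that attenuates the geographic effect.
    """

    n_sites: int = 13
    site_extent_km: float = 4000.0
    hosts_per_site: int = 3
    mt_intercept: float = 0.002
    mt_slope: float = 2e-6  # MT distance units per km
    mt_noise_sd: float = 0.003
    n_sgbs: int = 200
    occupancy_prob: float = 0.6
    beta_geo0: float = 0.4
    beta_host: float = 0.2
    sgb_baseline: float = 0.25
    sgb_noise_sd: float = 0.1
    sporulation_coupling: float = 1.0  # lambda
    bm_sigma: float = 1.0
    bm_root_log_abundance: float = 3.4  # ~30 genes at the root
    heterogeneric_delta: float = 0.1
    congeneric_delta_fraction: float = 0.25
    n_species: int = 3
    comparator_hosts_per_site: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1 or self.hosts_per_site < 1 or self.n_sgbs < 1:
            raise ValueError("n_sites, hosts_per_site, n_sgbs must be positive")
        if not (0.0 < self.occupancy_prob <= 1.0):
            raise ValueError("occupancy_prob must lie in (0, 1]")
        for name in (
            "mt_noise_sd", "sgb_noise_sd", "bm_sigma", "beta_geo0", "beta_host",
            "sporulation_coupling", "heterogeneric_delta", "site_extent_km",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticWorld:
    config: ScenarioConfig
    samples: list
    D_geo: DistanceMatrix
    D_mt: DistanceMatrix
    strain_matrices: dict
    tree: dendropy.Tree
    spor_abundance: dict
    completeness: dict
    truth: pd.DataFrame


# ------------------------------------------------------------ components
def _make_sites(cfg: ScenarioConfig, rng) -> list:
    """Uniform site coordinates on the square, as (site_code, lat, lon)."""
    xy = rng.uniform(0.0, cfg.site_extent_km, size=(cfg.n_sites, 2))
    sites = []
    for k, (x, y) in enumerate(xy):
        lat = _ORIGIN_LAT + (y - cfg.site_extent_km / 2) / _KM_PER_DEG
        lon = _ORIGIN_LON + (x - cfg.site_extent_km / 2) / (
            _KM_PER_DEG * math.cos(math.radians(_ORIGIN_LAT))
        )
        sites.append((f"SITE{k:02d}", lat, lon))
    return sites


def _make_samples(cfg: ScenarioConfig, sites, rng, sympatric: bool) -> list:
    samples = []
    idx = 0
    species_plan = [(FOCAL_SPECIES, cfg.hosts_per_site)]
    if sympatric:
        comp = list(COMPARATOR_SPECIES)[: max(0, cfg.n_species - 1)]
        species_plan += [(sp, cfg.comparator_hosts_per_site) for sp in comp]
    for site_code, lat, lon in sites:
        for sp, count in species_plan:
            for _ in range(count):
                idx += 1
                samples.append(
                    SampleRecord(
                        sample_id=f"S{idx:04d}",
                        host_id=f"H{idx:04d}",
                        host_species=sp,
                        site_code=site_code,
                        latitude=lat,
                        longitude=lon,
                        n_compared_bases=int(rng.integers(5e5, 5e6)),
                        n_snps=int(rng.integers(100, 20000)),
                    )
                )
    return samples


def _mt_matrix(cfg: ScenarioConfig, D_geo: DistanceMatrix, rng) -> DistanceMatrix:
    n = D_geo.n
    iu, ju = np.tril_indices(n, -1)
    g = D_geo.values[iu, ju]
    vals = cfg.mt_intercept + cfg.mt_slope * g + rng.normal(0.0, cfg.mt_noise_sd, g.size)
    vals = np.clip(vals, 0.0, None)
    M = np.zeros((n, n))
    M[iu, ju] = vals
    M[ju, iu] = vals
    return DistanceMatrix(M, D_geo.labels, genetic=True)


def _birth_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree with tips SGB0001..SGBnnnn.

    Branch lengths are rescaled to unit mean root-to-tip depth so that
    ``bm_sigma`` reads directly as the root-to-tip standard deviation of the
    Brownian trait (the usual normalisation in comparative-methods
    simulations).
    """
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace([f"SGB{i + 1:04d}" for i in range(n_tips)])
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        taxon_namespace=taxa,
        rng=random.Random(int(seed)),
    )
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    mean_depth = sum(depths) / len(depths)
    if mean_depth > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= mean_depth
    # the process stops at a birth event, leaving a zero-length cherry;
    # pad so every branch carries positive Brownian variance
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 1e-6:
            edge.length = 1e-3
    return tree


def _brownian_tips(tree: dendropy.Tree, sigma: float, root_value: float, rng) -> dict:
    """Brownian motion down the tree; returns tip -> value."""
    values = {}
    state = {tree.seed_node: root_value}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        b = nd.edge.length or 0.0
        state[nd] = state[nd.parent_node] + rng.normal(0.0, sigma * math.sqrt(b))
    for leaf in tree.leaf_node_iter():
        values[leaf.taxon.label] = state[leaf]
    return values


def _scaled_predictor(D: DistanceMatrix, iu, ju) -> np.ndarray:
    """Vectorized predictor z-scored then min-max rescaled to [0, 1]."""
    v = D.values[iu, ju]
    sd = v.std(ddof=0)
    z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    lo, hi = z.min(), z.max()
    return (z - lo) / (hi - lo) if hi > lo else np.zeros_like(z)


# ------------------------------------------------------------------ main
def _build_world(cfg: ScenarioConfig, sympatric: bool) -> SyntheticWorld:
    cfg.validate()
    if sympatric and cfg.n_species < 3:
        raise ValueError("sympatric worlds need n_species >= 3")
    rng_sites = substream(cfg.seed, "sites")
    sites = _make_sites(cfg, rng_sites)
    samples = _make_samples(cfg, sites, substream(cfg.seed, "samples"), sympatric)
    D_geo = geo_distance_matrix(samples)
    D_mt = _mt_matrix(cfg, D_geo, substream(cfg.seed, "mt"))

    tree = _birth_tree(cfg.n_sgbs, substream(cfg.seed, "tree").integers(2**31))
    log_spor = _brownian_tips(
        tree, cfg.bm_sigma, cfg.bm_root_log_abundance, substream(cfg.seed, "bm")
    )
    spor = {s: int(round(math.exp(v))) for s, v in log_spor.items()}
    max_spor = max(max(spor.values()), 1)

    n = len(samples)
    ids = [s.sample_id for s in samples]
    by_id = {s.sample_id: s for s in samples}
    iu, ju = np.tril_indices(n, -1)
    geo_s = _scaled_predictor(D_geo, iu, ju)
    mt_s = _scaled_predictor(D_mt, iu, ju)

    # host-pairing category per pair, for sympatric inflation
    if sympatric:
        inflation = np.zeros(iu.size)
        for k in range(iu.size):
            sa, sb = by_id[ids[iu[k]]], by_id[ids[ju[k]]]
            kinds = {sa.host_species, sb.host_species}
            if kinds == {FOCAL_SPECIES}:
                continue
            if FOCAL_SPECIES in kinds:
                other = (kinds - {FOCAL_SPECIES}).pop()
                pairing = COMPARATOR_SPECIES.get(other)
                if pairing == "congeneric":
                    inflation[k] = cfg.heterogeneric_delta * cfg.congeneric_delta_fraction
                elif pairing == "heterogeneric":
                    inflation[k] = cfg.heterogeneric_delta
            else:
                # comparator-comparator pairs: treat as heterogeneric-level
                inflation[k] = cfg.heterogeneric_delta
    else:
        inflation = None

    strain_matrices = {}
    truth_rows = []
    comp_rng = substream(cfg.seed, "completeness")
    completeness = {}
    for sgb in sorted(spor):
        rng = substream(cfg.seed, "sgb", sgb)
        beta_geo_s = cfg.beta_geo0 * math.exp(
            -cfg.sporulation_coupling * spor[sgb] / max_spor
        )
        vals = (
            cfg.sgb_baseline
            + beta_geo_s * geo_s
            + cfg.beta_host * mt_s
            + rng.normal(0.0, cfg.sgb_noise_sd, iu.size)
        )
        if inflation is not None:
            vals = vals + inflation
        vals = np.clip(vals, 0.0, 1.0)
        M = np.zeros((n, n))
        M[iu, ju] = vals
        M[ju, iu] = vals
        occupied = rng.random(n) < cfg.occupancy_prob
        occ_ids = [ids[i] for i in range(n) if occupied[i]]
        if len(occ_ids) < 2:
            occ_ids = list(ids[:2])  # degenerate draw: keep the matrix usable
        full = DistanceMatrix(M, ids, genetic=True, validate=False)
        strain_matrices[sgb] = full.restrict(occ_ids)
        completeness[sgb] = float(comp_rng.uniform(0.85, 1.0))
        truth_rows.append(
            {
                "sgb_id": sgb,
                "beta_geo_s": beta_geo_s,
                "beta_host": cfg.beta_host,
                "spor_abundance": spor[sgb],
                "n_occupied": len(occ_ids),
                "is_ibd": beta_geo_s > 0,
                "is_ibh": cfg.beta_host > 0,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("sgb_id")
    return SyntheticWorld(
        cfg, samples, D_geo, D_mt, strain_matrices, tree, spor, completeness, truth
    )


def make_world(config: ScenarioConfig) -> SyntheticWorld:
    """Single-species world with IBD/IBH mixture strain divergence."""
    return _build_world(config, sympatric=False)


def make_null_world(config: ScenarioConfig) -> SyntheticWorld:
    """As :func:`make_world` with both strain effects zeroed.

    Geography and host-mitochondria structure stay intact; strain matrices
    are pure noise — the null for type-I-error calibration.
    """
    return _build_world(
        config.replace(beta_geo0=0.0, beta_host=0.0), sympatric=False
    )


def make_sympatric_world(config: ScenarioConfig) -> SyntheticWorld:
    """Multi-species world with additive cross-species inflation."""
    return _build_world(config, sympatric=True)


# ------------------------------------------------------- allele profiles
def simulate_allele_profiles(
    sgb_id: str,
    sample_ids: list,
    pairwise_divergence: float,
    n_sites: int = 1000,
    seed: int = 0,
    contig: str = "contig_1",
    depth: int = 10,
):
    """Allele profiles whose expected pairwise 1 - conANI equals a target.

    Each sample independently substitutes reference sites at the per-sample
    rate q solving 2q(1-q) + (2/3)q^2 = p (uniform alternative alleles), so
    any two samples mismatch at rate ``pairwise_divergence`` in expectation.
    """
    p = pairwise_divergence
    if not (0.0 <= p < 1.0):
        raise ValueError("pairwise_divergence must lie in [0, 1)")
    # solve 2q - 2q^2 + (2/3) q^2 = p  =>  (4/3) q^2 - 2q + p = 0
    if p == 0.0:
        q = 0.0
    else:
        q = (2 - math.sqrt(4 - (16.0 / 3.0) * p)) / (8.0 / 3.0)
    rng = substream(seed, "profiles", sgb_id)
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, n_sites)
    profiles = []
    for sid in sample_ids:
        alleles = ref.copy()
        mutate = rng.random(n_sites) < q
        shift = rng.integers(1, 4, n_sites)
        alleles[mutate] = (alleles[mutate] + shift[mutate]) % 4
        sites = {
            (contig, int(pos)): (str(bases[alleles[pos]]), depth)
            for pos in range(n_sites)
        }
        profiles.append(AlleleProfile(sgb_id, sid, sites))
    return profiles


# ---------------------------------------------------------------- output
def write_world(world: SyntheticWorld, outdir) -> None:
    """Write the on-disk representation consumed by the pipeline CLI."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_samples_tsv(world.samples, out / "samples.tsv")
    world.D_geo.to_tsv(out / "geo.tsv")
    world.D_mt.to_tsv(out / "mt.tsv")
    (out / "matrices").mkdir(exist_ok=True)
    for sgb, D in world.strain_matrices.items():
        D.to_tsv(out / "matrices" / f"sgb_{sgb}.tsv")
    with open(out / "tree.nwk", "w") as fh:
        fh.write(write_newick(world.tree))
    pd.DataFrame(
        {"sgb_id": list(world.spor_abundance), "trait_name": "sporulation",
         "abundance": list(world.spor_abundance.values())}
    ).to_csv(out / "sporulation.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"sgb_id": list(world.completeness), "completeness": list(world.completeness.values())}
    ).to_csv(out / "completeness.tsv", sep="\t", index=False)
    world.truth.to_csv(out / "truth.tsv", sep="\t")
    with open(out / "scenario.json", "w") as fh:
        json.dump(world.config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
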