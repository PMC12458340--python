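"""Config-driven orchestration: screen -> traits -> sympatry.

Functions here read the standard on-disk layout (sample metadata TSV,
square distance-matrix TSVs, newick tree, trait tables), compose the
analysis modules, and write result tables plus a JSON run manifest
(resolved config, input checksums, package version) sufficient to
re-execute a run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distmat import DistanceMatrix, common_labels
from .geodist import geo_distance_matrix, read_samples_tsv, retain_one_sample_per_host
from .matrixtests import (
    residualize,
    run_ibd_ibh_screen,
    screen_sgbs,
    screen_to_frame,
)
from .phylo import (
    binary_trait_association,
    count_trait_genes,
    read_newick_file,
    trait_eligibility,
    trait_pipeline_regression,
)
from .sympatry import (
    build_pairings,
    mean_of_means_test,
    pairings_to_frame,
    sympatric_sgb_tests,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_screen", "run_traits", "run_sympatry", "load_world_dir"]


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run (study values as defaults)."""

    data_dir: str = "."
    out_dir: str = "results"
    alpha: float = 0.05
    n_perm_mrm: int = 10000
    n_perm_trait: int = 100000
    n_perm_ttest: int = 10000
    min_hosts: int = 3
    min_pops: int = 2
    min_completeness: float = 0.90
    min_trait_samples: int = 4
    min_shared_sites: int = 50
    seed: int = 0
    fdr_family_mode: str = "per_family"
    focal_species: str = "P_maniculatus"
    comparator_species: dict = field(
        default_factory=lambda: {"P_leucopus": "congeneric", "R_megalotis": "heterogeneric"}
    )

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("n_perm_mrm", "n_perm_trait", "n_perm_ttest"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_hosts < 3:
            raise ValueError("min_hosts must be >= 3 (MRM needs 3 samples)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


# ------------------------------------------------------------------- io
def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _write_manifest(cfg: RunConfig, stage: str, inputs: list, outdir: Path) -> None:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "config": cfg.to_dict(),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()},
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_world_dir(data_dir):
    """Read samples, geo/mt matrices and per-SGB strain matrices from disk."""
    d = Path(data_dir)
    samples = read_samples_tsv(d / "samples.tsv")
    geo_path = d / "geo.tsv"
    if geo_path.is_file():
        D_geo = DistanceMatrix.read_tsv(geo_path)
    else:
        D_geo = geo_distance_matrix(samples)
    D_mt = DistanceMatrix.read_tsv(d / "mt.tsv", genetic=True)
    strain = {}
    for p in sorted((d / "matrices").glob("sgb_*.tsv")):
        sgb = p.stem[len("sgb_"):]
        strain[sgb] = DistanceMatrix.read_tsv(p, genetic=True)
    if not strain:
        raise FileNotFoundError(f"no matrices/sgb_*.tsv found under {d}")
    return samples, D_geo, D_mt, strain


def _occupancy(strain: dict, samples: list) -> dict:
    by_id = {s.sample_id: s for s in samples}
    occ = {}
    for sgb, D in strain.items():
        occ[sgb] = {
            (by_id[x].host_id, by_id[x].site_code) for x in D.labels if x in by_id
        }
    return occ


def _check_label_overlap(strain: dict, samples: list) -> None:
    known = {s.sample_id for s in samples}
    for sgb, D in strain.items():
        extra = set(D.labels) - known
        if extra:
            raise ValueError(
                f"SGB {sgb}: matrix labels absent from sample metadata: {sorted(extra)[:10]}"
            )


# ---------------------------------------------------------------- stages
def run_screen(cfg: RunConfig):
    """Per-SGB IBD/IBH MRM screen plus visualization residuals.

    Returns the screen DataFrame; writes screen.tsv, residuals.tsv and a
    manifest under ``cfg.out_dir``.
    """
    cfg.validate()
    d = Path(cfg.data_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, D_geo, D_mt, strain = load_world_dir(d)
    _check_label_overlap(strain, samples)
    samples = retain_one_sample_per_host(samples)
    keep_ids = {s.sample_id for s in samples}
    strain = {
        sgb: D.restrict([x for x in D.labels if x in keep_ids])
        for sgb, D in strain.items()
        if sum(x in keep_ids for x in D.labels) >= 2
    }

    occ = _occupancy(strain, samples)
    eligible = screen_sgbs(occ, min_hosts=cfg.min_hosts, min_pops=cfg.min_pops)
    logger.info("screen: %d/%d SGBs pass occupancy filter", len(eligible), len(strain))
    strain_el = {sgb: strain[sgb] for sgb in eligible}

    results = run_ibd_ibh_screen(
        strain_el, D_mt, D_geo,
        alpha=cfg.alpha, n_perm=cfg.n_perm_mrm, seed=cfg.seed,
        fdr_family_mode=cfg.fdr_family_mode,
    )
    table = screen_to_frame(results, occ)
    table.to_csv(out / "screen.tsv", sep="\t", index=False)

    # residuals of strain ~ MT (plotted vs geography) per SGB
    rows = []
    for sgb in eligible:
        Dy = strain_el[sgb]
        labels = common_labels(Dy, D_mt, D_geo)
        if len(labels) < 3:
            continue
        try:
            pairs, resid = residualize(Dy.restrict(labels), D_mt.restrict(labels))
        except ValueError:
            continue
        geo_r = D_geo.restrict(labels)
        mt_r = D_mt.restrict(labels)
        for (a, b), r in zip(pairs, resid):
            rows.append(
                {
                    "sgb_id": sgb,
                    "sample_i": a,
                    "sample_j": b,
                    "residual": r,
                    "geographic_distance": geo_r[a, b],
                    "mt_distance": mt_r[a, b],
                }
            )
    pd.DataFrame(rows).to_csv(out / "residuals.tsv", sep="\t", index=False)

    inputs = [d / "samples.tsv", d / "geo.tsv", d / "mt.tsv"]
    inputs += sorted((d / "matrices").glob("sgb_*.tsv"))
    _write_manifest(cfg, "screen", inputs, out)
    return table


def _ibd_strength_from_screen(screen_table: pd.DataFrame) -> dict:
    return dict(zip(screen_table["sgb_id"], screen_table["coef_geo_pearson"]))


def run_traits(cfg: RunConfig, screen_table: pd.DataFrame | None = None):
    """Trait gene-abundance PIC regressions and binary-trait associations.

    IBD strength per SGB is the standardized Pearson MRM geographic
    coefficient from the screen stage. Gene-abundance inputs come either
    from ``gene_annotations.tsv`` + ``curated_<trait>.txt`` lists (counted
    here) or directly from an abundance table ``sporulation.tsv`` /
    ``trait_abundance.tsv``. Binary calls, if present, are read from
    ``binary_traits.tsv``.
    """
    cfg.validate()
    d = Path(cfg.data_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if screen_table is None:
        screen_path = out / "screen.tsv"
        if not screen_path.is_file():
            raise FileNotFoundError("run the screen stage first (screen.tsv not found)")
        screen_table = pd.read_csv(screen_path, sep="\t")
    ibd_strength = _ibd_strength_from_screen(screen_table)

    tree = read_newick_file(d / "tree.nwk")

    # gene abundances per trait category
    abundances: dict = {}
    ann_path = d / "gene_annotations.tsv"
    if ann_path.is_file():
        ann = pd.read_csv(ann_path, sep="\t", dtype=str)
        table = {sgb: set(grp["gene_id"]) for sgb, grp in ann.groupby("sgb_id")}
        for lst in sorted(d.glob("curated_*.txt")):
            trait = lst.stem[len("curated_"):]
            with open(lst) as fh:
                curated = {line.strip() for line in fh if line.strip()}
            if not curated:
                raise ValueError(f"curated list {lst.name} is empty")
            abundances[trait] = count_trait_genes(table, curated)
    for cand in ("sporulation.tsv", "trait_abundance.tsv"):
        p = d / cand
        if p.is_file():
            df = pd.read_csv(p, sep="\t", dtype={"sgb_id": str})
            for trait, grp in df.groupby("trait_name"):
                abundances[str(trait)] = dict(
                    zip(grp["sgb_id"], grp["abundance"].astype(float))
                )
    if not abundances:
        raise FileNotFoundError("no gene-abundance inputs found (annotations or abundance table)")

    # eligibility: completeness + occupancy
    comp_path = d / "completeness.tsv"
    if comp_path.is_file():
        comp_df = pd.read_csv(comp_path, sep="\t", dtype={"sgb_id": str})
        completeness = dict(zip(comp_df["sgb_id"], comp_df["completeness"].astype(float)))
    else:
        completeness = {sgb: 1.0 for sgb in ibd_strength}
    samples, _, _, strain = load_world_dir(d)
    occ = {sgb: D.labels for sgb, D in strain.items()}
    eligible = set(
        trait_eligibility(
            completeness, occ,
            min_completeness=cfg.min_completeness,
            min_samples=cfg.min_trait_samples,
        )
    ) & set(ibd_strength)

    rows = []
    for trait, ab in sorted(abundances.items()):
        ab_el = {s: v for s, v in ab.items() if s in eligible}
        res = trait_pipeline_regression(
            tree, ab_el, ibd_strength,
            n_perm=cfg.n_perm_trait, seed=cfg.seed, substream_key=f"traits/{trait}",
        )
        rows.append(
            {
                "trait_name": trait,
                "slope": res.slope,
                "p_one_sided_negative": res.p_one_sided_negative,
                "n_contrasts_used": res.n_contrasts_used,
                "n_outliers_removed": res.n_outliers_removed,
                "n_perm": res.n_perm,
            }
        )
    trait_table = pd.DataFrame(rows)
    trait_table.to_csv(out / "trait_regressions.tsv", sep="\t", index=False)

    # binary traits (e.g. classifier consensus calls); NA = no consensus
    bin_path = d / "binary_traits.tsv"
    bin_rows = []
    if bin_path.is_file():
        bt = pd.read_csv(bin_path, sep="\t", dtype={"sgb_id": str}, na_values=["NA"])
        for trait, grp in bt.groupby("trait_name"):
            calls = {
                r.sgb_id: (None if pd.isna(r.call) else int(r.call))
                for r in grp.itertuples(index=False)
                if r.sgb_id in eligible
            }
            try:
                slope, p, n_used = binary_trait_association(calls, ibd_strength)
            except ValueError as exc:
                logger.warning("binary trait %s skipped: %s", trait, exc)
                continue
            bin_rows.append(
                {"trait_name": trait, "slope": slope, "p": p, "n_sgb": n_used}
            )
    pd.DataFrame(bin_rows, columns=["trait_name", "slope", "p", "n_sgb"]).to_csv(
        out / "binary_trait_associations.tsv", sep="\t", index=False
    )

    inputs = [d / "tree.nwk", d / "sporulation.tsv", d / "completeness.tsv"]
    _write_manifest(cfg, "traits", inputs, out)
    return trait_table


def run_sympatry(cfg: RunConfig):
    """Sympatric host-pairing comparisons with FDR and mean-of-means tests."""
    cfg.validate()
    d = Path(cfg.data_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, _, _, strain = load_world_dir(d)
    samples = retain_one_sample_per_host(samples)
    if len({s.host_species for s in samples}) < 2:
        raise ValueError("sympatry analysis needs >= 2 host species in metadata")
    pairings = build_pairings(
        strain, samples, cfg.focal_species, cfg.comparator_species
    )
    pairings_to_frame(pairings).to_csv(out / "pairings.tsv", sep="\t", index=False)
    tests = sympatric_sgb_tests(
        pairings, alpha=cfg.alpha, n_perm=cfg.n_perm_ttest, seed=cfg.seed
    )
    tests.to_csv(out / "sympatry_tests.tsv", sep="\t", index=False)

    mm_rows = []
    for contrast in (("conspecific", "congeneric"), ("congeneric", "heterogeneric")):
        try:
            from ._rng import substream

            p, diff = mean_of_means_test(
                pairings, contrast, n_perm=cfg.n_perm_ttest,
                seed=substream(cfg.seed, "mean_of_means", *contrast),
            )
        except ValueError as exc:
            logger.warning("mean-of-means %s skipped: %s", contrast, exc)
            continue
        mm_rows.append(
            {"contrast": f"{contrast[0]}_vs_{contrast[1]}", "mean_diff": diff, "p": p}
        )
    pd.DataFrame(mm_rows, columns=["contrast", "mean_diff", "p"]).to_csv(
        out / "mean_of_means.tsv", sep="\t", index=False
    )
    _write_manifest(cfg, "sympatry", [d / "samples.tsv"], out)
    return tests
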