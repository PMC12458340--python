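"""Observational distance layers: conANI strain distances and geography.

Two kinds of pairwise distance enter the isolation-by-distance /
isolation-by-host analysis:

* **strain genetic distance**, ``1 - conANI``, where conANI compares the
  consensus (major) allele of two samples at every genomic site covered in
  both;
* **geographic distance**, the great-circle (haversine) distance between the
  sampling coordinates of the two hosts.

This module also implements the one-sample-per-host retention rule used when
a host was sampled repeatedly: keep the sample with the best microdiversity
profile, judged by mean rank of compared bases and SNP count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .distmat import DistanceMatrix

__all__ = [
    "EARTH_RADIUS_KM",
    "SampleRecord",
    "AlleleProfile",
    "haversine_km",
    "geo_distance_matrix",
    "conani",
    "strain_distance_matrix",
    "retain_one_sample_per_host",
    "read_samples_tsv",
    "write_samples_tsv",
    "read_allele_profiles_tsv",
    "write_allele_profiles_tsv",
]

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: Default minimum number of shared genomic sites for a valid conANI pair.
DEFAULT_MIN_SHARED_SITES = 50


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced fecal sample with host and site metadata."""

    sample_id: str
    host_id: str
    host_species: str
    site_code: str
    latitude: float
    longitude: float
    n_compared_bases: int | None = None
    n_snps: int | None = None

    def __post_init__(self) -> None:
        _check_coords(self.latitude, self.longitude)
        for name in ("n_compared_bases", "n_snps"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass
class AlleleProfile:
    """Per-sample major-allele profile for one species-level genome bin.

    ``sites`` maps (contig, 0-based position) to (major allele, depth).
    """

    sgb_id: str
    sample_id: str
    sites: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, (allele, depth) in self.sites.items():
            if allele not in "ACGT":
                raise ValueError(f"invalid allele {allele!r} at {key}")
            if depth < 1:
                raise ValueError(f"depth must be >= 1 at {key}, got {depth}")


def _check_coords(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0):
        raise ValueError(f"latitude out of range [-90, 90]: {lat}")
    if not (-180.0 <= lon <= 180.0):
        raise ValueError(f"longitude out of range [-180, 180]: {lon}")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def geo_distance_matrix(samples: list) -> DistanceMatrix:
    """Complete pairwise haversine matrix over sample coordinates."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids")
    lat = np.radians([s.latitude for s in samples])
    lon = np.radians([s.longitude for s in samples])
    dphi = lat[:, None] - lat[None, :]
    dlam = lon[:, None] - lon[None, :]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids)


def conani(a: AlleleProfile, b: AlleleProfile, min_depth: int = 1):
    """Consensus ANI between two profiles of the same SGB.

    Restricts to sites covered in both profiles with depth >= ``min_depth``
    in both, then counts major-allele agreement.

    Returns
    -------
    (ani, n_shared)
        ``ani`` is None when no site qualifies.
    """
    if a.sgb_id != b.sgb_id:
        raise ValueError(f"profiles are from different SGBs: {a.sgb_id} vs {b.sgb_id}")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    matches = 0
    shared = 0
    small, big = (a.sites, b.sites) if len(a.sites) <= len(b.sites) else (b.sites, a.sites)
    for key, (allele1, depth1) in small.items():
        other = big.get(key)
        if other is None:
            continue
        allele2, depth2 = other
        if depth1 < min_depth or depth2 < min_depth:
            continue
        shared += 1
        if allele1 == allele2:
            matches += 1
    if shared == 0:
        return None, 0
    return matches / shared, shared


def strain_distance_matrix(
    profiles: list,
    min_depth: int = 1,
    min_shared_sites: int = DEFAULT_MIN_SHARED_SITES,
) -> DistanceMatrix:
    """Pairwise 1 - conANI matrix for one SGB.

    Pairs with fewer than ``min_shared_sites`` qualifying shared sites are
    recorded as missing (NA) rather than trusted as distances.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    sgbs = {p.sgb_id for p in profiles}
    if len(sgbs) != 1:
        raise ValueError(f"profiles span multiple SGBs: {sorted(sgbs)}")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids among profiles")
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ani, shared = conani(profiles[i], profiles[j], min_depth=min_depth)
            if ani is None or shared < min_shared_sites:
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = 1.0 - ani
    return DistanceMatrix(d, ids, genetic=True)


def retain_one_sample_per_host(samples: list) -> list:
    """Keep one sample per host: best mean rank of compared bases and SNPs.

    Ties break to the lexicographically smallest sample_id. Input order of
    hosts is preserved.
    """
    by_host: dict = {}
    for s in samples:
        by_host.setdefault(s.host_id, []).append(s)
    kept = []
    for host, group in by_host.items():
        if len(group) == 1:
            kept.append(group[0])
            continue
        for s in group:
            if s.n_compared_bases is None or s.n_snps is None:
                raise ValueError(
                    f"sample {s.sample_id}: QC fields required to choose among "
                    f"{len(group)} samples of host {host}"
                )
        bases = rankdata([s.n_compared_bases for s in group])
        snps = rankdata([s.n_snps for s in group])
        score = (bases + snps) / 2.0
        best = max(zip(score, group), key=lambda t: (t[0], _neg_lex(t[1].sample_id)))
        kept.append(best[1])
    return kept


class _neg_lex(str):
    """Reverse lexicographic comparison, so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


# ---------------------------------------------------------------------- io
_SAMPLE_COLUMNS = [
    "sample_id",
    "host_id",
    "host_species",
    "site_code",
    "latitude",
    "longitude",
    "n_compared_bases",
    "n_snps",
]


def read_samples_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "host_id": str, "site_code": str})
    required = _SAMPLE_COLUMNS[:6]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"samples table missing required columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        qc = {}
        for col in ("n_compared_bases", "n_snps"):
            if col in df.columns:
                v = getattr(row, col)
                qc[col] = None if pd.isna(v) else int(v)
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                host_id=str(row.host_id),
                host_species=str(row.host_species),
                site_code=str(row.site_code),
                latitude=float(row.latitude),
                longitude=float(row.longitude),
                **qc,
            )
        )
    return records


def write_samples_tsv(samples: list, path) -> None:
    pd.DataFrame([{c: getattr(s, c) for c in _SAMPLE_COLUMNS} for s in samples]).to_csv(
        path, sep="\t", index=False
    )


def read_allele_profiles_tsv(path) -> dict:
    """Long-format profile TSV -> {sgb_id: [AlleleProfile, ...]}.

    Columns: sgb_id, sample_id, contig, position, major_allele, depth.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sgb_id": str, "sample_id": str, "contig": str})
    out: dict = {}
    for (sgb, sample), grp in df.groupby(["sgb_id", "sample_id"], sort=True):
        sites = {}
        for row in grp.itertuples(index=False):
            key = (row.contig, int(row.position))
            if key in sites:
                raise ValueError(f"duplicate site {key} for {sgb}/{sample}")
            sites[key] = (row.major_allele, int(row.depth))
        out.setdefault(sgb, []).append(AlleleProfile(sgb, sample, sites))
    return out


def write_allele_profiles_tsv(profiles: list, path) -> None:
    rows = []
    for p in profiles:
        for (contig, pos), (allele, depth) in sorted(p.sites.items()):
            rows.append(
                {
                    "sgb_id": p.sgb_id,
                    "sample_id": p.sample_id,
                    "contig": contig,
                    "position": pos,
                    "major_allele": allele,
                    "depth": depth,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
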