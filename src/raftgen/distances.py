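"""Chord genetic distances, geographic distances and habitat-gap matrices.

The chord distance between two allele-frequency vectors p and q at one
locus uses the bounded convention

    d = (2/pi) * sqrt(2 * (1 - sum_a sqrt(p_a q_a)))

averaged arithmetically over loci.  With the INA option the vectors are
EM-corrected visible frequencies augmented with the null class as one
shared allelic state (each vector sums to 1 including the null), which
is how null alleles are "included" in the distance.

Geographic distances are an input whenever real marine routes matter; a
great-circle matrix from site coordinates is a documented fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import AlleleFrequencyTable, GenotypeDataset, SampleSite, allele_frequencies
from .null_alleles import corrected_frequencies

EARTH_RADIUS_KM = 6371.0088
CHORD_MAX = (2.0 / math.pi) * math.sqrt(2.0)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = "genetic_DC"  # genetic_DC | geographic_km | gap_indicator

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        if self.kind == "gap_indicator":
            off = v[~np.eye(len(self.labels), dtype=bool)]
            if not np.isin(off, (0.0, 1.0)).all():
                raise ValueError("gap indicator entries must be 0 or 1")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "geographic_km") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(l) for l in df.index], df.to_numpy(dtype=float), kind)


# ---------------------------------------------------------------------
# Chord distance


def chord_distance_per_locus(p: dict[int, float], q: dict[int, float]) -> float:
    """Single-locus chord distance over the union of the allele universes."""
    labels = set(p) | set(q)
    s = sum(math.sqrt(p.get(a, 0.0) * q.get(a, 0.0)) for a in labels)
    return (2.0 / math.pi) * math.sqrt(2.0 * max(1.0 - s, 0.0))


def chord_distance(
    table: AlleleFrequencyTable, pop_a: str, pop_b: str
) -> float:
    """Mean over loci of the per-locus chord distance between two populations."""
    ds = []
    for locus in table.loci:
        ca, cb = table.cell(pop_a, locus), table.cell(pop_b, locus)
        if not (ca.available and cb.available):
            raise ValueError(f"cell unavailable at locus {locus}")
        ds.append(chord_distance_per_locus(dict(ca.freqs), dict(cb.freqs)))
    return float(np.mean(ds))


def dc_matrix(
    dataset: GenotypeDataset,
    ina: bool = True,
    blank_mode: str = "blanks-as-nulls",
    table: AlleleFrequencyTable | None = None,
) -> DistanceMatrix:
    """All-pairs chord distance matrix, null-corrected (INA) by default."""
    if table is None:
        table = (
            corrected_frequencies(dataset, blank_mode, include_null=True)
            if ina
            else allele_frequencies(dataset)
        )
    pops = table.populations
    n = len(pops)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = chord_distance(table, pops[i], pops[j])
    return DistanceMatrix(list(pops), values, "genetic_DC")


def delta_dc(matrix_a: DistanceMatrix, matrix_b: DistanceMatrix) -> dict[str, float]:
    """Leave-one-locus-out style comparison of two D_C matrices.

    Returns the Pearson correlation of the vectorized upper triangles
    and the mean and sample SD of the absolute entry-wise differences.
    """
    if matrix_a.labels != matrix_b.labels:
        raise ValueError("matrices must share labels")
    ua, ub = matrix_a.upper_triangle(), matrix_b.upper_triangle()
    diffs = np.abs(ua - ub)
    r = float(np.corrcoef(ua, ub)[0, 1]) if len(ua) > 1 else 1.0
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    return {"pearson_r": r, "mean_abs_delta": float(diffs.mean()), "sd_abs_delta": sd}


# ---------------------------------------------------------------------
# Geographic and habitat-gap matrices


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def great_circle_matrix(sites: Sequence[SampleSite]) -> DistanceMatrix:
    n = len(sites)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(
                sites[i].latitude, sites[i].longitude,
                sites[j].latitude, sites[j].longitude,
            )
            values[i, j] = values[j, i] = d
    return DistanceMatrix([s.site_id for s in sites], values, "geographic_km")


def gap_matrix(
    sites: Sequence[SampleSite], gap_spec: tuple[Sequence[str], Sequence[str]]
) -> DistanceMatrix:
    """Binary habitat-discontinuity indicator: 1 iff a pair spans the gap.

    ``gap_spec`` partitions the site ids into the two groups on either
    side of the discontinuity.
    """
    group_a, group_b = set(gap_spec[0]), set(gap_spec[1])
    ids = [s.site_id for s in sites]
    if group_a & group_b:
        raise ValueError("gap groups overlap")
    if set(ids) != group_a | group_b:
        raise ValueError("gap groups must partition the site ids")
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            spans = (ids[i] in group_a) != (ids[j] in group_a)
            values[i, j] = values[j, i] = 1.0 if spans else 0.0
    return DistanceMatrix(ids, values, "gap_indicator")
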