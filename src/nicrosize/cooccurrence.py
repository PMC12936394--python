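"""Equal-area gridding of occurrences and the co-occurrence (richness) analysis.

Occurrence points are projected with a world cylindrical equal-area
projection (standard parallel 0, spherical WGS84 authalic radius) and binned
into 200 km x 200 km (40,000 km^2) cells. Cells with fewer than a minimum
number of records are dropped, richness (number of species present) is
classed 1..6 and "7+", and the per-cell size extremes — min/max/mean of the
*global* species mean widths of the species present — are compared across
richness classes with a one-way ANOVA.

The random-assemblage null asks how much of the spread of extremes is pure
sampling: a cell with k species is simulated as k independent uniform(4, 11)
draws, 50 cells per richness level, and the expected min/mean/max per level
is averaged over replicates. The expected maximum of k uniforms is
lo + (hi - lo) * k / (k + 1), so the null "divergence" of the maximum from
the 7.5 mm midpoint saturates quickly with k.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import OccurrenceRecord

__all__ = [
    "EARTH_RADIUS_M",
    "GridCellSummary",
    "AnovaResult",
    "AssemblageNullResult",
    "project_equal_area",
    "inverse_equal_area",
    "assign_cells",
    "summarize_cells",
    "cells_frame",
    "observed_by_richness",
    "oneway_anova",
    "richness_anovas",
    "random_assemblage_null",
    "cells_geojson",
]

#: authalic (equal-area) sphere radius for WGS84, metres
EARTH_RADIUS_M = 6_371_007.181


@dataclass(frozen=True)
class GridCellSummary:
    cell_id: tuple[int, int]
    n_records: int
    species: frozenset[str]
    k: int  # richness: number of species present
    k_class: str  # "1".."6" or "7+"
    min_species_mean_mm: float
    max_species_mean_mm: float
    mean_species_mean_mm: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class AssemblageNullResult:
    """Null expectations of per-cell size statistics by richness level."""

    table: pd.DataFrame  # index k=1..k_max; columns mean_min/mean/max with CIs
    reps: int
    squares_per_k: int
    lo: float
    hi: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def divergence_max(self, k: int) -> float:
        """Null divergence of the mean maximum from the overall null mean."""
        return float(self.table.loc[k, "mean_max"] - self.midpoint)

    def divergence_increment(self, k_from: int, k_to: int) -> float:
        return self.divergence_max(k_to) - self.divergence_max(k_from)


def project_equal_area(latitude, longitude):
    """Cylindrical equal-area forward projection (degrees -> metres)."""
    lat = np.radians(np.asarray(latitude, dtype=float))
    lon = np.radians(np.asarray(longitude, dtype=float))
    return EARTH_RADIUS_M * lon, EARTH_RADIUS_M * np.sin(lat)


def inverse_equal_area(x, y):
    """Inverse of :func:`project_equal_area` (metres -> degrees)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = np.degrees(x / EARTH_RADIUS_M)
    lat = np.degrees(np.arcsin(np.clip(y / EARTH_RADIUS_M, -1.0, 1.0)))
    return lat, lon


def assign_cells(
    records: Sequence[OccurrenceRecord], cell_m: float = 200_000.0
) -> list[tuple[int, int]]:
    """Cell id (floor(x/cell), floor(y/cell)) per record, in record order."""
    lats = np.array([r.latitude for r in records])
    lons = np.array([r.longitude for r in records])
    x, y = project_equal_area(lats, lons)
    ix = np.floor(x / cell_m).astype(int)
    iy = np.floor(y / cell_m).astype(int)
    return list(zip(ix.tolist(), iy.tolist()))


def summarize_cells(
    records: Sequence[OccurrenceRecord],
    species_means: Mapping[str, float],
    min_records: int = 10,
    k_cap: int = 7,
    cell_m: float = 200_000.0,
) -> list[GridCellSummary]:
    """Per-cell record counts, richness and size extremes.

    Cells with fewer than ``min_records`` records are dropped. Extremes are
    computed over the global species mean widths of the species present;
    every species in the records must have a mean. Richness >= ``k_cap`` is
    pooled into the "``k_cap``+" class.
    """
    missing = sorted({r.species for r in records} - set(species_means))
    if missing:
        raise ValueError(f"species without a global mean width: {missing}")
    cells = assign_cells(records, cell_m=cell_m)
    by_cell: dict[tuple[int, int], list[str]] = {}
    for cid, rec in zip(cells, records):
        by_cell.setdefault(cid, []).append(rec.species)
    out = []
    for cid in sorted(by_cell):
        specs = by_cell[cid]
        if len(specs) < min_records:
            continue
        uniq = frozenset(specs)
        means = np.array([species_means[s] for s in uniq])
        k = len(uniq)
        out.append(GridCellSummary(
            cell_id=cid, n_records=len(specs), species=uniq, k=k,
            k_class=(f"{k_cap}+" if k >= k_cap else str(k)),
            min_species_mean_mm=float(means.min()),
            max_species_mean_mm=float(means.max()),
            mean_species_mean_mm=float(means.mean()),
        ))
    return out


def cells_frame(cells: Sequence[GridCellSummary]) -> pd.DataFrame:
    return pd.DataFrame({
        "cell_x": [c.cell_id[0] for c in cells],
        "cell_y": [c.cell_id[1] for c in cells],
        "n_records": [c.n_records for c in cells],
        "k": [c.k for c in cells],
        "k_class": [c.k_class for c in cells],
        "min_mm": [c.min_species_mean_mm for c in cells],
        "max_mm": [c.max_species_mean_mm for c in cells],
        "mean_mm": [c.mean_species_mean_mm for c in cells],
    })


def observed_by_richness(cells: Sequence[GridCellSummary]) -> pd.DataFrame:
    """Mean min/mean/max (with 1.96-SE CIs) per richness class."""
    df = cells_frame(cells)
    rows = []
    for kc, grp in df.groupby("k_class"):
        row = {"k_class": kc, "n_cells": len(grp)}
        for col, name in (("min_mm", "min"), ("mean_mm", "mean"), ("max_mm", "max")):
            v = grp[col].to_numpy()
            m = v.mean()
            se = v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else 0.0
            row[f"mean_{name}"] = m
            row[f"mean_{name}_lo"] = m - 1.96 * se
            row[f"mean_{name}_hi"] = m + 1.96 * se
        rows.append(row)
    out = pd.DataFrame(rows)
    out["order"] = out["k_class"].map(lambda s: int(s.rstrip("+")))
    return out.sort_values("order").drop(columns="order").set_index("k_class")


def oneway_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across the groups."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 1 for a in arrays):
        raise ValueError("every ANOVA group must be nonempty")
    F, p = stats.f_oneway(*arrays)
    g = len(arrays)
    N = sum(a.size for a in arrays)
    return AnovaResult(F=float(F), df_between=g - 1, df_within=N - g, p=float(p))


def richness_anovas(cells: Sequence[GridCellSummary]) -> dict[str, AnovaResult]:
    """ANOVA of per-cell max/mean/min size by richness class."""
    df = cells_frame(cells)
    out = {}
    for col, name in (("max_mm", "maximum"), ("mean_mm", "mean"), ("min_mm", "minimum")):
        groups = {kc: grp[col].tolist() for kc, grp in df.groupby("k_class")}
        out[name] = oneway_anova(groups)
    return out


def random_assemblage_null(
    squares_per_k: int = 50,
    reps: int = 1000,
    lo: float = 4.0,
    hi: float = 11.0,
    k_max: int = 7,
    seed: int = 0,
) -> AssemblageNullResult:
    """Random-assemblage null for size extremes by richness.

    For each richness level k = 1..k_max, each replicate simulates
    ``squares_per_k`` cells of k uniform(lo, hi) species sizes and records the
    per-cell min, mean and max; level summaries average over all cells of all
    replicates, with normal-approximation 95% CIs across cells.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, k_max + 1):
        draws = rng.uniform(lo, hi, size=(reps * squares_per_k, k))
        row = {"k": k}
        for stat_name, vals in (("min", draws.min(axis=1)),
                                ("mean", draws.mean(axis=1)),
                                ("max", draws.max(axis=1))):
            m = float(vals.mean())
            se = float(vals.std(ddof=1) / math.sqrt(vals.size))
            row[f"mean_{stat_name}"] = m
            row[f"mean_{stat_name}_lo"] = m - 1.96 * se
            row[f"mean_{stat_name}_hi"] = m + 1.96 * se
        rows.append(row)
    table = pd.DataFrame(rows).set_index("k")
    return AssemblageNullResult(table=table, reps=reps, squares_per_k=squares_per_k,
                                lo=lo, hi=hi)


def cells_geojson(cells: Sequence[GridCellSummary], cell_m: float = 200_000.0) -> str:
    """GeoJSON FeatureCollection of cell polygons (lat/lon corners) for mapping."""
    feats = []
    for c in cells:
        ix, iy = c.cell_id
        xs = [ix * cell_m, (ix + 1) * cell_m]
        ys = [iy * cell_m, (iy + 1) * cell_m]
        corners = [(xs[0], ys[0]), (xs[1], ys[0]), (xs[1], ys[1]), (xs[0], ys[1]), (xs[0], ys[0])]
        ring = []
        for x, y in corners:
            lat, lon = inverse_equal_area(x, y)
            ring.append([float(lon), float(lat)])
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"cell_x": ix, "cell_y": iy, "n_records": c.n_records,
                           "k": c.k, "k_class": c.k_class,
                           "min_mm": c.min_species_mean_mm,
                           "max_mm": c.max_species_mean_mm,
                           "mean_mm": c.mean_species_mean_mm},
        })
    return json.dumps({"type": "FeatureCollection", "features": feats})
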