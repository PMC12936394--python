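"""Occurrence-table and phylogeny input/output.

The occurrence table is the package's primary data format: one row per
specimen (museum) or literature record of a burying beetle, carrying the
species name, sex, pronotal width in millimetres (the standard beetle
body-size proxy), decimal WGS84 coordinates and the record source.
Literature records may lack a measured width; they are later imputed from
museum measurements of the same species (and sex, when known).

Trees are dated ultrametric phylogenies in Newick with branch lengths in
millions of years (Ma); :class:`DatedTree` wraps a dendropy tree and adds
the comparative machinery the analysis needs (tip depths, the Brownian
variance-covariance matrix, cherry enumeration).
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceRecord",
    "RowError",
    "SpeciesSummary",
    "DatedTree",
    "OccurrenceTableError",
    "read_occurrence_table",
    "write_occurrence_table",
    "impute_literature_widths",
    "species_summaries",
    "summaries_frame",
    "read_newick",
]

SEXES = ("male", "female", "unknown")
SOURCES = ("museum", "literature")

OCCURRENCE_HEADER = ("species", "sex", "pronotal_width_mm", "latitude", "longitude", "source")

#: hard plausibility bound on pronotal width (mm); no burying beetle approaches it
MAX_WIDTH_MM = 20.0


class OccurrenceTableError(ValueError):
    """Fatal problem with an occurrence table (missing file, empty, bad header)."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """One specimen or literature record."""

    species: str
    sex: str  # male | female | unknown
    width_mm: float | None  # pronotal width, mm; None only for literature records
    latitude: float  # decimal degrees, WGS84
    longitude: float
    source: str  # museum | literature


@dataclass(frozen=True)
class RowError:
    """Diagnostic for a rejected input row (1-based row number incl. header)."""

    row: int
    message: str


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-species aggregate of the occurrence records."""

    species: str
    n: int
    mean_width_mm: float
    sd_width_mm: float
    min_width_mm: float
    max_width_mm: float
    mean_latitude: float


def _parse_row(row: Sequence[str], rownum: int) -> OccurrenceRecord | RowError:
    if len(row) != len(OCCURRENCE_HEADER):
        return RowError(rownum, f"expected {len(OCCURRENCE_HEADER)} fields, got {len(row)}")
    species, sex, width_s, lat_s, lon_s, source = (f.strip() for f in row)
    if not species:
        return RowError(rownum, "empty species name")
    if sex not in SEXES:
        return RowError(rownum, f"unknown sex value {sex!r}")
    if source not in SOURCES:
        return RowError(rownum, f"unknown source value {source!r}")
    width: float | None = None
    if width_s:
        try:
            width = float(width_s)
        except ValueError:
            return RowError(rownum, f"malformed width {width_s!r}")
        if not (0.0 < width < MAX_WIDTH_MM):
            return RowError(rownum, f"width {width} mm outside (0, {MAX_WIDTH_MM})")
    elif source == "museum":
        return RowError(rownum, "museum record lacks a measured width")
    try:
        lat = float(lat_s)
        lon = float(lon_s)
    except ValueError:
        return RowError(rownum, f"malformed coordinates ({lat_s!r}, {lon_s!r})")
    if not (-90.0 <= lat <= 90.0):
        return RowError(rownum, f"latitude {lat} outside [-90, 90]")
    if not (-180.0 <= lon <= 180.0):
        return RowError(rownum, f"longitude {lon} outside [-180, 180]")
    if not (math.isfinite(lat) and math.isfinite(lon)):
        return RowError(rownum, "non-finite coordinates")
    return OccurrenceRecord(species, sex, width, lat, lon, source)


def read_occurrence_table(path: str | Path) -> tuple[list[OccurrenceRecord], list[RowError]]:
    """Read a comma-separated occurrence table.

    Returns the valid records together with row-numbered diagnostics for every
    rejected row. An empty file or wrong header is fatal
    (:class:`OccurrenceTableError`).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise OccurrenceTableError(f"{path}: empty occurrence table") from None
        if tuple(h.strip() for h in header) != OCCURRENCE_HEADER:
            raise OccurrenceTableError(
                f"{path}: bad header {header!r}; expected {','.join(OCCURRENCE_HEADER)}"
            )
        records: list[OccurrenceRecord] = []
        errors: list[RowError] = []
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            parsed = _parse_row(row, rownum)
            if isinstance(parsed, RowError):
                errors.append(parsed)
            else:
                records.append(parsed)
    if not records and not errors:
        raise OccurrenceTableError(f"{path}: no data rows")
    return records, errors


def write_occurrence_table(records: Iterable[OccurrenceRecord], path: str | Path) -> None:
    """Write records in the same dialect :func:`read_occurrence_table` reads."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(OCCURRENCE_HEADER)
        for r in records:
            width = "" if r.width_mm is None else repr(float(r.width_mm))
            writer.writerow([r.species, r.sex, width, repr(float(r.latitude)),
                             repr(float(r.longitude)), r.source])


def impute_literature_widths(
    records: Sequence[OccurrenceRecord],
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Fill missing literature widths from museum measurements.

    A literature record without a width receives the museum mean width of its
    species and sex when the sex is known and measured museum records of that
    sex exist; otherwise the pooled museum species mean. Records that already
    carry a width are returned unchanged. Literature records of species with
    no measured museum record cannot be imputed and are returned separately
    (second element) rather than silently dropped.
    """
    by_species: dict[str, list[float]] = {}
    by_species_sex: dict[tuple[str, str], list[float]] = {}
    for r in records:
        if r.source == "museum" and r.width_mm is not None:
            by_species.setdefault(r.species, []).append(r.width_mm)
            if r.sex in ("male", "female"):
                by_species_sex.setdefault((r.species, r.sex), []).append(r.width_mm)

    out: list[OccurrenceRecord] = []
    unimputable: list[OccurrenceRecord] = []
    for r in records:
        if r.width_mm is not None:
            out.append(r)
            continue
        pool = None
        if r.sex in ("male", "female"):
            pool = by_species_sex.get((r.species, r.sex))
        if pool is None:
            pool = by_species.get(r.species)
        if pool is None:
            unimputable.append(r)
            continue
        out.append(OccurrenceRecord(r.species, r.sex, float(np.mean(pool)),
                                    r.latitude, r.longitude, r.source))
    return out, unimputable


def species_summaries(
    records: Sequence[OccurrenceRecord],
    source_filter: str = "museum_only",
) -> list[SpeciesSummary]:
    """Aggregate records into per-species summaries, sorted by species name.

    ``source_filter`` is ``"museum_only"`` (the default used for all
    comparative analyses) or ``"all"``. Records without a width are ignored
    for the width statistics but still contribute to mean latitude. Sample SD
    uses the n-1 denominator; single-record species get sd 0.
    """
    if source_filter not in ("museum_only", "all"):
        raise ValueError(f"source_filter must be 'museum_only' or 'all', got {source_filter!r}")
    widths: dict[str, list[float]] = {}
    lats: dict[str, list[float]] = {}
    for r in records:
        if source_filter == "museum_only" and r.source != "museum":
            continue
        lats.setdefault(r.species, []).append(r.latitude)
        if r.width_mm is not None:
            widths.setdefault(r.species, []).append(r.width_mm)
    out = []
    for sp in sorted(widths):
        w = np.asarray(widths[sp], dtype=float)
        sd = float(np.std(w, ddof=1)) if w.size > 1 else 0.0
        out.append(SpeciesSummary(
            species=sp, n=int(w.size), mean_width_mm=float(w.mean()),
            sd_width_mm=sd, min_width_mm=float(w.min()), max_width_mm=float(w.max()),
            mean_latitude=float(np.mean(lats[sp])),
        ))
    return out


def summaries_frame(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    """Summaries as a DataFrame indexed by species."""
    return pd.DataFrame(
        {
            "n": [s.n for s in summaries],
            "mean_width_mm": [s.mean_width_mm for s in summaries],
            "sd_width_mm": [s.sd_width_mm for s in summaries],
            "min_width_mm": [s.min_width_mm for s in summaries],
            "max_width_mm": [s.max_width_mm for s in summaries],
            "mean_latitude": [s.mean_latitude for s in summaries],
        },
        index=pd.Index([s.species for s in summaries], name="species"),
    )


# ---------------------------------------------------------------------------
# Dated trees


class DatedTree:
    """Rooted, bifurcating, (near-)ultrametric dated tree.

    Wraps a :class:`dendropy.Tree` whose branch lengths are in Ma. Polytomies
    are resolved into zero-length bifurcations on construction (stable under
    fixed input order) so that independent contrasts are always computable.
    Internal nodes get stable labels ``n0, n1, ...`` in preorder when the
    Newick did not name them.
    """

    def __init__(self, tree: dendropy.Tree, ultrametric_tol: float = 1e-6):
        tree = tree.clone(depth=1)
        for leaf in tree.leaf_node_iter():
            if leaf.edge.length is None:
                raise ValueError("tree has tips with missing branch lengths")
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                raise ValueError("tree has internal edges with missing branch lengths")
        names = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tip names in tree")
        n_before = sum(1 for _ in tree.preorder_internal_node_iter())
        tree.resolve_polytomies(rng=None)  # deterministic: splits in input order
        n_after = sum(1 for _ in tree.preorder_internal_node_iter())
        if n_after != n_before:
            warnings.warn(
                f"resolved {n_after - n_before} polytomies with zero-length branches",
                stacklevel=2,
            )
        for node in tree.preorder_internal_node_iter():
            if node.edge.length is None:
                node.edge.length = 0.0
        i = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node.label is None:
                node.label = f"n{i}"
            i += 1
        self._tree = tree
        self._depths: dict[dendropy.Node, float] = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            base = self._depths[parent] if parent is not None else 0.0
            self._depths[node] = base + (node.edge.length or 0.0)
        tip_depths = np.array([self._depths[lf] for lf in tree.leaf_node_iter()])
        self.root_height = float(tip_depths.max())
        self.max_ultrametric_deviation = float(tip_depths.max() - tip_depths.min())
        if self.max_ultrametric_deviation > ultrametric_tol * max(self.root_height, 1.0):
            warnings.warn(
                "tree is not ultrametric: max tip-depth deviation "
                f"{self.max_ultrametric_deviation:.6g} Ma",
                stacklevel=2,
            )
        self.tip_names: list[str] = [lf.taxon.label for lf in tree.leaf_node_iter()]

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, **kwargs) -> "DatedTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
            raise ValueError(f"duplicate tip names in tree: {e}") from None
        return cls(tree, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "DatedTree":
        return cls.from_newick(Path(path).read_text(encoding="utf-8"), **kwargs)

    # -- basic structure ----------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def depth(self, node: dendropy.Node) -> float:
        """Distance of ``node`` from the root (Ma)."""
        return self._depths[node]

    def age(self, node: dendropy.Node) -> float:
        """Time before present (Ma); 0 at the tips of an ultrametric tree."""
        return self.root_height - self._depths[node]

    def leaves(self) -> list[dendropy.Node]:
        return list(self._tree.leaf_node_iter())

    def internal_nodes(self) -> list[dendropy.Node]:
        return [nd for nd in self._tree.preorder_node_iter() if not nd.is_leaf()]

    # -- comparative machinery ----------------------------------------------

    def vcv(self) -> tuple[list[str], np.ndarray]:
        """Brownian-motion tip covariance: shared path length from the root.

        Returns tip names (in ``tip_names`` order) and the symmetric matrix
        whose (i, j) entry is the depth of the MRCA of tips i and j. Cached
        after the first call.
        """
        if getattr(self, "_vcv_cache", None) is not None:
            return list(self.tip_names), self._vcv_cache
        order = {name: i for i, name in enumerate(self.tip_names)}
        n = len(order)
        C = np.zeros((n, n))
        # postorder sweep: at each internal node, tip pairs split across its
        # children share exactly that node's depth
        below: dict[dendropy.Node, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                idx = [order[node.taxon.label]]
                C[idx[0], idx[0]] = self._depths[node]
            else:
                idx = []
                kids = [below[ch] for ch in node.child_nodes()]
                d = self._depths[node]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            C[i, kids[b]] = d
                            C[kids[b], i] = d
                    idx.extend(kids[a])
            below[node] = idx
        self._vcv_cache = C
        return list(self.tip_names), C

    def cherries(self) -> list[tuple[str, str, float]]:
        """Two-tip clades as (tip_a, tip_b, MRCA age in Ma)."""
        out = []
        for node in self._tree.preorder_internal_node_iter():
            kids = node.child_nodes()
            if len(kids) == 2 and all(k.is_leaf() for k in kids):
                out.append((kids[0].taxon.label, kids[1].taxon.label, self.age(node)))
        return out

    def prune_to(self, names: Iterable[str]) -> "DatedTree":
        """Subtree restricted to ``names`` (all must be tips)."""
        keep = set(names)
        missing = keep - set(self.tip_names)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        t = self._tree.clone(depth=1)
        t.retain_taxa_with_labels(sorted(keep))
        return DatedTree(t)


def read_newick(path: str | Path) -> DatedTree:
    """Read a single dated Newick tree (branch lengths mandatory, Ma).

    Polytomies are resolved with zero-length branches and a warning; a
    non-ultrametric tree triggers a warning reporting the maximum tip-depth
    deviation.
    """
    return DatedTree.from_file(path)
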