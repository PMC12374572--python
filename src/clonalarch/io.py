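"""Data model and tabular I/O for grid-referenced multilocus microsatellite genotypes.

The interchange format is a flat CSV with one row per sampled ramet:

    sample_id, quadrat_id, row, col, stage, <locus>_1, <locus>_2, ...

Two columns per locus hold integer allele fragment sizes (bp); a missing
genotype is encoded as ``0`` (or an empty field) in *both* columns.  Quadrat
layouts (grid shape, forest type) live in a YAML/JSON sidecar config, not in
the CSV.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional

import yaml

logger = logging.getLogger("clonalarch")

MISSING = 0  #: sentinel allele value for a missing genotype

#: fixed leading columns of the interchange CSV
_FIXED_COLUMNS = ("sample_id", "quadrat_id", "row", "col", "stage")


class Stage(str, Enum):
    """Life stage of a sampled ramet."""

    ON_FLOOR = "on_floor"
    ON_TREE = "on_tree"


class ForestType(str, Enum):
    YOUNG = "young"
    OLD_GROWTH = "old_growth"


class GenotypeTableError(ValueError):
    """Raised for any violation of the genotype-table contract."""


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered diploid microsatellite marker panel."""

    loci: tuple[str, ...]
    ploidy: int = 2
    motif_bp: Optional[Mapping[str, int]] = None
    allele_range: Optional[Mapping[str, tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if self.ploidy != 2:
            raise GenotypeTableError("only diploid panels are supported (ploidy == 2)")
        if len(self.loci) < 1:
            raise GenotypeTableError("panel needs at least one locus")
        if len(set(self.loci)) != len(self.loci):
            raise GenotypeTableError("locus names must be unique")

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass(frozen=True, order=True)
class LocusGenotype:
    """Unordered diploid allele call at one locus, stored in ascending order.

    Both alleles are present, or both are the :data:`MISSING` sentinel.
    """

    allele_a: int
    allele_b: int

    def __post_init__(self) -> None:
        a, b = self.allele_a, self.allele_b
        if (a == MISSING) != (b == MISSING):
            raise GenotypeTableError(
                f"half-missing genotype ({a}, {b}): both alleles must be present or both missing"
            )
        if a > b:
            object.__setattr__(self, "allele_a", b)
            object.__setattr__(self, "allele_b", a)

    @property
    def is_missing(self) -> bool:
        return self.allele_a == MISSING

    @property
    def is_heterozygous(self) -> bool:
        return not self.is_missing and self.allele_a != self.allele_b

    @property
    def alleles(self) -> tuple[int, int]:
        return (self.allele_a, self.allele_b)

    @classmethod
    def missing(cls) -> "LocusGenotype":
        return cls(MISSING, MISSING)


@dataclass(frozen=True)
class QuadratLayout:
    """Sampling grid of one quadrat (default 10 x 10 cells of 1 m)."""

    quadrat_id: str
    forest_type: Optional[ForestType] = None
    grid_rows: int = 10
    grid_cols: int = 10
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise GenotypeTableError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise GenotypeTableError("cell size must be positive")


@dataclass(frozen=True)
class RametRecord:
    """One sampled stem: identity, grid position, life stage, L-locus genotype."""

    sample_id: str
    quadrat_id: str
    row: int
    col: int
    stage: Stage
    genotype: tuple[LocusGenotype, ...]

    @property
    def cell(self) -> tuple[int, int]:
        return (self.row, self.col)

    @property
    def is_complete(self) -> bool:
        return all(not g.is_missing for g in self.genotype)

    def position(self, layout: QuadratLayout) -> tuple[float, float]:
        """Metric position of the ramet: the centre of its grid cell.

        x runs east along columns, y north along rows, from the quadrat origin.
        """
        s = layout.cell_size
        return ((self.col - 0.5) * s, (self.row - 0.5) * s)


@dataclass
class SampleSet:
    """A marker panel, quadrat layouts, and the sampled ramet records.

    Record order is the canonical order for every deterministic tie-break
    downstream (MLG numbering, round-robin representatives, merge order).
    """

    panel: MarkerPanel
    layouts: dict[str, QuadratLayout]
    records: list[RametRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_ids: set[str] = set()
        seen_slots: set[tuple[str, int, int, Stage]] = set()
        for rec in self.records:
            if rec.sample_id in seen_ids:
                raise GenotypeTableError(f"duplicate sample_id {rec.sample_id!r}")
            seen_ids.add(rec.sample_id)
            if rec.quadrat_id not in self.layouts:
                raise GenotypeTableError(
                    f"record {rec.sample_id!r}: no layout for quadrat {rec.quadrat_id!r}"
                )
            layout = self.layouts[rec.quadrat_id]
            if not (1 <= rec.row <= layout.grid_rows and 1 <= rec.col <= layout.grid_cols):
                raise GenotypeTableError(
                    f"record {rec.sample_id!r}: cell ({rec.row}, {rec.col}) outside "
                    f"{layout.grid_rows} x {layout.grid_cols} grid of {rec.quadrat_id!r}"
                )
            slot = (rec.quadrat_id, rec.row, rec.col, rec.stage)
            if slot in seen_slots:
                raise GenotypeTableError(
                    f"more than one record for quadrat {rec.quadrat_id!r} "
                    f"cell ({rec.row}, {rec.col}) stage {rec.stage.value}"
                )
            seen_slots.add(slot)
            if len(rec.genotype) != self.panel.n_loci:
                raise GenotypeTableError(
                    f"record {rec.sample_id!r}: {len(rec.genotype)} loci, "
                    f"panel has {self.panel.n_loci}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.records)

    @property
    def quadrat_ids(self) -> list[str]:
        seen: list[str] = []
        for rec in self.records:
            if rec.quadrat_id not in seen:
                seen.append(rec.quadrat_id)
        return seen

    def subset(self, quadrat_id: str) -> "SampleSet":
        """Records of a single quadrat, order preserved."""
        if quadrat_id not in self.layouts:
            raise GenotypeTableError(f"unknown quadrat {quadrat_id!r}")
        recs = [r for r in self.records if r.quadrat_id == quadrat_id]
        return SampleSet(self.panel, {quadrat_id: self.layouts[quadrat_id]}, recs)

    def record_by_id(self, sample_id: str) -> RametRecord:
        for rec in self.records:
            if rec.sample_id == sample_id:
                return rec
        raise KeyError(sample_id)


@dataclass(frozen=True)
class DropReport:
    """Outcome of :func:`drop_incomplete_samples`."""

    dropped_ids: tuple[str, ...]
    n_before: int
    n_after: int

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_ids)


def _parse_allele(token: str, where: str) -> int:
    token = token.strip()
    if token == "":
        return MISSING
    try:
        value = int(token)
    except ValueError as exc:
        raise GenotypeTableError(f"{where}: allele {token!r} is not an integer") from exc
    if value < 0:
        raise GenotypeTableError(f"{where}: negative allele size {value}")
    return value


def _parse_stage(token: str, where: str) -> Stage:
    try:
        return Stage(token.strip())
    except ValueError as exc:
        raise GenotypeTableError(
            f"{where}: unknown stage {token!r} (expected 'on_floor' or 'on_tree')"
        ) from exc


def read_genotype_table(
    path: str | Path,
    panel: Optional[MarkerPanel] = None,
    layouts: Optional[Mapping[str, QuadratLayout]] = None,
) -> SampleSet:
    """Read a genotype CSV into a validated :class:`SampleSet`.

    Locus names are inferred from the header (``<locus>_1`` / ``<locus>_2``
    column pairs) unless an explicit ``panel`` is supplied.  Quadrats without
    a supplied layout get the default 10 x 10 grid.  Allele pairs are
    canonicalized ascending; file row order is preserved.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeTableError(f"{path}: empty file") from None
        if tuple(header[: len(_FIXED_COLUMNS)]) != _FIXED_COLUMNS:
            raise GenotypeTableError(
                f"{path}: header must start with {', '.join(_FIXED_COLUMNS)}"
            )
        locus_cols = header[len(_FIXED_COLUMNS):]
        if len(locus_cols) % 2 != 0:
            raise GenotypeTableError(f"{path}: odd number of allele columns")
        loci: list[str] = []
        for i in range(0, len(locus_cols), 2):
            c1, c2 = locus_cols[i], locus_cols[i + 1]
            if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
                raise GenotypeTableError(
                    f"{path}: allele columns {c1!r}, {c2!r} are not a <locus>_1/<locus>_2 pair"
                )
            loci.append(c1[:-2])
        if panel is None:
            panel = MarkerPanel(tuple(loci))
        elif tuple(loci) != panel.loci:
            raise GenotypeTableError(
                f"{path}: header loci {loci} do not match panel {list(panel.loci)}"
            )

        records: list[RametRecord] = []
        quadrats_seen: list[str] = []
        for lineno, rowvals in enumerate(reader, start=2):
            if not rowvals or all(v.strip() == "" for v in rowvals):
                continue
            where = f"{path}:{lineno}"
            if len(rowvals) != len(header):
                raise GenotypeTableError(f"{where}: expected {len(header)} fields")
            sample_id, quadrat_id, row_s, col_s, stage_s = rowvals[:5]
            try:
                row, col = int(row_s), int(col_s)
            except ValueError as exc:
                raise GenotypeTableError(f"{where}: non-integer grid cell") from exc
            stage = _parse_stage(stage_s, where)
            genotype = []
            for i, locus in enumerate(panel.loci):
                a = _parse_allele(rowvals[5 + 2 * i], where)
                b = _parse_allele(rowvals[6 + 2 * i], where)
                try:
                    genotype.append(LocusGenotype(a, b))
                except GenotypeTableError as exc:
                    raise GenotypeTableError(f"{where}: locus {locus!r}: {exc}") from None
            records.append(
                RametRecord(sample_id.strip(), quadrat_id.strip(), row, col, stage,
                            tuple(genotype))
            )
            if quadrat_id.strip() not in quadrats_seen:
                quadrats_seen.append(quadrat_id.strip())

    layout_map: dict[str, QuadratLayout] = dict(layouts or {})
    for qid in quadrats_seen:
        layout_map.setdefault(qid, QuadratLayout(qid))
    sample_set = SampleSet(panel, layout_map, records)
    logger.info("read %d records (%d quadrats, %d loci) from %s",
                len(records), len(quadrats_seen), panel.n_loci, path)
    return sample_set


def write_genotype_table(sample_set: SampleSet, path: str | Path) -> None:
    """Write a :class:`SampleSet` back to the interchange CSV (round-trip stable)."""
    path = Path(path)
    header = list(_FIXED_COLUMNS)
    for locus in sample_set.panel.loci:
        header += [f"{locus}_1", f"{locus}_2"]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for rec in sample_set.records:
            row = [rec.sample_id, rec.quadrat_id, str(rec.row), str(rec.col), rec.stage.value]
            for g in rec.genotype:
                row += [str(g.allele_a), str(g.allele_b)]
            writer.writerow(row)


def drop_incomplete_samples(sample_set: SampleSet) -> tuple[SampleSet, DropReport]:
    """Remove every record with one or more missing loci (strict mode).

    Retained genotypes are untouched; the report lists the removed sample ids.
    """
    kept = [r for r in sample_set.records if r.is_complete]
    dropped = tuple(r.sample_id for r in sample_set.records if not r.is_complete)
    report = DropReport(dropped, sample_set.n_samples, len(kept))
    if dropped:
        logger.info("dropped %d/%d incomplete samples", len(dropped), sample_set.n_samples)
    return SampleSet(sample_set.panel, dict(sample_set.layouts), kept), report


# ---------------------------------------------------------------------------
# layout sidecar config


def load_layout_config(path: str | Path) -> dict[str, QuadratLayout]:
    """Read quadrat layouts from a YAML/JSON sidecar.

    Schema::

        quadrats:
          - quadrat_id: N1
            forest_type: young        # optional
            grid_rows: 10             # optional
            grid_cols: 10
            cell_size: 1.0
    """
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh) if path.suffix in {".yml", ".yaml"} else json.load(fh)
    layouts: dict[str, QuadratLayout] = {}
    for entry in data.get("quadrats", []):
        ft = entry.get("forest_type")
        layouts[entry["quadrat_id"]] = QuadratLayout(
            quadrat_id=entry["quadrat_id"],
            forest_type=ForestType(ft) if ft else None,
            grid_rows=int(entry.get("grid_rows", 10)),
            grid_cols=int(entry.get("grid_cols", 10)),
            cell_size=float(entry.get("cell_size", 1.0)),
        )
    return layouts


def save_layout_config(layouts: Mapping[str, QuadratLayout], path: str | Path) -> None:
    path = Path(path)
    data = {
        "quadrats": [
            {
                "quadrat_id": lay.quadrat_id,
                "forest_type": lay.forest_type.value if lay.forest_type else None,
                "grid_rows": lay.grid_rows,
                "grid_cols": lay.grid_cols,
                "cell_size": lay.cell_size,
            }
            for lay in layouts.values()
        ]
    }
    with path.open("w") as fh:
        if path.suffix in {".yml", ".yaml"}:
            yaml.safe_dump(data, fh, sort_keys=False)
        else:
            json.dump(data, fh, indent=2)
            fh.write("\n")
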