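"""Microsatellite genomic signatures: data model, tidy-table IO and QC filters.

A cell's *genomic signature* is its vector of repeat-count deviations from the
putative zygote across a panel of microsatellite loci.  Each diploid locus
carries two parental alleles (``A`` and ``B``), distinguishable because the
two parental strains were chosen with well-separated reference repeat sizes.
Deviations are stored in whole repeat units (steps), never base pairs.

Quality control mirrors the wet-lab pipeline:

1. loci that showed signal in a PCR-plate negative control are removed from
   every cell on that plate;
2. loci displaying more than two alleles in a cell (candidate spontaneous
   mutations at the four-chromatid oocyte stage) are excluded from that
   cell's deviations but remembered in ``multiallelic_loci``;
3. only cells with more than ``min_alleles`` amplified alleles are retained.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

#: (locus_id, parental) with parental in {"A", "B"}
AlleleKey = tuple[str, str]

PARENTALS = ("A", "B")

POPULATIONS = ("oocyte", "lymphocyte", "msc", "cumulus", "islet", "other")

SIGNATURE_COLUMNS = [
    "cell_id",
    "mouse_id",
    "age_days",
    "population",
    "ovary_side",
    "follicle_id",
    "plate_id",
    "pcr_repeat_of",
    "locus_id",
    "parental",
    "deviation",
    "multiallelic_flag",
]

PANEL_COLUMNS = ["locus_id", "repeat_unit_len", "allele_a_ref_size", "allele_b_ref_size"]


class TableFormatError(ValueError):
    """Raised for malformed signature / panel tables (carries the line number)."""


@dataclass(frozen=True)
class Locus:
    """One microsatellite locus of the panel.

    Reference sizes are repeat counts of the two strain alleles; they must
    differ so that parental origin is never confounded by sizing alone.
    """

    locus_id: str
    repeat_unit_len: int
    allele_a_ref_size: int
    allele_b_ref_size: int

    def __post_init__(self) -> None:
        if self.allele_a_ref_size == self.allele_b_ref_size:
            raise ValueError(
                f"locus {self.locus_id}: strain reference sizes must differ "
                f"(both {self.allele_a_ref_size})"
            )
        if self.repeat_unit_len < 1:
            raise ValueError(f"locus {self.locus_id}: repeat_unit_len must be >= 1")


@dataclass
class CellSignature:
    """One cell's per-allele repeat-step deviations plus sample metadata.

    ``deviations`` maps :data:`AlleleKey` to the signed integer deviation from
    the strain reference; alleles that failed to amplify (allelic dropout) are
    simply absent.  Loci flagged as showing more than two alleles live in
    ``multiallelic_loci`` and are guaranteed absent from ``deviations``.
    """

    cell_id: str
    mouse_id: str = ""
    age_days: int = 0
    population: str = "other"
    ovary_side: Optional[str] = None
    follicle_id: Optional[str] = None
    plate_id: Optional[str] = None
    is_pcr_repeat_of: Optional[str] = None
    deviations: dict[AlleleKey, int] = field(default_factory=dict)
    multiallelic_loci: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = self.multiallelic_loci & {loc for loc, _ in self.deviations}
        if bad:
            raise ValueError(
                f"cell {self.cell_id}: loci {sorted(bad)} are flagged multiallelic "
                "but still carry deviations"
            )

    @property
    def n_alleles(self) -> int:
        return len(self.deviations)

    def loci_present(self) -> set[str]:
        return {loc for loc, _ in self.deviations}

    def copy(self) -> "CellSignature":
        return dataclasses.replace(
            self,
            deviations=dict(self.deviations),
            multiallelic_loci=set(self.multiallelic_loci),
        )


@dataclass
class RootSignature:
    """Putative-zygote signature: per-allele median over all sampled cells."""

    deviations: dict[AlleleKey, int] = field(default_factory=dict)

    @property
    def n_alleles(self) -> int:
        return len(self.deviations)


def assign_parental(locus: Locus, size_repeats: float) -> Optional[str]:
    """Assign a measured repeat size to parental allele A or B.

    Nearest strain reference wins.  An exact midpoint cannot be attributed to
    either strain and returns ``None`` (caller drops the locus for that cell);
    with a properly separable strain pair this only fires on corrupt input.
    """
    da = abs(size_repeats - locus.allele_a_ref_size)
    db = abs(size_repeats - locus.allele_b_ref_size)
    if da == db:
        return None
    return "A" if da < db else "B"


# ---------------------------------------------------------------------------
# panel IO


def read_panel(path: str | Path) -> list[Locus]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"panel table missing columns: {missing}")
    loci = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            loci.append(
                Locus(
                    locus_id=row.locus_id,
                    repeat_unit_len=int(row.repeat_unit_len),
                    allele_a_ref_size=int(row.allele_a_ref_size),
                    allele_b_ref_size=int(row.allele_b_ref_size),
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"panel line {i}: {exc}") from exc
    return loci


def write_panel(loci: Iterable[Locus], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(l) for l in loci], columns=PANEL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signature IO


def _parse_flag(raw: str) -> bool:
    return raw.strip().lower() in {"1", "true", "yes"}


def read_signature_table(path: str | Path, panel: list[Locus]) -> list[CellSignature]:
    """Read a tidy signature TSV (one row per cell, locus, parental allele).

    Rows flagged multiallelic contribute only to ``multiallelic_loci``; any
    deviation rows for a flagged (cell, locus) are discarded so the exclusion
    invariant holds.  Unknown loci and malformed rows raise
    :class:`TableFormatError` with the offending locus / line number.
    """
    known = {l.locus_id for l in panel}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SIGNATURE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"signature table missing columns: {missing}")

    cells: dict[str, CellSignature] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        locus_id = row.locus_id
        if locus_id not in known:
            raise TableFormatError(f"line {i}: unknown locus_id {locus_id!r}")
        cid = row.cell_id
        if not cid:
            raise TableFormatError(f"line {i}: empty cell_id")
        if cid not in cells:
            try:
                cells[cid] = CellSignature(
                    cell_id=cid,
                    mouse_id=row.mouse_id,
                    age_days=int(row.age_days) if row.age_days else 0,
                    population=row.population or "other",
                    ovary_side=row.ovary_side or None,
                    follicle_id=row.follicle_id or None,
                    plate_id=row.plate_id or None,
                    is_pcr_repeat_of=row.pcr_repeat_of or None,
                )
            except ValueError as exc:
                raise TableFormatError(f"line {i}: bad metadata ({exc})") from exc
        cell = cells[cid]
        if _parse_flag(row.multiallelic_flag):
            cell.multiallelic_loci.add(locus_id)
            continue
        parental = row.parental.strip().upper()
        if parental not in PARENTALS:
            raise TableFormatError(f"line {i}: parental must be A or B, got {row.parental!r}")
        try:
            deviation = int(row.deviation)
        except ValueError as exc:
            raise TableFormatError(f"line {i}: non-integer deviation {row.deviation!r}") from exc
        cell.deviations[(locus_id, parental)] = deviation

    # Enforce multiallelic exclusion after the fact: a flag row anywhere in the
    # file voids that (cell, locus) pair's deviations regardless of row order.
    out = []
    for cell in cells.values():
        for loc in cell.multiallelic_loci:
            cell.deviations.pop((loc, "A"), None)
            cell.deviations.pop((loc, "B"), None)
        out.append(cell)
    return out


def write_signature_table(cells: Iterable[CellSignature], path: str | Path) -> None:
    """Write cells back to the tidy TSV dialect (inverse of the reader)."""
    rows = []
    for cell in cells:
        meta = dict(
            cell_id=cell.cell_id,
            mouse_id=cell.mouse_id,
            age_days=cell.age_days,
            population=cell.population,
            ovary_side=cell.ovary_side or "",
            follicle_id=cell.follicle_id or "",
            plate_id=cell.plate_id or "",
            pcr_repeat_of=cell.is_pcr_repeat_of or "",
        )
        for (locus_id, parental) in sorted(cell.deviations):
            rows.append(
                {**meta, "locus_id": locus_id, "parental": parental,
                 "deviation": cell.deviations[(locus_id, parental)],
                 "multiallelic_flag": 0}
            )
        for locus_id in sorted(cell.multiallelic_loci):
            rows.append(
                {**meta, "locus_id": locus_id, "parental": "", "deviation": "",
                 "multiallelic_flag": 1}
            )
    pd.DataFrame(rows, columns=SIGNATURE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC filters


def filter_min_alleles(
    cells: list[CellSignature], min_alleles: int = 25
) -> list[CellSignature]:
    """Keep cells with strictly more than ``min_alleles`` amplified alleles."""
    if min_alleles < 0:
        raise ValueError("min_alleles must be >= 0")
    return [c for c in cells if c.n_alleles > min_alleles]


def apply_plate_negative_control(
    cells: list[CellSignature], failed: set[tuple[str, str]]
) -> list[CellSignature]:
    """Remove loci that showed negative-control signal, per PCR plate.

    ``failed`` holds ``(plate_id, locus_id)`` pairs; both parental alleles of
    each failed locus are removed from every cell run on that plate.  Cells
    are copied, never mutated in place.
    """
    if not failed:
        return [c.copy() for c in cells]
    by_plate: dict[str, set[str]] = {}
    for plate, locus in failed:
        by_plate.setdefault(plate, set()).add(locus)
    out = []
    for cell in cells:
        cell = cell.copy()
        for locus in by_plate.get(cell.plate_id or "", ()):
            cell.deviations.pop((locus, "A"), None)
            cell.deviations.pop((locus, "B"), None)
        out.append(cell)
    return out


def apply_qc(
    cells: list[CellSignature],
    failed: set[tuple[str, str]] | None = None,
    min_alleles: int = 25,
) -> list[CellSignature]:
    """Full QC chain in the fixed order: plate negative control, then the
    per-cell allele-count filter (multiallelic exclusion already happened at
    read time)."""
    cells = apply_plate_negative_control(cells, failed or set())
    return filter_min_alleles(cells, min_alleles)


def lower_median(values: list[int]) -> int:
    """Integer median; even counts take the lower of the two middle values."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def compute_root_signature(
    cells: list[CellSignature], tie: str = "lower"
) -> RootSignature:
    """Putative-zygote signature: per-allele median over cells carrying it.

    Deviations are integers and the root must be an integer signature, so an
    even count of observations takes the lower middle value by default
    (``tie="upper"`` flips that).  Alleles observed in no cell are absent.
    """
    if not cells:
        raise ValueError("need at least one cell to compute a root signature")
    if tie not in ("lower", "upper"):
        raise ValueError("tie must be 'lower' or 'upper'")
    per_key: dict[AlleleKey, list[int]] = {}
    for cell in cells:
        for key, dev in cell.deviations.items():
            per_key.setdefault(key, []).append(dev)
    root: dict[AlleleKey, int] = {}
    for key, vals in per_key.items():
        s = sorted(vals)
        idx = (len(s) - 1) // 2 if tie == "lower" else len(s) // 2
        root[key] = s[idx]
    return RootSignature(deviations=root)
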