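"""Tabular input/output for peptide tables, target lists, group maps and fluctuation assays.

The canonical interchange format is TSV (UTF-8, header row, '.' decimal
separator) so that every artifact diffs cleanly; xlsx reading is a
convenience layer for supplementary-style spreadsheets and goes through the
same column contract. Accessions are opaque, case-sensitive strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeptideRecord",
    "ProteinQuant",
    "FluctuationAssay",
    "Culture",
    "TableFormatError",
    "TableValidationError",
    "ReadReport",
    "read_peptide_table",
    "read_target_list",
    "read_group_map",
    "read_fluctuation_table",
    "write_fluctuation_table",
    "write_peptide_table",
    "write_protein_table",
    "read_protein_table",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")

PEPTIDE_COLUMNS = [
    "spectrum_id",
    "protein_id",
    "peptide_seq",
    "charge",
    "light_area",
    "heavy_area",
    "ratio_valid",
]

PROTEIN_COLUMNS = [
    "protein_id",
    "group",
    "n_unique_peptides",
    "sum_light",
    "sum_heavy",
    "ratio_hl",
    "log2_ratio",
    "sd_log2_top3",
    "known_sumo_target",
]

FLUCTUATION_COLUMNS = ["strain", "culture_id", "mutant_count", "viable_cells"]


class TableFormatError(ValueError):
    """A table is structurally malformed (missing column, bad header)."""


class TableValidationError(ValueError):
    """A table parsed but violates a domain invariant (negative count, duplicate key)."""


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide with light/heavy isotope areas.

    ``ratio_valid`` records whether the isotope-pair quantifier produced a
    usable heavy/light ratio for this identification. Areas are arbitrary
    intensity units; the combined area is always derived, never stored.
    """

    spectrum_id: str
    protein_id: str
    peptide_seq: str
    charge: int
    light_area: float
    heavy_area: float
    ratio_valid: bool

    def __post_init__(self) -> None:
        if self.light_area < 0 or self.heavy_area < 0:
            raise ValueError(
                f"{self.spectrum_id}: negative isotope area "
                f"(light={self.light_area}, heavy={self.heavy_area})"
            )
        if self.charge < 1:
            raise ValueError(f"{self.spectrum_id}: charge must be a positive integer")
        if not self.peptide_seq or not set(self.peptide_seq) <= _AA:
            raise ValueError(
                f"{self.spectrum_id}: peptide sequence {self.peptide_seq!r} is not an "
                "uppercase amino-acid string"
            )

    @property
    def combined_area(self) -> float:
        return self.light_area + self.heavy_area


@dataclass
class ProteinQuant:
    """Protein-level heavy/light quantification rolled up from unique peptides."""

    protein_id: str
    n_unique_peptides: int
    sum_light: float
    sum_heavy: float
    ratio_hl: float
    log2_ratio: float
    sd_log2_top3: float | None = None
    group: str | None = None
    known_sumo_target: bool = False


@dataclass(frozen=True)
class Culture:
    culture_id: str
    mutant_count: int
    viable_cells: int

    def __post_init__(self) -> None:
        if self.mutant_count < 0:
            raise TableValidationError(
                f"culture {self.culture_id}: mutant_count must be >= 0, got {self.mutant_count}"
            )
        if self.viable_cells <= 0:
            raise TableValidationError(
                f"culture {self.culture_id}: viable_cells must be > 0, got {self.viable_cells}"
            )


@dataclass
class FluctuationAssay:
    """Mutant-colony counts from parallel cultures of one strain."""

    strain: str
    cultures: list[Culture]

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.mutant_count for c in self.cultures], dtype=float)

    @property
    def viable_cells(self) -> np.ndarray:
        return np.array([c.viable_cells for c in self.cultures], dtype=float)


@dataclass
class ReadReport:
    """Row accounting for a reader: rows_in == len(records) + len(rejected)."""

    rows_in: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def rejected_count(self) -> int:
        return len(self.rejected)


def _read_frame(path: str | Path, dialect: str) -> pd.DataFrame:
    path = Path(path)
    if dialect == "tsv":
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "xlsx":
        return pd.read_excel(path, dtype=str, engine="openpyxl").fillna("")
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'xlsx'")


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {', '.join(missing)}")


_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f"}


def _parse_bool(text: str) -> bool:
    low = text.strip().lower()
    if low in _TRUTHY:
        return True
    if low in _FALSY:
        return False
    raise ValueError(f"cannot interpret {text!r} as a boolean")


def read_peptide_table(
    path: str | Path,
    dialect: str = "tsv",
    return_report: bool = False,
) -> list[PeptideRecord] | tuple[list[PeptideRecord], ReadReport]:
    """Read a peptide quantification table into :class:`PeptideRecord` rows.

    Rows whose numeric fields do not parse (blank or non-numeric areas,
    fractional charge) are rejected with a row-indexed warning rather than
    silently dropped; the optional :class:`ReadReport` carries the full
    accounting. Input row order is preserved.
    """
    path = Path(path)
    frame = _read_frame(path, dialect)
    report = ReadReport(rows_in=len(frame))
    _require_columns(frame, PEPTIDE_COLUMNS, path)
    if frame.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return ([], report) if return_report else []

    records: list[PeptideRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        try:
            rec = PeptideRecord(
                spectrum_id=str(getattr(row, "spectrum_id")),
                protein_id=str(getattr(row, "protein_id")),
                peptide_seq=str(getattr(row, "peptide_seq")).upper(),
                charge=int(str(getattr(row, "charge"))),
                light_area=float(getattr(row, "light_area")),
                heavy_area=float(getattr(row, "heavy_area")),
                ratio_valid=_parse_bool(str(getattr(row, "ratio_valid"))),
            )
        except (TypeError, ValueError) as exc:
            report.rejected.append((idx, str(exc)))
            warnings.warn(f"{path}: rejected row {idx}: {exc}", stacklevel=2)
            continue
        records.append(rec)
    return (records, report) if return_report else records


def write_peptide_table(records: Iterable[PeptideRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "spectrum_id": r.spectrum_id,
                "protein_id": r.protein_id,
                "peptide_seq": r.peptide_seq,
                "charge": r.charge,
                "light_area": repr(r.light_area),
                "heavy_area": repr(r.heavy_area),
                "ratio_valid": r.ratio_valid,
            }
            for r in records
        ],
        columns=PEPTIDE_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_target_list(path: str | Path) -> set[str]:
    """Read a plain-text list of known SUMO-target accessions.

    One accession per line; ``#`` starts a comment; duplicates collapse;
    case is preserved (yeast gene names are case-sensitive strings here).
    """
    path = Path(path)
    accessions: set[str] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        text = line.split("#", 1)[0].strip()
        if text:
            accessions.add(text)
    if not accessions:
        warnings.warn(f"{path}: target list is empty", stacklevel=2)
    return accessions


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping accession -> functional group label."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, ["accession", "group"], path)
    mapping: dict[str, str] = {}
    for idx, row in frame.iterrows():
        acc, grp = row["accession"], row["group"]
        if acc in mapping and mapping[acc] != grp:
            raise TableValidationError(
                f"{path}: accession {acc!r} mapped to both {mapping[acc]!r} and {grp!r}"
            )
        mapping[acc] = grp
    return mapping


def read_fluctuation_table(path: str | Path) -> list[FluctuationAssay]:
    """Read a fluctuation-assay table, grouping cultures by strain.

    Columns: strain, culture_id, mutant_count, viable_cells. Strain order
    follows first appearance; duplicate (strain, culture_id) pairs, negative
    mutant counts and non-positive viable-cell counts are validation errors.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, FLUCTUATION_COLUMNS, path)

    assays: dict[str, list[Culture]] = {}
    seen: set[tuple[str, str]] = set()
    for idx, row in frame.iterrows():
        strain = row["strain"]
        key = (strain, row["culture_id"])
        if key in seen:
            raise TableValidationError(
                f"{path}: duplicated (strain, culture_id) = {key} at row {idx}"
            )
        seen.add(key)
        try:
            culture = Culture(
                culture_id=row["culture_id"],
                mutant_count=int(row["mutant_count"]),
                viable_cells=int(float(row["viable_cells"])),
            )
        except TableValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise TableValidationError(f"{path}: row {idx}: {exc}") from exc
        assays.setdefault(strain, []).append(culture)
    return [FluctuationAssay(strain=s, cultures=cs) for s, cs in assays.items()]


def write_fluctuation_table(assays: Iterable[FluctuationAssay], path: str | Path) -> None:
    rows = [
        {
            "strain": a.strain,
            "culture_id": c.culture_id,
            "mutant_count": c.mutant_count,
            "viable_cells": c.viable_cells,
        }
        for a in assays
        for c in a.cultures
    ]
    pd.DataFrame(rows, columns=FLUCTUATION_COLUMNS).to_csv(path, sep="\t", index=False)


def _fmt(value: float | None) -> str:
    # repr round-trips doubles exactly; blank encodes "undefined"
    return "" if value is None else repr(float(value))


def write_protein_table(proteins: Iterable[ProteinQuant], path: str | Path) -> None:
    """Write protein quantifications as TSV with a fixed column order.

    Numeric columns are written with full double precision so that
    ``read_protein_table(write_protein_table(x)) == x`` field for field.
    """
    rows = [
        {
            "protein_id": p.protein_id,
            "group": p.group or "",
            "n_unique_peptides": p.n_unique_peptides,
            "sum_light": _fmt(p.sum_light),
            "sum_heavy": _fmt(p.sum_heavy),
            "ratio_hl": _fmt(p.ratio_hl),
            "log2_ratio": _fmt(p.log2_ratio),
            "sd_log2_top3": _fmt(p.sd_log2_top3),
            "known_sumo_target": p.known_sumo_target,
        }
        for p in proteins
    ]
    pd.DataFrame(rows, columns=PROTEIN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_protein_table(path: str | Path) -> list[ProteinQuant]:
    frame = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, PROTEIN_COLUMNS, Path(path))
    out: list[ProteinQuant] = []
    for _, row in frame.iterrows():
        out.append(
            ProteinQuant(
                protein_id=row["protein_id"],
                n_unique_peptides=int(row["n_unique_peptides"]),
                sum_light=float(row["sum_light"]),
                sum_heavy=float(row["sum_heavy"]),
                ratio_hl=float(row["ratio_hl"]),
                log2_ratio=float(row["log2_ratio"]),
                sd_log2_top3=float(row["sd_log2_top3"]) if row["sd_log2_top3"] else None,
                group=row["group"] or None,
                known_sumo_target=_parse_bool(row["known_sumo_target"]),
            )
        )
    return out
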