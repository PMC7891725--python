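"""Peptide-level quality filtering and redundancy removal.

Two stages, applied in order before any protein rollup:

1. :func:`filter_peptides` — drop low-quality identifications: a peptide is
   kept only if its combined (light + heavy) intensity area exceeds the
   threshold *and* the isotope-pair quantifier reported a valid ratio.
2. :func:`deduplicate_peptides` — keep only the most abundant and unique
   peptides of each protein: redundant identifications of the same sequence
   under the same protein collapse to the single most abundant one, and
   (by default) sequences shared between proteins are removed outright.

"Unique" is enforced in both senses the field uses: unique *within* a
protein (one record per sequence, the most abundant) and unique *across*
proteins (shared sequences carry ambiguous evidence and are dropped; a
config switch retains them for sensitivity analyses).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .quant_io import PeptideRecord

__all__ = ["FilterConfig", "FilterReport", "filter_peptides", "deduplicate_peptides"]

DEFAULT_INTENSITY_THRESHOLD = 1e-3  # combined-area cutoff, quantifier's intensity units


@dataclass(frozen=True)
class FilterConfig:
    """Tunable knobs for the quality and uniqueness filters.

    intensity_threshold
        Minimum combined (light + heavy) area; records at or below it are
        dropped. Default 1e-3 in the quantifier's normalized intensity units.
    require_valid_ratio
        Drop records whose heavy/light ratio the quantifier flagged unusable.
    drop_shared_peptides
        Remove any peptide sequence observed under two or more proteins.
    dedup_charge_sensitive
        If True the redundancy key is (protein, sequence, charge) instead of
        (protein, sequence); charge states of one sequence then survive as
        separate records.
    """

    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD
    require_valid_ratio: bool = True
    drop_shared_peptides: bool = True
    dedup_charge_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.intensity_threshold < 0:
            raise ValueError("intensity_threshold must be >= 0")


@dataclass
class FilterReport:
    """Per-rule row accounting. A dropped record is charged to the first rule
    it fails (intensity before ratio validity), so counts always reconcile:
    rows_in == kept + dropped_below_threshold + dropped_invalid_ratio
    + dropped_duplicate + dropped_shared."""

    rows_in: int = 0
    kept: int = 0
    dropped_below_threshold: int = 0
    dropped_invalid_ratio: int = 0
    dropped_duplicate: int = 0
    dropped_shared: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)

    def merge(self, other: "FilterReport") -> "FilterReport":
        merged = FilterReport()
        for k in merged.__dict__:
            setattr(merged, k, getattr(self, k) + getattr(other, k))
        return merged


def filter_peptides(
    records: Sequence[PeptideRecord],
    config: FilterConfig = FilterConfig(),
    report: FilterReport | None = None,
) -> list[PeptideRecord]:
    """Drop low-quality identifications.

    Kept records satisfy ``combined_area > intensity_threshold`` (strict — the
    rule is *above* the threshold) and, when required, ``ratio_valid``.
    Relative input order is preserved. Pass a :class:`FilterReport` to collect
    kept/dropped counts per rule.
    """
    if report is None:
        report = FilterReport()
    report.rows_in += len(records)
    kept: list[PeptideRecord] = []
    for rec in records:
        if not rec.combined_area > config.intensity_threshold:
            report.dropped_below_threshold += 1
        elif config.require_valid_ratio and not rec.ratio_valid:
            report.dropped_invalid_ratio += 1
        else:
            kept.append(rec)
    report.kept += len(kept)
    return kept


def _dedup_key(rec: PeptideRecord, config: FilterConfig) -> tuple:
    if config.dedup_charge_sensitive:
        return (rec.protein_id, rec.peptide_seq, rec.charge)
    return (rec.protein_id, rec.peptide_seq)


def deduplicate_peptides(
    records: Sequence[PeptideRecord],
    config: FilterConfig = FilterConfig(),
    report: FilterReport | None = None,
) -> list[PeptideRecord]:
    """Keep only the most abundant and unique peptides of each protein.

    Within each redundancy key (protein, sequence[, charge]) the record with
    the largest combined area wins; ties break to the lexicographically
    smallest spectrum_id, for determinism. With ``drop_shared_peptides`` any
    sequence observed under two or more distinct proteins is removed from all
    of them. Output is sorted by protein_id, then descending combined area,
    then spectrum_id.
    """
    if report is None:
        report = FilterReport()
    report.rows_in += len(records)

    work = list(records)
    if config.drop_shared_peptides:
        owners: dict[str, set[str]] = {}
        for rec in work:
            owners.setdefault(rec.peptide_seq, set()).add(rec.protein_id)
        shared = {seq for seq, prots in owners.items() if len(prots) > 1}
        n_before = len(work)
        work = [r for r in work if r.peptide_seq not in shared]
        report.dropped_shared += n_before - len(work)

    best: dict[tuple, PeptideRecord] = {}
    for rec in work:
        key = _dedup_key(rec, config)
        cur = best.get(key)
        if (
            cur is None
            or rec.combined_area > cur.combined_area
            or (rec.combined_area == cur.combined_area and rec.spectrum_id < cur.spectrum_id)
        ):
            best[key] = rec
    report.dropped_duplicate += len(work) - len(best)

    out = sorted(
        best.values(), key=lambda r: (r.protein_id, -r.combined_area, r.spectrum_id)
    )
    report.kept += len(out)
    return out
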