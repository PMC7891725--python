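"""Protein-level heavy/light quantification from filtered unique peptides.

The protein ratio is a *summed-area* ratio: sum the light areas and the
heavy areas over all unique peptides of the protein, then take the quotient

    R = H / L = (Σ heavy_i) / (Σ light_i),      log2_ratio = log2 R.

This intensity-weighted rollup is not the mean of per-peptide ratios — a
peptide contributes in proportion to its signal. The dispersion estimate is
the sample standard deviation (n−1) of the per-peptide log2(heavy/light)
ratios of the *top 3* peptides by combined area; proteins with fewer than
three unique peptides carry no SD and are reported in a separate
low-evidence table rather than silently dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .quant_io import PeptideRecord, ProteinQuant

__all__ = [
    "ComparisonLabel",
    "UndefinedRatioError",
    "quantify_protein",
    "quantify_proteins",
    "top3_sd",
    "apply_min_peptides",
    "annotate_proteins",
    "annotate_and_filter_targets",
    "group_summary",
]


class UndefinedRatioError(ValueError):
    """Summed light or heavy area is zero, so the ratio (and its log) is undefined."""


@dataclass(frozen=True)
class ComparisonLabel:
    """Which biological condition sits in each isotope channel, and which
    orientation the reported log2 ratios use.

    The raw tables are heavy/light; a figure may want mutant-vs-wild-type or
    the reverse. ``numerator_condition``/``denominator_condition`` name the
    requested orientation, and flipping it negates every log2 value
    (log2(a/b) = −log2(b/a)).
    """

    heavy_condition: str
    light_condition: str
    numerator_condition: str | None = None
    denominator_condition: str | None = None

    def __post_init__(self) -> None:
        if self.heavy_condition == self.light_condition:
            raise ValueError("heavy and light conditions must be distinct")
        num = self.numerator_condition or self.heavy_condition
        den = self.denominator_condition or self.light_condition
        if {num, den} != {self.heavy_condition, self.light_condition}:
            raise ValueError(
                "numerator/denominator must name the heavy and light conditions"
            )
        object.__setattr__(self, "numerator_condition", num)
        object.__setattr__(self, "denominator_condition", den)

    @property
    def flip_sign(self) -> bool:
        """True when the requested orientation is light/heavy."""
        return self.numerator_condition == self.light_condition


def top3_sd(peptides: Sequence[PeptideRecord], k: int = 3) -> float | None:
    """Sample SD of per-peptide log2(heavy/light) over the top-``k`` peptides
    by combined area.

    Selection is by combined intensity, not by ratio. A selected peptide with
    a zero area has no finite log ratio; it is skipped with a warning and, if
    fewer than ``k`` usable peptides remain, the SD is undefined (None).
    """
    if len(peptides) < k:
        return None
    ranked = sorted(peptides, key=lambda r: (-r.combined_area, r.spectrum_id))
    log_ratios: list[float] = []
    for rec in ranked:
        if rec.light_area == 0 or rec.heavy_area == 0:
            warnings.warn(
                f"{rec.spectrum_id}: zero isotope area, excluded from top-{k} SD",
                stacklevel=2,
            )
            continue
        log_ratios.append(math.log2(rec.heavy_area / rec.light_area))
        if len(log_ratios) == k:
            break
    if len(log_ratios) < k:
        return None
    return float(np.std(log_ratios, ddof=1))


def quantify_protein(peptides: Sequence[PeptideRecord]) -> ProteinQuant:
    """Roll one protein's unique peptides up to a summed-area ratio.

    All records must share a protein_id and be post-filter, post-dedup.
    Raises :class:`UndefinedRatioError` when either summed channel is zero.
    """
    if not peptides:
        raise ValueError("no peptides supplied")
    ids = {p.protein_id for p in peptides}
    if len(ids) != 1:
        raise ValueError(f"records span multiple proteins: {sorted(ids)}")
    protein_id = peptides[0].protein_id
    sum_light = float(sum(p.light_area for p in peptides))
    sum_heavy = float(sum(p.heavy_area for p in peptides))
    if sum_light == 0 or sum_heavy == 0:
        raise UndefinedRatioError(
            f"{protein_id}: summed areas L={sum_light}, H={sum_heavy} leave the "
            "heavy/light ratio undefined"
        )
    ratio = sum_heavy / sum_light
    return ProteinQuant(
        protein_id=protein_id,
        n_unique_peptides=len({p.peptide_seq for p in peptides}),
        sum_light=sum_light,
        sum_heavy=sum_heavy,
        ratio_hl=ratio,
        log2_ratio=math.log2(ratio),
        sd_log2_top3=top3_sd(peptides),
    )


def quantify_proteins(
    records: Sequence[PeptideRecord],
) -> tuple[list[ProteinQuant], list[str]]:
    """Quantify every protein present in the (filtered, deduplicated) records.

    Returns the quantifications sorted by protein_id plus the ids of proteins
    excluded because one summed channel was zero (flagged, not silently lost).
    """
    by_protein: dict[str, list[PeptideRecord]] = {}
    for rec in records:
        by_protein.setdefault(rec.protein_id, []).append(rec)
    quants: list[ProteinQuant] = []
    undefined: list[str] = []
    for protein_id in sorted(by_protein):
        try:
            quants.append(quantify_protein(by_protein[protein_id]))
        except UndefinedRatioError as exc:
            warnings.warn(str(exc), stacklevel=2)
            undefined.append(protein_id)
    return quants, undefined


def apply_min_peptides(
    proteins: Sequence[ProteinQuant], k: int = 3
) -> tuple[list[ProteinQuant], list[ProteinQuant]]:
    """Split proteins at the minimum-peptide-evidence gate (default ≥ 3).

    Returns ``(passed, low_evidence)``; the low-evidence list feeds a
    secondary table so the gate is auditable.
    """
    if k < 1:
        raise ValueError("minimum peptide count must be >= 1")
    passed = [p for p in proteins if p.n_unique_peptides >= k]
    low = [p for p in proteins if p.n_unique_peptides < k]
    return passed, low


def annotate_proteins(
    proteins: Iterable[ProteinQuant],
    targets: set[str],
    groups: dict[str, str] | None = None,
) -> list[ProteinQuant]:
    """Set known_sumo_target membership and group labels on every protein."""
    groups = groups or {}
    out = []
    for p in proteins:
        out.append(
            ProteinQuant(
                protein_id=p.protein_id,
                n_unique_peptides=p.n_unique_peptides,
                sum_light=p.sum_light,
                sum_heavy=p.sum_heavy,
                ratio_hl=p.ratio_hl,
                log2_ratio=p.log2_ratio,
                sd_log2_top3=p.sd_log2_top3,
                group=groups.get(p.protein_id, p.group),
                known_sumo_target=p.protein_id in targets,
            )
        )
    return out


def annotate_and_filter_targets(
    proteins: Sequence[ProteinQuant],
    targets: set[str],
    groups: dict[str, str] | None = None,
) -> list[ProteinQuant]:
    """Annotate all proteins, then keep only known SUMO targets for the final table.

    An empty target list would empty the final table, so it is an error.
    Proteins absent from the group map keep ``group=None`` and are retained.
    """
    if not targets:
        raise ValueError("target list is empty; final table would contain nothing")
    annotated = annotate_proteins(proteins, targets, groups)
    return [p for p in annotated if p.known_sumo_target]


def group_summary(
    proteins: Sequence[ProteinQuant],
    orientation: ComparisonLabel,
) -> pd.DataFrame:
    """Figure-facing summary: (group, protein, log2_ratio, sd) ordered by
    group then protein, in the requested ratio orientation.

    The orientation is embedded in ``DataFrame.attrs['orientation']`` so a
    rendered bar plot can label its axis; flipping numerator and denominator
    negates every log2 value and leaves the SD unchanged.
    """
    sign = -1.0 if orientation.flip_sign else 1.0
    rows = [
        {
            "group": p.group or "(ungrouped)",
            "protein_id": p.protein_id,
            "log2_ratio": sign * p.log2_ratio,
            "sd_log2_top3": p.sd_log2_top3,
            "n_unique_peptides": p.n_unique_peptides,
        }
        for p in proteins
    ]
    frame = pd.DataFrame(
        rows,
        columns=["group", "protein_id", "log2_ratio", "sd_log2_top3", "n_unique_peptides"],
    ).sort_values(["group", "protein_id"], kind="stable", ignore_index=True)
    frame.attrs["orientation"] = (
        f"log2({orientation.numerator_condition}/{orientation.denominator_condition})"
    )
    frame.attrs["heavy_condition"] = orientation.heavy_condition
    frame.attrs["light_condition"] = orientation.light_condition
    return frame
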