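"""Synthetic SILAC peptide tables and Luria–Delbrück fluctuation assays with
known ground truth.

The SILAC generator emulates the measurement model behind a two-channel
isotope-labeling comparison: each protein carries a true log2 heavy/light
ratio drawn around its functional group's mean; each of its peptides draws a
combined (light + heavy) intensity from a log-normal, perturbs the protein
ratio with multiplicative (Gaussian-on-log2) noise, and splits the combined
intensity into the two channels accordingly. Controlled fractions of
records are corrupted in the ways real search/quantifier output is: ratios
flagged invalid, intensities below the quality threshold, peptide sequences
shared between two proteins, and duplicate identifications of the same
peptide under different spectrum ids. All randomness flows from a single
seeded :class:`numpy.random.Generator`.

The fluctuation generator draws, per culture, a Poisson number of mutational
events with mean m = μ·N_t and gives each event a clone of final size
⌊1/U⌋, U ~ Uniform(0, 1], capped at N_t — the Luria–Delbrück model under
deterministic exponential growth. Plating efficiency is 1 (all cells
plated), so rates are per cell plated.

Default group means mirror the qualitative structure of a SUMO-pathway
mutant vs wild-type comparison: septin sumoylation up 2–4 fold, nuclear-pore
proteins unchanged, nucleolar/RNA-Pol-I, SMC-complex and replication/repair
(MCM) proteins down 2–4 fold, chromosome-segregation proteins mildly down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quant_io import Culture, FluctuationAssay, PeptideRecord

__all__ = [
    "GroupSpec",
    "SilacSimConfig",
    "SilacGroundTruth",
    "FluctuationSimConfig",
    "simulate_silac",
    "simulate_fluctuation",
    "write_ground_truth",
    "read_ground_truth",
    "DEFAULT_GROUPS",
]

# SILAC label mass shifts (Da): heavy Lys +8.014199, heavy Arg +10.00827;
# carbamidomethyl-Cys +57.021464 static. Used only to emit plausible
# per-peptide mass metadata; quantification never touches them.
LYS_DELTA_DA = 8.014199
ARG_DELTA_DA = 10.00827
CYS_STATIC_DA = 57.021464

_RESIDUE_MASS = {
    "A": 71.03711, "C": 103.00919, "D": 115.02694, "E": 129.04259,
    "F": 147.06841, "G": 57.02146, "H": 137.05891, "I": 113.08406,
    "K": 128.09496, "L": 113.08406, "M": 131.04049, "N": 114.04293,
    "P": 97.05276, "Q": 128.05858, "R": 156.10111, "S": 87.03203,
    "T": 101.04768, "V": 99.06841, "W": 186.07931, "Y": 163.06333,
}
_WATER = 18.010565
_INTERIOR_AA = "ACDEFGHILMNPQSTVWY"  # tryptic interiors: no K/R before the terminus


@dataclass(frozen=True)
class GroupSpec:
    """Per-functional-group simulation parameters."""

    n_proteins: int
    log2_ratio_mean: float
    log2_ratio_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.log2_ratio_sd < 0:
            raise ValueError("log2_ratio_sd must be >= 0")


DEFAULT_GROUPS: dict[str, GroupSpec] = {
    "Septins": GroupSpec(5, 1.5, 0.3),
    "NPC associated": GroupSpec(8, 0.0, 0.2),
    "Nucleolus and RNA Pol-I": GroupSpec(8, -1.5, 0.4),
    "SMC complexes": GroupSpec(8, -1.5, 0.4),
    "DNA replication and repair": GroupSpec(8, -1.5, 0.4),
    "Chromosome segregation": GroupSpec(8, -0.3, 0.2),
}


@dataclass
class SilacSimConfig:
    """Knobs of the SILAC table generator; defaults give a clean, realistic run.

    peptide_noise_sd is the SD of the per-peptide Gaussian perturbation on
    the log2 heavy/light ratio; intensity_log10_mean/sd parameterize the
    log-normal combined-area distribution (log10 scale); the frac_* knobs
    inject the four corruption modes and default to 0 so the baseline table
    is pristine.
    """

    seed: int = 0
    groups: dict[str, GroupSpec] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    peptides_per_protein: tuple[int, int] = (3, 10)
    peptide_noise_sd: float = 0.2
    intensity_log10_mean: float = 6.0
    intensity_log10_sd: float = 1.0
    intensity_threshold: float = 1e-3
    frac_invalid_ratio: float = 0.0
    frac_below_threshold: float = 0.0
    frac_shared_peptides: float = 0.0
    frac_duplicate_ids: float = 0.0
    lys_delta: float = LYS_DELTA_DA
    arg_delta: float = ARG_DELTA_DA
    cys_static: float = CYS_STATIC_DA

    def __post_init__(self) -> None:
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("peptides_per_protein must be a range [min, max], min >= 1")
        if self.peptide_noise_sd < 0:
            raise ValueError("peptide_noise_sd must be >= 0")
        for name in (
            "frac_invalid_ratio",
            "frac_below_threshold",
            "frac_shared_peptides",
            "frac_duplicate_ids",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if min(self.lys_delta, self.arg_delta, self.cys_static) <= 0:
            raise ValueError("label mass constants must be positive")


@dataclass(frozen=True)
class ProteinTruth:
    true_log2_ratio: float
    group: str
    n_peptides_emitted: int


SilacGroundTruth = dict[str, ProteinTruth]


def _tryptic_sequence(rng: np.random.Generator, length: int) -> str:
    interior = rng.choice(list(_INTERIOR_AA), size=length - 1)
    terminus = rng.choice(["K", "R"])
    return "".join(interior) + terminus


def peptide_mass(seq: str, heavy: bool, config: SilacSimConfig) -> float:
    """Monoisotopic peptide mass with static Cys and, if heavy, the label shifts."""
    mass = _WATER + sum(_RESIDUE_MASS[a] for a in seq)
    mass += seq.count("C") * config.cys_static
    if heavy:
        mass += seq.count("K") * config.lys_delta + seq.count("R") * config.arg_delta
    return mass


def simulate_silac(
    config: SilacSimConfig,
) -> tuple[list[PeptideRecord], SilacGroundTruth]:
    """Generate a peptide table plus the manifest of true per-protein ratios.

    For each peptide the combined area c is log-normal; with per-peptide
    ratio R (log2 R = true_log2 + Normal(0, σ)) the channels are
    light = c/(1+R) and heavy = c − light, so heavy/light = R and rollup of a
    noiseless protein reproduces its true ratio to double precision.
    Corruption fractions are applied per peptide record after generation;
    duplicated identifications are re-emitted under a fresh spectrum_id with
    areas scaled by a Uniform(0.3, 0.9) factor (same peptide, weaker scan).
    """
    rng = np.random.default_rng(config.seed)
    records: list[PeptideRecord] = []
    truth: SilacGroundTruth = {}
    lo, hi = config.peptides_per_protein

    protein_index = 0
    spectrum_index = 0
    protein_rows: list[tuple[str, float, list[tuple[str, int]]]] = []

    for group, spec in config.groups.items():
        for _ in range(spec.n_proteins):
            protein_index += 1
            protein_id = f"SIM{protein_index:04d}"
            true_log2 = spec.log2_ratio_mean + spec.log2_ratio_sd * rng.standard_normal()
            n_pep = int(rng.integers(lo, hi + 1))
            peptides = []
            seen: set[str] = set()
            while len(peptides) < n_pep:
                seq = _tryptic_sequence(rng, int(rng.integers(8, 21)))
                if seq in seen:
                    continue
                seen.add(seq)
                peptides.append((seq, int(rng.integers(2, 4))))
            protein_rows.append((protein_id, true_log2, peptides))
            truth[protein_id] = ProteinTruth(
                true_log2_ratio=float(true_log2), group=group, n_peptides_emitted=n_pep
            )

    # share a fraction of peptide sequences across protein pairs: the second
    # protein of each sampled pair re-emits the first's sequence verbatim
    n_proteins = len(protein_rows)
    if config.frac_shared_peptides > 0 and n_proteins >= 2:
        total_peptides = sum(len(p) for _, _, p in protein_rows)
        n_shared = int(round(config.frac_shared_peptides * total_peptides))
        for _ in range(n_shared):
            i, j = rng.choice(n_proteins, size=2, replace=False)
            donor_seq, donor_charge = protein_rows[i][2][
                int(rng.integers(len(protein_rows[i][2])))
            ]
            protein_rows[j][2].append((donor_seq, donor_charge))

    for protein_id, true_log2, peptides in protein_rows:
        for seq, charge in peptides:
            spectrum_index += 1
            log2_r = true_log2 + config.peptide_noise_sd * rng.standard_normal()
            ratio = 2.0**log2_r
            combined = 10.0 ** (
                config.intensity_log10_mean
                + config.intensity_log10_sd * rng.standard_normal()
            )
            if rng.random() < config.frac_below_threshold:
                combined = config.intensity_threshold * rng.random()
            light = combined / (1.0 + ratio)
            heavy = combined - light
            valid = rng.random() >= config.frac_invalid_ratio
            rec = PeptideRecord(
                spectrum_id=f"scan{spectrum_index:06d}",
                protein_id=protein_id,
                peptide_seq=seq,
                charge=charge,
                light_area=light,
                heavy_area=heavy,
                ratio_valid=valid,
            )
            records.append(rec)
            if rng.random() < config.frac_duplicate_ids:
                spectrum_index += 1
                scale = rng.uniform(0.3, 0.9)
                records.append(
                    PeptideRecord(
                        spectrum_id=f"scan{spectrum_index:06d}",
                        protein_id=protein_id,
                        peptide_seq=seq,
                        charge=charge,
                        light_area=light * scale,
                        heavy_area=heavy * scale,
                        ratio_valid=valid,
                    )
                )
    return records, truth


def write_ground_truth(truth: SilacGroundTruth, path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "protein_id": pid,
                "true_log2_ratio": repr(t.true_log2_ratio),
                "group": t.group,
                "n_peptides_emitted": t.n_peptides_emitted,
            }
            for pid, t in truth.items()
        ],
        columns=["protein_id", "true_log2_ratio", "group", "n_peptides_emitted"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> SilacGroundTruth:
    frame = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    return {
        row["protein_id"]: ProteinTruth(
            true_log2_ratio=float(row["true_log2_ratio"]),
            group=row["group"],
            n_peptides_emitted=int(row["n_peptides_emitted"]),
        )
        for _, row in frame.iterrows()
    }


@dataclass
class FluctuationSimConfig:
    """Luria–Delbrück simulator parameters.

    mutation_rate μ is per cell per generation; with N_t final cells per
    culture the expected number of mutational events is m = μ·N_t (the sum
    over generations of rate × cells at risk telescopes to μ·N_t under
    deterministic doubling).
    """

    seed: int = 0
    mutation_rate: float = 2e-8
    n_t: int = 10**8
    n_cultures: int = 16
    strain: str = "simulated"

    def __post_init__(self) -> None:
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be > 0")
        if self.n_t < 1:
            raise ValueError("n_t must be a positive integer")
        if self.n_cultures < 2:
            raise ValueError("need at least 2 cultures")

    @property
    def m(self) -> float:
        return self.mutation_rate * self.n_t


def simulate_fluctuation(config: FluctuationSimConfig) -> FluctuationAssay:
    """Simulate one assay: per culture, M ~ Poisson(m) mutational events, each
    founding a clone of ⌊1/U⌋ cells (U ~ Uniform(0,1]), capped at N_t; the
    mutant count is the clone-size sum."""
    rng = np.random.default_rng(config.seed)
    counts = sample_mutant_counts(rng, config.m, config.n_t, config.n_cultures)
    cultures = [
        Culture(culture_id=f"c{i + 1:03d}", mutant_count=int(r), viable_cells=config.n_t)
        for i, r in enumerate(counts)
    ]
    return FluctuationAssay(strain=config.strain, cultures=cultures)


def sample_mutant_counts(
    rng: np.random.Generator, m: float, n_t: int, n_cultures: int
) -> np.ndarray:
    """Vectorized Luria–Delbrück mutant counts for ``n_cultures`` cultures."""
    events = rng.poisson(m, size=n_cultures)
    total = int(events.sum())
    if total == 0:
        return np.zeros(n_cultures, dtype=np.int64)
    u = 1.0 - rng.random(total)  # Uniform(0, 1]
    clone_sizes = np.minimum(np.floor(1.0 / u), float(n_t)).astype(np.int64)
    owners = np.repeat(np.arange(n_cultures), events)
    counts = np.bincount(owners, weights=clone_sizes, minlength=n_cultures)
    return counts.astype(np.int64)
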