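import numpy as np
import pytest

from sumoquant.quant_io import PeptideRecord


def make_record(
    spectrum_id="s1",
    protein_id="YDR356W",
    peptide_seq="ACDEFK",
    charge=2,
    light_area=100.0,
    heavy_area=200.0,
    ratio_valid=True,
):
    return PeptideRecord(
        spectrum_id=spectrum_id,
        protein_id=protein_id,
        peptide_seq=peptide_seq,
        charge=charge,
        light_area=light_area,
        heavy_area=heavy_area,
        ratio_valid=ratio_valid,
    )


@pytest.fixture
def record_factory():
    return make_record


def random_peptide_table(rng: np.random.Generator, n_rows: int) -> list[PeptideRecord]:
    """Small random table over few proteins/sequences with a coarse area grid,
    so duplicate keys, shared sequences and exact area ties all occur."""
    proteins = ["PA", "PB", "PC"]
    sequences = ["ACDK", "EFGR", "HILK", "MNPR", "QSTK"]
    records = []
    for i in range(n_rows):
        records.append(
            make_record(
                spectrum_id=f"s{i:03d}",
                protein_id=proteins[int(rng.integers(len(proteins)))],
                peptide_seq=sequences[int(rng.integers(len(sequences)))],
                charge=int(rng.integers(2, 4)),
                light_area=float(rng.integers(0, 5)) * 0.5e-3,
                heavy_area=float(rng.integers(0, 5)) * 0.5e-3,
                ratio_valid=bool(rng.random() < 0.8),
            )
        )
    return records
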