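"""Summed-area rollup, top-3 dispersion, evidence gate and annotation."""

import math

import numpy as np
import pytest

from sumoquant.protein_quant import (
    ComparisonLabel,
    UndefinedRatioError,
    annotate_and_filter_targets,
    annotate_proteins,
    apply_min_peptides,
    group_summary,
    quantify_protein,
    quantify_proteins,
    top3_sd,
)

from conftest import make_record


def protein_peptides(pairs, protein_id="P1"):
    return [
        make_record(spectrum_id=f"s{i}", protein_id=protein_id, peptide_seq=seq,
                    light_area=l, heavy_area=h)
        for i, ((l, h), seq) in enumerate(
            zip(pairs, ["ACDK", "EFGR", "HILK", "MNPR", "QSTK", "WYVK"])
        )
    ]


class TestQuantifyProtein:
    def test_summed_area_arithmetic(self):
        quant = quantify_protein(protein_peptides([(10, 20), (20, 40), (30, 60)]))
        assert quant.sum_light == 60 and quant.sum_heavy == 120
        assert quant.ratio_hl == pytest.approx(2.0, abs=1e-12)
        assert quant.log2_ratio == pytest.approx(1.0, abs=1e-12)
        assert quant.n_unique_peptides == 3

    def test_equal_channels_give_unit_ratio(self):
        quant = quantify_protein(protein_peptides([(5, 5), (7, 7)]))
        assert quant.ratio_hl == 1.0 and quant.log2_ratio == 0.0

    def test_summed_area_is_not_mean_of_per_peptide_ratios(self):
        peptides = protein_peptides([(10, 20), (100, 100), (10, 40)])
        quant = quantify_protein(peptides)
        assert quant.ratio_hl == pytest.approx(160 / 120, abs=1e-12)
        assert quant.log2_ratio == pytest.approx(math.log2(160 / 120), abs=1e-12)
        mean_of_ratios = np.mean([2.0, 1.0, 4.0])
        assert abs(quant.ratio_hl - mean_of_ratios) > 0.9

    def test_zero_channel_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            quantify_protein(protein_peptides([(10, 0), (20, 0)]))

    def test_mixed_proteins_rejected(self):
        recs = protein_peptides([(1, 1)]) + protein_peptides([(2, 2)], protein_id="P2")
        with pytest.raises(ValueError, match="multiple proteins"):
            quantify_protein(recs)

    def test_reorder_and_rescale_invariance(self):
        peptides = protein_peptides([(10, 25), (40, 13), (7, 7), (1, 9)])
        base = quantify_protein(peptides)
        shuffled = quantify_protein(peptides[::-1])
        assert shuffled.ratio_hl == base.ratio_hl
        scaled = quantify_protein(
            [
                make_record(spectrum_id=p.spectrum_id, peptide_seq=p.peptide_seq,
                            light_area=3.0 * p.light_area, heavy_area=3.0 * p.heavy_area)
                for p in peptides
            ]
        )
        assert scaled.ratio_hl == pytest.approx(base.ratio_hl, rel=1e-12)


class TestTop3SD:
    def test_closed_form_sample_sd(self):
        # per-peptide log2 ratios 1, 2, 3 -> sample SD exactly 1
        peptides = protein_peptides([(10, 20), (10, 40), (10, 80)])
        assert top3_sd(peptides) == pytest.approx(1.0, abs=1e-12)

    def test_identical_ratios_have_zero_sd(self):
        assert top3_sd(protein_peptides([(10, 20), (5, 10), (8, 16)])) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_selection_is_by_combined_area_not_ratio(self):
        # top 3 by area have log2 ratios {0, 0, 3}; the two small ones log2 = 10
        peptides = protein_peptides(
            [(100, 100), (90, 90), (10, 80), (0.01, 10.24), (0.02, 20.48)]
        )
        assert top3_sd(peptides) == pytest.approx(math.sqrt(3), abs=1e-12)

    def test_fewer_than_three_peptides_is_undefined(self):
        assert top3_sd(protein_peptides([(1, 2), (3, 4)])) is None

    def test_zero_area_peptide_skipped_with_warning(self):
        peptides = protein_peptides([(0, 100), (10, 20), (5, 10), (8, 16)])
        with pytest.warns(UserWarning, match="zero isotope area"):
            sd = top3_sd(peptides)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_undefined_when_too_few_usable(self):
        peptides = protein_peptides([(0, 100), (10, 20), (5, 10)])
        with pytest.warns(UserWarning):
            assert top3_sd(peptides) is None


class TestEvidenceGate:
    @staticmethod
    def _proteins(counts):
        out = []
        for i, n in enumerate(counts):
            pairs = [(10.0 + j, 20.0 + j) for j in range(n)]
            seqs = [f"{'ACDEFGHILMNP'[j % 12] * 4}K" for j in range(n)]
            recs = [
                make_record(spectrum_id=f"p{i}s{j}", protein_id=f"P{i}",
                            peptide_seq=seqs[j], light_area=l, heavy_area=h)
                for j, (l, h) in enumerate(pairs)
            ]
            out.append(quantify_protein(recs))
        return out

    def test_counts_one_to_ten_with_k3_keeps_eight(self):
        passed, low = apply_min_peptides(self._proteins(range(1, 11)), k=3)
        assert len(passed) == 8 and len(low) == 2
        assert all(p.n_unique_peptides >= 3 for p in passed)

    def test_two_peptides_excluded_and_kept_in_low_evidence(self):
        passed, low = apply_min_peptides(self._proteins([2]))
        assert passed == [] and len(low) == 1

    def test_k1_is_identity(self):
        proteins = self._proteins([1, 2, 3])
        passed, low = apply_min_peptides(proteins, k=1)
        assert passed == proteins and low == []

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            apply_min_peptides([], k=0)

    def test_sd_defined_iff_gate_passed_in_default_flow(self):
        for p in self._proteins(range(1, 6)):
            assert (p.sd_log2_top3 is not None) == (p.n_unique_peptides >= 3)


class TestAnnotation:
    @staticmethod
    def _quants():
        peptides = {
            "CDC3": [(10, 40), (20, 80), (30, 120)],
            "SMC5": [(40, 10), (80, 20), (120, 30)],
            "NOPE": [(5, 5), (6, 6), (7, 7)],
        }
        return [
            quantify_protein(protein_peptides(pairs, protein_id=pid))
            for pid, pairs in peptides.items()
        ]

    def test_membership_flags_and_final_filter(self):
        final = annotate_and_filter_targets(self._quants(), {"CDC3", "SMC5"})
        assert {p.protein_id for p in final} == {"CDC3", "SMC5"}
        assert all(p.known_sumo_target for p in final)

    def test_non_target_retained_in_unfiltered_output(self):
        annotated = annotate_proteins(self._quants(), {"CDC3"})
        flags = {p.protein_id: p.known_sumo_target for p in annotated}
        assert flags == {"CDC3": True, "SMC5": False, "NOPE": False}

    def test_empty_target_list_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            annotate_and_filter_targets(self._quants(), set())

    def test_protein_missing_from_group_map_keeps_none_group(self):
        final = annotate_and_filter_targets(
            self._quants(), {"CDC3", "SMC5"}, {"CDC3": "Septins"}
        )
        groups = {p.protein_id: p.group for p in final}
        assert groups == {"CDC3": "Septins", "SMC5": None}


class TestGroupSummary:
    @staticmethod
    def _final():
        quants = TestAnnotation._quants()
        return annotate_and_filter_targets(
            quants,
            {"CDC3", "SMC5", "NOPE"},
            {"CDC3": "Septins", "SMC5": "SMC complexes", "NOPE": "SMC complexes"},
        )

    def test_rows_ordered_by_group_then_protein(self):
        label = ComparisonLabel(heavy_condition="mutant", light_condition="WT")
        frame = group_summary(self._final(), label)
        # lexicographic group order: "SMC complexes" sorts before "Septins"
        assert list(frame["protein_id"]) == ["NOPE", "SMC5", "CDC3"]
        assert list(frame["group"]) == ["SMC complexes", "SMC complexes", "Septins"]
        assert frame.attrs["orientation"] == "log2(mutant/WT)"

    def test_orientation_flip_negates_every_log2(self):
        final = self._final()
        hl = group_summary(
            final, ComparisonLabel(heavy_condition="mutant", light_condition="WT")
        )
        lh = group_summary(
            final,
            ComparisonLabel(
                heavy_condition="mutant", light_condition="WT",
                numerator_condition="WT", denominator_condition="mutant",
            ),
        )
        assert np.allclose(lh["log2_ratio"], -hl["log2_ratio"])
        assert list(lh["sd_log2_top3"]) == list(hl["sd_log2_top3"])

    def test_identical_conditions_rejected(self):
        with pytest.raises(ValueError):
            ComparisonLabel(heavy_condition="WT", light_condition="WT")


def test_quantify_proteins_flags_undefined_and_sorts():
    records = (
        protein_peptides([(10, 20), (30, 10), (5, 5)], protein_id="B")
        + protein_peptides([(10, 0), (20, 0), (30, 0)], protein_id="A")
    )
    with pytest.warns(UserWarning, match="undefined"):
        quants, undefined = quantify_proteins(records)
    assert [q.protein_id for q in quants] == ["B"]
    assert undefined == ["A"]
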