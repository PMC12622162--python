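import numpy as np
import pandas as pd
import pytest

from fevep.epidemiology import (
    GeneEpiRecord,
    PenetranceInput,
    bonferroni_threshold,
    build_masks,
    carrier_frequency,
    cohort_carriage,
    cumulative_allele_frequency,
    gene_epi_table,
    genetic_prevalence,
    penetrance,
    rank_gp,
    MASK_NAMES,
    AF_THRESHOLDS,
)


class TestCAF:
    def test_sums_allele_frequencies(self):
        assert cumulative_allele_frequency([0.001, 0.002]) == pytest.approx(0.003)

    def test_empty_is_zero(self):
        assert cumulative_allele_frequency([]) == 0.0

    def test_clamped_at_one(self, caplog):
        with caplog.at_level("WARNING"):
            assert cumulative_allele_frequency([0.7, 0.6]) == 1.0
        assert "clamped" in caplog.text

    def test_negative_af_rejected(self):
        with pytest.raises(ValueError):
            cumulative_allele_frequency([-0.1])


class TestGeneticPrevalence:
    def test_x_linked_recessive_hand_value(self):
        # CAF(CAF+1)/2 at CAF=0.5: 0.5*1.5/2
        assert genetic_prevalence(0.5, "XLR") == pytest.approx(0.375)

    def test_x_linked_dominant_hand_value(self):
        # (1-CAF)*CAF + CAF*(CAF+1)/2 at CAF=0.1: 0.09 + 0.055
        assert genetic_prevalence(0.1, "XLD") == pytest.approx(0.145)

    @pytest.mark.parametrize("mode", ["AD", "AR", "XLR", "XLD"])
    def test_zero_caf_gives_zero(self, mode):
        assert genetic_prevalence(0.0, mode) == 0.0

    def test_xlr_gp_over_caf_tends_to_half(self):
        for caf in (1e-3, 1e-5, 1e-7):
            assert genetic_prevalence(caf, "XLR") / caf == pytest.approx(0.5, rel=1e-2)

    def test_ar_gp_never_exceeds_carrier_frequency(self):
        for caf in np.linspace(0, 1, 101):
            assert genetic_prevalence(caf, "AR") <= carrier_frequency(caf, "AR") + 1e-12

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError, match="unknown inheritance"):
            genetic_prevalence(0.1, "mitochondrial")


class TestCarrierFrequency:
    def test_autosomal_hand_value(self):
        assert carrier_frequency(0.25, "AD") == pytest.approx(0.4375)

    def test_boundaries(self):
        assert carrier_frequency(0.0, "AR") == 0.0
        assert carrier_frequency(1.0, "AD") == 1.0

    def test_x_linked_pools_sexes(self):
        caf = 0.2
        expected = 0.5 * caf + 0.5 * (1 - (1 - caf) ** 2)
        assert carrier_frequency(caf, "XLR") == pytest.approx(expected)


class TestPenetrance:
    def test_bayes_hand_value(self):
        inp = PenetranceInput(
            prevalence=0.01, carrier_in_cases=0.05, carrier_in_population=0.001
        )
        assert penetrance(inp) == pytest.approx(0.5)

    def test_equal_carrier_rates_reduce_to_prevalence(self):
        inp = PenetranceInput(
            prevalence=0.03, carrier_in_cases=0.02, carrier_in_population=0.02
        )
        assert penetrance(inp) == pytest.approx(0.03)

    def test_clamped_at_one_with_warning(self, caplog):
        inp = PenetranceInput(
            prevalence=0.5, carrier_in_cases=1.0, carrier_in_population=0.1
        )
        with caplog.at_level("WARNING"):
            assert penetrance(inp) == 1.0
        assert "clamped" in caplog.text

    def test_zero_population_carrier_rejected(self):
        with pytest.raises(ValueError):
            PenetranceInput(
                prevalence=0.01, carrier_in_cases=0.5, carrier_in_population=0.0
            )


def _record(gene, crf, gp, mode="AD"):
    return GeneEpiRecord(gene=gene, inheritance=mode, caf=0.0, crf=crf, gp=gp)


class TestCohortCarriage:
    def test_two_genes_complement_product(self):
        out = cohort_carriage([_record("A", 0.5, 0.1), _record("B", 0.5, 0.2)])
        assert out["p_any_carrier"] == pytest.approx(0.75)
        assert out["expected_genotypes"] == pytest.approx(0.3)

    def test_single_gene_is_its_crf(self):
        assert cohort_carriage([_record("A", 0.37, 0.0)])["p_any_carrier"] == 0.37

    def test_empty_gives_zeroes(self):
        out = cohort_carriage([])
        assert out == {"p_any_carrier": 0.0, "expected_genotypes": 0.0}

    def test_monotone_in_each_crf(self):
        base = [_record("A", 0.2, 0.0), _record("B", 0.3, 0.0)]
        p0 = cohort_carriage(base)["p_any_carrier"]
        bumped = [_record("A", 0.25, 0.0), _record("B", 0.3, 0.0)]
        assert cohort_carriage(bumped)["p_any_carrier"] > p0


class TestRankGp:
    def test_middle_rank(self):
        assert rank_gp(0.5, [0.9, 0.3]) == 2

    def test_largest_is_rank_one(self):
        assert rank_gp(0.9, [0.5, 0.3]) == 1

    def test_all_equal_share_rank_one(self):
        assert rank_gp(0.5, [0.5, 0.5]) == 1

    def test_empty_comparators_rejected(self):
        with pytest.raises(ValueError):
            rank_gp(0.5, [])


def _classified_fixture():
    rng = np.random.default_rng(21)
    classes = ["P", "LP", "VUS_high", "VUS_mid", "VUS_low", "LB", "B"]
    pvs1 = ["very_strong", "strong", "moderate", "supporting", "none"]
    cons = ["missense", "synonymous", "stop_gained"]
    rows = []
    for i in range(300):
        rows.append(
            {
                "key": f"1:{i + 1}:A:T",
                "consequence": cons[int(rng.integers(3))],
                "acmg_class": classes[int(rng.integers(len(classes)))],
                "pvs1_strength": pvs1[int(rng.integers(len(pvs1)))],
                "score": float(rng.random()),
                "af": float(10 ** rng.uniform(-6, -0.2)),
                "ac": int(rng.choice([1, 5, 100])),
                "splice_score": float(rng.random() * 0.5),
            }
        )
    return pd.DataFrame(rows)


class TestMasks:
    def test_emits_13_masks_by_4_af_strata(self):
        masks = build_masks(_classified_fixture())
        assert len(masks) == 13 * 4
        assert {m.mask_id for m in masks} == set(MASK_NAMES)
        assert {m.af_threshold for m in masks} == set(AF_THRESHOLDS)

    def test_vus_mid_missense_above_cutoff_is_pred_damaging(self):
        df = pd.DataFrame(
            [
                {
                    "key": "1:1:A:T", "consequence": "missense", "acmg_class": "VUS_mid",
                    "pvs1_strength": "none", "score": 0.70, "af": 0.001, "ac": 5,
                    "splice_score": 0.0,
                }
            ]
        )
        masks = {(m.mask_id, m.af_threshold): m.members for m in build_masks(df)}
        assert "1:1:A:T" in masks[("pred-D", "0.5")]
        assert "1:1:A:T" in masks[("P+LP+VUS-H+pred-D", "0.5")]

    def test_splice_altering_synonymous_excluded(self):
        df = pd.DataFrame(
            [
                {
                    "key": "1:1:A:T", "consequence": "synonymous", "acmg_class": "B",
                    "pvs1_strength": "none", "score": 0.0, "af": 0.001, "ac": 5,
                    "splice_score": 0.3,
                }
            ]
        )
        masks = {(m.mask_id, m.af_threshold): m.members for m in build_masks(df)}
        assert masks[("synonymous", "0.5")] == frozenset()

    def test_af_stratum_excludes_common_variants(self):
        df = pd.DataFrame(
            [
                {
                    "key": "1:1:A:T", "consequence": "missense", "acmg_class": "P",
                    "pvs1_strength": "none", "score": 0.9, "af": 0.02, "ac": 100,
                    "splice_score": 0.0,
                }
            ]
        )
        masks = {(m.mask_id, m.af_threshold): m.members for m in build_masks(df)}
        assert "1:1:A:T" in masks[("P", "0.1")]
        assert "1:1:A:T" not in masks[("P", "0.01")]

    def test_missing_column_errors(self):
        with pytest.raises(KeyError, match="lacks columns"):
            build_masks(pd.DataFrame([{"key": "1:1:A:T"}]))

    def test_membership_matches_row_filter_oracle(self):
        """Mask membership equals an independent per-rule row filter."""
        df = _classified_fixture()
        masks = {(m.mask_id, m.af_threshold): m.members for m in build_masks(df)}
        af_rule = {
            "0.5": lambda r: r.af <= 0.5,
            "0.1": lambda r: r.af <= 0.1,
            "0.01": lambda r: r.af <= 0.01,
            "singleton": lambda r: r.ac == 1,
        }
        pred_d = lambda r: (
            r.consequence == "missense"
            and r.acmg_class in {"P", "LP", "VUS_high", "VUS_mid", "VUS_low"}
            and r.score > 0.631
        )
        class_rule = {
            "P": lambda r: r.acmg_class == "P",
            "P+LP": lambda r: r.acmg_class in {"P", "LP"},
            "P+LP+VUS-H": lambda r: r.acmg_class in {"P", "LP", "VUS_high"},
            "P+LP+VUS-H+pred-D": lambda r: r.acmg_class in {"P", "LP", "VUS_high"}
            or pred_d(r),
            "pred-D": pred_d,
            "PVS1-VS": lambda r: r.pvs1_strength == "very_strong",
            "PVS1-S": lambda r: r.pvs1_strength == "strong",
            "PVS1-M": lambda r: r.pvs1_strength == "moderate",
            "PVS1-P": lambda r: r.pvs1_strength == "supporting",
            "PVS1-VS+S": lambda r: r.pvs1_strength in {"very_strong", "strong"},
            "PVS1-VS+S+M": lambda r: r.pvs1_strength
            in {"very_strong", "strong", "moderate"},
            "PVS1-VS+S+M+P": lambda r: r.pvs1_strength
            in {"very_strong", "strong", "moderate", "supporting"},
            "synonymous": lambda r: r.consequence == "synonymous"
            and r.splice_score < 0.2,
        }
        for mask_id in MASK_NAMES:
            for thr in AF_THRESHOLDS:
                expected = {
                    r.key
                    for r in df.itertuples(index=False)
                    if class_rule[mask_id](r) and af_rule[thr](r)
                }
                assert masks[(mask_id, thr)] == frozenset(expected), (mask_id, thr)


class TestGeneEpiTable:
    def test_per_gene_records(self):
        af = pd.DataFrame(
            {
                "gene": ["A", "A", "B"],
                "af": [0.01, 0.02, 0.1],
            }
        )
        records = gene_epi_table(af, {"A": "AR", "B": "XLR"})
        by_gene = {r.gene: r for r in records}
        assert by_gene["A"].caf == pytest.approx(0.03)
        assert by_gene["A"].gp == pytest.approx(0.03**2)
        assert by_gene["B"].gp == pytest.approx(0.1 * 1.1 / 2)

    def test_missing_inheritance_errors(self):
        af = pd.DataFrame({"gene": ["A"], "af": [0.01]})
        with pytest.raises(KeyError, match="inheritance"):
            gene_epi_table(af, {})


class TestBonferroni:
    def test_threshold_is_alpha_over_n(self):
        assert bonferroni_threshold(0.05, 490) == pytest.approx(0.05 / 490)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
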