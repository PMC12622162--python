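import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fevep.acmg import (
    AcmgClass,
    CalibrationTable,
    EvidenceProfile,
    ScoreInterval,
    assign_evidence,
    class_from_points,
    classification_metrics,
    combine_points,
    fit_calibration,
    posterior_from_lr,
    strength_cutoffs,
)


class TestPosterior:
    def test_uninformative_evidence_returns_prior(self):
        assert posterior_from_lr(0.1, 1.0) == pytest.approx(0.1)

    def test_lr_ceiling_closed_form(self):
        # 350 * 0.1 / (350 * 0.1 + 0.9) = 35 / 35.9
        assert posterior_from_lr(0.1, 350) == pytest.approx(35 / 35.9, rel=1e-12)
        assert posterior_from_lr(0.1, 350) == pytest.approx(0.97493, abs=5e-6)

    def test_limit_to_one_for_huge_lr(self):
        assert posterior_from_lr(0.1, 1e12) == pytest.approx(1.0, abs=1e-10)

    @settings(deadline=None, derandomize=True)
    @given(
        prior=st.floats(0.01, 0.99),
        lr1=st.floats(0.01, 1000),
        lr2=st.floats(0.01, 1000),
    )
    def test_strictly_increasing_in_lr(self, prior, lr1, lr2):
        if lr1 == lr2:
            return
        lo, hi = sorted([lr1, lr2])
        assert posterior_from_lr(prior, lo) < posterior_from_lr(prior, hi)


class TestStrengthCutoffs:
    def test_default_ceiling_values(self):
        c = strength_cutoffs(350)["pathogenic"]
        assert c["supporting"] == pytest.approx(350 ** 0.125, rel=1e-12)
        assert c["supporting"] == pytest.approx(2.0797, abs=1e-4)
        assert c["moderate"] == pytest.approx(4.3253, abs=1e-4)
        assert c["strong"] == pytest.approx(18.7083, abs=1e-4)

    def test_algebraic_identity_supporting_to_the_eighth(self):
        c = strength_cutoffs(350)
        assert c["pathogenic"]["supporting"] ** 8 == pytest.approx(350, rel=1e-9)
        assert c["pathogenic"]["moderate"] ** 4 == pytest.approx(350, rel=1e-9)
        assert c["pathogenic"]["strong"] ** 2 == pytest.approx(350, rel=1e-9)

    def test_ceiling_sixteen_hand_roots(self):
        c = strength_cutoffs(16)["pathogenic"]
        assert c["supporting"] == pytest.approx(2 ** 0.5, rel=1e-12)
        assert c["strong"] == pytest.approx(4.0, rel=1e-12)

    def test_benign_cutoffs_are_reciprocals(self):
        c = strength_cutoffs(350)
        for k in ("supporting", "moderate", "strong"):
            assert c["benign"][k] == pytest.approx(1 / c["pathogenic"][k], rel=1e-12)


def _gaussian_calibration(seed=0, n=5000):
    rng = np.random.default_rng(seed)
    scores = np.concatenate([rng.normal(1, 1, n), rng.normal(-1, 1, n)])
    labels = np.concatenate([np.ones(n, int), np.zeros(n, int)])
    return scores, labels


class TestFitCalibration:
    def test_recovers_analytic_gaussian_lr_within_20pct(self):
        """Positives N(1,1), negatives N(-1,1): true LR(s) = exp(2s)."""
        scores, labels = _gaussian_calibration(seed=0)
        table = fit_calibration(scores, labels, prior=0.1)
        for s in np.linspace(-1.5, 1.5, 31):
            true_lr = np.exp(2 * s)
            assert abs(table.lr_at(s) - true_lr) / true_lr < 0.20, s

    def test_labels_independent_of_scores_give_no_evidence(self):
        all_none = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = fit_calibration(rng.normal(0, 1, 2000), rng.integers(0, 2, 2000))
            all_none += all(iv.evidence == "none" for iv in table.intervals)
        assert all_none >= 18  # >= 90% of 20 seeds

    def test_perfect_separation_reaches_strong_both_sides(self):
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.normal(10, 0.1, 500), rng.normal(-10, 0.1, 500)])
        labels = np.concatenate([np.ones(500, int), np.zeros(500, int)])
        table = fit_calibration(scores, labels)
        assert table.intervals[0].evidence == "BP4_strong"
        assert table.intervals[-1].evidence == "PP3_strong"

    def test_invariant_to_monotone_score_transform(self):
        scores, labels = _gaussian_calibration(seed=7, n=2000)
        t1 = fit_calibration(scores, labels)
        t2 = fit_calibration(np.tanh(scores), labels)
        lr1 = [iv.lr for iv in t1.intervals]
        lr2 = [iv.lr for iv in t2.intervals]
        np.testing.assert_allclose(lr1, lr2, rtol=1e-12)

    def test_lr_monotone_in_score(self):
        scores, labels = _gaussian_calibration(seed=3, n=2000)
        table = fit_calibration(scores, labels)
        lrs = [iv.lr for iv in table.intervals]
        assert (np.diff(lrs) >= -1e-12).all()

    def test_insufficient_data_errors(self):
        with pytest.raises(ValueError, match="at least"):
            fit_calibration([0.1, 0.9] * 20, [0, 1] * 20, window_min=100)

    def test_table_round_trips_through_tsv(self, tmp_path):
        scores, labels = _gaussian_calibration(seed=2, n=1000)
        t = fit_calibration(scores, labels)
        t.save(tmp_path / "t.tsv")
        t2 = CalibrationTable.load(tmp_path / "t.tsv")
        assert t2.prior == t.prior
        np.testing.assert_allclose(
            [iv.lr for iv in t.intervals], [iv.lr for iv in t2.intervals], rtol=1e-9
        )
        assert [iv.evidence for iv in t.intervals] == [iv.evidence for iv in t2.intervals]


def _table_with_lrs(lrs):
    cut = strength_cutoffs(350)
    from fevep.acmg import _evidence_for_lr

    bounds = np.linspace(0, 1, len(lrs) + 1)
    return CalibrationTable(
        prior=0.1,
        lr_ceiling=350,
        intervals=[
            ScoreInterval(
                low=bounds[i], high=bounds[i + 1], local_ppv=0.5, local_npv=0.5,
                lr=lr, evidence=_evidence_for_lr(lr, cut),
            )
            for i, lr in enumerate(lrs)
        ],
    )


class TestAssignEvidence:
    def test_lr_20_is_strong_pathogenic(self):
        table = _table_with_lrs([0.5, 1.0, 20.0])
        assert assign_evidence(0.9, table) == ("PP3", "strong")

    def test_lr_one_is_no_evidence(self):
        table = _table_with_lrs([0.5, 1.0, 20.0])
        assert assign_evidence(0.5, table) is None

    def test_lr_point2_is_moderate_benign(self):
        table = _table_with_lrs([0.2, 1.0, 20.0])
        assert assign_evidence(0.1, table) == ("BP4", "moderate")

    def test_out_of_range_scores_clamp(self):
        table = _table_with_lrs([0.04, 1.0, 20.0])
        assert assign_evidence(-99.0, table) == ("BP4", "strong")
        assert assign_evidence(99.0, table) == ("PP3", "strong")


class TestCombinePoints:
    def test_strong_plus_moderate_is_likely_pathogenic(self):
        profile = EvidenceProfile(
            variant_key="v", criteria=frozenset({("PP3", "strong"), ("PM1", "moderate")})
        )
        out = combine_points(profile)
        assert (out.points, out.label) == (6, "LP")

    def test_empty_profile_is_vus_low(self):
        out = combine_points(EvidenceProfile(variant_key="v", criteria=frozenset()))
        assert (out.points, out.label) == (0, "VUS_low")

    def test_benign_moderate_plus_strong_is_likely_benign(self):
        profile = EvidenceProfile(
            variant_key="v", criteria=frozenset({("BP4", "moderate"), ("BS1", "strong")})
        )
        out = combine_points(profile)
        assert (out.points, out.label) == (-6, "LB")

    def test_pp3_and_bp4_mutually_exclusive(self):
        with pytest.raises(ValueError, match="mutually exclusive"):
            EvidenceProfile(
                variant_key="v",
                criteria=frozenset({("PP3", "supporting"), ("BP4", "supporting")}),
            )

    def test_band_boundaries(self):
        assert class_from_points(10) == "P"
        assert class_from_points(9) == "LP"
        assert class_from_points(6) == "LP"
        assert class_from_points(5) == "VUS_high"
        assert class_from_points(4) == "VUS_high"
        assert class_from_points(3) == "VUS_mid"
        assert class_from_points(2) == "VUS_mid"
        assert class_from_points(1) == "VUS_low"
        assert class_from_points(0) == "VUS_low"
        assert class_from_points(-1) == "LB"
        assert class_from_points(-6) == "LB"
        assert class_from_points(-7) == "B"

    def test_permutation_invariant(self):
        criteria = [("PP3", "strong"), ("PM1", "moderate"), ("PVS1", "very_strong")]
        results = set()
        for order in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            profile = EvidenceProfile(
                variant_key="v", criteria=frozenset(criteria[i] for i in order)
            )
            results.add(combine_points(profile))
        assert results == {AcmgClass(points=14, label="P")}


class TestClassificationMetrics:
    def test_conclusiveness_counts_vus_mid(self):
        classes = ["P"] * 5 + ["B"] * 4 + ["VUS_mid"]
        labels = [1] * 5 + [0] * 5
        m = classification_metrics(classes, labels)
        assert m["conclusiveness"] == pytest.approx(0.9)

    def test_all_vus_mid_gives_zero_conclusiveness(self):
        m = classification_metrics(["VUS_mid"] * 4, [1, 0, 1, 0])
        assert m["conclusiveness"] == 0.0

    def test_perfect_classes_give_perfect_metrics(self):
        classes = ["P", "LP", "B", "LB"]
        labels = [1, 1, 0, 0]
        m = classification_metrics(classes, labels)
        assert m["concordance"] == 1.0
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="align"):
            classification_metrics(["P"], [1, 0])
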