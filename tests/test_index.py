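"""The oncomiR index: presets, scoring, logistic link, fitting, monitoring."""

import math

import numpy as np
import pandas as pd
import pytest

from oncomir.index import (
    IndexModel,
    classify,
    cns_probability,
    compute_index,
    fit_coefficients,
    flag_rising_trajectory,
    get_preset,
    load_presets,
    score_table,
)
from oncomir.roc import auc


class TestPresets:
    def test_registry_complete(self):
        presets = load_presets()
        assert len(presets) == 8
        assert {m.compartment for m in presets.values()} == {"CSF", "plasma"}

    def test_all_thresholds_log2_consistent(self):
        for model in load_presets().values():
            assert abs(np.log2(model.threshold_raw) - model.threshold_log2) <= 0.005, (
                model.name
            )

    def test_unknown_preset_lists_available(self):
        with pytest.raises(KeyError, match="DLBCL-CSF"):
            get_preset("nope")


class TestComputeIndex:
    def test_zero_abundance_gives_zero(self):
        m = get_preset("DLBCL-CSF")
        assert compute_index(m, {k: 0.0 for k in m.panel}) == 0.0

    def test_unit_abundance_gives_coefficient_sum(self):
        m = get_preset("DLBCL-CSF")
        assert compute_index(m, {k: 1.0 for k in m.panel}) == pytest.approx(4.92)

    def test_weighted_sum(self):
        m = get_preset("BL-CSF")
        assert compute_index(m, {"miR-21": 2.0, "miR-155": 1.0}) == pytest.approx(4.89)

    def test_missing_mirna_named(self):
        m = get_preset("DLBCL-CSF")
        with pytest.raises(ValueError, match="miR-155"):
            compute_index(m, {"miR-21": 1.0, "miR-20a": 1.0})

    def test_score_table_propagates_missing(self):
        m = get_preset("BL-CSF")
        values = pd.DataFrame(
            {"miR-21": [1.0, np.nan], "miR-155": [1.0, 1.0]}, index=["a", "b"]
        )
        s = score_table(m, values)
        assert s["a"] == pytest.approx(1.57 + 1.75)
        assert np.isnan(s["b"])

    def test_zero_coefficient_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            IndexModel(name="bad", coefficients={"miR-21": 0.0, "miR-155": 1.0})


class TestCnsProbability:
    def test_midpoint_at_intercept(self):
        m = IndexModel(name="m", coefficients={"miR-21": 1.0}, intercept=3.0)
        assert cns_probability(m, {"miR-21": 3.0}) == pytest.approx(0.5)

    def test_closed_form(self):
        m = IndexModel(name="m", coefficients={"miR-21": 1.0}, intercept=0.0)
        assert cns_probability(m, {"miR-21": math.log(3)}) == pytest.approx(0.75)

    def test_monotone_and_saturating(self):
        m = IndexModel(name="m", coefficients={"miR-21": 1.0}, intercept=0.0)
        probs = [cns_probability(m, {"miR-21": s}) for s in (0.1, 1, 3, 10, 30)]
        assert all(a < b for a, b in zip(probs, probs[1:]))
        assert probs[-1] > 1 - 1e-9
        assert cns_probability(m, {"miR-21": 1000.0}) == 1.0  # saturation limit

    def test_preset_requires_explicit_intercept(self):
        m = get_preset("DLBCL-CSF")
        with pytest.raises(ValueError, match="intercept"):
            cns_probability(m, {k: 1.0 for k in m.panel})
        p = cns_probability(m, {k: 1.0 for k in m.panel}, intercept=4.92)
        assert p == pytest.approx(0.5)


class TestClassify:
    def test_boundary_is_positive(self):
        m = get_preset("DLBCL-CSF")
        positive, score = classify(m, score=m.threshold_raw)
        assert positive and score == m.threshold_raw

    def test_zero_score_negative(self):
        for m in load_presets().values():
            positive, _ = classify(m, score=0.0)
            assert not positive

    def test_log2_decision_agrees(self):
        m = get_preset("DLBCL-CSF")  # threshold_log2 3.07
        score = 2.0**3.08
        positive, _ = classify(m, score=score)
        assert positive == (np.log2(score) >= np.log2(m.threshold_raw))
        assert positive


class TestFitCoefficients:
    @staticmethod
    def two_mirna_data(seed, fc_signal=8.0, n=60, fc_noise=1.0):
        rng = np.random.default_rng(seed)
        n2 = n // 2
        sig = np.concatenate([
            2.0 ** rng.normal(0, 1, n2), fc_signal * 2.0 ** rng.normal(0, 1, n2)
        ])
        noise = np.concatenate([
            2.0 ** rng.normal(0, 1, n2), fc_noise * 2.0 ** rng.normal(0, 1, n2)
        ])
        values = pd.DataFrame({"miR-21": sig, "miR-19a": noise})
        labels = np.array([False] * n2 + [True] * n2)
        return values, labels

    def test_null_objective_near_zero(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame({
            "miR-21": 2.0 ** rng.normal(0, 1, 200),
            "miR-155": 2.0 ** rng.normal(0, 1, 200),
        })
        labels = np.array([True, False] * 100)  # classes identically distributed
        fit = fit_coefficients(values, labels, seed=1, n_starts=6)
        assert fit.objective < 0.15

    def test_informative_mirna_recovered(self):
        values, labels = self.two_mirna_data(seed=3, n=100)
        fit = fit_coefficients(values, labels, seed=3)
        assert "miR-21" in fit.model.panel
        coef_noise = fit.model.coefficients.get("miR-19a", 0.0)
        assert coef_noise <= 0.2 * fit.model.coefficients["miR-21"]

    def test_single_mirna_fit_preserves_auc(self):
        """The index is a monotone transform of a single miRNA, so the fitted
        model's training ROC equals the raw miRNA's."""
        values, labels = self.two_mirna_data(seed=5, n=80)
        single = values[["miR-21"]]
        fit = fit_coefficients(single, labels, panel=["miR-21"], seed=5, n_starts=4)
        scores = score_table(fit.model, single)
        assert auc(scores, labels) == pytest.approx(
            auc(values["miR-21"], labels), abs=1e-12
        )

    def test_deterministic_given_seed(self):
        values, labels = self.two_mirna_data(seed=9)
        a = fit_coefficients(values, labels, seed=4)
        b = fit_coefficients(values, labels, seed=4)
        assert a.model.coefficients == b.model.coefficients
        assert a.objective == b.objective

    def test_single_class_rejected(self):
        values, _ = self.two_mirna_data(seed=1)
        with pytest.raises(ValueError, match="class"):
            fit_coefficients(values, np.ones(len(values), bool))

    def test_unbounded_search_rejected(self):
        values, labels = self.two_mirna_data(seed=1)
        with pytest.raises(ValueError, match="identifiable"):
            fit_coefficients(values, labels, coef_bounds=None)


class TestSplit:
    def test_stratified_partition(self):
        from oncomir.index import split_train_test

        values, labels = TestFitCoefficients.two_mirna_data(seed=2, n=100)
        vtr, ltr, vte, lte = split_train_test(values, labels, 0.3, seed=1)
        assert len(vtr) + len(vte) == len(values)
        assert ltr.sum() + lte.sum() == labels.sum()
        assert lte.sum() == 15  # 30% of 50 positives
        # generalization sanity: model fitted on train separates test
        fit = fit_coefficients(vtr, ltr, seed=1, n_starts=6)
        assert auc(score_table(fit.model, vte), lte) > 0.8


def rising_oracle(times, scores, k, rel):
    """Brute force over all contiguous windows of k rises."""
    for start in range(len(scores) - k):
        w = scores[start : start + k + 1]
        if all(w[i] < w[i + 1] for i in range(k)):
            if w[0] == 0 or w[-1] / w[0] >= rel:
                return times[start]
    return None


class TestRisingTrajectory:
    def test_flat_series_no_alert(self):
        assert not flag_rising_trajectory([0, 1, 2, 3], [4, 4, 4, 4]).alert

    def test_alert_with_onset(self):
        res = flag_rising_trajectory([0, 1, 2], [2, 3, 5])
        assert res.alert and res.onset_time == 0 and res.fold_rise == pytest.approx(2.5)

    def test_sawtooth_no_alert(self):
        assert not flag_rising_trajectory([0, 1, 2, 3], [2, 3, 2, 3]).alert

    def test_unordered_timestamps_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            flag_rising_trajectory([0, 2, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="timepoints"):
            flag_rising_trajectory([0, 1], [1, 2], k=2)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 10))
            scores = rng.integers(1, 8, n).astype(float)
            times = np.arange(n, dtype=float)
            res = flag_rising_trajectory(times, scores, k=2, rel_increase=1.5)
            expected = rising_oracle(list(times), list(scores), 2, 1.5)
            assert res.alert == (expected is not None)
            if res.alert:
                assert res.onset_time == expected
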