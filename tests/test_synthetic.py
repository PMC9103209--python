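"""The synthetic cohort generator: determinism, latent-truth consistency,
trajectory shapes, and survival-model structure."""

import numpy as np
import pandas as pd
import pytest

from oncomir.quantification import quantify
from oncomir.roc import auc
from oncomir.survival import kaplan_meier, logrank_test
from oncomir.synthetic import (
    SyntheticConfig,
    generate_cohort,
    generate_longitudinal,
    generate_survival,
)


class TestValidation:
    def test_negative_fold_change_rejected(self):
        cfg = SyntheticConfig(fold_changes={("SCNSL", "CSF"): -2.0})
        with pytest.raises(ValueError, match="fold change"):
            cfg.validate()

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError, match="group_sizes"):
            SyntheticConfig(group_sizes={}).validate()

    def test_unknown_pattern_rejected(self, small_config):
        with pytest.raises(ValueError, match="pattern"):
            generate_longitudinal(small_config, pattern="miracle")


class TestDeterminism:
    def test_same_seed_byte_identical(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        assert a.ct_records.to_csv() == b.ct_records.to_csv()
        assert a.metadata.to_csv() == b.metadata.to_csv()
        assert a.truth.to_csv() == b.truth.to_csv()

    def test_different_seed_differs(self, small_config):
        from dataclasses import replace

        a = generate_cohort(small_config)
        b = generate_cohort(replace(small_config, seed=small_config.seed + 1))
        assert a.ct_records.to_csv() != b.ct_records.to_csv()


class TestCohortStructure:
    def test_counts_and_pairing(self, small_cohort):
        meta = small_cohort.metadata
        per_group = meta.groupby(["diagnosis", "group"])["patient_id"].nunique()
        assert per_group[("DLBCL", "SCNSL")] == 12
        assert per_group[("control", "control")] == 10
        # paired compartments share patient_id and timepoint
        by_patient = meta.groupby("patient_id")["compartment"].nunique()
        assert (by_patient == 2).all()
        assert meta.groupby("patient_id")["timepoint_months"].nunique().eq(1).all()

    def test_reference_and_spike_records_present(self, small_cohort):
        ct = small_cohort.ct_records
        samples = set(small_cohort.metadata["sample_id"])
        for assay in ("let-7a", "cel-miR-39"):
            assert set(ct.loc[ct["assay"] == assay, "sample_id"]) == samples

    def test_truth_recovered_at_zero_noise(self, noiseless_cohort):
        """2^-dCt recomputed from emitted Ct values equals the latent
        abundance exactly when noise is off."""
        _, ds = noiseless_cohort
        ct = ds.ct_records.pivot_table(index="sample_id", columns="assay",
                                       values="ct", aggfunc="mean")
        truth = ds.truth.set_index("sample_id")
        recomputed = 2.0 ** -(ct["miR-21"] - ct["let-7a"])
        assert np.allclose(recomputed.loc[truth.index], truth["miR-21"])

    def test_null_config_gives_chance_auc(self):
        cfg = SyntheticConfig(
            seed=123,
            group_sizes={("DLBCL", "systemic"): 150, ("DLBCL", "SCNSL"): 150},
            fold_changes={},  # every group at control level
        )
        ds = generate_cohort(cfg)
        table = quantify(ds.ct_records, ds.metadata, reference_group=None)
        meta = ds.metadata.set_index("sample_id")
        csf = meta[meta["compartment"] == "CSF"]
        scores = table.values.loc[csf.index, "miR-21"]
        assert auc(scores, csf["group"] == "SCNSL") == pytest.approx(0.5, abs=0.07)


class TestLongitudinal:
    def test_responder_monotone_decreasing_latent(self):
        cfg = SyntheticConfig(seed=1, sd_log2={"CSF": 0.0, "plasma": 0.0},
                              ct_noise_sd=0.0)
        ds = generate_longitudinal(cfg, "responder", n_timepoints=5)
        truth = ds.truth[ds.truth["compartment"] == "CSF"]
        assert np.all(np.diff(truth["miR-21"].to_numpy()) < 0)

    def test_refractory_monotone_increasing_latent(self):
        cfg = SyntheticConfig(seed=1, sd_log2={"CSF": 0.0, "plasma": 0.0},
                              ct_noise_sd=0.0)
        ds = generate_longitudinal(cfg, "refractory", n_timepoints=5)
        truth = ds.truth[ds.truth["compartment"] == "CSF"]
        assert np.all(np.diff(truth["miR-21"].to_numpy()) > 0)

    def test_pre_relapse_onset_position(self):
        cfg = SyntheticConfig(seed=1, sd_log2={"CSF": 0.0, "plasma": 0.0},
                              ct_noise_sd=0.0)
        ds = generate_longitudinal(
            cfg, "pre_relapse", n_timepoints=13, interval_months=1.0,
            relapse_month=12.0, onset_months=3.0,
        )
        truth = ds.truth[ds.truth["compartment"] == "CSF"].reset_index()
        months = ds.metadata[ds.metadata["compartment"] == "CSF"][
            "timepoint_months"].to_numpy()
        vals = truth["miR-21"].to_numpy()
        flat = vals[months < 9.0]
        assert np.allclose(flat, flat[0])  # flat before month 9
        assert np.all(np.diff(vals[months >= 9.0]) > 0)  # rising from month 9

    def test_too_few_timepoints_rejected(self, small_config):
        with pytest.raises(ValueError, match="timepoints"):
            generate_longitudinal(small_config, "responder", n_timepoints=2)

    def test_refractory_triggers_monitoring_flag(self):
        """A rising-trajectory alert fires on nearly every noisy refractory
        series (50 seeded replicates)."""
        from oncomir.index import flag_rising_trajectory, get_preset, score_table
        from dataclasses import replace

        model = get_preset("DLBCL-CSF")
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            cfg = SyntheticConfig(seed=seed, sd_log2={"CSF": 0.1, "plasma": 0.1},
                                  ct_noise_sd=0.05, compartments=("CSF",))
            ds = generate_longitudinal(cfg, "refractory", n_timepoints=6)
            table = quantify(ds.ct_records, ds.metadata, reference_group=None)
            scores = score_table(model, table.values)
            meta = ds.metadata.set_index("sample_id")
            months = meta.loc[scores.index, "timepoint_months"]
            order = months.argsort()
            res = flag_rising_trajectory(months.iloc[order], scores.iloc[order])
            hits += res.alert
        assert hits >= 0.95 * n_rep


class TestGenerateSurvival:
    def test_scores_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            generate_survival([1.0, 0.0], SyntheticConfig())

    def test_full_censoring_means_no_events(self):
        cfg = SyntheticConfig(seed=2, censor_rate=1.0)
        out = generate_survival(np.full(50, 4.0), cfg)
        assert out["relapse_event"].sum() == 0
        km = kaplan_meier(out["relapse_time"], out["relapse_event"])
        assert np.all(km.survival == 1.0)

    def test_null_beta_strata_indistinguishable(self):
        cfg = SyntheticConfig(seed=3, hazard_beta=0.0, censor_rate=0.1)
        scores = np.concatenate([np.full(100, 1.0), np.full(100, 16.0)])
        out = generate_survival(scores, cfg)
        hi = out.iloc[100:]
        lo = out.iloc[:100]
        res = logrank_test(hi["relapse_time"], hi["relapse_event"],
                           lo["relapse_time"], lo["relapse_event"])
        assert res.p_value > 0.01

    def test_true_hazard_ratio_structure(self):
        """With hazard_beta = ln(4), a score doubling quadruples the hazard;
        median event times scale accordingly at zero censoring."""
        cfg = SyntheticConfig(seed=4, hazard_beta=np.log(4), censor_rate=0.0,
                              followup_months=1e9, include_death=False)
        scores = np.concatenate([np.full(3000, 1.0), np.full(3000, 2.0)])
        out = generate_survival(scores, cfg)
        med_lo = out["relapse_time"][:3000].median()
        med_hi = out["relapse_time"][3000:].median()
        assert med_lo / med_hi == pytest.approx(4.0, rel=0.15)


class TestNullCalibration:
    def test_mann_whitney_p_uniform_under_null(self):
        """Kolmogorov distance of null Mann-Whitney p-values from uniform
        stays below 0.1 over 500 replicates."""
        from oncomir.groups import mann_whitney_u
        from scipy.stats import kstest

        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(500):
            x, y = rng.normal(size=20), rng.normal(size=20)
            pvals.append(mann_whitney_u(x, y).p_value)
        dist = kstest(pvals, "uniform").statistic
        assert dist < 0.1
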