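"""Synthetic liquid-biopsy cohorts with the statistical structure the
analysis pipeline assumes.

No patient-level data are publicly deposited for the study population
this package models, so every downstream stage is exercised on synthetic
cohorts.  The generator emulates:

* per-group miRNA abundances that are log-normal on the 2^-dCt scale
  (Gaussian in log2 units, so replicate noise stays Gaussian in Ct
  cycles), with multiplicative group/compartment fold-changes over the
  control mean;
* raw qPCR plumbing — duplicate Ct measurements back-computed exactly from
  the latent abundance via Ct_target = Ct_ref - log2(abundance), plus
  endogenous reference (let-7a) and exogenous spike-in (cel-miR-39)
  records per sample;
* longitudinal responder / refractory / pre-relapse trajectories, the
  last with a rise starting a configurable 1-4 months before the recorded
  relapse;
* relapse and death times from an exponential proportional-hazards model
  whose log-hazard is linear in the log2 index score, with administrative
  censoring.

Every draw flows from a single seeded generator, so a fixed seed gives
byte-identical tables.  The latent truth (abundances, scores, hazards) is
returned alongside the observables for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .quantification import ONCOMIRS, REFERENCE_ASSAY, SPIKE_IN_ASSAY

__all__ = [
    "SyntheticConfig",
    "CohortDataset",
    "default_group_sizes",
    "default_fold_changes",
    "generate_cohort",
    "generate_longitudinal",
    "generate_survival",
]

GROUPS = ("control", "systemic", "SCNSL")
TRAJECTORY_PATTERNS = ("responder", "refractory", "pre_relapse")


def default_group_sizes() -> dict[tuple[str, str], int]:
    """Cohort layout mirroring the study population: 22 non-lymphoma
    controls, 108 systemic and 54 CNS-involved B-NHL across four subtypes."""
    return {
        ("control", "control"): 22,
        ("DLBCL", "systemic"): 72,
        ("DLBCL", "SCNSL"): 25,
        ("MCL", "systemic"): 19,
        ("MCL", "SCNSL"): 15,
        ("BL", "systemic"): 13,
        ("BL", "SCNSL"): 5,
        ("B-NHL-NOS", "systemic"): 4,
        ("B-NHL-NOS", "SCNSL"): 9,
    }


def default_fold_changes() -> dict[tuple[str, str], float]:
    """Multiplicative abundance shifts vs the control mean, keyed by
    (group, compartment) and applied to every panel miRNA.

    CNS-involved disease raises CSF oncomiRs strongly (4x over systemic);
    in plasma systemic disease already runs about 2x control and CNS
    involvement adds a further ~2x, consistent with the reported 1.5-4x
    plasma rise accompanying CNS spread.
    """
    return {
        ("control", "CSF"): 1.0,
        ("control", "plasma"): 1.0,
        ("systemic", "CSF"): 1.0,
        ("systemic", "plasma"): 2.0,
        ("SCNSL", "CSF"): 4.0,
        ("SCNSL", "plasma"): 4.0,
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``fold_changes`` may be keyed ``(group, compartment)`` (applied to all
    miRNAs) or ``(group, compartment, miRNA)``; the finer key wins.
    ``hazard_beta`` is the log-hazard slope per log2 unit of index score.
    """

    seed: int = 0
    group_sizes: Mapping[tuple[str, str], int] = field(default_factory=default_group_sizes)
    compartments: tuple[str, ...] = ("CSF", "plasma")
    mirnas: tuple[str, ...] = ONCOMIRS
    base_log2_abundance: Mapping[str, float] = field(
        default_factory=lambda: {
            "miR-21": -3.0, "miR-19a": -5.0, "miR-20a": -4.0,
            "miR-92a": -4.0, "miR-155": -5.0,
        }
    )
    sd_log2: Mapping[str, float] = field(
        default_factory=lambda: {"CSF": 1.0, "plasma": 1.0}
    )
    fold_changes: Mapping[tuple, float] = field(default_factory=default_fold_changes)
    ct_reference_mean: float = 25.0
    spike_ct_mean: float = 20.0
    ct_noise_sd: float = 0.25
    n_replicates: int = 2
    # survival model
    hazard_beta: float = 0.8
    baseline_hazard: float = 0.01       # relapse events / month at log2 score 0
    death_baseline_hazard: float = 0.008
    include_death: bool = True
    censor_rate: float = 0.2
    followup_months: float = 60.0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes must not be empty")
        for key, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"negative count for group {key}")
        for comp, sd in self.sd_log2.items():
            if sd < 0:
                raise ValueError(f"negative sd_log2 for {comp}")
        for key, fc in self.fold_changes.items():
            if not fc > 0:
                raise ValueError(f"fold change must be > 0, got {fc} for {key}")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        if self.baseline_hazard <= 0 or self.death_baseline_hazard <= 0:
            raise ValueError("baseline hazards must be positive")

    def fold_change(self, group: str, compartment: str, mirna: str) -> float:
        fc = self.fold_changes.get((group, compartment, mirna))
        if fc is None:
            fc = self.fold_changes.get((group, compartment), 1.0)
        return float(fc)


@dataclass(frozen=True)
class CohortDataset:
    """Observable Ct records, sample metadata, and the latent truth."""

    ct_records: pd.DataFrame   # sample_id, assay, replicate, ct
    metadata: pd.DataFrame     # one row per sample
    truth: pd.DataFrame        # one row per sample: latent abundances etc.

    def __post_init__(self) -> None:
        samples = set(self.metadata["sample_id"])
        for assay in (REFERENCE_ASSAY, SPIKE_IN_ASSAY):
            have = set(self.ct_records.loc[self.ct_records["assay"] == assay, "sample_id"])
            if have != samples:
                raise ValueError(f"every sample needs {assay} records")
        if len(self.truth) != len(self.metadata):
            raise ValueError("truth table must have one row per sample")

    def to_csv(self, directory) -> dict[str, str]:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [("ct_long", self.ct_records), ("metadata", self.metadata),
                         ("truth", self.truth)]:
            p = directory / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        return paths


def _emit_sample(
    rows: list, truth_rows: list, rng: np.random.Generator, config: SyntheticConfig,
    patient_id: str, sample_id: str, compartment: str, latent_log2: Mapping[str, float],
) -> None:
    """Append Ct records (duplicates) and a truth row for one sample."""
    noise = config.ct_noise_sd
    ct_ref = config.ct_reference_mean
    for rep in range(1, config.n_replicates + 1):
        rows.append((sample_id, REFERENCE_ASSAY, rep, ct_ref + rng.normal(0, noise) if noise else ct_ref))
        rows.append((sample_id, SPIKE_IN_ASSAY, rep,
                     config.spike_ct_mean + rng.normal(0, noise) if noise else config.spike_ct_mean))
    truth_row = {"patient_id": patient_id, "sample_id": sample_id,
                 "compartment": compartment}
    for mirna in config.mirnas:
        l2 = latent_log2[mirna]
        ct_true = ct_ref - l2  # inverts 2^-dCt exactly
        for rep in range(1, config.n_replicates + 1):
            ct = ct_true + rng.normal(0, noise) if noise else ct_true
            rows.append((sample_id, mirna, rep, ct))
        truth_row[mirna] = float(2.0 ** l2)
    truth_rows.append(truth_row)


def generate_cohort(config: SyntheticConfig | None = None) -> CohortDataset:
    """Generate a cross-sectional diagnosis-time cohort.

    Per (group, compartment, miRNA) the latent abundance is log-normal:
    Normal(base_log2 + log2(fold_change), sd_log2) on the log2 scale.  Ct
    values are back-computed exactly from the latent abundance and receive
    additive Gaussian replicate noise in cycle units.  Paired CSF/plasma
    samples share the patient id and timepoint.  Relapse and death times
    are coupled to the latent plasma abundance sum via the exponential
    proportional-hazards model of :func:`generate_survival`.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    ct_rows: list = []
    truth_rows: list = []
    meta_rows: list = []
    patient_scores: list[float] = []
    patient_meta: list[dict] = []

    for (diagnosis, group), count in sorted(config.group_sizes.items()):
        grp = "control" if group == "control" else group
        for i in range(count):
            patient_id = f"{diagnosis}-{group}-{i:03d}"
            localization = ""
            if group == "SCNSL":
                localization = rng.choice(
                    ["meningeal", "parenchymal", "parenchymal+meningeal"],
                    p=[0.45, 0.3, 0.25],
                )
            cns_ipi = ""
            if diagnosis != "control":
                cns_ipi = rng.choice(["low", "intermediate", "high"], p=[0.2, 0.4, 0.4])
            plasma_score = np.nan
            for compartment in config.compartments:
                sample_id = f"{patient_id}-{compartment}"
                sd = float(config.sd_log2.get(compartment, 1.0))
                latent = {}
                for mirna in config.mirnas:
                    mu = (config.base_log2_abundance.get(mirna, -4.0)
                          + np.log2(config.fold_change(grp, compartment, mirna)))
                    latent[mirna] = mu + (rng.normal(0, sd) if sd else 0.0)
                _emit_sample(ct_rows, truth_rows, rng, config,
                             patient_id, sample_id, compartment, latent)
                # survival couples to plasma abundances (or the only
                # compartment available)
                if compartment == "plasma" or len(config.compartments) == 1:
                    plasma_score = float(sum(2.0 ** v for v in latent.values()))
                meta_rows.append({
                    "patient_id": patient_id, "sample_id": sample_id,
                    "diagnosis": diagnosis, "group": group,
                    "compartment": compartment, "localization": localization,
                    "timepoint_months": 0.0, "cns_ipi": cns_ipi,
                })
            patient_scores.append(plasma_score)
            patient_meta.append({"patient_id": patient_id, "is_lymphoma": diagnosis != "control"})

    surv = generate_survival(np.array(patient_scores), config, rng=rng)
    surv["patient_id"] = [m["patient_id"] for m in patient_meta]
    for col in ("relapse_time", "death_time"):
        surv.loc[[not m["is_lymphoma"] for m in patient_meta], col] = np.nan
    for col in ("relapse_event", "death_event"):
        surv.loc[[not m["is_lymphoma"] for m in patient_meta], col] = 0

    metadata = pd.DataFrame(meta_rows).merge(surv, on="patient_id", how="left")
    truth = pd.DataFrame(truth_rows)
    truth["true_plasma_score"] = truth["patient_id"].map(
        dict(zip([m["patient_id"] for m in patient_meta], patient_scores))
    )
    ct = pd.DataFrame(ct_rows, columns=["sample_id", "assay", "replicate", "ct"])
    return CohortDataset(ct_records=ct, metadata=metadata, truth=truth)


def generate_longitudinal(
    config: SyntheticConfig | None = None,
    pattern: str = "responder",
    n_timepoints: int = 6,
    n_patients: int = 1,
    interval_months: float = 1.5,
    relapse_month: float | None = None,
    onset_months: float = 3.0,
    rise_log2_per_month: float = 1.0,
) -> CohortDataset:
    """Generate serial samples for patients following a named trajectory.

    Patterns
    --------
    responder
        Latent log2 abundance decreases monotonically from the CNS-involved
        level back to the control baseline over the series.
    refractory
        Latent abundance increases monotonically from the systemic level.
    pre_relapse
        Flat at the systemic level, then rising from ``onset_months``
        before the recorded relapse (default 3, the reported median lead;
        observed range 1-4 months) at ``rise_log2_per_month``.

    ``relapse_month`` defaults to the time of the last sample for the
    pre-relapse pattern.
    """
    config = config or SyntheticConfig()
    config.validate()
    if pattern not in TRAJECTORY_PATTERNS:
        raise ValueError(
            f"unknown pattern {pattern!r}; expected one of {TRAJECTORY_PATTERNS}"
        )
    if n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    rng = np.random.default_rng(config.seed)
    months = np.arange(n_timepoints) * interval_months
    horizon = months[-1]
    if relapse_month is None:
        relapse_month = horizon

    ct_rows: list = []
    truth_rows: list = []
    meta_rows: list = []
    for p in range(n_patients):
        patient_id = f"serial-{pattern}-{p:03d}"
        for compartment in config.compartments:
            sd = float(config.sd_log2.get(compartment, 1.0))
            for t_idx, month in enumerate(months):
                latent = {}
                for mirna in config.mirnas:
                    base = config.base_log2_abundance.get(mirna, -4.0)
                    high = base + np.log2(config.fold_change("SCNSL", compartment, mirna))
                    low = base + np.log2(config.fold_change("systemic", compartment, mirna))
                    frac = month / horizon if horizon > 0 else 0.0
                    if pattern == "responder":
                        mu = high + (base - high) * frac
                    elif pattern == "refractory":
                        mu = low + (high + 1.0 - low) * frac
                    else:  # pre_relapse
                        onset = relapse_month - onset_months
                        mu = low if month < onset else low + (month - onset) * rise_log2_per_month
                    latent[mirna] = mu + (rng.normal(0, sd * 0.2) if sd else 0.0)
                sample_id = f"{patient_id}-{compartment}-t{t_idx}"
                _emit_sample(ct_rows, truth_rows, rng, config,
                             patient_id, sample_id, compartment, latent)
                relapse_event = int(pattern == "pre_relapse")
                meta_rows.append({
                    "patient_id": patient_id, "sample_id": sample_id,
                    "diagnosis": "DLBCL", "group": pattern,
                    "compartment": compartment, "localization": "",
                    "timepoint_months": float(month), "cns_ipi": "",
                    "relapse_time": float(relapse_month) if relapse_event else np.nan,
                    "relapse_event": relapse_event,
                    "death_time": np.nan, "death_event": 0,
                })
    ct = pd.DataFrame(ct_rows, columns=["sample_id", "assay", "replicate", "ct"])
    return CohortDataset(
        ct_records=ct, metadata=pd.DataFrame(meta_rows), truth=pd.DataFrame(truth_rows)
    )


def generate_survival(
    index_values,
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw relapse/death outcomes from an exponential hazards model.

    The per-patient relapse hazard is
    ``baseline_hazard * exp(hazard_beta * log2(score))`` and the death
    hazard analogously with ``death_baseline_hazard``, independent given
    the score.  A ``censor_rate`` fraction of patients is administratively
    censored at enrollment (time 0, contributing no follow-up): censoring
    a fixed fraction *during* follow-up while suppressing their events
    would be informative and attenuate hazard-ratio estimates, whereas
    entry censoring is an independent thinning and leaves estimation
    unbiased.  Everyone else is censored at the follow-up horizon.  The
    true hazard ratio between two scores is
    ``exp(hazard_beta * (log2(s1) - log2(s2)))``.
    """
    config = config or SyntheticConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    scores = np.asarray(index_values, dtype=float)
    if np.any(~np.isfinite(scores)) or np.any(scores <= 0):
        raise ValueError("index scores must be finite and positive")
    n = scores.size
    log2s = np.log2(scores)

    def draw(h0: float) -> np.ndarray:
        hazard = h0 * np.exp(config.hazard_beta * log2s)
        return rng.exponential(1.0 / hazard)

    relapse_latent = draw(config.baseline_hazard)
    death_latent = (draw(config.death_baseline_hazard) if config.include_death
                    else np.full(n, np.inf))

    dropout = rng.random(n) < config.censor_rate
    censor = np.where(dropout, 0.0, config.followup_months)

    relapse_event = ((relapse_latent <= censor) & ~dropout).astype(int)
    relapse_time = np.where(relapse_event == 1, relapse_latent, censor)
    death_event = ((death_latent <= censor) & ~dropout).astype(int)
    death_time = np.where(death_event == 1, death_latent, censor)
    return pd.DataFrame({
        "relapse_time": relapse_time, "relapse_event": relapse_event,
        "death_time": death_time, "death_event": death_event,
    })
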