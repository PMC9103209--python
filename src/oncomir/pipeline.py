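"""End-to-end orchestration: quantification -> index scoring/fitting ->
ROC -> group comparisons -> survival, with a manifest for reproducibility.

Every number in the emitted report is produced by one of the library
operations; this layer only sequences them and writes tables.  A fixed
seed makes the whole bundle byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import groups as gc
from . import index as im
from . import roc as rm
from . import survival as sv
from .io import write_table
from .quantification import ONCOMIRS, quantify
from .synthetic import CohortDataset, SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``synthetic`` (a :class:`SyntheticConfig`) or
    ``input_dir`` (a directory holding ``ct_long.csv`` and
    ``metadata.csv``) must be supplied.
    """

    out_dir: str = "oncomir_report"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None
    reference_group: str = "control"
    survival_horizon_months: float = 48.0
    fit_panel: tuple[str, ...] = ONCOMIRS
    fit_starts: int = 8

    def validate(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError("supply exactly one of synthetic config or input_dir")


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    roc_summaries: pd.DataFrame
    survival_summary: dict


def _config_hash(config: PipelineConfig) -> str:
    def stringify(obj):
        if isinstance(obj, dict):
            return {str(k): stringify(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
        if isinstance(obj, (list, tuple)):
            return [stringify(v) for v in obj]
        return obj

    payload = json.dumps(stringify(asdict(config)), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _load_data(config: PipelineConfig) -> CohortDataset | tuple[pd.DataFrame, pd.DataFrame]:
    if config.synthetic is not None:
        synth = config.synthetic
        if synth.seed != config.seed:
            from dataclasses import replace

            synth = replace(synth, seed=config.seed)
        return generate_cohort(synth)
    from .io import read_table

    base = Path(config.input_dir)
    ct = read_table(base / "ct_long.csv", "ct_long")
    meta = read_table(base / "metadata.csv", "metadata")
    return ct, meta


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write a report bundle to ``out_dir``.

    Stages (each failure aborts with the stage name):

    1. data: synthetic cohort generation or CSV input
    2. quantification: Ct -> equalized relative expression + QC
    3. index: preset scoring and per-(diagnosis, compartment) fitting
    4. roc: CNS-vs-systemic curves, closest-corner thresholds, Youden
    5. groups: Kruskal-Wallis + Mann-Whitney per miRNA and compartment
    6. survival: high/low stratification, incidence, Cox hazard ratios
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    stage = "data"
    try:
        data = _load_data(config)
        if isinstance(data, CohortDataset):
            ct, meta = data.ct_records, data.metadata
            paths = data.to_csv(out / "synthetic")
            outputs += list(paths.values())
        else:
            ct, meta = data

        stage = "quantification"
        table = quantify(ct, meta, reference_group=config.reference_group)
        expr_path = write_table(table.values.reset_index(), out / "expression.csv")
        qc_path = write_table(table.qc, out / "qc_flags.csv")
        outputs += [str(expr_path), str(qc_path)]

        stage = "index"
        sample_meta = meta.set_index("sample_id").loc[table.values.index]
        preset_scores = {}
        for name, model in im.load_presets().items():
            panel_ok = all(m in table.values.columns for m in model.panel)
            if panel_ok:
                preset_scores[name] = im.score_table(model, table.values)
        preset_df = pd.DataFrame(preset_scores)
        preset_df.insert(0, "sample_id", preset_df.index)
        outputs.append(str(write_table(preset_df, out / "preset_scores.csv")))

        fitted: dict[tuple[str, str], im.FitResult] = {}
        for (diagnosis, compartment), sub in sample_meta.groupby(["diagnosis", "compartment"]):
            if diagnosis == "control":
                continue
            labels = sub["group"] == "SCNSL"
            if labels.sum() < 2 or (~labels).sum() < 2:
                continue
            vals = table.values.loc[sub.index, list(config.fit_panel)].dropna()
            labs = labels.loc[vals.index]
            fit = im.fit_coefficients(
                vals, labs, panel=config.fit_panel, seed=config.seed,
                n_starts=config.fit_starts,
                name=f"{diagnosis}-{compartment}-fitted", compartment=compartment,
            )
            fitted[(diagnosis, compartment)] = fit

        stage = "roc"
        roc_rows = []
        fitted_models = {}
        for (diagnosis, compartment), fit in fitted.items():
            sub = sample_meta[(sample_meta["diagnosis"] == diagnosis)
                              & (sample_meta["compartment"] == compartment)]
            scores = im.score_table(fit.model, table.values.loc[sub.index]).dropna()
            labels = (sub.loc[scores.index, "group"] == "SCNSL").to_numpy()
            curve = rm.select_threshold_closest_corner(rm.roc_curve(scores, labels))
            model = fit.model.with_threshold(curve.threshold)
            fitted_models[f"{diagnosis}-{compartment}"] = model
            roc_rows.append({
                "diagnosis": diagnosis, "compartment": compartment,
                "auc": curve.auc,
                "sensitivity": curve.threshold_sensitivity,
                "specificity": curve.threshold_specificity,
                "youden": rm.youden_index(curve.threshold_sensitivity,
                                          curve.threshold_specificity),
                "threshold_raw": curve.threshold,
                "threshold_log2": float(np.log2(curve.threshold))
                if curve.threshold and curve.threshold > 0 else np.nan,
                "objective": fit.objective,
                "panel": "/".join(model.panel),
            })
        roc_df = pd.DataFrame(roc_rows)
        outputs.append(str(write_table(roc_df, out / "roc_summary.csv")))
        models_json = {k: m.to_dict() for k, m in fitted_models.items()}
        (out / "fitted_models.json").write_text(json.dumps(models_json, indent=2))
        outputs.append(str(out / "fitted_models.json"))

        stage = "groups"
        group_rows = []
        for compartment, sub in sample_meta.groupby("compartment"):
            for mirna in table.values.columns:
                vals = table.values.loc[sub.index, mirna]
                by = {
                    g: vals[sub["group"] == g].dropna().to_numpy()
                    for g in sub["group"].unique()
                }
                by = {g: v for g, v in by.items() if v.size > 0}
                if len(by) >= 2:
                    kw = gc.kruskal_wallis(*by.values())
                    group_rows.append({
                        "compartment": compartment, "mirna": mirna,
                        "test": "kruskal-wallis", "groups": "/".join(by),
                        "statistic": kw.statistic, "p_value": kw.p_value,
                        "stars": gc.significance_stars(kw.p_value),
                    })
                if "SCNSL" in by and "systemic" in by:
                    mw = gc.mann_whitney_u(by["SCNSL"], by["systemic"])
                    group_rows.append({
                        "compartment": compartment, "mirna": mirna,
                        "test": "mann-whitney", "groups": "SCNSL/systemic",
                        "statistic": mw.statistic, "p_value": mw.p_value,
                        "stars": gc.significance_stars(mw.p_value),
                    })
        outputs.append(str(write_table(pd.DataFrame(group_rows), out / "group_tests.csv")))

        stage = "survival"
        survival_summary: dict = {}
        key = "DLBCL-plasma"
        if key in fitted_models and "relapse_time" in meta.columns:
            model = fitted_models[key]
            sub = sample_meta[(sample_meta["diagnosis"] == "DLBCL")
                              & (sample_meta["compartment"] == "plasma")]
            scores = im.score_table(model, table.values.loc[sub.index])
            strata = sv.stratify_by_index(scores, model.threshold_raw)
            surv = sub.loc[strata.index, ["patient_id", "relapse_time", "relapse_event",
                                          "death_time", "death_event", "cns_ipi"]].copy()
            surv["stratum"] = strata["stratum"]
            surv = surv.dropna(subset=["relapse_time"])
            if (surv["stratum"] == "high").any() and (surv["stratum"] == "low").any():
                tbl = sv.risk_table(
                    surv.rename(columns={"relapse_time": "time", "relapse_event": "event"}),
                    "stratum", horizon=config.survival_horizon_months, reference="low",
                )
                outputs.append(str(write_table(tbl.reset_index(), out / "relapse_risk.csv")))
                hi, lo = surv["stratum"] == "high", surv["stratum"] == "low"
                lr = sv.logrank_test(
                    surv.loc[hi, "relapse_time"], surv.loc[hi, "relapse_event"],
                    surv.loc[lo, "relapse_time"], surv.loc[lo, "relapse_event"],
                )
                combined = sv.combined_risk_strata(
                    (surv["stratum"] == "high"), surv["cns_ipi"] == "high"
                )
                surv["combined"] = combined
                ctbl = sv.risk_table(
                    surv.rename(columns={"relapse_time": "time", "relapse_event": "event"}),
                    "combined", horizon=config.survival_horizon_months, reference="no risk",
                )
                outputs.append(str(write_table(ctbl.reset_index(), out / "combined_risk.csv")))
                survival_summary = {
                    "model": key,
                    "fraction_high": strata.attrs["fraction_high"],
                    "logrank_chi2": lr.chi2, "logrank_p": lr.p_value,
                    "risk_table": tbl.reset_index().to_dict(orient="records"),
                    "combined_risk_table": ctbl.reset_index().to_dict(orient="records"),
                }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "outputs": sorted(str(Path(p).relative_to(out)) for p in outputs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    summary = {
        "seed": config.seed,
        "roc": roc_df.to_dict(orient="records"),
        "survival": survival_summary,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return PipelineResult(
        out_dir=out, manifest=manifest, roc_summaries=roc_df,
        survival_summary=survival_summary,
    )
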