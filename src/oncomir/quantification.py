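"""qPCR quantification: duplicate averaging, 2^-dCt relative expression,
spike-in QC, and equalization to a reference group.

The pipeline turns raw Ct records (one row per sample x assay x replicate)
into an :class:`ExpressionTable` of dimensionless relative expression
values — the per-miRNA ``Abundance`` inputs of the oncomiR index:

1. replicate Ct values are averaged on the cycle scale (replicate noise is
   approximately Gaussian in cycles);
2. each target miRNA is normalized to the endogenous reference miR-let-7a
   via 2^-(Ct_target - Ct_reference);
3. values are equalized so the mean of a designated reference group
   (non-lymphoma controls by default, optionally the systemic-lymphoma
   group) is exactly 1 per (miRNA, compartment).

Undetermined Ct values are treated as missing throughout — never as a
pseudo-Ct at the detection limit — and every missing output is traceable
to a QC flag.  Samples whose exogenous spike-in (cel-miR-39) deviates from
the batch median are flagged and excluded from equalization statistics but
retained in the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCE_ASSAY",
    "SPIKE_IN_ASSAY",
    "ONCOMIRS",
    "ExpressionTable",
    "average_duplicates",
    "relative_expression",
    "spike_in_qc",
    "equalize_to_reference",
    "quantify",
]

REFERENCE_ASSAY = "let-7a"
SPIKE_IN_ASSAY = "cel-miR-39"
ONCOMIRS = ("miR-21", "miR-19a", "miR-20a", "miR-92a", "miR-155")

#: Replicate Ct spread (cycles) above which the averaged value is flagged.
DEFAULT_SPREAD_TOLERANCE = 1.0
#: Spike-in deviation from the batch median (cycles) that fails a sample.
DEFAULT_SPIKE_TOLERANCE = 2.0

CT_COLUMNS = ["sample_id", "assay", "replicate", "ct"]


@dataclass(frozen=True)
class ExpressionTable:
    """Samples x miRNAs matrix of relative expression with QC sidecar.

    ``values`` holds strictly positive relative-expression values (NaN
    where missing); ``qc`` holds one row per flag with columns
    ``sample_id, assay, flag, detail``; ``meta`` carries per-sample
    metadata (at minimum ``sample_id``, typically also group, diagnosis,
    compartment).  ``equalized_to`` names the reference group once
    :func:`equalize_to_reference` has run.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    qc: pd.DataFrame
    reference_assay: str = REFERENCE_ASSAY
    equalized_to: str | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("relative expression must be strictly positive or missing")

    def failed_samples(self) -> set[str]:
        """Samples with a spike-in failure flag."""
        if self.qc.empty:
            return set()
        bad = self.qc.loc[self.qc["flag"] == "spike_in_fail", "sample_id"]
        return set(bad)


def _qc_frame(rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["sample_id", "assay", "flag", "detail"])


def average_duplicates(
    records: pd.DataFrame, spread_tolerance: float = DEFAULT_SPREAD_TOLERANCE
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse replicate Ct measurements to one value per (sample, assay).

    Parameters
    ----------
    records
        Long-format frame with columns ``sample_id, assay, replicate, ct``;
        ``ct`` is NaN for undetermined wells.
    spread_tolerance
        Maximum tolerated replicate range in cycles before flagging.

    Returns
    -------
    (averaged, qc)
        ``averaged`` has columns ``sample_id, assay, ct`` (NaN when every
        replicate was undetermined); ``qc`` lists ``replicate_spread``,
        ``partial_replicates`` and ``all_undetermined`` flags.
    """
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct records missing columns: {missing}")
    if (records["replicate"] < 1).any():
        raise ValueError("replicate numbers must be >= 1")

    qc_rows: list[tuple] = []
    out_rows: list[tuple] = []
    for (sample, assay), grp in records.groupby(["sample_id", "assay"], sort=True):
        cts = grp["ct"].to_numpy(dtype=float)
        valid = cts[np.isfinite(cts)]
        if valid.size == 0:
            out_rows.append((sample, assay, np.nan))
            qc_rows.append((sample, assay, "all_undetermined",
                            f"{cts.size} undetermined replicate(s)"))
            continue
        if valid.size < cts.size:
            qc_rows.append((sample, assay, "partial_replicates",
                            f"{cts.size - valid.size} of {cts.size} undetermined"))
        if valid.size > 1 and np.ptp(valid) > spread_tolerance:
            qc_rows.append((sample, assay, "replicate_spread",
                            f"range {np.ptp(valid):.2f} > {spread_tolerance} cycles"))
        out_rows.append((sample, assay, float(valid.mean())))
    averaged = pd.DataFrame(out_rows, columns=["sample_id", "assay", "ct"])
    return averaged, _qc_frame(qc_rows)


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Relative expression by the 2^-dCt rule: 2^-(Ct_target - Ct_ref).

    Strictly positive and decreasing in ``ct_target`` (each extra cycle
    halves the estimate).  NaN inputs propagate to NaN.
    """
    return float(2.0 ** -(np.asarray(ct_target, dtype=float)
                          - np.asarray(ct_reference, dtype=float)))


def spike_in_qc(
    spike_cts: pd.Series, tolerance: float = DEFAULT_SPIKE_TOLERANCE
) -> pd.DataFrame:
    """Per-sample pass/fail on the exogenous cel-miR-39 spike-in.

    A sample fails when its spike-in Ct deviates from the batch median by
    more than ``tolerance`` cycles (poor recovery or inhibition), or when
    the spike-in is missing entirely.

    Parameters
    ----------
    spike_cts
        Series indexed by sample_id of spike-in Ct values (NaN = missing).
    tolerance
        Allowed absolute deviation from the batch median, in cycles.

    Returns
    -------
    pandas.DataFrame
        Columns ``sample_id, spike_ct, deviation, passed, reason``.
    """
    if len(spike_cts) < 3:
        raise ValueError(
            f"batch too small for spike-in QC: {len(spike_cts)} samples (need >= 3)"
        )
    cts = spike_cts.astype(float)
    batch_median = float(np.nanmedian(cts.to_numpy()))
    rows = []
    for sample, ct in cts.items():
        if not np.isfinite(ct):
            rows.append((sample, np.nan, np.nan, False, "no spike-in"))
            continue
        dev = abs(ct - batch_median)
        ok = dev <= tolerance
        rows.append((sample, float(ct), float(dev), ok,
                     "" if ok else f"deviation {dev:.2f} > {tolerance} cycles"))
    return pd.DataFrame(
        rows, columns=["sample_id", "spike_ct", "deviation", "passed", "reason"]
    )


def equalize_to_reference(
    table: ExpressionTable,
    reference_group: str,
    group_column: str = "group",
    compartment_column: str = "compartment",
) -> ExpressionTable:
    """Divide every value by the reference-group mean per (miRNA, compartment).

    After equalization the reference group's mean is exactly 1 for each
    miRNA within each compartment, so values read as fold change over the
    reference (controls, or the systemic-lymphoma average when fitting
    indices against systemic disease).  Samples that failed spike-in QC are
    excluded from the denominator but still rescaled.
    """
    if group_column not in table.meta.columns:
        raise ValueError(f"metadata lacks a {group_column!r} column")
    meta = table.meta.set_index("sample_id")
    if compartment_column in meta.columns:
        compartments = meta.loc[table.values.index, compartment_column]
    else:
        compartments = pd.Series("all", index=table.values.index)
    groups = meta.loc[table.values.index, group_column]
    failed = table.failed_samples()
    usable = ~table.values.index.isin(sorted(failed))

    values = table.values.copy()
    for comp in compartments.unique():
        in_comp = (compartments == comp).to_numpy()
        ref_mask = in_comp & (groups == reference_group).to_numpy() & usable
        for mirna in values.columns:
            ref_vals = values.loc[ref_mask, mirna].dropna()
            if ref_vals.empty:
                raise ValueError(
                    f"empty reference group {reference_group!r} for "
                    f"({mirna}, compartment {comp!r})"
                )
            values.loc[in_comp, mirna] = values.loc[in_comp, mirna] / ref_vals.mean()
    return replace(table, values=values, equalized_to=reference_group)


def quantify(
    records: pd.DataFrame,
    meta: pd.DataFrame,
    reference_group: str | None = "control",
    reference_assay: str = REFERENCE_ASSAY,
    spike_assay: str = SPIKE_IN_ASSAY,
    spread_tolerance: float = DEFAULT_SPREAD_TOLERANCE,
    spike_tolerance: float = DEFAULT_SPIKE_TOLERANCE,
) -> ExpressionTable:
    """Full quantification pipeline from raw Ct records to expression.

    Averages duplicates, runs spike-in QC per compartment batch, computes
    2^-dCt against ``reference_assay``, and (unless ``reference_group`` is
    None) equalizes to the reference group mean.  Samples with a missing
    endogenous reference Ct get all-missing values plus a
    ``missing_reference`` flag.
    """
    averaged, qc = average_duplicates(records, spread_tolerance)
    wide = averaged.pivot(index="sample_id", columns="assay", values="ct")
    if reference_assay not in wide.columns:
        raise ValueError(f"reference assay {reference_assay!r} absent from records")

    qc_rows: list[tuple] = []
    meta_idx = meta.set_index("sample_id")
    comp = (
        meta_idx.loc[wide.index, "compartment"]
        if "compartment" in meta_idx.columns
        else pd.Series("all", index=wide.index)
    )

    if spike_assay in wide.columns:
        for batch_label in comp.unique():
            batch = wide.index[comp == batch_label]
            if len(batch) < 3:
                continue
            report = spike_in_qc(wide.loc[batch, spike_assay], spike_tolerance)
            for _, row in report[~report["passed"]].iterrows():
                qc_rows.append((row["sample_id"], spike_assay,
                                "spike_in_fail", row["reason"]))

    targets = [c for c in wide.columns if c not in (reference_assay, spike_assay)]
    ref_ct = wide[reference_assay]
    for sample in wide.index[ref_ct.isna()]:
        qc_rows.append((sample, reference_assay, "missing_reference",
                        "reference Ct undetermined; sample values missing"))
    expr = 2.0 ** -(wide[targets].sub(ref_ct, axis=0))

    table = ExpressionTable(
        values=expr,
        meta=meta,
        qc=pd.concat([qc, _qc_frame(qc_rows)], ignore_index=True),
        reference_assay=reference_assay,
    )
    if reference_group is not None:
        table = equalize_to_reference(table, reference_group)
    return table
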