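"""Longitudinal single-vessel flow analysis.

Relative changes against baseline, the arteriole-venule flow-conservation
fit (flow entering a closed vascular bed through arterioles must leave
through venules, so their flow *changes* should correlate over time), and
the V/D² decomposition separating velocity-dominated from dilation-
dominated flow changes. Since Q = k (pi/4) V D², the percent change of
V/D² is positive when a flow change is achieved mainly by a velocity
increase (arteriole-like) and negative when achieved mainly by dilation
(venule-like).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import LongitudinalSeries, ParameterError


def relative_change(value: float, baseline_value: float) -> float:
    """Percent change relative to baseline: ``(value/baseline - 1) * 100``."""
    if baseline_value == 0:
        raise ParameterError("baseline value must be nonzero")
    return (value / baseline_value - 1.0) * 100.0


def flow_conservation_fit(
    arteriole_dq_pct: Sequence[float],
    venule_dq_pct: Sequence[float],
) -> tuple[float, float, float]:
    """OLS fit of venule flow change on arteriole flow change.

    Returns ``(slope, intercept, r_squared)`` where R² is the squared
    Pearson correlation. Conservation of flow through the vascular bed
    predicts a strong positive correlation.
    """
    x = np.asarray(arteriole_dq_pct, dtype=float)
    y = np.asarray(venule_dq_pct, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("series must be paired (equal length)")
    if x.size < 3:
        raise ParameterError("need at least 3 paired timepoints")
    if np.ptp(x) == 0:
        raise ParameterError("arteriole series has zero variance")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


def series_relative_changes(series: LongitudinalSeries) -> pd.DataFrame:
    """Per-timepoint percent changes of V, D and Q relative to baseline."""
    base = series.baseline
    rows = []
    for m in series.measurements:
        rows.append({
            "vessel_id": series.vessel_id,
            "vessel_type": series.vessel_type,
            "timepoint": m.timepoint,
            "dv_pct": relative_change(m.velocity_mm_s, base.velocity_mm_s),
            "dd_pct": relative_change(m.diameter_um, base.diameter_um),
            "dq_pct": relative_change(m.flow_nl_s, base.flow_nl_s),
        })
    return pd.DataFrame(rows)


def v_over_d2_ratio(series: LongitudinalSeries) -> pd.DataFrame:
    """Percent change of V/D² per timepoint (0 at baseline by construction).

    Positive values mean the flow change is velocity-dominated
    (arteriole-like), negative means dilation-dominated (venule-like).
    """
    base = series.baseline
    base_ratio = base.velocity_mm_s / base.diameter_um ** 2
    if base_ratio == 0:
        raise ParameterError("baseline V/D^2 is zero")
    rows = []
    for m in series.measurements:
        ratio = m.velocity_mm_s / m.diameter_um ** 2
        rows.append({
            "vessel_id": series.vessel_id,
            "vessel_type": series.vessel_type,
            "timepoint": m.timepoint,
            "v_over_d2_change_pct": (ratio / base_ratio - 1.0) * 100.0,
        })
    return pd.DataFrame(rows)


def summarize_cohort(values_by_timepoint: pd.DataFrame,
                     value_column: str,
                     timepoint_column: str = "timepoint",
                     timepoint_order: Sequence[str] | None = None,
                     ) -> pd.DataFrame:
    """Per-timepoint mean ± sample SD (n-1 denominator) with n.

    SD is reported as NaN when n = 1 (undefined, never 0).
    """
    if values_by_timepoint.empty:
        raise ParameterError("empty cohort table")
    grouped = values_by_timepoint.groupby(timepoint_column)[value_column]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    out = out.reset_index()
    if timepoint_order is not None:
        out[timepoint_column] = pd.Categorical(out[timepoint_column],
                                               categories=timepoint_order,
                                               ordered=True)
        out = out.sort_values(timepoint_column).reset_index(drop=True)
    return out


def friedman_test(values: pd.DataFrame, value_column: str,
                  subject_column: str = "replicate",
                  timepoint_column: str = "timepoint") -> tuple[float, float]:
    """Friedman test across timepoints with subjects as blocks.

    Delegated to the standard implementation; returns (statistic, p-value).
    """
    pivot = values.pivot(index=subject_column, columns=timepoint_column,
                         values=value_column)
    if pivot.isna().any().any():
        raise ParameterError("unbalanced design: missing timepoints")
    groups = [pivot[c].to_numpy() for c in pivot.columns]
    stat, p = stats.friedmanchisquare(*groups)
    return float(stat), float(p)


def conservation_analysis(cohort: pd.DataFrame,
                          pool: str = "replicates") -> dict:
    """Flow-conservation fit on a paired arteriole/venule cohort table.

    ``cohort`` must carry columns ``replicate, vessel_type, timepoint,
    flow_nl_s``. With ``pool="replicates"`` all per-replicate non-baseline
    timepoints are pooled into one fit; with ``pool="means"`` the fit uses
    per-timepoint cohort means (both are reported by the pipeline since the
    pooling convention affects R²).
    """
    if pool not in ("replicates", "means"):
        raise ParameterError("pool must be 'replicates' or 'means'")
    records = []
    for rep, sub in cohort.groupby("replicate"):
        for vtype in ("arteriole", "venule"):
            vs = sub[sub.vessel_type == vtype].set_index("timepoint")
            base = vs.loc["baseline", "flow_nl_s"]
            for tp in vs.index:
                if tp == "baseline":
                    continue
                records.append({
                    "replicate": rep, "timepoint": tp, "vessel_type": vtype,
                    "dq_pct": relative_change(vs.loc[tp, "flow_nl_s"], base),
                })
    changes = pd.DataFrame(records)
    wide = changes.pivot_table(index=["replicate", "timepoint"],
                               columns="vessel_type", values="dq_pct")
    if pool == "means":
        wide = wide.groupby(level="timepoint").mean()
    slope, intercept, r2 = flow_conservation_fit(wide["arteriole"],
                                                 wide["venule"])
    return {"slope": slope, "intercept": intercept, "r_squared": r2,
            "n_points": int(len(wide)), "pooling": pool}
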