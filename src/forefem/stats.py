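"""Cohort-level statistical screening of model outputs.

The screening follows the convention of small clinical cohort studies:
Shapiro-Wilk normality tests gate each variable; pairs where both
variables pass use Pearson correlation, otherwise Spearman rank
correlation; summaries are medians with inter-quartile ranges, and an
optional reference subject is ranked within the cohort (ties share the
lowest rank, flagged with '=').  No multiple-testing correction is applied
by default, matching the exploratory character of such screens; a
Benjamini-Hochberg option is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

#: canonical screening pairs: the four model predictions against the
#: clinical covariates and morphological measures
METRIC_VARS = ("shear_p99", "vol_over_10pct", "pressure_p99",
               "max_pressure_gradient")
COVARIATE_VARS = ("bmi", "disease_duration", "lfis_if", "instances_count",
                  "tissue_depth_mh1", "sesamoid_lateral_offset_pct",
                  "mh1_curvature")


@dataclass
class NormalityGate:
    parametric: bool
    statistic: float
    p_value: float
    degenerate: bool = False


@dataclass
class CohortSummary:
    table: pd.DataFrame                      # median / IQR per variable
    reference_ranks: Optional[pd.DataFrame] = None


def normality_gate(values, alpha: float = 0.05) -> NormalityGate:
    """Shapiro-Wilk gate: parametric iff p > alpha.

    Constant vectors cannot be tested and are flagged degenerate and
    non-parametric.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError(f"normality test needs n >= 3, got {len(x)}")
    if np.ptp(x) == 0:
        return NormalityGate(False, np.nan, np.nan, degenerate=True)
    stat, p = sps.shapiro(x)
    return NormalityGate(bool(p > alpha), float(stat), float(p))


def correlate(x, y, gate_x: Optional[NormalityGate] = None,
              gate_y: Optional[NormalityGate] = None, alpha: float = 0.05):
    """Pearson if both variables pass the normality gate, else Spearman.

    Returns ``(coefficient, p_value, method)`` with a two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"correlation needs n >= 3, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance variable in correlation")
    if gate_x is None:
        gate_x = normality_gate(x, alpha)
    if gate_y is None:
        gate_y = normality_gate(y, alpha)
    if gate_x.parametric and gate_y.parametric:
        r, p = sps.pearsonr(x, y)
        return float(r), float(p), "pearson"
    r, p = sps.spearmanr(x, y)
    return float(r), float(p), "spearman"


def correlation_table(df: pd.DataFrame,
                      metric_vars=METRIC_VARS, covariate_vars=COVARIATE_VARS,
                      alpha: float = 0.05,
                      bh_correction: bool = False) -> pd.DataFrame:
    """Full metric-vs-covariate correlation screen with normality gating.

    Missing data are handled pairwise-complete; ``n`` is reported per row.
    """
    gates = {}
    for v in list(metric_vars) + list(covariate_vars):
        if v not in df.columns:
            continue
        col = df[v].to_numpy(dtype=float)
        col = col[~np.isnan(col)]
        gates[v] = (normality_gate(col, alpha) if len(col) >= 3
                    and np.ptp(col) > 0 else
                    NormalityGate(False, np.nan, np.nan, True))
    rows = []
    for m in metric_vars:
        if m not in df.columns:
            continue
        for c in covariate_vars:
            if c not in df.columns:
                continue
            x = df[m].to_numpy(dtype=float)
            y = df[c].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            try:
                r, p, method = correlate(x[ok], y[ok], gates[m], gates[c],
                                         alpha)
            except ValueError:
                r, p, method = np.nan, np.nan, "n/a"
            rows.append({"variable_1": m, "variable_2": c,
                         "coefficient": r, "p_value": p, "method": method,
                         "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    if bh_correction and len(out):
        from statsmodels.stats.multitest import multipletests
        okp = out["p_value"].notna()
        adj = multipletests(out.loc[okp, "p_value"], method="fdr_bh")[1]
        out.loc[okp, "p_value_bh"] = adj
    return out


def _rank_with_ties(cohort_values, ref_value):
    """Rank of the reference within cohort+reference (1 = lowest)."""
    vals = np.concatenate([np.asarray(cohort_values, float), [ref_value]])
    vals = vals[~np.isnan(vals)]
    order = np.sort(vals)
    rank = int(np.searchsorted(order, ref_value, side="left")) + 1
    tied = int((np.abs(vals - ref_value) < 1e-12).sum()) > 1
    return rank, tied


def summarize(df: pd.DataFrame, reference: Optional[dict] = None,
              metric_vars=METRIC_VARS, covariate_vars=COVARIATE_VARS,
              alpha: float = 0.05):
    """Median (IQR) table plus the gated correlation screen.

    ``reference`` is an optional single-subject record ranked within the
    cohort for each shared variable (ties share rank, flagged '=').
    """
    if len(df) < 3:
        raise ValueError("summaries need at least 3 subjects")
    variables = [v for v in list(covariate_vars) + list(metric_vars)
                 if v in df.columns]
    rows = []
    for v in variables:
        x = df[v].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        if len(x) == 0:
            continue
        rows.append({"variable": v, "median": float(np.median(x)),
                     "iqr_low": float(np.percentile(x, 25)),
                     "iqr_high": float(np.percentile(x, 75)),
                     "n": len(x)})
    summary = pd.DataFrame(rows)

    ranks = None
    if reference is not None:
        rrows = []
        for v in variables:
            if v not in reference or reference[v] is None:
                continue
            x = df[v].to_numpy(dtype=float)
            rank, tied = _rank_with_ties(x[~np.isnan(x)], float(reference[v]))
            rrows.append({"variable": v, "value": float(reference[v]),
                          "rank": rank, "of": int((~np.isnan(x)).sum()) + 1,
                          "tied": "=" if tied else ""})
        ranks = pd.DataFrame(rrows)

    corr = correlation_table(df, metric_vars, covariate_vars, alpha)
    return CohortSummary(summary, ranks), corr
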