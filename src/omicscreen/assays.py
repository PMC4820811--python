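"""Validation-assay computations: delta-delta-Ct relative qPCR
quantification, dual-reporter (luciferase/phosphatase) normalization, and
fold comparisons of percent-positive cell populations.

Undetected qPCR expression (the conventional Ct > 40 cycles) must be
encoded as NaN, never as a number: folds against an undetected calibrator
are undefined and raise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CT_UNDETECTED_CYCLES = 40.0


def mark_undetected(ct: pd.Series, limit: float = CT_UNDETECTED_CYCLES) -> pd.Series:
    """Replace Ct values beyond the detection limit with NaN."""
    return ct.where(ct <= limit)


def delta_delta_ct(records: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    ``records`` needs columns ``group``, ``ct_target``, ``ct_reference``.
    Per record, dCt = ct_target - ct_reference; per group,
    ddCt = mean dCt(group) - mean dCt(calibrator) and fold = 2**(-ddCt).
    Replicate dispersion is propagated as the conventional fold range
    2**(-(ddCt +/- s.d.)).
    """
    df = records.copy()
    if calibrator_group not in set(df["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} not present")
    df["dct"] = df["ct_target"] - df["ct_reference"]
    cal = df.loc[df["group"] == calibrator_group, "dct"]
    if cal.isna().any() or cal.empty:
        raise ValueError("undetected target in calibrator group; fold undefined")
    cal_mean = cal.mean()
    out = []
    for group, sub in df.groupby("group", sort=False):
        dct = sub["dct"]
        ddct = dct.mean() - cal_mean
        sd = dct.std(ddof=1) if len(dct) > 1 else 0.0
        out.append(
            {
                "group": group,
                "n": int(len(dct)),
                "ddct": ddct,
                "fold": 2.0**-ddct,
                "fold_low": 2.0 ** -(ddct + sd),
                "fold_high": 2.0 ** -(ddct - sd),
                "dct_sd": sd,
            }
        )
    return pd.DataFrame(out).set_index("group")


def reporter_normalize(
    gluc: float, seap: float, control_gluc: float, control_seap: float
) -> tuple[float, float]:
    """Dual-reporter normalization: luciferase over phosphatase.

    The secreted phosphatase channel controls for transfection efficiency;
    returns (normalized activity, fold versus the control pair).
    """
    for name, v in (("seap", seap), ("control_seap", control_seap)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    activity = gluc / seap
    control_activity = control_gluc / control_seap
    return activity, activity / control_activity


def percent_positive_fold(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> dict:
    """Fold change of percent-positive cells between two replicate groups.

    Each group's DataFrame needs ``counts_pos`` and ``counts_total`` per
    replicate.  Returns per-group percentages, the fold of mean percentages
    (group_a over group_b), and a two-sided Student's t-test on the
    replicate percentages.  Swapping the groups inverts the fold.
    """
    pct = {}
    for name, g in (("a", group_a), ("b", group_b)):
        if len(g) < 2:
            raise ValueError("need >=2 replicates per group for testing")
        if (g["counts_total"] <= 0).any():
            raise ValueError("zero-total replicate")
        if ((g["counts_pos"] < 0) | (g["counts_pos"] > g["counts_total"])).any():
            raise ValueError("counts_pos must lie in [0, counts_total]")
        pct[name] = 100.0 * g["counts_pos"] / g["counts_total"]
    mean_a, mean_b = pct["a"].mean(), pct["b"].mean()
    if mean_b == 0:
        raise ValueError("mean percent of group_b is zero; fold undefined")
    if pct["a"].var(ddof=1) == 0 and pct["b"].var(ddof=1) == 0:
        p = 1.0 if mean_a == mean_b else 0.0
    else:
        p = float(stats.ttest_ind(pct["a"], pct["b"]).pvalue)
    return {
        "percent_a": pct["a"].to_numpy(),
        "percent_b": pct["b"].to_numpy(),
        "mean_percent_a": float(mean_a),
        "mean_percent_b": float(mean_b),
        "fold": float(mean_a / mean_b),
        "p_value": p,
    }
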