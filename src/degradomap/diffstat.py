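"""Per-protein two-group differential abundance testing.

The test is the unpaired two-sample t-test on log2 intensities, with the
pooled-variance (Student) form as default and Welch's unequal-variance
form behind a flag.  Multiple testing is controlled per contrast with the
Benjamini-Hochberg step-up procedure; the adjusted values are the
Q-values used for hit calling.  Both the statistic and the adjustment
are implemented from first principles here so that the inference chain
is auditable; library implementations serve only as cross-checks in the
test suite.

The result container (``DiffTable``) is a DataFrame indexed by
``protein_id`` with columns ``mean_treat``, ``mean_ref``, ``log2fc``,
``t``, ``df``, ``p``, ``q``, ``n_treat``, ``n_ref``, ``status``.
Proteins failing preconditions are flagged (``status != "ok"``), never
silently dropped.

Degenerate zero-variance cases are resolved deterministically: equal
means give p = 1, unequal means give p = 0 with status
``zero_variance``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .quantio import arm_samples, validate_design

__all__ = ["two_group_test", "bh_adjust", "DIFFTABLE_COLUMNS"]

DIFFTABLE_COLUMNS = [
    "mean_treat", "mean_ref", "log2fc", "t", "df", "p", "q",
    "n_treat", "n_ref", "status",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Q-values).

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, returned in the
    input order.  Values outside [0, 1] raise ``ValueError``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _student_t(mean_d, var_t, var_r, n_t, n_r):
    """Pooled-variance t statistic and df (vectorized)."""
    df = n_t + n_r - 2
    pooled = ((n_t - 1) * var_t + (n_r - 1) * var_r) / df
    se = np.sqrt(pooled * (1.0 / n_t + 1.0 / n_r))
    return mean_d / se, np.broadcast_to(df, mean_d.shape).astype(float)


def _welch_t(mean_d, var_t, var_r, n_t, n_r):
    """Welch t statistic with Welch-Satterthwaite df (vectorized)."""
    vt, vr = var_t / n_t, var_r / n_r
    se = np.sqrt(vt + vr)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (vt + vr) ** 2 / (vt**2 / (n_t - 1) + vr**2 / (n_r - 1))
    return mean_d / se, df


def two_group_test(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    treatment_arm: str,
    reference_arm: str,
    test: str = "student",
) -> pd.DataFrame:
    """Unpaired two-sided t-test of treatment vs reference per protein.

    ``matrix`` must be on the log2 scale.  log2fc = mean(treatment) -
    mean(reference).  Proteins with fewer than 2 observed values in
    either group are flagged ``untested`` (statistics NaN, q excluded
    from the BH adjustment).
    """
    if test not in ("student", "welch"):
        raise ValueError("test must be 'student' or 'welch'")
    validate_design(design)
    treat_cols = [s for s in arm_samples(design, treatment_arm) if s in matrix.columns]
    ref_cols = [s for s in arm_samples(design, reference_arm) if s in matrix.columns]
    if len(treat_cols) < 2 or len(ref_cols) < 2:
        raise ValueError("need at least 2 samples per arm")

    vt = matrix[treat_cols].to_numpy(dtype=float)
    vr = matrix[ref_cols].to_numpy(dtype=float)
    n_t = np.sum(~np.isnan(vt), axis=1)
    n_r = np.sum(~np.isnan(vr), axis=1)
    tested = (n_t >= 2) & (n_r >= 2)

    with np.errstate(invalid="ignore"):
        mean_t = np.nanmean(np.where(np.isnan(vt), np.nan, vt), axis=1)
        mean_r = np.nanmean(np.where(np.isnan(vr), np.nan, vr), axis=1)
        var_t = _nanvar(vt, n_t)
        var_r = _nanvar(vr, n_r)

    mean_d = mean_t - mean_r
    if test == "student":
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat, df = _student_t(mean_d, var_t, var_r, n_t, n_r)
    else:
        t_stat, df = _welch_t(mean_d, var_t, var_r, n_t, n_r)

    p = np.full(matrix.shape[0], np.nan)
    ok = tested & np.isfinite(t_stat)
    p[ok] = 2.0 * stats.t.sf(np.abs(t_stat[ok]), df[ok])

    status = np.where(tested, "ok", "untested").astype(object)
    # zero-variance conventions: deterministic, flagged
    zero_var = tested & (var_t + var_r == 0)
    equal = zero_var & (mean_d == 0)
    unequal = zero_var & (mean_d != 0)
    p[equal] = 1.0
    p[unequal] = 0.0
    t_stat = np.where(equal, 0.0, t_stat)
    with np.errstate(invalid="ignore"):
        t_stat = np.where(unequal, np.sign(mean_d) * np.inf, t_stat)
    status[zero_var] = "zero_variance"

    q = np.full_like(p, np.nan)
    q[tested] = bh_adjust(p[tested])

    table = pd.DataFrame(
        {
            "mean_treat": mean_t,
            "mean_ref": mean_r,
            "log2fc": mean_d,
            "t": t_stat,
            "df": df,
            "p": p,
            "q": q,
            "n_treat": n_t,
            "n_ref": n_r,
            "status": status,
        },
        index=matrix.index,
    )
    table.attrs["treatment_arm"] = treatment_arm
    table.attrs["reference_arm"] = reference_arm
    table.attrs["test"] = test
    return table


def _nanvar(values: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Sample variance (ddof=1) ignoring NaN; NaN where n < 2."""
    out = np.full(values.shape[0], np.nan)
    rows = n >= 2
    if rows.any():
        v = values[rows]
        mean = np.nanmean(v, axis=1, keepdims=True)
        out[rows] = np.nansum((v - mean) ** 2, axis=1) / (n[rows] - 1)
    return out
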