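"""Reporter-assay normalization and dose-response curve fitting.

Covers the quantitative read-outs around the degradomics core:

* luciferase/GFP reporter normalization to unstimulated and stimulated
  vehicle controls (percent activity);
* four-parameter logistic (4PL) dose-response fits reporting pIC50;
* a biphasic bell model — the product of a rising and a falling
  logistic — for Hook-effect curves, where a PROTAC loses efficacy at
  high concentration because binary complexes outcompete the ternary
  complex;
* AICc model selection between the two;
* ddCt relative expression for qPCR and bound/input ChIP enrichment
  normalized to intergenic control primers.

All fits are deterministic: nonlinear least squares from a fixed
multi-start grid over log10 concentration, no hidden randomness.
Concentrations are molar; pIC50 = -log10(IC50 / M).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FourPLFit",
    "BellFit",
    "normalize_reporter",
    "fit_4pl",
    "fit_bell",
    "select_model",
    "qpcr_relative_expression",
    "chip_enrichment",
]

MIN_CONCENTRATIONS = 5


@dataclass
class FourPLFit:
    """response = bottom + (top - bottom) / (1 + (conc / ic50)^hill)

    With hill > 0 the curve falls from ``top`` (low conc) to ``bottom``
    (high conc); the parameterization is canonicalized to top >= bottom.
    """

    top: float
    bottom: float
    ic50: float
    hill: float
    residual_ss: float = 0.0
    converged: bool = True
    status: str = "ok"          # ok | unidentifiable

    @property
    def pic50(self) -> float:
        return float(-np.log10(self.ic50))

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1 + (c / self.ic50) ** self.hill)

    n_params = 4


@dataclass
class BellFit:
    """Biphasic (Hook-effect) model: baseline + amplitude * rising
    logistic * falling logistic, with ec50_rise < ec50_fall enforced."""

    baseline: float
    amplitude: float
    ec50_rise: float
    hill_rise: float
    ec50_fall: float
    hill_fall: float
    peak_conc: float = np.nan
    residual_ss: float = 0.0
    converged: bool = True
    status: str = "ok"          # ok | degenerate | flat

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        rise = 1.0 / (1.0 + (self.ec50_rise / c) ** self.hill_rise)
        fall = 1.0 / (1.0 + (c / self.ec50_fall) ** self.hill_fall)
        return self.baseline + self.amplitude * rise * fall

    n_params = 6


def normalize_reporter(raw, unstim_control_mean: float, stim_control_mean: float):
    """Percent pathway activity relative to vehicle controls:
    100 * (raw - unstimulated) / (stimulated - unstimulated)."""
    span = stim_control_mean - unstim_control_mean
    if span == 0:
        raise ValueError("stimulated and unstimulated control means coincide")
    return 100.0 * (np.asarray(raw, dtype=float) - unstim_control_mean) / span


def _check_data(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    conc = data["concentration_M"].to_numpy(dtype=float)
    resp = data["response"].to_numpy(dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(conc)) < MIN_CONCENTRATIONS:
        raise ValueError(f"need >= {MIN_CONCENTRATIONS} distinct concentrations")
    return conc, resp


def fit_4pl(data: pd.DataFrame) -> FourPLFit:
    """Least-squares 4PL fit with multi-start over log10(IC50).

    ``data`` needs columns ``concentration_M`` and ``response``.  Flat
    data (fitted span indistinguishable from the residual noise) is
    flagged ``unidentifiable`` with no IC50 reported.
    """
    conc, resp = _check_data(data)
    logc = np.log10(conc)
    lo, hi = resp.min(), resp.max()

    def residuals(params):
        top, bottom, x, hill = params
        return bottom + (top - bottom) / (1 + 10 ** (hill * (logc - x))) - resp

    best = None
    for x0 in np.linspace(logc.min(), logc.max(), 5):
        for hill0 in (1.0, -1.0):
            res = least_squares(
                residuals, [hi, lo, x0, hill0],
                bounds=([-np.inf, -np.inf, logc.min() - 4, -10],
                        [np.inf, np.inf, logc.max() + 4, 10]),
                method="trf",
            )
            if best is None or res.cost < best.cost:
                best = res
    top, bottom, x, hill = best.x
    if top < bottom:   # same curve under (top<->bottom, hill -> -hill)
        top, bottom, hill = bottom, top, -hill
    ss = float(2 * best.cost)
    rmse = np.sqrt(ss / len(resp))
    fit = FourPLFit(top=float(top), bottom=float(bottom), ic50=float(10**x),
                    hill=float(hill), residual_ss=ss, converged=bool(best.success))
    if abs(top - bottom) <= max(2 * rmse, 1e-12 * max(abs(top), abs(bottom), 1.0)):
        fit.status = "unidentifiable"
        fit.ic50 = np.nan
    return fit


def fit_bell(data: pd.DataFrame) -> BellFit:
    """Least-squares biphasic fit; rising EC50 < falling EC50 by
    construction (the falling EC50 is parameterized as a nonnegative
    log-offset from the rising one).

    Data whose best fit peaks at the edge of the tested concentration
    range (i.e. effectively monotone) is flagged ``degenerate``; a fit
    with vanishing amplitude is flagged ``flat``.
    """
    conc, resp = _check_data(data)
    logc = np.log10(conc)
    span = resp.max() - resp.min()

    def model(params, lc):
        base, amp, xr, hr, gap, hf = params
        c = 10.0**lc
        rise = 1.0 / (1.0 + (10.0**xr / c) ** hr)
        fall = 1.0 / (1.0 + (c / 10.0 ** (xr + gap)) ** hf)
        return base + amp * rise * fall

    def residuals(params):
        return model(params, logc) - resp

    lo_b = [resp.min() - 2 * max(span, 1.0), -4 * max(span, 1.0),
            logc.min() - 4, 0.2, 1e-6, 0.2]
    hi_b = [resp.max() + 2 * max(span, 1.0), 4 * max(span, 1.0),
            logc.max() + 4, 10, 10, 10]
    best = None
    for xr0 in np.linspace(logc.min(), logc.max(), 4):
        for gap0 in (0.5, 1.5, 3.0):
            for amp0 in (span, -span if span > 0 else -1.0):
                p0 = [resp.min(), amp0 if amp0 != 0 else 1.0, xr0, 1.0, gap0, 1.0]
                p0 = np.clip(p0, lo_b, hi_b)
                res = least_squares(residuals, p0, bounds=(lo_b, hi_b), method="trf")
                if best is None or res.cost < best.cost:
                    best = res
    base, amp, xr, hr, gap, hf = best.x
    ss = float(2 * best.cost)
    fit = BellFit(baseline=float(base), amplitude=float(amp),
                  ec50_rise=float(10**xr), hill_rise=float(hr),
                  ec50_fall=float(10 ** (xr + gap)), hill_fall=float(hf),
                  residual_ss=ss, converged=bool(best.success))
    rmse = np.sqrt(ss / len(resp))
    if abs(amp) <= max(2 * rmse, 1e-12):
        fit.status = "flat"
        return fit
    # locate the interior maximum of |deviation from baseline|
    grid = np.linspace(logc.min(), logc.max(), 2001)
    curve = model(best.x, grid)
    idx = int(np.argmax(np.abs(curve - base)))
    edge = max(3, len(grid) // 100)
    if idx < edge or idx > len(grid) - 1 - edge:
        fit.status = "degenerate"
        return fit
    # refine the peak on a finer local grid
    local = np.linspace(grid[idx - edge], grid[idx + edge], 2001)
    lcurve = model(best.x, local)
    fit.peak_conc = float(10 ** local[np.argmax(np.abs(lcurve - base))])
    return fit


def _aicc(ss: float, n: int, k: int) -> float:
    if n <= k + 1:
        raise ValueError(
            f"AICc needs n > k + 1 data points (n={n}, k={k}); collect more points"
        )
    return n * np.log(max(ss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def select_model(data: pd.DataFrame) -> dict:
    """Fit both the 4PL and the bell model and pick by AICc.

    k counts the model parameters plus the residual variance.  Returns
    ``{"selected": "four_pl" | "bell", "aicc": {...}, "fits": {...}}``.
    """
    fit4 = fit_4pl(data)
    fitb = fit_bell(data)
    n = len(data)
    scores = {
        "four_pl": _aicc(fit4.residual_ss, n, FourPLFit.n_params + 1),
        "bell": _aicc(fitb.residual_ss, n, BellFit.n_params + 1),
    }
    selected = min(scores, key=scores.get)
    return {"selected": selected, "aicc": scores,
            "fits": {"four_pl": fit4, "bell": fitb}}


def qpcr_relative_expression(
    records: pd.DataFrame, reference_condition: str
) -> pd.Series:
    """ddCt relative expression: fold = 2^-(dCt_condition - dCt_reference)
    with dCt = Ct_target - Ct_housekeeping, Ct averaged over replicates.

    ``records`` needs columns ``condition``, ``ct_target``,
    ``ct_housekeeping``.
    """
    required = {"condition", "ct_target", "ct_housekeeping"}
    if not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if records[["ct_target", "ct_housekeeping"]].isna().any().any():
        raise ValueError("missing Ct values")
    grouped = records.groupby("condition")[["ct_target", "ct_housekeeping"]].mean()
    if reference_condition not in grouped.index:
        raise ValueError(f"reference condition {reference_condition!r} not present")
    dct = grouped["ct_target"] - grouped["ct_housekeeping"]
    ddct = dct - dct[reference_condition]
    return np.exp2(-ddct).rename("fold_change")


def chip_enrichment(records: pd.DataFrame) -> pd.Series:
    """ChIP enrichment per locus: (bound / input) normalized to the mean
    bound / input ratio of the intergenic control loci.

    ``records`` needs columns ``locus``, ``bound``, ``input`` and a
    boolean ``is_intergenic``.
    """
    required = {"locus", "bound", "input", "is_intergenic"}
    if not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if (records["input"] <= 0).any():
        raise ValueError("input signal must be > 0")
    ratio = records["bound"] / records["input"]
    intergenic = ratio[records["is_intergenic"].astype(bool)]
    if intergenic.empty:
        raise ValueError("no intergenic control records")
    norm = float(intergenic.mean())
    out = ratio / norm
    out.index = records["locus"]
    return out.rename("enrichment")
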