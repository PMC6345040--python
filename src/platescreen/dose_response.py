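"""Four-parameter logistic dose-response fitting and absolute IC50 analysis.

Viability as a function of drug concentration c is modelled by the
four-parameter logistic (4PL) sigmoid

    v(c) = bottom + (top - bottom) / (1 + (c / ec50)^hill)

fitted by least squares in log10-concentration space with multi-start
initialization. The reported potency is the *absolute* IC50 — the
concentration at which the fitted curve equals 50% of control — obtained
in closed form from the fitted parameters:

    IC50 = ec50 * ((top - 50) / (50 - bottom))^(1/hill)

which is distinct from the curve's inflection point (the relative EC50)
whenever top != 100 or bottom != 0. If the fitted curve never crosses 50%
no absolute IC50 exists and :class:`NoAbsoluteIC50Error` is raised,
deliberately distinct from a fit failure.

Independent experiments are fitted separately and their IC50s averaged
(mean +/- SEM, SD with n-1); arms are compared by the IC50 fold change and
a two-sided, unpaired, equal-variance Student's t-test on the
per-experiment IC50s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import CurveInputError, NoAbsoluteIC50Error

# Fit bounds, chosen to keep the 50% crossing identifiable for viability
# data expressed in percent of control.
HILL_BOUNDS = (1e-6, 10.0)
TOP_BOUNDS = (50.0, 150.0)
BOTTOM_BOUNDS = (-20.0, 50.0 - 1e-9)
#: ec50 is constrained within this factor of the tested dose range.
EC50_RANGE_FACTOR = 100.0


def four_pl(c, top: float, bottom: float, hill: float, ec50: float):
    """Evaluate the 4PL viability curve at concentration(s) ``c`` (nM)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ec50) ** hill)


@dataclass(frozen=True)
class DoseResponseCurve:
    """One experiment's concentration-viability series for one compound/arm."""

    compound_id: str
    condition: str
    experiment: int
    concentrations_nM: np.ndarray
    percent_viability: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_nM, dtype=float)
        v = np.asarray(self.percent_viability, dtype=float)
        if c.shape != v.shape or c.ndim != 1:
            raise CurveInputError("concentrations and viabilities must be 1-D and aligned")
        if np.any(~np.isfinite(c)) or np.any(c <= 0):
            raise CurveInputError("concentrations must be finite and strictly positive")
        if len(np.unique(c)) < 4:
            raise CurveInputError(
                f"need >= 4 distinct concentrations for a 4-parameter fit, "
                f"got {len(np.unique(c))}"
            )
        object.__setattr__(self, "concentrations_nM", c)
        object.__setattr__(self, "percent_viability", v)


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters with residual sum of squares and a convergence flag."""

    top: float
    bottom: float
    hill: float
    ec50: float
    rss: float
    converged: bool

    def predict(self, c):
        return four_pl(c, self.top, self.bottom, self.hill, self.ec50)


@dataclass(frozen=True)
class IC50Estimate:
    """Absolute IC50 aggregated over independent experiments."""

    compound_id: str
    condition: str
    per_experiment_ic50: tuple[float, ...]
    mean_ic50: float
    sem: float
    single_replicate: bool = False


@dataclass(frozen=True)
class IC50Comparison:
    """Fold change of mean IC50s with Student's t-test significance."""

    fold_change: float
    t_statistic: float
    p_value: float
    df: int
    p_defined: bool


def _crossing_guess(logc: np.ndarray, y: np.ndarray) -> list[float]:
    """log10(ec50) starting points: the dose bracketing the 50% crossing
    (linear interpolation in log space) plus the geometric mid-range."""
    order = np.argsort(logc)
    lx, ly = logc[order], y[order]
    guesses = [float(logc.mean())]
    half = 0.5 * (np.nanmax(ly) + np.nanmin(ly))
    for i in range(len(lx) - 1):
        y0, y1 = ly[i], ly[i + 1]
        if (y0 - half) * (y1 - half) <= 0 and y0 != y1:
            guesses.insert(0, float(lx[i] + (half - y0) * (lx[i + 1] - lx[i]) / (y1 - y0)))
            break
    return guesses


def fit_four_pl(curve: DoseResponseCurve) -> FourPLFit:
    """Least-squares 4PL fit of one dose-response series.

    The optimization runs over (top, bottom, hill, log10 ec50) with several
    starting points (hill in {0.7, 1.5, 3}, ec50 at the observed 50%
    crossing and at the geometric mid-range); the best residual sum of
    squares wins. A series with no spread at all (every viability equal)
    leaves ec50 and hill unidentifiable: the degenerate fit is returned
    with ``converged=False`` rather than raising.
    """
    c = curve.concentrations_nM
    y = curve.percent_viability
    logc = np.log10(c)

    if np.ptp(y) < 1e-9:
        return FourPLFit(
            top=float(y.mean()), bottom=float(y.mean()), hill=1.0,
            ec50=float(10 ** logc.mean()), rss=0.0, converged=False,
        )

    lo = np.array([TOP_BOUNDS[0], BOTTOM_BOUNDS[0], HILL_BOUNDS[0],
                   logc.min() - math.log10(EC50_RANGE_FACTOR)])
    hi = np.array([TOP_BOUNDS[1], BOTTOM_BOUNDS[1], HILL_BOUNDS[1],
                   logc.max() + math.log10(EC50_RANGE_FACTOR)])

    def residuals(p):
        top, bottom, hill, logec50 = p
        return four_pl(c, top, bottom, hill, 10.0 ** logec50) - y

    top0 = float(np.clip(y.max(), *TOP_BOUNDS))
    bottom0 = float(np.clip(y.min(), BOTTOM_BOUNDS[0], BOTTOM_BOUNDS[1] - 1e-6))
    best = None
    any_success = False
    for logec0 in _crossing_guess(logc, y):
        for hill0 in (0.7, 1.5, 3.0):
            p0 = np.clip(np.array([top0, bottom0, hill0, logec0]), lo + 1e-12, hi - 1e-12)
            try:
                res = optimize.least_squares(
                    residuals, p0, bounds=(lo, hi), method="trf",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
                )
            except Exception:
                continue
            rss = float(2.0 * res.cost)
            if best is None or rss < best[0]:
                best = (rss, res.x)
            any_success = any_success or bool(res.success)
    if best is None:
        raise CurveInputError("4PL optimization failed from every starting point")
    rss, (top, bottom, hill, logec50) = best
    identifiable = (top - bottom) > 1e-6 * max(1.0, abs(top))
    return FourPLFit(
        top=float(top), bottom=float(bottom), hill=float(hill),
        ec50=float(10.0 ** logec50), rss=rss,
        converged=bool(any_success and identifiable),
    )


def absolute_ic50(fit: FourPLFit) -> float:
    """Concentration (nM) at which the fitted curve equals 50% of control.

    Solves v(c) = 50 analytically; requires the curve to cross 50%
    (min(bottom, top) < 50 < max(bottom, top)).
    """
    lo, hi = min(fit.bottom, fit.top), max(fit.bottom, fit.top)
    if not (lo < 50.0 < hi):
        raise NoAbsoluteIC50Error(
            f"fitted curve spans [{lo:.3g}, {hi:.3g}]% and never crosses 50%; "
            "no absolute IC50"
        )
    return float(fit.ec50 * ((fit.top - 50.0) / (50.0 - fit.bottom)) ** (1.0 / fit.hill))


def aggregate_ic50_replicates(
    per_experiment: "list[float] | np.ndarray",
    compound_id: str = "",
    condition: str = "",
) -> IC50Estimate:
    """Mean and SEM of per-experiment absolute IC50s.

    SEM = SD/sqrt(n) with the n-1 SD; a single replicate yields SEM 0 and
    a warning, since no spread can be estimated.
    """
    values = np.asarray(list(per_experiment), dtype=float)
    if values.size == 0:
        raise CurveInputError("no per-experiment IC50 values to aggregate")
    if np.any(values <= 0):
        raise CurveInputError("IC50 values must be positive")
    single = values.size == 1
    if single:
        warnings.warn(
            f"IC50 for {compound_id or 'compound'} rests on a single experiment; "
            "SEM reported as 0",
            stacklevel=2,
        )
    sem = 0.0 if single else float(values.std(ddof=1) / math.sqrt(values.size))
    return IC50Estimate(
        compound_id=compound_id,
        condition=condition,
        per_experiment_ic50=tuple(float(v) for v in values),
        mean_ic50=float(values.mean()),
        sem=sem,
        single_replicate=single,
    )


def compare_ic50(a: IC50Estimate, b: IC50Estimate) -> IC50Comparison:
    """Fold change mean(a)/mean(b) plus Student's t-test on replicate IC50s.

    The t-test is two-sided, unpaired and equal-variance (classical
    Student). With fewer than 2 experiments on either side the fold is
    still returned but the p-value is undefined (NaN, ``p_defined=False``).
    """
    fold = a.mean_ic50 / b.mean_ic50
    xa = np.asarray(a.per_experiment_ic50, dtype=float)
    xb = np.asarray(b.per_experiment_ic50, dtype=float)
    if xa.size < 2 or xb.size < 2:
        warnings.warn(
            "fewer than 2 experiments on one side; p-value undefined",
            stacklevel=2,
        )
        return IC50Comparison(
            fold_change=float(fold), t_statistic=math.nan, p_value=math.nan,
            df=0, p_defined=False,
        )
    t_stat, p = stats.ttest_ind(xa, xb, equal_var=True)
    return IC50Comparison(
        fold_change=float(fold), t_statistic=float(t_stat), p_value=float(p),
        df=int(xa.size + xb.size - 2), p_defined=True,
    )


def curves_from_table(table: pd.DataFrame) -> list[DoseResponseCurve]:
    """Split a long viability table into per-experiment dose-response curves.

    Expects columns ``compound_id, condition, experiment, concentration_nM,
    percent_viability``; one curve per (compound_id, condition, experiment).
    """
    required = ["compound_id", "condition", "experiment",
                "concentration_nM", "percent_viability"]
    missing = [col for col in required if col not in table.columns]
    if missing:
        raise CurveInputError(f"dose-response table missing columns {missing}")
    curves = []
    for (cid, cond, exp), grp in table.groupby(
        ["compound_id", "condition", "experiment"], sort=True
    ):
        curves.append(
            DoseResponseCurve(
                compound_id=str(cid),
                condition=str(cond),
                experiment=int(exp),
                concentrations_nM=grp["concentration_nM"].to_numpy(dtype=float),
                percent_viability=grp["percent_viability"].to_numpy(dtype=float),
            )
        )
    return curves


def fit_dose_response_table(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[tuple[str, str], IC50Estimate], pd.DataFrame]:
    """Fit every (compound, condition) group of a long table.

    Returns
    -------
    fits : DataFrame
        One row per (compound, condition, experiment) with the 4PL
        parameters, rss, convergence flag and absolute IC50 (NaN when the
        curve never crosses 50%).
    estimates : dict
        (compound_id, condition) -> :class:`IC50Estimate`, for groups with
        at least one usable IC50.
    failures : DataFrame
        Groups/experiments that produced no absolute IC50, with the reason;
        reported rather than silently dropped.
    """
    fit_rows = []
    fail_rows = []
    by_group: dict[tuple[str, str], list[float]] = {}
    for curve in curves_from_table(table):
        fit = fit_four_pl(curve)
        row = {
            "compound_id": curve.compound_id,
            "condition": curve.condition,
            "experiment": curve.experiment,
            "top": fit.top, "bottom": fit.bottom, "hill": fit.hill,
            "ec50_nM": fit.ec50, "rss": fit.rss, "converged": fit.converged,
            "ic50_nM": math.nan,
        }
        reason = None
        if not fit.converged:
            reason = "fit did not converge (degenerate or unidentifiable curve)"
        else:
            try:
                ic50 = absolute_ic50(fit)
            except NoAbsoluteIC50Error as exc:
                reason = str(exc)
            else:
                row["ic50_nM"] = ic50
                by_group.setdefault(
                    (curve.compound_id, curve.condition), []
                ).append(ic50)
        if reason is not None:
            fail_rows.append(
                {"compound_id": curve.compound_id, "condition": curve.condition,
                 "experiment": curve.experiment, "reason": reason}
            )
        fit_rows.append(row)
    estimates = {
        key: aggregate_ic50_replicates(vals, compound_id=key[0], condition=key[1])
        for key, vals in by_group.items()
    }
    fits = pd.DataFrame(fit_rows)
    failures = pd.DataFrame(
        fail_rows, columns=["compound_id", "condition", "experiment", "reason"]
    )
    return fits, estimates, failures
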