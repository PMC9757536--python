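"""Expected-lactation-curve (ELC) fitting.

The ELC of a lactation is an estimate of the daily milk yield a cow would
have produced in the absence of perturbations (disease, heat stress,
management upsets).  Because perturbations only ever *depress* yield, the
ELC is obtained by an iterative robust-fitting procedure:

1. smooth the complete daily series with a two-sided weighted moving
   average (window of 5 days, weights 0.1/0.2/0.4/0.2/0.1);
2. fit four classical lactation-curve models and keep the one with the
   highest R**2 on the original kg scale:

   * Wood            ``Y(t) = a * t**b * exp(-c*t)``
   * Nelder          ``1/Y(t) = a + b/t + c*t``  (inverse polynomial)
   * Wilmink         ``Y(t) = a + b*exp(-0.05*t) + c*t``
   * Ali-Schaeffer   ``Y(t) = a + b*t + c*t**2 + d*ln(t) + e*ln(t)**2``

3. repeatedly delete days whose deviation from the current fit falls below
   ``LQ - 1.5*IQR`` (a one-sided, low-only outlier rule: high deviations
   are never removed) and refit the same model until no day is deleted;
4. accept the curve only if every fitted daily value lies in (0, 100] kg
   and the final-iteration R**2 exceeds 0.75.

Days in milk (DIM) are 1-based; all series span DIM 1..305.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

N_DIM = 305
#: model evaluation order; also the tie-break order for equal R**2
MODEL_NAMES = ("wood", "nelder", "wilmink", "ali_schaeffer")
MODEL_N_PARAMS = {"wood": 3, "nelder": 3, "wilmink": 3, "ali_schaeffer": 5}

#: decay rate fixed inside the exponential regressor of the Wilmink model
WILMINK_K = 0.05

_MA_WEIGHTS = np.array([0.1, 0.2, 0.4, 0.2, 0.1])


class CurveFitError(RuntimeError):
    """A curve model could not be fitted (singular design, bad transform...)."""


@dataclass
class CurveFit:
    model_name: str
    params: np.ndarray
    fitted: np.ndarray  # evaluated on DIM 1..305
    r2: float


@dataclass
class ELCResult:
    """Outcome of the iterative ELC procedure for one lactation."""

    model_name: str
    params: np.ndarray
    fitted: np.ndarray
    r2: float
    retained_days: np.ndarray  # DIM (1-based) used in the final fit
    n_iterations: int
    qc_pass: bool
    qc_reason: str = ""
    smoothed: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def wood(t, a, b, c):
    return a * np.power(t, b) * np.exp(-c * t)


def nelder(t, a, b, c):
    denom = a + b / t + c * t
    with np.errstate(divide="ignore"):
        return 1.0 / denom


def wilmink(t, a, b, c):
    return a + b * np.exp(-WILMINK_K * t) + c * t


def ali_schaeffer(t, a, b, c, d, e):
    lt = np.log(t)
    return a + b * t + c * t ** 2 + d * lt + e * lt ** 2


MODEL_FUNCS = {
    "wood": wood,
    "nelder": nelder,
    "wilmink": wilmink,
    "ali_schaeffer": ali_schaeffer,
}


def evaluate_model(model_name: str, params, days=None) -> np.ndarray:
    """Evaluate a named lactation-curve model on a DIM grid (default 1..305)."""
    if model_name not in MODEL_FUNCS:
        raise ValueError(f"unknown lactation-curve model {model_name!r}")
    t = np.arange(1, N_DIM + 1, dtype=float) if days is None else np.asarray(days, dtype=float)
    return MODEL_FUNCS[model_name](t, *params)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth_weighted_ma(series: np.ndarray) -> np.ndarray:
    """Two-sided weighted moving average with window 5.

    Interior days use weights (0.1, 0.2, 0.4, 0.2, 0.1); at the boundaries
    the weights that fall inside the series are renormalized to sum to one
    (e.g. day 1 uses (0.4, 0.2, 0.1)/0.7 over days 1..3).
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = y.size
    out = np.empty(n)
    for t in range(n):
        lo = max(0, t - 2)
        hi = min(n, t + 3)
        w = _MA_WEIGHTS[lo - t + 2 : hi - t + 2]
        out[t] = np.dot(w, y[lo:hi]) / w.sum()
    return out


# ---------------------------------------------------------------------------
# per-model fitting
# ---------------------------------------------------------------------------

def _ols(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise CurveFitError("singular design matrix")
    return coef


def _fit_wood(t, y):
    if np.any(y <= 0):
        raise CurveFitError("Wood model requires positive yields")
    # log-linear initialization: ln y = ln a + b ln t - c t
    design = np.column_stack([np.ones_like(t), np.log(t), -t])
    la, b0, c0 = _ols(design, np.log(y))
    x0 = np.array([np.exp(la), b0, c0])

    def resid(p):
        return wood(t, *p) - y

    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=2000)
    if not sol.success and not np.all(np.isfinite(sol.x)):
        raise CurveFitError("Wood nonlinear fit failed")
    return sol.x


def _fit_nelder(t, y):
    if np.any(y <= 0):
        raise CurveFitError("Nelder model requires positive yields")
    design = np.column_stack([np.ones_like(t), 1.0 / t, t])
    return _ols(design, 1.0 / y)


def _fit_wilmink(t, y):
    design = np.column_stack([np.ones_like(t), np.exp(-WILMINK_K * t), t])
    return _ols(design, y)


def _fit_ali_schaeffer(t, y):
    lt = np.log(t)
    design = np.column_stack([np.ones_like(t), t, t ** 2, lt, lt ** 2])
    return _ols(design, y)


_FITTERS = {
    "wood": _fit_wood,
    "nelder": _fit_nelder,
    "wilmink": _fit_wilmink,
    "ali_schaeffer": _fit_ali_schaeffer,
}


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination on the original kg scale."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    sse = np.sum((observed - predicted) ** 2)
    sst = np.sum((observed - observed.mean()) ** 2)
    if sst == 0:
        return np.nan
    return 1.0 - sse / sst


def fit_curve(days, values, model_name: str) -> CurveFit:
    """Fit one lactation-curve model to (DIM, kg) points.

    ``days`` are 1-based DIM.  The Wood model is fitted by nonlinear least
    squares on the kg scale (log-linear OLS start); the Nelder model by OLS
    on the reciprocal response; Wilmink and Ali-Schaeffer by OLS on their
    linear regressor bases.  R**2 is always computed on the kg scale over
    the supplied days; fitted values are returned on the full DIM 1..305
    grid.

    Raises :class:`CurveFitError` when the model cannot be fitted, so the
    caller can mark it unavailable for this lactation.
    """
    t = np.asarray(days, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("days and values differ in length")
    n_par = MODEL_N_PARAMS[model_name]
    if t.size < n_par + 2:
        raise CurveFitError(f"{model_name}: need at least {n_par + 2} points")
    params = np.asarray(_FITTERS[model_name](t, y), dtype=float)
    if not np.all(np.isfinite(params)):
        raise CurveFitError(f"{model_name}: non-finite parameters")
    fitted = evaluate_model(model_name, params)
    if not np.all(np.isfinite(fitted)):
        raise CurveFitError(f"{model_name}: non-finite fitted values")
    r2 = r_squared(y, evaluate_model(model_name, params, t))
    return CurveFit(model_name, params, fitted, r2)


def select_model(fits: dict[str, CurveFit]) -> str:
    """Pick the model with the highest R**2 (ties: first in MODEL_NAMES)."""
    best, best_r2 = None, -np.inf
    for name in MODEL_NAMES:
        fit = fits.get(name)
        if fit is None or not np.isfinite(fit.r2):
            continue
        if fit.r2 > best_r2:
            best, best_r2 = name, fit.r2
    if best is None:
        raise CurveFitError("no lactation-curve model could be fitted")
    return best


# ---------------------------------------------------------------------------
# iterative procedure
# ---------------------------------------------------------------------------

def iterate_elc(
    series: np.ndarray,
    model_name: str | None = None,
    smooth: bool = True,
    max_iterations: int = 50,
) -> ELCResult:
    """Run the full iterative ELC procedure on one complete 305-day series.

    The series is smoothed (unless ``smooth=False``), all four models are
    fitted on the full data and the best-R**2 model is locked in, then days
    whose deviation (data - fit) falls below ``LQ - 1.5*IQR`` are removed
    and the same model refitted until no day is removed.  Safeguards not
    part of the core definition: an iteration cap and a minimum retained
    day count of p+2 (p = number of model parameters); hitting either marks
    the result ``qc_pass=False`` rather than raising.
    """
    y = np.asarray(series, dtype=float)
    if y.size != N_DIM:
        raise ValueError(f"series must have exactly {N_DIM} values")
    if np.any(~np.isfinite(y)):
        raise ValueError("series must be complete (impute first)")

    work = smooth_weighted_ma(y) if smooth else y.copy()
    days = np.arange(1, N_DIM + 1)
    retained = np.ones(N_DIM, dtype=bool)

    def _failed(reason: str, model: str = "", n_iter: int = 0) -> ELCResult:
        return ELCResult(
            model_name=model,
            params=np.array([]),
            fitted=np.full(N_DIM, np.nan),
            r2=np.nan,
            retained_days=days[retained],
            n_iterations=max(n_iter, 1),
            qc_pass=False,
            qc_reason=reason,
            smoothed=work,
        )

    if model_name is None:
        fits = {}
        for name in MODEL_NAMES:
            try:
                fits[name] = fit_curve(days, work, name)
            except CurveFitError:
                continue
        if not fits:
            return _failed("all models failed")
        model_name = select_model(fits)
        fit = fits[model_name]
    else:
        try:
            fit = fit_curve(days, work, model_name)
        except CurveFitError as exc:
            return _failed(str(exc), model_name)

    min_points = MODEL_N_PARAMS[model_name] + 2
    n_iter = 1
    while True:
        dev = work[retained] - fit.fitted[retained]
        lq, uq = np.percentile(dev, [25, 75])  # linear interpolation ("type 7")
        threshold = lq - 1.5 * (uq - lq)
        outlier = dev < threshold
        if not outlier.any():
            break
        keep_days = days[retained][~outlier]
        if keep_days.size < min_points:
            return _failed("too few retained days", model_name, n_iter)
        retained = np.isin(days, keep_days)
        if n_iter >= max_iterations:
            return _failed("iteration cap reached", model_name, n_iter)
        try:
            fit = fit_curve(days[retained], work[retained], model_name)
        except CurveFitError as exc:
            return _failed(str(exc), model_name, n_iter)
        n_iter += 1

    result = ELCResult(
        model_name=model_name,
        params=fit.params,
        fitted=fit.fitted,
        r2=fit.r2,
        retained_days=days[retained],
        n_iterations=n_iter,
        qc_pass=True,
        smoothed=work,
    )
    passed, reason = elc_quality_control(result)
    result.qc_pass = passed
    result.qc_reason = reason
    return result


def elc_quality_control(result: ELCResult, r2_threshold: float = 0.75) -> tuple[bool, str]:
    """Secondary QC: every fitted value in (0, 100] kg and final R**2 > 0.75."""
    if not np.all(np.isfinite(result.fitted)):
        return False, "non-finite fitted values"
    if np.any(result.fitted <= 0.0) or np.any(result.fitted > 100.0):
        return False, "fitted values outside (0, 100] kg"
    if not (result.r2 > r2_threshold):
        return False, f"R2 {result.r2:.3f} <= {r2_threshold}"
    return True, ""
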