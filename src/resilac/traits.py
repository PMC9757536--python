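"""Resilience indicators from actual-vs-expected milk-yield deviations.

Resilient cows deviate little from their expected lactation curve (ELC)
when challenged and recover fast.  Two families of per-lactation
indicators quantify this:

**Milk-loss traits** built from *fluctuation* events.  A fluctuation is a
run of at least 10 consecutive days with yield strictly below the ELC,
during which the yield drops at least once strictly below 90% of the ELC.
Each event carries a duration (DML, days) and a loss (MLF, kg, the summed
shortfall); per lactation, ML is the total loss, NML the event count,
TDML the total event days and MLP the loss as a percentage of the 305-day
yield MY305.

**Variability traits** of the deviation series ``actual - fitted``:
the natural-log SD (Lnsd), lag-1 autocorrelation (Ra) and skewness (Ske),
each over four DIM windows -- 1: DIM 1-305, 2: DIM 11-295, 3: peak period
DIM 60-90, 4: the negative-deviation days only.  Low Lnsd, low Ra and
near-zero Ske indicate small, quickly-damped, symmetric deviations --
the signature of resilience borrowed from critical-slowing-down theory.

Deviations use the UNSMOOTHED imputed daily series against the ELC, even
though the curve itself was fitted on the smoothed series: the traits are
defined on actual records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .elc import N_DIM, ELCResult
from .preprocessing import LactationSeries

MIN_EVENT_DAYS = 10
DEPTH_FRACTION = 0.9
DIM_CLASS_EDGES = (1, 45, 100, 200, N_DIM + 1)
DIM_CLASS_LABELS = ("1-44", "45-99", "100-199", "200-305")

VARIABILITY_WINDOWS = (1, 2, 3, 4)
TRAIT_COLUMNS = (
    ["MY305", "ML", "NML", "TDML", "MLP"]
    + [f"Lnsd{w}" for w in VARIABILITY_WINDOWS]
    + [f"Ra{w}" for w in VARIABILITY_WINDOWS]
    + [f"Ske{w}" for w in VARIABILITY_WINDOWS]
)


@dataclass
class FluctuationEvent:
    """One perturbation: a qualifying run of negative deviations."""

    start_dim: int
    end_dim: int
    nadir_dim: int  # day of the largest shortfall (earliest on ties)
    duration_days: int  # DML
    loss_kg: float  # MLF = sum of (fitted - actual) over the run

    @property
    def dim_class(self) -> str:
        for lo, hi, lab in zip(DIM_CLASS_EDGES[:-1], DIM_CLASS_EDGES[1:], DIM_CLASS_LABELS):
            if lo <= self.start_dim < hi:
                return lab
        raise ValueError(f"start DIM {self.start_dim} outside 1..{N_DIM}")


def compute_deviations(actual: np.ndarray, fitted: np.ndarray) -> np.ndarray:
    """Elementwise actual - fitted over the complete 305-day grid."""
    actual = np.asarray(actual, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if actual.shape != fitted.shape or actual.size != N_DIM:
        raise ValueError(f"both series must have exactly {N_DIM} values")
    return actual - fitted


def detect_fluctuations(actual: np.ndarray, fitted: np.ndarray) -> list[FluctuationEvent]:
    """Find all fluctuation events in one lactation.

    Events are the *maximal* runs of consecutive days with
    ``actual < fitted`` whose length is >= 10 and that contain at least one
    day with ``actual < 0.9 * fitted`` (both inequalities strict).  A run
    of any length is one event, never split.
    """
    dev = compute_deviations(actual, fitted)
    neg = dev < 0
    events: list[FluctuationEvent] = []
    i = 0
    while i < N_DIM:
        if not neg[i]:
            i += 1
            continue
        j = i
        while j + 1 < N_DIM and neg[j + 1]:
            j += 1
        length = j - i + 1
        if length >= MIN_EVENT_DAYS and np.any(
            actual[i : j + 1] < DEPTH_FRACTION * fitted[i : j + 1]
        ):
            shortfall = fitted[i : j + 1] - actual[i : j + 1]
            nadir = i + int(np.argmax(shortfall))
            events.append(
                FluctuationEvent(
                    start_dim=i + 1,
                    end_dim=j + 1,
                    nadir_dim=nadir + 1,
                    duration_days=length,
                    loss_kg=float(shortfall.sum()),
                )
            )
        i = j + 1
    return events


def my305(imputed: np.ndarray) -> float:
    """305-day milk yield: sum of the complete (measured + imputed) series."""
    imputed = np.asarray(imputed, dtype=float)
    if imputed.size != N_DIM or np.any(np.isnan(imputed)):
        raise ValueError(f"need a complete {N_DIM}-day series")
    return float(imputed.sum())


def milk_loss_traits(events: list[FluctuationEvent], my305_kg: float):
    """Aggregate per-event losses to (ML, NML, TDML, MLP) for one lactation."""
    if my305_kg <= 0:
        raise ValueError("MY305 must be positive")
    ml = float(sum(e.loss_kg for e in events))
    nml = len(events)
    tdml = int(sum(e.duration_days for e in events))
    mlp = 100.0 * ml / my305_kg
    return ml, nml, tdml, mlp


def select_window(dev: np.ndarray, window_id: int) -> np.ndarray:
    """Deviation values of one variability window, in DIM order.

    1: DIM 1-305 (305 values); 2: DIM 11-295 (285); 3: DIM 60-90 (31);
    4: the days with strictly negative deviation.
    """
    dev = np.asarray(dev, dtype=float)
    if dev.size != N_DIM:
        raise ValueError(f"deviations must have {N_DIM} values")
    if window_id == 1:
        return dev.copy()
    if window_id == 2:
        return dev[10:295]
    if window_id == 3:
        return dev[59:90]
    if window_id == 4:
        return dev[dev < 0]
    raise ValueError(f"window_id must be 1..4, got {window_id}")


def lnsd(values: np.ndarray) -> float:
    """Natural log of the sample SD (n-1 denominator); NaN if degenerate."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        return np.nan
    sd = values.std(ddof=1)
    return float(np.log(sd)) if sd > 0 else np.nan


def lnsd_interval_halfwidth(lnsd_value: float) -> float:
    """Half-width (kg) of the 95% normal interval implied by an Lnsd value.

    The deviations' SD is ``exp(Lnsd)``, so under normality 95% of daily
    deviations fall within ``+/- 1.96 * exp(Lnsd)`` kg of the curve.
    """
    return 1.96 * float(np.exp(lnsd_value))


def lag1_autocorr(values: np.ndarray) -> float:
    """Lag-1 autocorrelation over adjacent positions of the ordered window.

    ``r = sum((d_t - m)(d_{t+1} - m)) / sum((d_t - m)^2)`` with m the
    window mean.  NaN for windows shorter than 3 or with zero variance.
    """
    d = np.asarray(values, dtype=float)
    if d.size < 3:
        return np.nan
    c = d - d.mean()
    denom = np.sum(c ** 2)
    if denom == 0:
        return np.nan
    return float(np.sum(c[:-1] * c[1:]) / denom)


def skewness(values: np.ndarray) -> float:
    """Adjusted Fisher-Pearson sample skewness g1 * sqrt(n(n-1))/(n-2)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3 or values.std(ddof=1) == 0:
        return np.nan
    return float(stats.skew(values, bias=False))


def variability_traits(dev: np.ndarray) -> dict[str, float]:
    """Lnsd/Ra/Ske over the four windows; missing where degenerate."""
    out: dict[str, float] = {}
    for w in VARIABILITY_WINDOWS:
        vals = select_window(dev, w)
        out[f"Lnsd{w}"] = lnsd(vals)
        out[f"Ra{w}"] = lag1_autocorr(vals)
        out[f"Ske{w}"] = skewness(vals)
    return out


def compute_phenotypes(
    lactation: LactationSeries, elc_result: ELCResult
) -> tuple[dict, list[dict]]:
    """All resilience indicators for one lactation.

    Returns (phenotype row, per-event rows).  The deviation series uses the
    unsmoothed imputed yields against the fitted ELC.
    """
    actual = lactation.yields
    fitted = elc_result.fitted
    dev = compute_deviations(actual, fitted)
    events = detect_fluctuations(actual, fitted)
    total = my305(actual)
    ml, nml, tdml, mlp = milk_loss_traits(events, total)
    row = {
        "cow_id": lactation.cow_id,
        "parity": lactation.parity,
        "herd": lactation.herd,
        "calving_date": lactation.calving_date,
        "afc_days": lactation.afc_days,
        "cluster": lactation.cluster_id,
        "curve_model": elc_result.model_name,
        "MY305": total,
        "ML": ml,
        "NML": nml,
        "TDML": tdml,
        "MLP": mlp,
    }
    row.update(variability_traits(dev))
    event_rows = [
        {
            "cow_id": lactation.cow_id,
            "parity": lactation.parity,
            "start_dim": e.start_dim,
            "end_dim": e.end_dim,
            "nadir_dim": e.nadir_dim,
            "DML": e.duration_days,
            "MLF": e.loss_kg,
            "dim_class": e.dim_class,
        }
        for e in events
    ]
    return row, event_rows


def finalize_cohort(
    phenotypes: pd.DataFrame, pedigree
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Final cohort filters before the genetic analysis.

    Drops lactations whose MY305 deviates three or more SD from the cohort
    mean, and cows whose sire or dam is unknown in the pedigree.
    """
    df = phenotypes.copy()
    report = {"my305_3sd": 0, "unknown_parents": 0}

    sd = df["MY305"].std(ddof=1)
    if len(df) >= 2 and sd > 0:
        keep = np.abs(df["MY305"] - df["MY305"].mean()) < 3 * sd
        report["my305_3sd"] = int((~keep).sum())
        df = df[keep]

    known = pedigree.known_parents()
    keep = df["cow_id"].map(lambda c: known.get(c, False))
    report["unknown_parents"] = int((~keep).sum())
    df = df[keep]
    return df.reset_index(drop=True), report


def summary_statistics(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Descriptive table (N, mean, SD, min, max, CV%) per trait column."""
    columns = list(columns) if columns is not None else [c for c in TRAIT_COLUMNS if c in df]
    rows = []
    for col in columns:
        vals = df[col].dropna().to_numpy(dtype=float)
        mean = vals.mean() if vals.size else np.nan
        sd = vals.std(ddof=1) if vals.size > 1 else np.nan
        rows.append(
            {
                "trait": col,
                "N": vals.size,
                "mean": mean,
                "SD": sd,
                "min": vals.min() if vals.size else np.nan,
                "max": vals.max() if vals.size else np.nan,
                "CV_pct": 100.0 * sd / abs(mean) if vals.size > 1 and mean != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
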