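"""Completion of partially observed lactations.

Two complementary rules produce a complete 305-day series per lactation:

* **edge rule** (DIM 1-4 and 305): the cluster's mean Z-scored yield at
  that DIM is mapped back to the lactation's own scale,
  ``y_hat = z_cluster(DIM) * SD(non-missing) + mean(non-missing)``;
* **interior rule** (DIM 5-304, in DIM order): a missing day n is
  predicted from an ordinary least-squares line through the five points at
  days n-4, n-3, n-2, n-1 and n+k, where n+k is the next day holding a
  value.  Days filled earlier in the scan serve as predictors for later
  days, and DIM 305 (guaranteed by the edge rule) is the terminal anchor.

Observed values are never modified, and imputed values are deliberately
NOT clamped to a plausible range -- extreme imputations are caught by the
downstream expected-lactation-curve quality control.
"""

from __future__ import annotations

import numpy as np

from .elc import N_DIM
from .preprocessing import LactationSeries

EDGE_DIMS = (1, 2, 3, 4, N_DIM)


def impute_edges(lactation: LactationSeries, cluster_profile: np.ndarray) -> LactationSeries:
    """Fill missing DIM 1-4 and 305 from the cluster's normalized profile.

    ``cluster_profile`` is the 305-slot mean Z-scored yield of the
    lactation's cluster.  Modifies the lactation in place and returns it.
    """
    if cluster_profile is None:
        raise ValueError("no cluster profile supplied")
    cluster_profile = np.asarray(cluster_profile, dtype=float)
    if cluster_profile.size != N_DIM:
        raise ValueError(f"cluster profile must have {N_DIM} slots")
    obs = lactation.observed_values()
    if obs.size < 2:
        raise ValueError("need at least 2 non-missing values to rescale")
    mean, sd = obs.mean(), obs.std(ddof=1)
    for dim in EDGE_DIMS:
        i = dim - 1
        if not np.isnan(lactation.yields[i]):
            continue
        z = cluster_profile[i]
        if np.isnan(z):
            raise ValueError(f"cluster profile undefined at DIM {dim}")
        lactation.yields[i] = z * sd + mean
        lactation.imputed_mask[i] = True
    return lactation


def impute_interior(lactation: LactationSeries) -> LactationSeries:
    """Sequential linear-regression interpolation of DIM 5-304.

    Requires DIM 1-4 and 305 to be present (run :func:`impute_edges`
    first).  Scanning n = 5..304 in order, each missing day is filled with
    the OLS-line prediction at n from the five points (n-4, n-3, n-2, n-1,
    n+k); because the scan is sequential, the four left-hand predictors
    always exist by the time day n is reached.
    """
    y = lactation.yields
    for dim in EDGE_DIMS[:4]:
        if np.isnan(y[dim - 1]):
            raise ValueError("DIM 1-4 must be present before interior imputation")
    if np.isnan(y[N_DIM - 1]):
        raise ValueError("DIM 305 must be present before interior imputation")

    for n in range(5, N_DIM):  # DIM 5..304
        i = n - 1
        if not np.isnan(y[i]):
            continue
        nxt = i + 1
        while np.isnan(y[nxt]):
            nxt += 1  # DIM 305 guarantees termination
        xs = np.array([n - 4, n - 3, n - 2, n - 1, nxt + 1], dtype=float)
        ys = y[[i - 4, i - 3, i - 2, i - 1, nxt]]
        slope, intercept = np.polyfit(xs, ys, 1)
        y[i] = slope * n + intercept
        lactation.imputed_mask[i] = True
    return lactation


def impute_lactation(lactation: LactationSeries, cluster_profile: np.ndarray) -> LactationSeries:
    """Edge rule then interior rule; afterwards the series is complete."""
    impute_edges(lactation, cluster_profile)
    impute_interior(lactation)
    assert not np.any(np.isnan(lactation.yields))
    return lactation
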