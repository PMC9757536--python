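"""Forward validation of resilience indicators.

Design: among sires with enough recorded daughters, each sire's daughters
are split by birth date into an older prediction set (80%) and a younger
validation set (20%).  Breeding values of validation cows are predicted
from prediction-set phenotypes and pedigree only, and the top and bottom
20% of validation animals on EBV are compared on companion traits with
Welch two-sample t tests.  If the indicator carries genetic signal, the
favourable-EBV group should be favourable on genetically correlated traits
it was never selected on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .quantgen import Pedigree, VarianceComponents, solve_ebv


def split_by_birthdate(
    daughters: pd.DataFrame,
    min_daughters: int = 40,
    fraction: float = 0.8,
    sire_col: str = "sire",
    animal_col: str = "animal",
    birth_col: str = "birth_date",
) -> tuple[list[str], list[str]]:
    """Per-sire 80/20 split of daughters by birth date.

    Sires with fewer than ``min_daughters`` recorded daughters are
    excluded.  Within each retained sire, daughters are sorted by birth
    date (ties broken by animal id); the oldest ``floor(fraction*n)`` go to
    the prediction set and the remainder to the validation set.  Returns
    (prediction ids, validation ids).
    """
    pred: list[str] = []
    valid: list[str] = []
    for _, grp in daughters.groupby(sire_col, sort=True):
        if len(grp) < min_daughters:
            continue
        ordered = grp.sort_values([birth_col, animal_col])
        n_pred = int(np.floor(fraction * len(ordered)))
        ids = ordered[animal_col].astype(str).tolist()
        pred.extend(ids[:n_pred])
        valid.extend(ids[n_pred:])
    return pred, valid


def predict_validation_ebv(
    phenotypes: pd.DataFrame,
    trait: str,
    pedigree: Pedigree,
    varcomp: VarianceComponents,
    prediction_ids: list[str],
    validation_ids: list[str],
    fixed_factors=("hys", "parity_class"),
    animal_col: str = "cow_id",
) -> pd.DataFrame:
    """EBVs of validation animals from prediction-set phenotypes only.

    The mixed-model equations see exclusively the phenotype rows of
    ``prediction_ids``; validation animals receive breeding values through
    the pedigree alone, so their own phenotypes cannot leak into their
    EBVs.
    """
    pred = phenotypes[phenotypes[animal_col].astype(str).isin(set(map(str, prediction_ids)))]
    ebv = solve_ebv(
        pred,
        trait,
        pedigree,
        varcomp,
        fixed_factors=fixed_factors,
        animal_col=animal_col,
        reliabilities=False,
    )
    val = set(map(str, validation_ids))
    out = ebv[ebv["animal"].isin(val)].reset_index(drop=True)
    return out


def compare_top_bottom(
    ebv_table: pd.DataFrame,
    phenotypes: pd.DataFrame,
    trait_cols: list[str],
    q: float = 0.2,
    lower_is_resilient: bool = True,
    animal_col: str = "animal",
) -> pd.DataFrame:
    """Compare the top and bottom EBV fractions on companion traits.

    ``ebv_table`` holds the validation animals' EBVs.  The "top"
    (most resilient) group is the ``floor(q*n)`` animals with the lowest
    EBV when ``lower_is_resilient`` (the convention for log-residual-SD
    indicators, where smaller variability means more resilient), else the
    highest.  Group means are compared per trait with Welch's unequal-
    variance t test.
    """
    ranked = ebv_table.sort_values(["ebv", animal_col]).reset_index(drop=True)
    n = len(ranked)
    g = int(np.floor(q * n))
    if g < 2:
        raise ValueError(f"group size floor(q*n) = {g} too small for a t test")
    low = ranked[animal_col].astype(str).iloc[:g]
    high = ranked[animal_col].astype(str).iloc[-g:]
    top_ids, bottom_ids = (low, high) if lower_is_resilient else (high, low)

    pheno = phenotypes.copy()
    pheno[animal_col] = pheno[animal_col].astype(str)
    top = pheno[pheno[animal_col].isin(top_ids)]
    bottom = pheno[pheno[animal_col].isin(bottom_ids)]

    rows = []
    for trait in trait_cols:
        a = top[trait].dropna().to_numpy(dtype=float)
        b = bottom[trait].dropna().to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "trait": trait,
                "n_top": a.size,
                "n_bottom": b.size,
                "top_mean": a.mean() if a.size else np.nan,
                "top_sd": a.std(ddof=1) if a.size > 1 else np.nan,
                "bottom_mean": b.mean() if b.size else np.nan,
                "bottom_sd": b.std(ddof=1) if b.size > 1 else np.nan,
                "t": float(t),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
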