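"""Quality control of raw daily milk-yield tables.

Input is a delimited table (comma or tab, detected from the header line)
with one row per cow-day::

    cow_id, herd, parity, calving_date, record_date, dim, yield_kg

Dates are ISO-8601.  ``dim`` (days in milk) is 1-based and must equal
``record_date - calving_date`` in days.  Two filter layers are applied:

* record level -- DIM in [1, 305], yield in [2.5, 100] kg (inclusive
  bounds), no duplicated (cow, parity, DIM) records;
* lactation level -- age at first calving in [600, 1800] days, a minimum
  number of observed days, and no gap of more than 10 consecutive missing
  days.

Each rule logs how many rows/lactations it removed; the per-rule counts sum
to the total removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elc import N_DIM

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "cow_id",
    "herd",
    "parity",
    "calving_date",
    "record_date",
    "dim",
    "yield_kg",
]


@dataclass
class FilterConfig:
    """Thresholds of the record- and lactation-level filters.

    The published bounds are DIM 1-305, daily yield 2.5-100 kg and age at
    first calving (AFC) 600-1800 days, all inclusive.  The minimum number
    of observed days per lactation is a strict but unprinted threshold of
    the original editing protocol; 250 is this package's default.
    """

    dim_range: tuple[int, int] = (1, N_DIM)
    yield_range: tuple[float, float] = (2.5, 100.0)
    afc_range: tuple[int, int] = (600, 1800)
    min_observed_days: int = 250
    max_gap_days: int = 10
    check_dim_consistency: bool = True


@dataclass
class LactationSeries:
    """One cow-parity's daily yields on the fixed DIM 1..305 grid.

    ``yields[t-1]`` holds the record for DIM t (NaN when missing before
    imputation); ``observed_mask`` marks measured days and
    ``imputed_mask`` days later filled by the imputation module.
    """

    cow_id: str
    parity: int
    yields: np.ndarray
    observed_mask: np.ndarray
    herd: str
    calving_date: pd.Timestamp
    afc_days: float = np.nan
    cluster_id: int | None = None
    imputed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.yields = np.asarray(self.yields, dtype=float)
        if self.yields.size != N_DIM:
            raise ValueError(f"yields must have {N_DIM} slots")
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros(N_DIM, dtype=bool)

    @property
    def key(self) -> tuple[str, int]:
        return (self.cow_id, self.parity)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    def observed_values(self) -> np.ndarray:
        return self.yields[self.observed_mask]


def read_records(path) -> pd.DataFrame:
    """Read a record table, auto-detecting comma vs tab from the header."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={"cow_id": str, "herd": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table is missing columns: {missing}")
    for col in ("calving_date", "record_date"):
        df[col] = pd.to_datetime(df[col], errors="coerce")
    df["dim"] = pd.to_numeric(df["dim"], errors="coerce")
    df["yield_kg"] = pd.to_numeric(df["yield_kg"], errors="coerce")
    return df


def split_rejects(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate rows that fail to parse (bad dates/numbers) from clean rows."""
    bad = (
        df["calving_date"].isna()
        | df["record_date"].isna()
        | df["dim"].isna()
        | df["yield_kg"].isna()
        | df["parity"].isna()
    )
    return df.loc[~bad].copy(), df.loc[bad].copy()


def filter_records(
    records: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the record-level filters; returns (kept records, removal ledger).

    Rules, in order: DIM window, yield window, DIM/date consistency, and
    duplicate removal.  Exact duplicates on (cow, parity, DIM) keep one
    copy; conflicting duplicates (same key, different yield) keep none and
    are logged as a warning.
    """
    config = config or FilterConfig()
    df = records.copy()
    report: dict[str, int] = {}

    n0 = len(df)
    lo, hi = config.dim_range
    df = df[(df["dim"] >= lo) & (df["dim"] <= hi)]
    report["dim_out_of_range"] = n0 - len(df)

    n0 = len(df)
    lo, hi = config.yield_range
    df = df[(df["yield_kg"] >= lo) & (df["yield_kg"] <= hi)]
    report["yield_out_of_range"] = n0 - len(df)

    if config.check_dim_consistency:
        n0 = len(df)
        delta = (df["record_date"] - df["calving_date"]).dt.days
        df = df[delta == df["dim"]]
        report["dim_date_mismatch"] = n0 - len(df)

    key = ["cow_id", "parity", "dim"]
    n0 = len(df)
    nuniq = df.groupby(key)["yield_kg"].transform("nunique")
    conflicting = nuniq > 1
    if conflicting.any():
        logger.warning(
            "%d records in conflicting duplicates (same cow/parity/DIM, "
            "different yield) dropped",
            int(conflicting.sum()),
        )
    df = df[~conflicting]
    df = df.drop_duplicates(subset=key, keep="first")
    report["duplicates"] = n0 - len(df)

    return df.reset_index(drop=True), report


def assemble_lactations(
    records: pd.DataFrame, birth_dates: dict | pd.Series | None = None
) -> list[LactationSeries]:
    """Pivot filtered records into per-cow-parity 305-slot series.

    ``birth_dates`` (cow_id -> birth date) enables the AFC computation; the
    age at first calving is the parity-1 calving date minus the birth date,
    attached to every parity of the cow.
    """
    if birth_dates is not None and not isinstance(birth_dates, pd.Series):
        birth_dates = pd.Series(birth_dates)

    first_calving = (
        records[records["parity"] == 1]
        .groupby("cow_id")["calving_date"]
        .min()
    )

    out: list[LactationSeries] = []
    for (cow, parity), grp in records.groupby(["cow_id", "parity"], sort=True):
        yields = np.full(N_DIM, np.nan)
        idx = grp["dim"].to_numpy(dtype=int) - 1
        yields[idx] = grp["yield_kg"].to_numpy(dtype=float)
        afc = np.nan
        if birth_dates is not None and cow in birth_dates.index and cow in first_calving.index:
            afc = float((first_calving[cow] - pd.Timestamp(birth_dates[cow])).days)
        out.append(
            LactationSeries(
                cow_id=cow,
                parity=int(parity),
                yields=yields,
                observed_mask=~np.isnan(yields),
                herd=str(grp["herd"].iloc[0]),
                calving_date=grp["calving_date"].iloc[0],
                afc_days=afc,
            )
        )
    return out


def longest_missing_gap(observed_mask: np.ndarray) -> int:
    """Length of the longest run of consecutive missing days over DIM 1..305."""
    gaps = 0
    best = 0
    for obs in observed_mask:
        gaps = 0 if obs else gaps + 1
        best = max(best, gaps)
    return best


def filter_lactations(
    records: pd.DataFrame,
    config: FilterConfig | None = None,
    birth_dates: dict | pd.Series | None = None,
) -> tuple[list[LactationSeries], dict[str, int]]:
    """Assemble and filter lactations; returns (kept series, removal ledger).

    Rules, in order: AFC outside [600, 1800] days (applied only when a
    birth date is available), fewer observed days than the configured
    minimum, and a gap of more than ``max_gap_days`` consecutive missing
    days anywhere in DIM 1..305.
    """
    config = config or FilterConfig()
    lactations = assemble_lactations(records, birth_dates)
    report = {"afc_out_of_range": 0, "too_few_observed_days": 0, "long_gap": 0}
    kept: list[LactationSeries] = []
    lo, hi = config.afc_range
    for lact in lactations:
        if np.isfinite(lact.afc_days) and not (lo <= lact.afc_days <= hi):
            report["afc_out_of_range"] += 1
            continue
        if lact.n_observed < config.min_observed_days:
            report["too_few_observed_days"] += 1
            continue
        if longest_missing_gap(lact.observed_mask) > config.max_gap_days:
            report["long_gap"] += 1
            continue
        kept.append(lact)
    return kept, report


def write_qc_report(report: dict[str, int], path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"rule": list(report.keys()), "removed": list(report.values())}
    ).to_csv(path, sep=sep, index=False)
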