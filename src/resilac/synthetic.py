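"""Synthetic herd data with the statistical structure the pipeline assumes.

The real daily-yield data behind this kind of analysis are proprietary farm
records, so every downstream stage is exercised on simulated cohorts whose
generative model mirrors the documented features of such data:

* a three-generation pedigree (sires, unrelated dams, recorded daughters);
* additive genetic variation in the log residual SD of daily yield
  (the Lnsd resilience trait), default heritability 0.25 on a phenotypic
  variance of ~0.107 (matching the reported Lnsd2 variance scale);
* 305-day lactations whose perturbation-free potential follows one of the
  classical lactation-curve shapes, with a ~5% minority of atypical shapes
  (delayed peak, flat/increasing curves);
* on average ~3.7 perturbation events per lactation lasting ~20 days, with
  elevated onset risk in early and late lactation, each event a
  piecewise-linear drop to a nadir followed by a linear recovery;
* herd-year-season additive shifts in daily yield; per-day missingness
  plus occasional multi-day gaps; negative noisy yields truncated to zero
  and treated as missing.

Everything is reproducible from the config seed; a :class:`TruthTable`
retains the simulated breeding values, potential curves and events for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .elc import N_DIM, evaluate_model
from .quantgen import Pedigree

#: six well-separated lactation-curve shape archetypes used in clustering
#: experiments: (model, params). Shapes differ in peak timing, early-
#: lactation level and persistency, so their Z-scored profiles separate.
ARCHETYPE_PARAMS: dict[str, tuple[str, tuple[float, ...]]] = {
    "early_peak_fast": ("wood", (25.0, 0.32, 0.0095)),  # peak ~DIM 34, steep decline
    "flat_persistent": ("wilmink", (33.0, -12.0, -0.004)),  # low peak, persistent
    "mid_peak": ("wood", (3.0, 0.75, 0.0058)),  # peak ~DIM 129
    "late_peak": ("wood", (0.35, 1.10, 0.0050)),  # delayed peak ~DIM 220
    "increasing": ("wilmink", (16.0, -6.0, 0.070)),  # monotone rise
    "u_shape": ("ali_schaeffer", (45.0, -0.25, 0.00082, 0.0, 0.0)),  # reversal curve
}

TYPICAL_ARCHETYPES = ("early_peak_fast", "flat_persistent", "mid_peak")
ATYPICAL_ARCHETYPES = ("late_peak", "increasing", "u_shape")

#: multiplicative yield scale by parity (1..5+)
PARITY_SCALE = (1.0, 1.12, 1.18, 1.20, 1.20)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate the documented herd structure."""

    n_sires: int = 30
    n_daughters_per_sire: int = 20
    n_herds: int = 3
    years: tuple[int, int] = (2017, 2020)
    mean_lnsd: float = 0.97
    sigma_a2_lnsd: float = 0.027
    sigma_e2_lnsd: float = 0.080
    perturbation_rate: float = 3.7
    duration_dist: tuple[str, dict] = ("lognormal", {"mean_log": 2.84, "sigma_log": 0.54, "minimum": 5.0})
    depth_dist: tuple[str, dict] = ("beta", {"a": 2.0, "b": 6.0})
    missing_day_prob: float = 0.03
    gap_rate: float = 0.4
    gap_length_dist: tuple[str, dict] = ("randint", {"low": 3, "high": 12})
    atypical_fraction: float = 0.05
    hys_sd: float = 1.0
    max_parity: int = 3
    bv_duration_coef: float = 0.15
    bv_depth_coef: float = 0.3
    seed: int = 2024

    def __post_init__(self):
        if min(self.sigma_a2_lnsd, self.sigma_e2_lnsd) < 0:
            raise ValueError("variances must be non-negative")
        if self.perturbation_rate < 0:
            raise ValueError("perturbation_rate must be non-negative")
        for p in (self.missing_day_prob,):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.atypical_fraction <= 1:
            raise ValueError("atypical_fraction must lie in [0, 1]")
        if self.n_sires < 0 or self.n_daughters_per_sire < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class PerturbationEvent:
    start_dim: int
    duration_days: int
    nadir_depth: float  # maximal fractional drop, in (0, 1)

    def depth_profile(self) -> np.ndarray:
        """Fractional drop per event day: linear decline over the first
        third to the nadir, then linear recovery; the drop reaches zero on
        the day after the event, so every event day is depressed."""
        d = self.duration_days
        t_nadir = max(1, int(np.ceil(d / 3)))
        prof = np.empty(d)
        for i in range(d):
            if i < t_nadir:
                prof[i] = self.nadir_depth * (i + 1) / t_nadir
            else:
                prof[i] = self.nadir_depth * (d - i) / (d - t_nadir)
        return prof


@dataclass
class TruthTable:
    """Ground truth retained for parameter-recovery tests."""

    breeding_values: pd.DataFrame  # animal, bv_lnsd
    lactations: pd.DataFrame  # cow_id, parity, lnsd_true, archetype, model
    potential_curves: dict[tuple[str, int], np.ndarray] = field(repr=False, default_factory=dict)
    events: pd.DataFrame = None  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# pedigree and breeding values
# ---------------------------------------------------------------------------

def simulate_pedigree(
    n_sires: int, n_daughters_per_sire: int, seed: int, years: tuple[int, int] = (2017, 2020)
) -> Pedigree:
    """Founder sires and dams plus one recorded daughter per dam.

    Daughters' birth dates are spread uniformly over ``years`` so that
    birth-date validation splits are meaningful; sires and dams are born
    earlier.  Topologically ordered by construction.
    """
    if n_sires < 0 or n_daughters_per_sire < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    animals, sires, dams, births, sexes = [], [], [], [], []
    y0, y1 = years
    for s in range(n_sires):
        animals.append(f"S{s:04d}")
        sires.append("0")
        dams.append("0")
        births.append(pd.Timestamp(f"{y0 - 6}-01-01") + pd.Timedelta(days=int(rng.integers(0, 365))))
        sexes.append("M")
    for s in range(n_sires):
        for k in range(n_daughters_per_sire):
            dam = f"D{s:04d}x{k:03d}"
            animals.append(dam)
            sires.append("0")
            dams.append("0")
            births.append(
                pd.Timestamp(f"{y0 - 4}-01-01") + pd.Timedelta(days=int(rng.integers(0, 730)))
            )
            sexes.append("F")
    for s in range(n_sires):
        for k in range(n_daughters_per_sire):
            animals.append(f"C{s:04d}x{k:03d}")
            sires.append(f"S{s:04d}")
            dams.append(f"D{s:04d}x{k:03d}")
            span_days = max((y1 - y0) * 365, 1)
            births.append(
                pd.Timestamp(f"{y0 - 2}-01-01") + pd.Timedelta(days=int(rng.integers(0, span_days)))
            )
            sexes.append("F")
    return Pedigree(animals, sires, dams, birth_dates=births, sexes=sexes)


def simulate_breeding_values(
    pedigree: Pedigree, sigma_a2: float, seed: int
) -> pd.Series:
    """Additive genetic effects: a ~ N(0, A*sigma_a2) by gene dropping.

    Founders are N(0, sigma_a2); a non-founder is the parent average plus a
    Mendelian-sampling deviate with variance
    ``0.5*sigma_a2*(1 - (F_s + F_d)/2)`` (a missing parent contributes 0
    with the corresponding variance adjustment).
    """
    if sigma_a2 < 0:
        raise ValueError("sigma_a2 must be non-negative")
    rng = np.random.default_rng(seed)
    F = pedigree.inbreeding()
    bv = np.zeros(pedigree.n)
    if sigma_a2 == 0:
        return pd.Series(bv, index=pedigree.animals, name="bv")
    for i in range(pedigree.n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s < 0 and d < 0:
            bv[i] = rng.normal(0.0, np.sqrt(sigma_a2))
        else:
            pa = 0.0
            if s >= 0 and d >= 0:
                pa = 0.5 * (bv[s] + bv[d])
                ms_var = 0.5 * sigma_a2 * (1.0 - 0.5 * (F[s] + F[d]))
            else:
                p = max(s, d)
                pa = 0.5 * bv[p]
                ms_var = 0.75 * sigma_a2 * (1.0 - F[p] / 3.0)
            bv[i] = pa + rng.normal(0.0, np.sqrt(ms_var))
    return pd.Series(bv, index=pedigree.animals, name="bv")


# ---------------------------------------------------------------------------
# lactation curves, events, daily records
# ---------------------------------------------------------------------------

def simulate_lactation_curve(model_name: str, params, parity_effect: float = 1.0) -> np.ndarray:
    """Deterministic potential curve: named model on DIM 1..305, scaled by
    the multiplicative parity effect.  Rejects non-positive curves."""
    curve = evaluate_model(model_name, params) * float(parity_effect)
    if np.any(curve <= 0) or not np.all(np.isfinite(curve)):
        raise ValueError("curve must be strictly positive over DIM 1..305")
    return curve


def _draw(dist: tuple[str, dict], rng: np.random.Generator, size=None):
    law, pars = dist
    if law == "lognormal":
        x = rng.lognormal(pars["mean_log"], pars["sigma_log"], size)
        return np.maximum(x, pars.get("minimum", 0.0))
    if law == "beta":
        return rng.beta(pars["a"], pars["b"], size)
    if law == "randint":
        return rng.integers(pars["low"], pars["high"] + 1, size)
    raise ValueError(f"unknown distribution law {law!r}")


def _start_dim_probs() -> np.ndarray:
    # elevated onset risk in early (DIM<=30) and late (DIM>=270) lactation
    w = np.ones(N_DIM)
    w[:30] = 3.0
    w[269:] = 2.0
    return w / w.sum()


_START_PROBS = _start_dim_probs()


def simulate_perturbation_events(
    rate: float,
    duration_dist: tuple[str, dict],
    depth_dist: tuple[str, dict],
    resilience_bv: float,
    seed,
    duration_coef: float = 0.15,
    depth_coef: float = 0.3,
) -> list[PerturbationEvent]:
    """Poisson(rate) perturbations for one lactation.

    Onset DIM has elevated early/late mass; durations and nadir depths come
    from the configured laws, shifted by the animal's (standardised)
    resilience breeding value through log-linear links: a more resilient
    animal (higher ``resilience_bv``) has shorter, shallower events --
    ``log(duration) -= duration_coef*bv`` and ``logit(depth) -= depth_coef*bv``.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate)
    events: list[PerturbationEvent] = []
    min_dur = duration_dist[1].get("minimum", 1.0)
    for _ in range(n):
        start = int(rng.choice(N_DIM, p=_START_PROBS)) + 1
        dur = float(_draw(duration_dist, rng))
        dur = max(np.exp(np.log(dur) - duration_coef * resilience_bv), min_dur)
        duration = int(np.round(dur))
        depth = float(np.clip(_draw(depth_dist, rng), 1e-6, 1 - 1e-6))
        logit = np.log(depth / (1 - depth)) - depth_coef * resilience_bv
        depth = 1.0 / (1.0 + np.exp(-logit))
        duration = min(duration, N_DIM - start + 1)
        events.append(PerturbationEvent(start, duration, depth))
    return events


def apply_events(potential: np.ndarray, events: list[PerturbationEvent]) -> np.ndarray:
    """Multiply the potential curve by (1 - depth) over each event's days.

    Overlapping events combine by taking the deeper drop on shared days.
    """
    depth = np.zeros(N_DIM)
    for ev in events:
        prof = ev.depth_profile()
        lo = ev.start_dim - 1
        hi = min(lo + ev.duration_days, N_DIM)
        depth[lo:hi] = np.maximum(depth[lo:hi], prof[: hi - lo])
    return potential * (1.0 - depth)


def simulate_daily_records(
    potential: np.ndarray,
    events: list[PerturbationEvent],
    lnsd_value: float,
    missing_day_prob: float,
    seed,
    gap_rate: float = 0.0,
    gap_length_dist: tuple[str, dict] | None = None,
) -> np.ndarray:
    """Observed daily yields (305 slots, NaN = missing).

    observed = potential*(1 - event depth) + N(0, exp(lnsd)^2); negative
    noisy yields are truncated at zero and treated as missing (they fall
    below the 2.5 kg record filter in any case).  Missingness: per-day
    Bernoulli deletions plus a Poisson number of multi-day gaps.
    """
    rng = np.random.default_rng(seed)
    clean = apply_events(np.asarray(potential, dtype=float), events)
    noise_sd = float(np.exp(lnsd_value))
    y = clean + rng.normal(0.0, noise_sd, N_DIM)
    y[y < 0] = np.nan  # truncated, then treated as missing
    if missing_day_prob > 0:
        y[rng.random(N_DIM) < missing_day_prob] = np.nan
    if gap_rate > 0 and gap_length_dist is not None:
        for _ in range(rng.poisson(gap_rate)):
            glen = int(_draw(gap_length_dist, rng))
            gstart = int(rng.integers(0, N_DIM - glen + 1))
            y[gstart : gstart + glen] = np.nan
    return y


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def _draw_archetype(cfg: SyntheticConfig, rng: np.random.Generator) -> str:
    if rng.random() < cfg.atypical_fraction:
        return str(rng.choice(ATYPICAL_ARCHETYPES))
    return str(rng.choice(TYPICAL_ARCHETYPES))


def _jitter_params(model: str, params: tuple[float, ...], rng: np.random.Generator):
    """Small multiplicative parameter noise so curves vary within archetype."""
    scale = 1.0 + 0.05 * rng.standard_normal(len(params))
    return tuple(p * s for p, s in zip(params, scale))


def simulate_dataset(config: SyntheticConfig):
    """Generate (records, pedigree, truth) for a full cohort.

    Records is a long table (cow_id, herd, parity, calving_date,
    record_date, dim, yield_kg); daily yields include the herd-year-season
    shift.  Byte-identical output for identical config (incl. seed).
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    s_ped, s_bv, s_cohort = root.spawn(3)
    pedigree = simulate_pedigree(
        cfg.n_sires, cfg.n_daughters_per_sire, s_ped, years=cfg.years
    )
    bv = simulate_breeding_values(pedigree, cfg.sigma_a2_lnsd, s_bv)
    rng = np.random.default_rng(s_cohort)

    bv_sd = np.sqrt(cfg.sigma_a2_lnsd) if cfg.sigma_a2_lnsd > 0 else 1.0
    hys_effects: dict[tuple[str, int, int], float] = {}
    cows = [a for a in pedigree.animals if a.startswith("C")]

    record_rows = []
    lact_rows = []
    event_rows = []
    curves: dict[tuple[str, int], np.ndarray] = {}

    for cow in cows:
        herd = f"H{rng.integers(0, cfg.n_herds):02d}"
        birth = pedigree.birth_dates[cow]
        afc = float(np.clip(rng.normal(760, 80), 560, 1900))
        n_par = int(rng.integers(1, cfg.max_parity + 1))
        calving = birth + pd.Timedelta(days=int(afc))
        for parity in range(1, n_par + 1):
            if parity > 1:
                calving = calving + pd.Timedelta(days=int(rng.normal(380, 15)))
            archetype = _draw_archetype(cfg, rng)
            model, base = ARCHETYPE_PARAMS[archetype]
            for _ in range(20):
                params = _jitter_params(model, base, rng)
                try:
                    potential = simulate_lactation_curve(
                        model, params, PARITY_SCALE[min(parity, 5) - 1]
                    )
                    break
                except ValueError:
                    continue
            else:  # pragma: no cover - jitter virtually never fails 20 times
                potential = simulate_lactation_curve(model, base, PARITY_SCALE[min(parity, 5) - 1])

            lnsd_true = cfg.mean_lnsd + bv[cow] + rng.normal(
                0.0, np.sqrt(cfg.sigma_e2_lnsd)
            )
            resilience = -bv[cow] / bv_sd
            events = simulate_perturbation_events(
                cfg.perturbation_rate,
                cfg.duration_dist,
                cfg.depth_dist,
                resilience,
                rng.integers(0, 2 ** 31),
                duration_coef=cfg.bv_duration_coef,
                depth_coef=cfg.bv_depth_coef,
            )
            daily = simulate_daily_records(
                potential,
                events,
                lnsd_true,
                cfg.missing_day_prob,
                rng.integers(0, 2 ** 31),
                gap_rate=cfg.gap_rate,
                gap_length_dist=cfg.gap_length_dist,
            )
            key = (herd, calving.year, (calving.month - 1) // 3 + 1)
            if key not in hys_effects:
                hys_effects[key] = rng.normal(0.0, cfg.hys_sd)
            daily = daily + hys_effects[key]

            curves[(cow, parity)] = potential
            lact_rows.append(
                {
                    "cow_id": cow,
                    "parity": parity,
                    "herd": herd,
                    "calving_date": calving,
                    "lnsd_true": lnsd_true,
                    "archetype": archetype,
                    "model": model,
                }
            )
            for ev in events:
                event_rows.append(
                    {
                        "cow_id": cow,
                        "parity": parity,
                        "start_dim": ev.start_dim,
                        "duration_days": ev.duration_days,
                        "nadir_depth": ev.nadir_depth,
                    }
                )
            for dim0 in np.flatnonzero(~np.isnan(daily)):
                record_rows.append(
                    {
                        "cow_id": cow,
                        "herd": herd,
                        "parity": parity,
                        "calving_date": calving,
                        "record_date": calving + pd.Timedelta(days=int(dim0) + 1),
                        "dim": int(dim0) + 1,
                        "yield_kg": round(float(daily[dim0]), 3),
                    }
                )

    records = pd.DataFrame(
        record_rows,
        columns=["cow_id", "herd", "parity", "calving_date", "record_date", "dim", "yield_kg"],
    )
    truth = TruthTable(
        breeding_values=bv.rename("bv_lnsd").rename_axis("animal").reset_index(),
        lactations=pd.DataFrame(lact_rows),
        potential_curves=curves,
        events=pd.DataFrame(
            event_rows, columns=["cow_id", "parity", "start_dim", "duration_days", "nadir_depth"]
        ),
    )
    return records, pedigree, truth


def simulate_trait_cohort(
    n_sires: int,
    n_daughters_per_sire: int,
    sigma_a2: float,
    sigma_e2: float,
    mean: float = 0.97,
    n_herds: int = 3,
    years: tuple[int, int] = (2017, 2020),
    seed: int = 0,
) -> tuple[pd.DataFrame, Pedigree]:
    """Direct per-cow phenotypes of a log-residual-SD-type trait.

    One record per daughter: ``y = mean + herd-year-season + parity shift +
    a + e`` with a from the pedigree and e ~ N(0, sigma_e2).  Used for
    heritability parameter-recovery experiments at scale, skipping the
    daily-record layer.
    """
    root = np.random.SeedSequence(seed)
    s_ped, s_bv, s_env = root.spawn(3)
    pedigree = simulate_pedigree(n_sires, n_daughters_per_sire, s_ped, years=years)
    bv = simulate_breeding_values(pedigree, sigma_a2, s_bv)
    rng = np.random.default_rng(s_env)
    cows = [a for a in pedigree.animals if a.startswith("C")]
    herds = [f"H{rng.integers(0, n_herds):02d}" for _ in cows]
    y0, y1 = years
    dates = [
        pd.Timestamp(f"{rng.integers(y0, y1 + 1)}-01-01")
        + pd.Timedelta(days=int(rng.integers(0, 365)))
        for _ in cows
    ]
    parities = rng.integers(1, 4, len(cows))
    hys_key = [f"{h}-{d.year}-Q{(d.month - 1) // 3 + 1}" for h, d in zip(herds, dates)]
    effects = {k: rng.normal(0, 0.05) for k in sorted(set(hys_key))}
    parity_shift = {1: 0.0, 2: 0.03, 3: 0.05}
    y = np.array(
        [
            mean
            + effects[k]
            + parity_shift[int(p)]
            + bv[c]
            + rng.normal(0, np.sqrt(sigma_e2))
            for c, k, p in zip(cows, hys_key, parities)
        ]
    )
    df = pd.DataFrame(
        {
            "cow_id": cows,
            "herd": herds,
            "calving_date": dates,
            "parity": parities,
            "trait": y,
            "hys": hys_key,
            "parity_class": [str(int(p)) for p in parities],
        }
    )
    return df, pedigree


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def write_records(records: pd.DataFrame, path, sep=",") -> None:
    records.to_csv(path, sep=sep, index=False, date_format="%Y-%m-%d")


def write_pedigree(pedigree: Pedigree, path, sep=",") -> None:
    pedigree.to_frame().to_csv(path, sep=sep, index=False, date_format="%Y-%m-%d")


def save_config(config: SyntheticConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def load_config(path) -> SyntheticConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("duration_dist", "depth_dist", "gap_length_dist", "years"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SyntheticConfig(**raw)
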