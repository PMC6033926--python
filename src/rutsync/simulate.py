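"""Synthetic raw data with the statistical structure the analysis assumes.

Two generators:

* :func:`simulate_experiment` — per-animal ovarian-cycle time series over a
  fixed observation window (default 26 weeks): alternating pre-ovulatory
  periods drawn from a treatment-specific shifted exponential and constant
  post-ovulatory (luteal) periods, with the final partial period censored
  at the window edge.  Defaults emulate the field experiment: 5 animals
  per treatment, Playback rate ~0.103/d with 5.71 d follicular phase,
  Control rate ~0.030/d with 4.03 d, ≤3-day sampling resolution available
  through the ``rounding`` flag.

* :func:`simulate_gestation_table` — a 41-species gestation allometry with
  log-uniform means, power-law SDs with log2-normal residuals, and a few
  rows labelled as excluded taxon groups (primates, elephants) that follow
  a deviating relationship, to exercise the exclusion filter.  Defaults
  are calibrated so the predicted SD at a 258-day mean is 5.74 d.

Cycle records are a pandas DataFrame with columns ``animal_id``,
``treatment``, ``period_type`` (``pre_ovulatory``/``post_ovulatory``),
``start_day``, ``end_day``, ``censored``.  Within an animal the periods
alternate in type and tile the window exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import ShiftedExponential
from .estimation import PreOvulatoryDataset

__all__ = [
    "SimulationConfig",
    "simulate_experiment",
    "apply_start_filter",
    "extract_durations",
    "durations_by_animal",
    "simulate_gestation_table",
    "CYCLE_COLUMNS",
    "DEFAULT_TREATMENT_LAWS",
]

CYCLE_COLUMNS = ("animal_id", "treatment", "period_type", "start_day", "end_day", "censored")

_LN5 = float(np.log(5.0))
# rates back-derived from the reported group T80 estimates (ln5 / T80),
# consistent with the reported fits of 0.10 and 0.03 per day
DEFAULT_TREATMENT_LAWS: dict[str, ShiftedExponential] = {
    "Control": ShiftedExponential(rate=_LN5 / 53.72, shift=4.03),
    "Playback": ShiftedExponential(rate=_LN5 / 15.70, shift=5.71),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the simulated playback experiment.

    ``post_ovulatory_days`` is the constant luteal-period length; it never
    enters pre-ovulatory inference and only sets how many cycles fit in the
    window.  ``rounding`` quantises transition times up to the sampling
    grid to emulate the ≤3-day collection schedule; default off so that
    analytic oracles are exact.
    """

    treatments: dict[str, ShiftedExponential] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_LAWS)
    )
    n_animals: int = 5
    window_days: float = 182.0
    post_ovulatory_days: float = 12.0
    sampling_interval_days: float = 3.0
    rounding: bool = False

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.window_days <= 0 or self.post_ovulatory_days <= 0:
            raise ValueError("window_days and post_ovulatory_days must be positive")
        if self.sampling_interval_days <= 0:
            raise ValueError("sampling_interval_days must be positive")
        if not self.treatments:
            raise ValueError("at least one treatment law required")


def _animal_records(
    animal_id: str,
    treatment: str,
    law: ShiftedExponential,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple]:
    rows = []
    t = 0.0
    period = "pre_ovulatory"
    while t < config.window_days:
        if period == "pre_ovulatory":
            dur = float(law.sample(1, rng)[0])
        else:
            dur = config.post_ovulatory_days
        end = t + dur
        censored = end > config.window_days
        rows.append((animal_id, treatment, period, t, min(end, config.window_days), censored))
        t = end
        period = "post_ovulatory" if period == "pre_ovulatory" else "pre_ovulatory"
    return rows


def _quantize(records: pd.DataFrame, step: float) -> pd.DataFrame:
    # transitions become observable only at the next sampling day; snapping
    # both edges keeps the tiling exact, zero-length periods are dropped
    out = records.copy()
    out["start_day"] = np.ceil(out["start_day"] / step) * step
    out["end_day"] = np.where(
        out["censored"], out["end_day"], np.ceil(out["end_day"] / step) * step
    )
    out = out[out["end_day"] > out["start_day"]].reset_index(drop=True)
    return out


def simulate_experiment(config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Simulate per-animal cycle time series for every treatment.

    Animal ids are the treatment initial plus a 1-based index (C1..C5,
    P1..P5 by default).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for treatment, law in config.treatments.items():
        prefix = treatment[:1].upper()
        for i in range(config.n_animals):
            rows.extend(
                _animal_records(f"{prefix}{i + 1}", treatment, law, config, rng)
            )
    records = pd.DataFrame(rows, columns=list(CYCLE_COLUMNS))
    if config.rounding:
        records = _quantize(records, config.sampling_interval_days)
    return records


def apply_start_filter(
    records: pd.DataFrame, threshold: float = 3.0
) -> tuple[pd.DataFrame, int]:
    """Drop first pre-ovulatory periods completed within ``threshold`` days.

    Animals whose first transition to the post-ovulatory period falls at or
    before ``threshold`` days were likely already in follicular phase when
    the experiment started, so that first record carries no treatment
    signal.  Returns the filtered records and the number removed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    drop: list = []
    for _, animal in records.groupby("animal_id", sort=False):
        first = animal.sort_values("start_day").iloc[0]
        if (
            first["period_type"] == "pre_ovulatory"
            and not first["censored"]
            and threshold > 0
            and first["end_day"] <= threshold
        ):
            drop.append(first.name)
    return records.drop(index=drop).reset_index(drop=True), len(drop)


def extract_durations(records: pd.DataFrame) -> dict[str, PreOvulatoryDataset]:
    """Pool completed pre-ovulatory durations by treatment.

    Censored periods are excluded (no censoring likelihood is used in the
    analysis); treatments whose completed-period count is zero still appear
    with an empty dataset.
    """
    out: dict[str, PreOvulatoryDataset] = {}
    for treatment, grp in records.groupby("treatment", sort=False):
        pre = grp[(grp["period_type"] == "pre_ovulatory") & (~grp["censored"])]
        durations = (pre["end_day"] - pre["start_day"]).to_numpy(dtype=float)
        out[treatment] = PreOvulatoryDataset(treatment=str(treatment), durations=durations)
    return out


def durations_by_animal(records: pd.DataFrame) -> dict[str, list[np.ndarray]]:
    """Completed pre-ovulatory durations grouped per animal within treatment.

    This is the input shape of the permutation test, which permutes whole
    animals between groups.
    """
    out: dict[str, list[np.ndarray]] = {}
    for treatment, grp in records.groupby("treatment", sort=False):
        per_animal = []
        for _, animal in grp.groupby("animal_id", sort=False):
            pre = animal[(animal["period_type"] == "pre_ovulatory") & (~animal["censored"])]
            durs = (pre["end_day"] - pre["start_day"]).to_numpy(dtype=float)
            if durs.size:
                per_animal.append(durs)
        out[treatment] = per_animal
    return out


def simulate_gestation_table(
    n_species: int = 41,
    slope: float = 0.9,
    sd_at_target: float = 5.74,
    target_mean: float = 258.0,
    log2_noise_sd: float = 0.3,
    mean_range: tuple[float, float] = (20.0, 700.0),
    n_primates: int = 3,
    n_elephants: int = 1,
    seed=None,
) -> pd.DataFrame:
    """Synthetic cross-species gestation allometry table.

    The intercept is derived from ``slope`` and the calibration point
    ``(target_mean, sd_at_target)``, so with zero noise the regression
    prediction at ``target_mean`` recovers ``sd_at_target`` exactly.
    Primate and elephant rows follow an offset relationship and are meant
    to be excluded before fitting.  Columns: ``species``, ``mean_days``,
    ``sd_days``, ``group``.
    """
    if n_species < n_primates + n_elephants + 3:
        raise ValueError("too few retained species")
    if sd_at_target <= 0 or target_mean <= 0 or log2_noise_sd < 0:
        raise ValueError("calibration parameters must be positive")
    rng = np.random.default_rng(seed)
    intercept = float(np.log2(sd_at_target) - slope * np.log2(target_mean))

    n_other = n_species - n_primates - n_elephants
    lo, hi = np.log2(mean_range[0]), np.log2(mean_range[1])
    x = rng.uniform(lo, hi, size=n_other)
    y = intercept + slope * x + rng.normal(0.0, log2_noise_sd, size=n_other)
    rows = [
        (f"sp{i + 1:02d}", float(2.0**xi), float(2.0**yi), "other")
        for i, (xi, yi) in enumerate(zip(x, y))
    ]
    # excluded taxa sit well off the main relationship (tighter gestation
    # spread than their mean predicts)
    xp = rng.uniform(np.log2(160.0), np.log2(280.0), size=n_primates)
    for i, xi in enumerate(xp):
        yi = intercept + slope * xi - 1.5 + rng.normal(0.0, log2_noise_sd)
        rows.append((f"primate{i + 1}", float(2.0**xi), float(2.0**yi), "primate"))
    xe = rng.uniform(np.log2(600.0), np.log2(680.0), size=n_elephants)
    for i, xi in enumerate(xe):
        yi = intercept + slope * xi - 1.5 + rng.normal(0.0, log2_noise_sd)
        rows.append((f"elephant{i + 1}", float(2.0**xi), float(2.0**yi), "elephant"))
    return pd.DataFrame(rows, columns=["species", "mean_days", "sd_days", "group"])
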