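"""End-to-end analysis pipeline and its configuration.

``run_pipeline`` composes the full analysis: start-filter the cycle
records, pool completed pre-ovulatory durations per treatment, fit the
shifted exponential by MVU with bootstrap CIs, compute T80 synchrony,
run the permutation test, bootstrap mating predictions against the
empirical mating window, fit the gestation allometry, and bootstrap
calving predictions against the empirical calving windows.  It returns a
machine-readable report (plain dict, JSON-serialisable) and can write it
alongside a short human-readable summary.

Every stochastic stage draws its generator from a per-stage child of the
master seed, so a config run twice gives byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .estimation import bootstrap_fit_ci, fit_mvu
from .inference import permutation_test
from .prediction import (
    fit_gestation_scaling,
    fraction_in_range,
    gestation_mean_from_range,
    predict_calving_t80,
    predict_mating_t80,
    predict_sigma,
)
from .synchrony import t80_shifted_exponential

__all__ = ["AnalysisConfig", "run_pipeline", "load_config", "write_report"]

log = logging.getLogger("rutsync")

_STAGES = ("fit_ci", "permutation", "mating", "gestation", "calving")


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunables of the analysis with their reported defaults.

    Windows are (lower, upper) days: the empirical mating window (80% of
    females mated within two to three weeks), the range of empirical
    calving T80 point estimates, and the outermost 95% confidence limits
    on those estimates.
    """

    control_label: str = "Control"
    playback_label: str = "Playback"
    p_coverage: float = 0.8
    n_perm: int = 50_000
    n_boot_ci: int = 2000
    n_boot_predict: int = 15_000
    seed: int = 0
    start_filter_days: float = 3.0
    mating_window: tuple[float, float] = (14.0, 21.0)
    calving_window: tuple[float, float] = (19.56, 28.99)
    calving_outer_window: tuple[float, float] = (15.67, 31.70)
    gestation_mean_days: float = field(default_factory=gestation_mean_from_range)
    user_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.p_coverage < 1:
            raise ValueError("p_coverage must lie in (0, 1)")
        for name in ("n_perm", "n_boot_ci", "n_boot_predict"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("mating_window", "calving_window", "calving_outer_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered (lower < upper)")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalysisConfig":
        """Build a config from a flat mapping, recording which keys were set."""
        names = {f.name for f in dataclasses.fields(cls)} - {"user_set"}
        unknown = set(mapping) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
        }
        return cls(**kwargs, user_set=tuple(sorted(mapping)))

    def provenance(self) -> dict[str, str]:
        return {
            f.name: ("user-set" if f.name in self.user_set else "config-default")
            for f in dataclasses.fields(self)
            if f.name != "user_set"
        }

    def stage_seeds(self) -> dict[str, list[int]]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {name: [int(s) for s in child.generate_state(2)]
                for name, child in zip(_STAGES, children)}


def load_config(path) -> AnalysisConfig:
    """Read a flat YAML key-value config file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a flat key-value mapping")
    return AnalysisConfig.from_mapping(data)


def _fit_report(fit, t80, t80_ci) -> dict:
    return {
        "n": fit.n,
        "rate_per_day": fit.params.rate,
        "shift_days": fit.params.shift,
        "shift_clamped": fit.shift_clamped,
        "ci_rate": list(fit.ci_rate),
        "ci_shift": list(fit.ci_shift),
        "ci_level": fit.ci_level,
        "t80_days": t80.width,
        "t80_interval": [t80.lower, t80.upper],
        "t80_ci": list(t80_ci),
    }


def _prediction_report(pred, fractions: dict) -> dict:
    return {
        "n_reps": pred.n_reps,
        "median_days": pred.median,
        "quantiles_days": {
            str(q): float(np.quantile(pred.values, q)) for q in (0.025, 0.25, 0.75, 0.975)
        },
        "n_redrawn": pred.n_redrawn,
        "fractions_within": fractions,
    }


def run_pipeline(
    cycles,
    gestation,
    config: AnalysisConfig | None = None,
    out_dir=None,
) -> dict:
    """Run every analysis stage and return the report dict.

    Parameters
    ----------
    cycles : pandas.DataFrame
        Cycle records (``rutsync.simulate.CYCLE_COLUMNS`` schema).
    gestation : pandas.DataFrame
        Cross-species gestation table (``species, mean_days, sd_days, group``).
    config : AnalysisConfig, optional
    out_dir : path-like, optional
        If given, write ``report.json`` and ``summary.txt`` there.
    """
    config = config or AnalysisConfig()
    seeds = config.stage_seeds()
    report: dict = {
        "config": {
            **{
                f.name: getattr(config, f.name)
                for f in dataclasses.fields(config)
                if f.name != "user_set"
            },
            "provenance": config.provenance(),
            "stage_seeds": seeds,
        }
    }

    t0 = time.perf_counter()
    filtered, n_removed = _stage_filter(cycles, config)
    report["start_filter"] = {
        "threshold_days": config.start_filter_days,
        "n_removed": n_removed,
    }
    log.info("start filter removed %d record(s) [%.2fs]", n_removed, time.perf_counter() - t0)

    datasets = rio.durations_to_datasets(rio.durations_frame(filtered))
    animal_lists = rio.durations_to_animal_lists(rio.durations_frame(filtered))
    for label in (config.control_label, config.playback_label):
        if label not in datasets:
            raise ValueError(f"treatment {label!r} absent from cycle records")

    t0 = time.perf_counter()
    fits, ln_term = {}, float(np.log1p(-config.p_coverage))
    rng_fit = np.random.default_rng(np.random.SeedSequence(seeds["fit_ci"]))
    for label in (config.control_label, config.playback_label):
        fit = bootstrap_fit_ci(
            fit_mvu(datasets[label]), n_boot=config.n_boot_ci, seed=rng_fit
        )
        t80 = t80_shifted_exponential(fit.params, config.p_coverage)
        t80_ci = (-ln_term / fit.ci_rate[1], -ln_term / fit.ci_rate[0])
        fits[label] = (fit, t80)
        report.setdefault("fits", {})[label] = _fit_report(fit, t80, t80_ci)
    report["t80_ratio_control_over_playback"] = (
        fits[config.control_label][1].width / fits[config.playback_label][1].width
    )
    log.info("fits + CIs done [%.2fs]", time.perf_counter() - t0)

    t0 = time.perf_counter()
    perm = permutation_test(
        animal_lists[config.control_label],
        animal_lists[config.playback_label],
        n_perm=config.n_perm,
        seed=np.random.default_rng(np.random.SeedSequence(seeds["permutation"])),
        p=config.p_coverage,
    )
    report["permutation"] = {
        "d_obs_days": perm.d_obs,
        "p_value": perm.p_value,
        "n_perm": perm.n_perm,
        "unit": perm.unit,
        "n_redrawn": perm.n_redrawn,
        "null_quantiles_days": {str(k): v for k, v in perm.null_quantiles.items()},
    }
    log.info("permutation test p=%.4f [%.2fs]", perm.p_value, time.perf_counter() - t0)

    t0 = time.perf_counter()
    rng_mat = np.random.default_rng(np.random.SeedSequence(seeds["mating"]))
    mating = {}
    for label in (config.control_label, config.playback_label):
        pred = predict_mating_t80(
            fits[label][0], n_reps=config.n_boot_predict, p=config.p_coverage, seed=rng_mat
        )
        mating[label] = pred
        frac = fraction_in_range(pred, *config.mating_window)
        report.setdefault("mating_predictions", {})[label] = _prediction_report(
            pred, {"mating_window": frac.fraction_within}
        )
    log.info("mating predictions done [%.2fs]", time.perf_counter() - t0)

    t0 = time.perf_counter()
    scaling = fit_gestation_scaling(gestation)
    sigma = predict_sigma(scaling, target_mean=config.gestation_mean_days)
    report["gestation_scaling"] = {
        "slope": scaling.slope,
        "intercept": scaling.intercept,
        "residual_sd_log2": scaling.residual_sd,
        "n_species": scaling.n_species,
        "excluded_groups": list(scaling.excluded_groups),
    }
    report["sigma_prediction"] = {
        "point_days": sigma.point,
        "log2_scale": sigma.log2_scale,
        "df": sigma.df,
        "target_mean_days": sigma.target_mean,
    }
    log.info("gestation scaling: sigma=%.3f d [%.2fs]", sigma.point, time.perf_counter() - t0)

    t0 = time.perf_counter()
    rng_cal = np.random.default_rng(np.random.SeedSequence(seeds["calving"]))
    for label in (config.control_label, config.playback_label):
        pred = predict_calving_t80(
            fits[label][0], sigma, n_reps=config.n_boot_predict,
            p=config.p_coverage, seed=rng_cal,
        )
        fr_point = fraction_in_range(pred, *config.calving_window)
        fr_outer = fraction_in_range(pred, *config.calving_outer_window)
        report.setdefault("calving_predictions", {})[label] = _prediction_report(
            pred,
            {
                "calving_window": fr_point.fraction_within,
                "calving_outer_window": fr_outer.fraction_within,
            },
        )
    log.info("calving predictions done [%.2fs]", time.perf_counter() - t0)

    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _stage_filter(cycles, config):
    from .simulate import apply_start_filter

    return apply_start_filter(cycles, threshold=config.start_filter_days)


def _summary_lines(report: dict) -> list[str]:
    lines = ["rutsync analysis summary", "========================"]
    for label, f in report["fits"].items():
        lines.append(
            f"{label}: n={f['n']}, rate={f['rate_per_day']:.4f}/d "
            f"(95% CI {f['ci_rate'][0]:.4f}-{f['ci_rate'][1]:.4f}), "
            f"shift={f['shift_days']:.2f} d, T80={f['t80_days']:.2f} d "
            f"(CI {f['t80_ci'][0]:.2f}-{f['t80_ci'][1]:.2f})"
        )
    lines.append(
        f"T80 ratio (Control/Playback): {report['t80_ratio_control_over_playback']:.2f}"
    )
    p = report["permutation"]
    lines.append(f"Permutation test: D_obs={p['d_obs_days']:.2f} d, p={p['p_value']:.4g}")
    for stage in ("mating_predictions", "calving_predictions"):
        for label, pr in report[stage].items():
            fr = ", ".join(f"{k}={100 * v:.2f}%" for k, v in pr["fractions_within"].items())
            lines.append(
                f"{stage.split('_')[0]} {label}: median={pr['median_days']:.2f} d ({fr})"
            )
    return lines


def write_report(report: dict, out_dir) -> Path:
    """Write ``report.json`` (and a text summary) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)
    with open(out / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(_summary_lines(report)) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")
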