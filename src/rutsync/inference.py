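"""Permutation test of equal T80 synchrony between treatment groups.

Null hypothesis: Control and Playback females are equally synchronous, so
the difference ``D = T80_Control - T80_Playback`` is 0; the one-sided
alternative is ``D > 0`` (Controls take longer to reach 80% ovulation).

Group labels are permuted at the ANIMAL level, preserving within-group
sample sizes: periods within an animal are not exchangeable between
groups, whereas whole animals are under the null.  Period-level
permutation (pooling all durations and reshuffling them individually) is
available via ``unit="period"`` for sensitivity analysis.  Within every
permutation the statistic is recomputed exactly as for the observed data:
pool the pseudo-group's durations, fit the shifted exponential by MVU,
take the closed-form T80 width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import MIN_FIT_SIZE, PreOvulatoryDataset, fit_mvu
from .synchrony import t80_shifted_exponential

__all__ = ["PermutationResult", "permutation_test"]


@dataclass(frozen=True)
class PermutationResult:
    """Observed difference, permutation p-value, and null summary."""

    d_obs: float
    p_value: float
    n_perm: int
    seed: int | None
    null_quantiles: dict[float, float]
    n_redrawn: int
    unit: str
    plus_one: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _group_arrays(group) -> list[np.ndarray]:
    arrays = [np.asarray(a, dtype=float).ravel() for a in group]
    if len(arrays) == 0:
        raise ValueError("empty group")
    for a in arrays:
        if a.size < 1:
            raise ValueError("every animal must contribute at least one duration")
        if np.any(a <= 0) or not np.all(np.isfinite(a)):
            raise ValueError("durations must be positive and finite")
    return arrays


def _observed_d(control_pool: np.ndarray, playback_pool: np.ndarray, p: float) -> float:
    wc = t80_shifted_exponential(
        fit_mvu(PreOvulatoryDataset("Control", control_pool)).params, p
    ).width
    wp = t80_shifted_exponential(
        fit_mvu(PreOvulatoryDataset("Playback", playback_pool)).params, p
    ).width
    return float(wc - wp)


def permutation_test(
    control,
    playback,
    n_perm: int = 50_000,
    seed=None,
    p: float = 0.8,
    unit: str = "animal",
    plus_one: bool = False,
    max_redraws: int | None = None,
) -> PermutationResult:
    """One-sided permutation test of ``T80_Control > T80_Playback``.

    Parameters
    ----------
    control, playback : sequence of 1-D arrays
        Per-animal pre-ovulatory durations (days).  With ``unit="period"``
        the animal structure is ignored and individual durations are
        permuted between pools of the observed sizes.
    n_perm : int
        Number of random label permutations (with replacement among the
        possible assignments).
    seed : int | numpy Generator | None
        Randomness source; identical seed and inputs give an identical
        p-value.
    plus_one : bool
        If True use the ``(k+1)/(n_perm+1)`` estimator instead of the raw
        proportion of ``D_perm >= D_obs``.
    max_redraws : int, optional
        Cap on redraws of degenerate permutations (pseudo-group with fewer
        than 3 pooled durations or zero spread); defaults to ``10 * n_perm``.

    Notes
    -----
    With ``p = 0.8`` the statistic in every replicate is the closed-form
    T80 of the MVU fit, which depends on the pooled durations only through
    their minimum, sum and count — permutations are therefore cheap.
    """
    if unit not in ("animal", "period"):
        raise ValueError("unit must be 'animal' or 'period'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ctrl = _group_arrays(control)
    play = _group_arrays(playback)
    if unit == "animal" and (len(ctrl) < 2 or len(play) < 2):
        raise ValueError("need at least 2 animals per group")

    rng = np.random.default_rng(seed)
    log1p5 = float(np.log(1.0 / (1.0 - p)))

    control_pool = np.concatenate(ctrl)
    playback_pool = np.concatenate(play)
    d_obs = _observed_d(control_pool, playback_pool, p)

    if unit == "animal":
        units_ = ctrl + play
        n_ctrl_units = len(ctrl)
        sums = np.array([a.sum() for a in units_])
        mins = np.array([a.min() for a in units_])
        lens = np.array([a.size for a in units_])
    else:
        pooled = np.concatenate([control_pool, playback_pool])
        n_ctrl_units = control_pool.size

    max_redraws = 10 * n_perm if max_redraws is None else max_redraws
    d_perm = np.empty(n_perm)
    n_units = len(ctrl) + len(play) if unit == "animal" else pooled.size
    n_redrawn = 0
    i = 0
    while i < n_perm:
        idx = rng.permutation(n_units)
        ic, ip = idx[:n_ctrl_units], idx[n_ctrl_units:]
        if unit == "animal":
            nc, np_ = int(lens[ic].sum()), int(lens[ip].sum())
            mc, sc = mins[ic].min(), sums[ic].sum()
            mp, sp = mins[ip].min(), sums[ip].sum()
            sc -= nc * mc
            sp -= np_ * mp
        else:
            xc, xp = pooled[ic], pooled[ip]
            nc, np_ = xc.size, xp.size
            sc = float(xc.sum() - nc * xc.min())
            sp = float(xp.sum() - np_ * xp.min())
        if nc < MIN_FIT_SIZE or np_ < MIN_FIT_SIZE or sc <= 0 or sp <= 0:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError("too many degenerate permutations; data too sparse")
            continue
        d_perm[i] = log1p5 * (sc / (nc - 1) - sp / (np_ - 1))
        i += 1

    k = int(np.count_nonzero(d_perm >= d_obs))
    p_value = (k + 1) / (n_perm + 1) if plus_one else k / n_perm
    qs = {q: float(np.quantile(d_perm, q)) for q in (0.025, 0.25, 0.5, 0.75, 0.975)}
    return PermutationResult(
        d_obs=d_obs,
        p_value=float(p_value),
        n_perm=int(n_perm),
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        null_quantiles=qs,
        n_redrawn=n_redrawn,
        unit=unit,
        plus_one=plus_one,
    )
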