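"""Probability laws for ovarian-cycle and calving timing.

The pre-ovulatory period of a female wildebeest is modelled as a constant
follicular phase of ``shift`` days followed by a memoryless waiting time
with per-day hazard ``rate`` — a shifted exponential law.  Calving time is
mating time plus an independent, normally distributed gestation, so calving
times follow a shifted ex-Gaussian law (exponential–normal convolution).

Both laws are small frozen dataclasses exposing ``pdf``/``cdf``/``quantile``
/``sample`` plus moments.  All times are real-valued days; nothing here
rounds or discretises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = ["ShiftedExponential", "ShiftedExGaussian"]

_SQRT2 = float(np.sqrt(2.0))


def _as_float_array(x):
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class ShiftedExponential:
    """Shifted exponential duration law.

    Parameters
    ----------
    rate : float
        Per-day rate at which the stochastic component of the pre-ovulatory
        period ends (the Poisson-process hazard); must be positive.
    shift : float
        Follicular-phase duration in days (location of the support's lower
        edge); must be nonnegative.

    Notes
    -----
    Mean is ``shift + 1/rate`` and standard deviation ``1/rate``.  The
    density is zero strictly below ``shift`` and equals ``rate`` at it.
    """

    rate: float
    shift: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValueError(f"rate must be positive and finite, got {self.rate!r}")
        if not np.isfinite(self.shift) or self.shift < 0:
            raise ValueError(f"shift must be nonnegative and finite, got {self.shift!r}")

    @property
    def mean(self) -> float:
        return self.shift + 1.0 / self.rate

    @property
    def sd(self) -> float:
        return 1.0 / self.rate

    @property
    def var(self) -> float:
        return 1.0 / self.rate**2

    def pdf(self, x):
        """Density in events per day; exactly 0 below the shift."""
        x = _as_float_array(x)
        out = np.where(
            x >= self.shift,
            self.rate * np.exp(-self.rate * np.maximum(x - self.shift, 0.0)),
            0.0,
        )
        return out if out.ndim else float(out)

    def cdf(self, x):
        x = _as_float_array(x)
        out = np.where(
            x >= self.shift,
            -np.expm1(-self.rate * np.maximum(x - self.shift, 0.0)),
            0.0,
        )
        return out if out.ndim else float(out)

    def quantile(self, q):
        """Inverse CDF in days; ``quantile(0)`` is the shift."""
        q = _as_float_array(q)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("quantile probabilities must lie in [0, 1]")
        with np.errstate(divide="ignore"):
            out = self.shift - np.log1p(-q) / self.rate
        return out if out.ndim else float(out)

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Draw ``n`` durations (days) with an explicit seed or Generator."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        return self.shift + rng.exponential(1.0 / self.rate, size=int(n))


@dataclass(frozen=True)
class ShiftedExGaussian:
    """Calving-time law: shifted exponential mating time plus normal gestation.

    Parameters
    ----------
    rate : float
        Per-day hazard of the exponential (mating) component.
    shift : float
        Location offset in days (follicular phase of the mating component).
    gestation_mean, gestation_sd : float
        Mean and standard deviation of the normal gestation component, days.

    Notes
    -----
    The density is the convolution of the shifted exponential and the
    normal density.  In closed form, with ``m = shift + gestation_mean``::

        f(b) = (rate/2) * exp(rate*(rate*sd^2/2 + m - b)) *
               erfc((rate*sd^2 + m - b) / (sqrt(2)*sd))

    Evaluated here through the scaled complementary error function
    ``erfcx`` so that no overflow occurs when ``rate*sd^2`` is large.
    Variance is ``1/rate^2 + gestation_sd^2`` — the location parameters
    only translate the law and have no effect on its spread.
    """

    rate: float
    shift: float
    gestation_mean: float
    gestation_sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValueError(f"rate must be positive and finite, got {self.rate!r}")
        if not np.isfinite(self.shift) or self.shift < 0:
            raise ValueError(f"shift must be nonnegative and finite, got {self.shift!r}")
        if not np.isfinite(self.gestation_mean):
            raise ValueError("gestation_mean must be finite")
        if not np.isfinite(self.gestation_sd) or self.gestation_sd <= 0:
            raise ValueError(
                f"gestation_sd must be positive and finite, got {self.gestation_sd!r}"
            )

    @property
    def location(self) -> float:
        """Total location offset ``shift + gestation_mean`` in days."""
        return self.shift + self.gestation_mean

    @property
    def mean(self) -> float:
        return self.location + 1.0 / self.rate

    @property
    def var(self) -> float:
        return 1.0 / self.rate**2 + self.gestation_sd**2

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.var))

    def pdf(self, b):
        b = _as_float_array(b)
        lam, sd = self.rate, self.gestation_sd
        d = self.location - b  # m - b
        z = (lam * sd * sd + d) / (_SQRT2 * sd)
        # erfcx branch for z >= 0 cancels the exploding exponential exactly:
        # f = lam/2 * erfcx(z) * exp(-(b - m)^2 / (2 sd^2))
        gauss = np.exp(-(d * d) / (2.0 * sd * sd))
        # the direct exponent is only evaluated on its own branch (z < 0,
        # where it is negative); elsewhere it is masked to -inf
        expo = np.where(z < 0.0, lam * d + 0.5 * (lam * sd) ** 2, -np.inf)
        direct = 0.5 * lam * np.exp(expo) * special.erfc(z)
        out = np.where(z >= 0.0, 0.5 * lam * special.erfcx(np.maximum(z, 0.0)) * gauss, direct)
        return out if out.ndim else float(out)

    def cdf(self, b):
        b = _as_float_array(b)
        lam, sd = self.rate, self.gestation_sd
        v = (b - self.location) / sd
        # F(b) = Phi(v) - exp(lam^2 sd^2/2 - lam*(b - m) + log Phi(v - lam*sd))
        expo = 0.5 * (lam * sd) ** 2 - lam * (b - self.location) + special.log_ndtr(v - lam * sd)
        out = np.clip(special.ndtr(v) - np.exp(expo), 0.0, 1.0)
        return out if out.ndim else float(out)

    def quantile(self, q):
        """Inverse CDF by bracketed root-finding (absolute tolerance 1e-8 d)."""
        q = _as_float_array(q)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("quantile probabilities must lie in [0, 1]")
        scalar = q.ndim == 0
        qs = np.atleast_1d(q)
        lo0 = self.location - 15.0 * self.gestation_sd
        out = np.empty_like(qs)
        for i, qi in enumerate(qs):
            if qi == 0.0:
                out[i] = -np.inf
                continue
            if qi == 1.0:
                out[i] = np.inf
                continue
            hi = self.location + 15.0 * self.gestation_sd + (
                -np.log1p(-qi) + 5.0
            ) / self.rate
            out[i] = optimize.brentq(
                lambda b: self.cdf(b) - qi, lo0, hi, xtol=1e-8, rtol=8.9e-16
            )
        return out[0] if scalar else out

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Draw by construction: shifted-exponential draw plus normal draw."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        mating = self.shift + rng.exponential(1.0 / self.rate, size=int(n))
        gestation = rng.normal(self.gestation_mean, self.gestation_sd, size=int(n))
        return mating + gestation
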