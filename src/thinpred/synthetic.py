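"""Synthetic count processes with known stationary moments.

The workhorse ground truth is the Poisson INAR(1) process

    X_t = alpha o X_{t-1} + eps_t,   eps_t ~ Poisson(lam),

where ``alpha o n`` is binomial thinning (each of the ``n`` previous events
survives independently with probability ``alpha``). Its stationary law is
Poisson with mean ``mu = lam / (1 - alpha)`` (so variance = mean) and its
lag-``k`` autocorrelation is ``alpha^k`` — every downstream theory test has
an exact closed-form oracle. INAR is also the natural count-valued
autoregression here: it keeps values integer (required by the binomial
observation model) and is itself built from the same thinning operator.

``generate_high_dispersion`` inflates dispersion by letting events arrive in
bursts of ``k``: multiplying counts by ``k`` scales the variance by ``k^2``
but the mean by ``k``, pushing Var/mean up k-fold into the regime where
external-signal correlation survives sampling.

External signals are linear-plus-noise: ``S_t = a X_t + eps_t`` with Gaussian
noise, giving target correlation ``rho = a sigma_X / sqrt(a^2 sigma_X^2 +
sigma_eps^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .series import CountSeries, RealSeries

__all__ = [
    "INARParams",
    "ExternalSignalParams",
    "generate_inar",
    "generate_poisson",
    "generate_external",
    "generate_high_dispersion",
    "noise_sd_for_correlation",
]


@dataclass(frozen=True)
class INARParams:
    """Poisson INAR(1) parameters.

    ``alpha`` in [0, 1) is the per-event survival probability between steps
    (the autoregressive coefficient); ``lam`` > 0 the Poisson innovation
    rate. Stationary mean ``lam / (1 - alpha)``, lag-k autocorrelation
    ``alpha**k``, Poisson marginal (variance = mean). Burn-in defaults to
    1000 steps with the initial state drawn from the stationary mean to
    shorten transients.
    """

    alpha: float
    lam: float
    length: int
    burn_in: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.lam <= 0:
            raise ValueError(f"innovation rate lam must be > 0, got {self.lam}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")

    @property
    def stationary_mean(self) -> float:
        return self.lam / (1.0 - self.alpha)

    def autocorrelation(self, lag: int) -> float:
        return self.alpha**lag


@dataclass(frozen=True)
class ExternalSignalParams:
    """Linear external-signal parameters: ``S_t = gain * X_t + N(0, noise_sd^2)``."""

    gain: float = 1.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def target_correlation(self, sigma_x: float) -> float:
        denom = math.hypot(self.gain * sigma_x, self.noise_sd)
        if denom == 0.0:
            raise ZeroDivisionError("correlation undefined: gain*sigma_x and noise_sd both zero")
        return self.gain * sigma_x / denom


def noise_sd_for_correlation(sigma_x: float, rho: float, gain: float = 1.0) -> float:
    """Noise level giving target correlation ``rho`` between S and X.

    Inverts ``rho = gain sigma_X / sqrt(gain^2 sigma_X^2 + sigma_eps^2)``.
    """
    if not (0.0 < rho <= 1.0):
        raise ValueError(f"target correlation must lie in (0, 1], got {rho}")
    return abs(gain) * sigma_x * math.sqrt(1.0 / rho**2 - 1.0)


def generate_inar(params: INARParams) -> CountSeries:
    """Simulate a Poisson INAR(1) path (burn-in discarded, seeded)."""
    rng = np.random.default_rng(params.seed)
    total = params.burn_in + params.length
    innovations = rng.poisson(params.lam, size=total)
    x = int(rng.poisson(params.stationary_mean))
    out = np.empty(total, dtype=np.int64)
    alpha = params.alpha
    for t in range(total):
        x = int(rng.binomial(x, alpha)) + int(innovations[t]) if alpha > 0 else int(innovations[t])
        out[t] = x
    return CountSeries(
        out[params.burn_in :],
        label=f"inar(alpha={params.alpha},lam={params.lam})",
    )


def generate_poisson(lam: float, length: int, seed: int | None = None) -> CountSeries:
    """iid Poisson(lam) counts — the memoryless baseline process."""
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return CountSeries(rng.poisson(lam, size=length), label=f"poisson(lam={lam})")


def generate_external(x: CountSeries, params: ExternalSignalParams) -> RealSeries:
    """External signal correlated with ``x``: ``S_t = gain X_t + noise``."""
    v = x.values.astype(np.float64)
    if params.gain != 0.0 and params.noise_sd == 0.0 and np.all(v == v[0]):
        raise ValueError("degenerate external signal: constant x with gain != 0 and no noise")
    rng = np.random.default_rng(params.seed)
    s = params.gain * v + rng.normal(0.0, params.noise_sd, size=v.size)
    return RealSeries(s, label=f"external({x.label})")


def generate_high_dispersion(x_base: CountSeries, scale: int) -> CountSeries:
    """Events arriving in bursts of ``scale``: counts multiplied by ``scale``.

    Variance scales by ``scale**2`` and the mean by ``scale``, so the
    dispersion ratio Var/mean is inflated ``scale``-fold while values stay
    integer counts.
    """
    if scale < 1:
        raise ValueError(f"scale must be a positive integer, got {scale}")
    return x_base.with_values(
        x_base.values * int(scale), label=f"{x_base.label}*k={scale}"
    )
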