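"""Stochastic partial observation of a count process.

The observation model: each event in the ground-truth series ``X`` is seen
independently with probability ``p`` (the sampling rate), so the observed
count at time ``t`` is a binomial thinning draw

    Y_t ~ Binomial(X_t, p),   E[Y_t] = p E[X_t].

This is the standard under-reporting model for surveillance counts and
rate-limited event streams (e.g. a platform exposing a fixed fraction of
posts). ``p = 0`` and ``p = 1`` bypass the RNG so the degenerate cases are
bit-exact.

Replicate ensembles use ``numpy`` seed-sequence spawning: replicate ``r``
draws from an independent substream derived deterministically from the
ensemble seed, so enlarging an ensemble never perturbs earlier replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import CountSeries

__all__ = ["SamplingConfig", "binomial_sample", "sample_ensemble"]


@dataclass(frozen=True)
class SamplingConfig:
    """Sampling rate, seed, and ensemble size for the observation process."""

    rate: float
    seed: int | None = None
    n_reps: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError(f"sampling rate must lie in [0, 1], got {self.rate}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")


def _thin(values: np.ndarray, rate: float, rng: np.random.Generator | None) -> np.ndarray:
    if rate == 1.0:
        return values.copy()
    if rate == 0.0:
        return np.zeros_like(values)
    assert rng is not None
    return rng.binomial(values, rate)


def binomial_sample(x: CountSeries, config: SamplingConfig) -> CountSeries:
    """Draw one observed series ``Y`` with ``Y_t ~ Binomial(X_t, p)``.

    Deterministic given ``config.seed``; ``Y_t <= X_t`` elementwise always.
    """
    rng = None if config.rate in (0.0, 1.0) else np.random.default_rng(config.seed)
    y = _thin(x.values, config.rate, rng)
    return x.with_values(y, label=f"{x.label}|p={config.rate}")


def sample_ensemble(x: CountSeries, config: SamplingConfig) -> list[CountSeries]:
    """Draw ``config.n_reps`` independent observed series.

    Replicate streams are spawned from a single seed sequence, so the
    ensemble is jointly reproducible and each replicate is independent.
    """
    if config.rate in (0.0, 1.0):
        return [binomial_sample(x, config) for _ in range(config.n_reps)]
    children = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    out = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        y = _thin(x.values, config.rate, rng)
        out.append(x.with_values(y, label=f"{x.label}|p={config.rate}|rep={r}"))
    return out
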