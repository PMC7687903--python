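"""Closed-form moments of a binomially thinned count series.

For a stationary ground truth ``X`` with mean ``E[X]``, variance ``Var(X)``
and lagged covariances ``Cov(X_i, X_{i+k})``, thinning at rate ``p`` gives

    Var(Y)            = p^2 Var(X) + p(1-p) E[X]          (diagonal)
    Cov(Y_i, Y_{i+k}) = p^2 Cov(X_i, X_{i+k})             (off-diagonal)
    rho_Y(k)          = p^2 Cov / (p^2 Var(X) + p(1-p) E[X])
    Cov(Y, S)         = p Cov(X, S)                        (external signal S)

The extra ``p(1-p) E[X]`` term is the binomial observation noise; it is what
makes the sampled autocorrelation decay. Dividing through by ``p^2`` shows
``|rho_Y(k)| = |Cov| / (Var(X) + (1/p - 1) E[X])`` is strictly increasing in
``p`` whenever ``E[X] > 0`` — predictability is monotone in the sampling rate.

Because the observation noise scales with the mean while the signal variance
scales with ``p^2``, the external-signal *correlation*

    rho_{Y,S} = p Cov(X,S) / (sigma_Y sigma_S)

is nearly flat in ``p`` when ``Var(X) >> E[X]`` (sigma_Y ~ p sigma_X, the two
linear factors cancel) but decays for Poisson-like signals where
``Var(X) ~ E[X]``.

These relations are implemented as exact formulas; the approximation error
inherent in their derivation is a property of the derivation, not of this
code, so Monte-Carlo tests compare against the formulas with tolerances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .series import CountSeries

__all__ = [
    "MomentSummary",
    "predicted_variance",
    "predicted_lag_covariance",
    "predicted_autocorrelation",
    "predicted_external_covariance",
    "predicted_std",
    "predicted_external_correlation",
    "estimate_moments",
]


def _check_rate(p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"sampling rate must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class MomentSummary:
    """Stationary moment estimates of a ground-truth count process.

    ``lag_cov`` maps positive lags ``k`` to ``Cov(X_i, X_{i+k})``. For true
    stationary moments Cauchy–Schwarz bounds ``|lag_cov[k]| <= variance``;
    finite-sample estimates with segment-specific means may violate that
    slightly, so it is not enforced here.
    """

    mean: float
    variance: float
    lag_cov: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("mean of a count process must be >= 0")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        for k in self.lag_cov:
            if not (isinstance(k, (int, np.integer)) and k >= 1):
                raise ValueError(f"lags must be positive integers, got {k!r}")

    def autocorrelation(self, lag: int) -> float:
        """Ground-truth autocorrelation Cov(k)/Var at a stored lag."""
        if self.variance == 0:
            raise ZeroDivisionError("autocorrelation undefined for zero variance")
        return self._cov(lag) / self.variance

    def _cov(self, lag: int) -> float:
        try:
            return self.lag_cov[int(lag)]
        except KeyError:
            raise KeyError(f"lag {lag} not present in moment summary") from None


def predicted_variance(m: MomentSummary, p: float) -> float:
    """Variance of the thinned series: ``p^2 Var(X) + p(1-p) E[X]``."""
    _check_rate(p)
    out = p * p * m.variance + p * (1.0 - p) * m.mean
    assert out >= 0.0  # both terms are non-negative for valid inputs
    return out


def predicted_lag_covariance(m: MomentSummary, lag: int, p: float) -> float:
    """Lagged covariance of the thinned series: ``p^2 Cov(X_i, X_{i+lag})``."""
    _check_rate(p)
    return p * p * m._cov(lag)


def predicted_autocorrelation(m: MomentSummary, lag: int, p: float) -> float:
    """Autocorrelation of the thinned series at a stored lag.

    At ``p = 1`` this reduces to the ground-truth autocorrelation; at
    ``p -> 0`` with ``E[X] > 0`` it vanishes (pure observation noise), which
    is returned as the continuous limit 0.
    """
    _check_rate(p)
    cov = m._cov(lag)
    if p == 0.0:
        if m.mean == 0.0:
            raise ZeroDivisionError(
                "sampled autocorrelation undefined at p=0 with zero mean"
            )
        return 0.0
    denom = predicted_variance(m, p)
    if denom <= 0.0:
        raise ZeroDivisionError("sampled variance is zero; autocorrelation undefined")
    return p * p * cov / denom


def predicted_external_covariance(cov_xs: float, p: float) -> float:
    """Covariance with an external signal: ``Cov(Y,S) = p Cov(X,S)``."""
    _check_rate(p)
    return p * cov_xs


def predicted_std(m: MomentSummary, p: float) -> float:
    """Standard deviation of the thinned series.

    Approaches ``p sigma_X`` as ``Var(X)/E[X] -> infinity`` — the
    high-dispersion regime in which external-signal correlation survives
    sampling.
    """
    return math.sqrt(predicted_variance(m, p))


def predicted_external_correlation(
    m: MomentSummary, cov_xs: float, sigma_s: float, p: float
) -> float:
    """Pearson correlation between the thinned series and an external signal.

    ``rho_{Y,S} = p Cov(X,S) / (sigma_Y sigma_S)``. Flat in ``p`` when
    ``Var(X) >> E[X]``; decays toward 0 for Poisson-like ``X``.
    """
    _check_rate(p)
    if sigma_s <= 0.0:
        raise ValueError("external signal standard deviation must be > 0")
    sig_y = predicted_std(m, p)
    if sig_y <= 0.0:
        raise ZeroDivisionError("thinned-series standard deviation is zero")
    return p * cov_xs / (sig_y * sigma_s)


def estimate_moments(
    x: CountSeries | np.ndarray, max_lag: int, *, segment_means: bool = True
) -> MomentSummary:
    """Sample mean, variance and lagged covariances of a count series.

    Stationarity is assumed. ``segment_means=True`` computes the lag-``k``
    covariance from the ``n - k`` overlapping pairs with each segment centred
    on its own mean (consistent with the Pearson autocorrelation in
    :mod:`thinpred.metrics`); ``segment_means=False`` centres both segments
    on the single global mean, the textbook stationary plug-in.
    """
    v = x.values if isinstance(x, CountSeries) else np.asarray(x)
    n = v.size
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if n < max_lag + 2:
        raise ValueError(
            f"series of length {n} too short for max_lag={max_lag} (need >= {max_lag + 2})"
        )
    v = v.astype(np.float64)
    mean = float(v.mean())
    variance = float(v.var(ddof=1))
    lag_cov: dict[int, float] = {}
    for k in range(1, max_lag + 1):
        a, b = v[:-k], v[k:]
        if segment_means:
            cov = float(np.cov(a, b, ddof=1)[0, 1])
        else:
            cov = float(np.sum((a - mean) * (b - mean)) / (a.size - 1))
        lag_cov[k] = cov
    return MomentSummary(mean=mean, variance=variance, lag_cov=lag_cov)
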