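"""Model-free predictability measures.

Three complementary measures of how forecastable a time series is:

* **Lagged Pearson autocorrelation** — linear self-similarity; the quantity
  the thinning theory in :mod:`thinpred.theory` predicts in closed form.
* **Permutation entropy (PE)** — Shannon entropy (in bits) of the
  distribution of ordinal patterns ("motifs") of length ``d`` at delay
  ``tau``. Higher PE means more diverse motifs and a less predictable
  signal. The weighted variant scales each motif's contribution by the
  amplitude variance of its values, emphasising ordinal changes of large
  amplitude over flat noise.
* **Plug-in mutual information** — shared information between two series
  from their empirical joint symbol distribution, capturing nonlinear
  dependence that covariance misses.

Ordinal-pattern ties are broken by stable sort (earlier position wins), the
usual Bandt–Pompe convention for integer-valued data where ties are common;
tie handling materially affects PE of low-count series. ``0 log 0 = 0``
throughout; all entropies are base-2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .series import CountSeries, RealSeries

__all__ = [
    "PEConfig",
    "autocorrelation",
    "best_lag",
    "ordinal_pattern_distribution",
    "permutation_entropy",
    "pe_grid_search",
    "mutual_information",
]

logger = logging.getLogger(__name__)

Normalization = Literal["possible_permutations", "observed_permutations", "none"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, (CountSeries, RealSeries)):
        return np.asarray(x.values, dtype=np.float64)
    return np.asarray(x, dtype=np.float64)


@dataclass(frozen=True)
class PEConfig:
    """Permutation-entropy parameters.

    ``order`` is the motif length ``d >= 2``; ``delay`` the temporal spacing
    ``tau >= 1`` between motif elements. A series needs at least
    ``(d - 1) tau + 1`` points to yield one motif.
    """

    order: int = 3
    delay: int = 1
    weighted: bool = True
    normalization: Normalization = "possible_permutations"

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError(f"order d must be >= 2, got {self.order}")
        if self.delay < 1:
            raise ValueError(f"delay tau must be >= 1, got {self.delay}")
        if self.normalization not in ("possible_permutations", "observed_permutations", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def min_length(self) -> int:
        return (self.order - 1) * self.delay + 1


def autocorrelation(x, lag: int) -> float:
    """Pearson correlation between a series and its ``lag``-shifted self.

    Each overlapping segment is centred on its own mean. A constant segment
    has no autocorrelation: zero variance raises rather than returning NaN.
    """
    v = _as_array(x)
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    if v.size < lag + 2:
        raise ValueError(f"series of length {v.size} too short for lag {lag}")
    a, b = v[:-lag], v[lag:]
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        raise ZeroDivisionError(
            f"autocorrelation undefined at lag {lag}: a segment is constant"
        )
    return float(np.corrcoef(a, b)[0, 1])


def best_lag(x, max_lag: int) -> int:
    """Lag in ``1..max_lag`` with the largest ``|autocorrelation|``.

    The winning lag of the ground truth is frozen and reused for every
    thinned version of the series, so that rate sweeps compare like with
    like. Ties break toward the smallest lag (shortest-memory explanation,
    and deterministic); lags where the autocorrelation is undefined are
    skipped.
    """
    v = _as_array(x)
    if v.size < max_lag + 2:
        raise ValueError(f"series of length {v.size} too short for max_lag {max_lag}")
    best, best_val = None, -1.0
    for lag in range(1, max_lag + 1):
        try:
            val = abs(autocorrelation(v, lag))
        except ZeroDivisionError:
            continue
        # improvements below 1e-12 are rounding noise: treat as a tie and
        # keep the smaller lag (shortest-memory explanation, deterministic)
        if val > best_val + 1e-12:
            best, best_val = lag, val
    if best is None:
        raise ZeroDivisionError("autocorrelation undefined at every candidate lag")
    return best


def _motifs(v: np.ndarray, d: int, tau: int) -> np.ndarray:
    n = v.size - (d - 1) * tau
    idx = np.arange(n)[:, None] + tau * np.arange(d)[None, :]
    return v[idx]


def ordinal_pattern_distribution(x, cfg: PEConfig) -> dict[tuple[int, ...], float]:
    """Probability of each observed ordinal pattern under ``cfg``.

    Weighted mode assigns each motif a weight equal to the population
    variance of its values; probabilities are weight shares.
    """
    v = _as_array(x)
    if v.size < cfg.min_length():
        raise ValueError(
            f"series of length {v.size} yields no motif for d={cfg.order}, tau={cfg.delay}"
        )
    motifs = _motifs(v, cfg.order, cfg.delay)
    # stable argsort: tied values keep temporal order (Bandt-Pompe for ties)
    patterns = np.argsort(motifs, axis=1, kind="stable")
    codes = patterns @ (cfg.order ** np.arange(cfg.order))
    if cfg.weighted:
        weights = motifs.var(axis=1)  # population variance, denominator d
        total = weights.sum()
        if total == 0.0:
            raise ZeroDivisionError(
                "degenerate input: every motif is constant, total weight is zero "
                "so weighted pattern probabilities are undefined"
            )
    else:
        weights = np.ones(motifs.shape[0])
        total = float(motifs.shape[0])
    uniq, inverse = np.unique(codes, return_inverse=True)
    binned = np.bincount(inverse, weights=weights)
    mass = binned / binned.sum()  # normalize by the binned sum: exact P=1 for one pattern
    out: dict[tuple[int, ...], float] = {}
    for code, p in zip(uniq, mass):
        digits = []
        c = int(code)
        for _ in range(cfg.order):
            digits.append(c % cfg.order)
            c //= cfg.order
        out[tuple(digits)] = float(p)
    return out


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]  # 0 log 0 = 0
    return max(0.0, float(-(p * np.log2(p)).sum()))


def permutation_entropy(x, cfg: PEConfig | None = None, **kwargs) -> float:
    """(Weighted, normalized) permutation entropy of a series, in bits.

    ``H = -sum_pi P(pi) log2 P(pi)`` over ordinal patterns ``pi`` of length
    ``d`` at delay ``tau``. Normalization divides by ``log2(d!)`` (possible
    patterns; result in [0, 1]), by ``log2`` of the number of *observed*
    distinct patterns (used inside the parameter grid search, where the
    possible-pattern normalizer would make H decrease in ``d`` mechanically),
    or not at all.

    A series whose motifs realise a single pattern has ``H = 0`` under every
    normalization (``0/0 -> 0`` for the observed normalizer, since the
    unnormalized entropy is itself 0).
    """
    if cfg is None:
        cfg = PEConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a PEConfig or keyword parameters, not both")
    dist = ordinal_pattern_distribution(x, cfg)
    h = _entropy_bits(np.array(list(dist.values())))
    if cfg.normalization == "possible_permutations":
        return h / math.log2(math.factorial(cfg.order))
    if cfg.normalization == "observed_permutations":
        n_obs = len(dist)
        if n_obs <= 1:
            return 0.0
        return h / math.log2(n_obs)
    return h


def pe_grid_search(
    x,
    d_range: range | tuple[int, int] = (2, 5),
    tau_range: range | tuple[int, int] = (1, 7),
    *,
    weighted: bool = True,
) -> tuple[int, int]:
    """Pick the PE parameters ``(d, tau)`` that minimise weighted PE.

    The search scores each feasible grid point with PE normalized by the
    number of *observed* permutations; grid points whose motif length
    exceeds the series are skipped with a warning. The winner is chosen
    once, on the ground truth, and then frozen for every thinned version.
    Ties break toward smallest ``d``, then smallest ``tau``.
    """
    ds = d_range if isinstance(d_range, range) else range(d_range[0], d_range[1] + 1)
    taus = tau_range if isinstance(tau_range, range) else range(tau_range[0], tau_range[1] + 1)
    v = _as_array(x)
    best: tuple[int, int] | None = None
    best_score = math.inf
    for d in ds:
        for tau in taus:
            cfg = PEConfig(order=d, delay=tau, weighted=weighted,
                           normalization="observed_permutations")
            if v.size < cfg.min_length():
                logger.warning(
                    "pe_grid_search: skipping infeasible (d=%d, tau=%d) for length %d",
                    d, tau, v.size,
                )
                continue
            score = permutation_entropy(v, cfg)
            if score < best_score:
                best, best_score = (d, tau), score
    if best is None:
        raise ValueError("no feasible (d, tau) grid point for this series length")
    return best


def _discretize(v: np.ndarray, bins) -> np.ndarray:
    if bins in (None, "none"):
        _, codes = np.unique(v, return_inverse=True)
        return codes
    if not (isinstance(bins, (int, np.integer)) and bins >= 1):
        raise ValueError(f"bins must be a positive integer or 'none', got {bins!r}")
    edges = np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, v, side="right")


def mutual_information(x, y, bins="auto") -> float:
    """Plug-in mutual information ``I = H(X) + H(Y) - H(X,Y)``, in bits.

    ``bins="none"`` treats values as discrete symbols (the right choice for
    integer counts); an integer requests that many equal-frequency
    (quantile) bins per series. The default ``"auto"`` uses discrete
    symbols for count series and ``ceil(sqrt(T))`` quantile bins for
    real-valued ones — a stability compromise for the plug-in estimator at
    typical series lengths.
    """
    vx, vy = _as_array(x), _as_array(y)
    if vx.size != vy.size:
        raise ValueError(f"length mismatch: {vx.size} vs {vy.size}")
    if vx.size < 2:
        raise ValueError("mutual information needs at least 2 observations")

    def auto_bins(orig) -> object:
        if isinstance(orig, CountSeries):
            return "none"
        return max(1, math.ceil(math.sqrt(vx.size)))

    bx = auto_bins(x) if bins == "auto" else bins
    by = auto_bins(y) if bins == "auto" else bins
    cx, cy = _discretize(vx, bx), _discretize(vy, by)
    joint = cx.astype(np.int64) * (cy.max() + 1) + cy
    n = vx.size

    def h(codes: np.ndarray) -> float:
        counts = np.bincount(np.unique(codes, return_inverse=True)[1])
        return _entropy_bits(counts / n)

    mi = h(cx) + h(cy) - h(joint)
    return max(0.0, float(mi))  # clip tiny negative rounding residue
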