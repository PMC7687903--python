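"""Sampling-rate sweep experiments.

Each experiment thins a ground-truth count series at a grid of sampling
rates and measures how a predictability quantity degrades, replicating the
study design behind the theory in :mod:`thinpred.theory`:

* :func:`sampling_sweep` — relative permutation entropy or autocorrelation
  across replicates/windows, summarised as median and inter-quartile range.
  Metric parameters (the PE ``(d, tau)`` or the autocorrelation lag) are
  chosen once on the ground truth and frozen across all rates.
* :func:`theory_vs_empirical` — closed-form sampled autocorrelation against
  its Monte-Carlo estimate, per rate.
* :func:`external_sweep` — covariance ratio, Pearson correlation and mutual
  information with an external signal, per rate.
* :func:`forecast_experiment` — one-step-ahead RMSE of an autoregressive
  predictor fit on thinned data versus a Poisson (train-mean) baseline.
* :func:`conditional_variance_regression` — the heteroskedasticity induced
  by thinning: Var(Y_t | X_t) = p(1-p) X_t, recovered by regressing the
  replicate variance on the ground-truth count.

Every routine takes one seed and derives all replicate streams from it by
seed-sequence spawning, so a top-level seed reproduces every table exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics, theory
from .sampling import SamplingConfig, sample_ensemble
from .series import CountSeries, RealSeries

__all__ = [
    "SweepResult",
    "ForecastResult",
    "random_windows",
    "sampling_sweep",
    "theory_vs_empirical",
    "external_sweep",
    "forecast_experiment",
    "conditional_variance_regression",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepResult:
    """Per-rate distribution of a relative predictability metric.

    The relative metric is the thinned series' value divided by the ground
    truth's value on the same window, so 1.0 means no loss; at ``p = 1`` it
    is exactly 1 for every replicate.
    """

    metric: str
    rates: np.ndarray
    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    params: dict = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not (np.all(self.q25 <= self.median + 1e-12) and np.all(self.median <= self.q75 + 1e-12)):
            raise ValueError("quartiles must satisfy q25 <= median <= q75")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p": self.rates, "median": self.median, "q25": self.q25, "q75": self.q75,
             "metric": self.metric}
        )


@dataclass(frozen=True)
class ForecastResult:
    """Per-rate median one-step RMSE for AR and Poisson-baseline forecasts.

    Both RMSEs are normalized by the test-segment standard deviation so that
    the rate-dependent scale of the thinned series (E[Y] = p E[X]) does not
    masquerade as a change in skill.
    """

    rates: np.ndarray
    ar_rmse: np.ndarray
    baseline_rmse: np.ndarray
    n_train: int
    n_test: int
    n_reps: int
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p": self.rates, "ar_rmse": self.ar_rmse, "baseline_rmse": self.baseline_rmse}
        )


def random_windows(
    x: CountSeries, window_len: int, n_windows: int, seed: int | None = None
) -> list[CountSeries]:
    """Uniformly random fixed-length windows, sampled with replacement."""
    if window_len < 1 or n_windows < 1:
        raise ValueError("window_len and n_windows must be >= 1")
    if window_len > len(x):
        raise ValueError(f"window of {window_len} exceeds series length {len(x)}")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(x) - window_len + 1, size=n_windows)
    return [
        CountSeries(x.values[s : s + window_len], start_index=x.start_index + int(s),
                    label=f"{x.label}[{s}:{s + window_len}]")
        for s in starts
    ]


def _rate_grid(rate_grid) -> np.ndarray:
    grid = np.asarray(list(rate_grid), dtype=np.float64)
    if grid.size == 0 or np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("rate grid must be non-empty with all rates in [0, 1]")
    return np.sort(grid)


def sampling_sweep(
    x: CountSeries,
    rate_grid,
    metric: str,
    n_reps: int = 100,
    window_len: int | None = None,
    seed: int | None = None,
    *,
    max_lag: int = 52,
    pe_weighted: bool = True,
) -> SweepResult:
    """Median/IQR of the relative PE or autocorrelation across a rate grid.

    ``metric`` is ``"pe"`` or ``"acf"``. The PE parameters (grid search) or
    the most-significant autocorrelation lag are determined once on the full
    ground truth and frozen. Each replicate draws one random window of
    ``window_len`` (or uses the full series) and its relative metric is the
    thinned window's value over the ground-truth window's value. Degenerate
    replicates (constant window, zero-weight motifs) are dropped and
    counted; if every replicate at some rate drops, the sweep raises.
    """
    grid = _rate_grid(rate_grid)
    if metric == "pe":
        d, tau = metrics.pe_grid_search(x, weighted=pe_weighted)
        cfg = metrics.PEConfig(order=d, delay=tau, weighted=pe_weighted,
                               normalization="possible_permutations")
        params: dict = {"d": d, "tau": tau, "weighted": pe_weighted}
        measure = lambda v: metrics.permutation_entropy(v, cfg)  # noqa: E731
    elif metric == "acf":
        lag = metrics.best_lag(x, max_lag=min(max_lag, len(x) - 2))
        params = {"lag": lag}
        measure = lambda v: metrics.autocorrelation(v, lag)  # noqa: E731
    else:
        raise ValueError(f"metric must be 'pe' or 'acf', got {metric!r}")

    root = np.random.SeedSequence(seed)
    win_seed, samp_seed = root.spawn(2)
    if window_len is None:
        windows = [x] * n_reps
    else:
        windows = random_windows(x, window_len, n_reps,
                                 seed=int(win_seed.generate_state(1)[0] % 2**31))

    truth: list[float | None] = []
    n_dropped = 0
    for w in windows:
        try:
            truth.append(measure(w))
        except (ZeroDivisionError, ValueError):
            truth.append(None)
            n_dropped += 1
    if all(t is None for t in truth):
        raise ValueError("every ground-truth window is degenerate for this metric")

    med = np.empty(grid.size)
    q25 = np.empty(grid.size)
    q75 = np.empty(grid.size)
    rep_seeds = samp_seed.spawn(n_reps)
    for i, p in enumerate(grid):
        ratios = []
        for r, (w, t) in enumerate(zip(windows, truth)):
            if t is None or t == 0.0:
                continue
            if p == 1.0:
                ratios.append(1.0)  # identity sampling, exact by construction
                continue
            y = sample_ensemble(
                w, SamplingConfig(rate=float(p), seed=int(rep_seeds[r].generate_state(1)[0] % 2**31), n_reps=1)
            )[0]
            try:
                ratios.append(measure(y) / t)
            except (ZeroDivisionError, ValueError):
                n_dropped += 1
        if not ratios:
            raise ValueError(f"all replicates degenerate at rate p={p}")
        arr = np.asarray(ratios)
        med[i], q25[i], q75[i] = np.median(arr), np.quantile(arr, 0.25), np.quantile(arr, 0.75)
    if n_dropped:
        logger.info("sampling_sweep(%s): dropped %d degenerate replicates", metric, n_dropped)
    return SweepResult(metric=metric, rates=grid, median=med, q25=q25, q75=q75,
                       params=params, n_dropped=n_dropped)


def theory_vs_empirical(
    x: CountSeries,
    rate_grid,
    lag: int = 1,
    n_reps: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Closed-form sampled autocorrelation vs Monte-Carlo medians, per rate.

    Returns a frame sorted by ``p`` with columns ``p``, ``predicted_acf``,
    ``empirical_acf`` (median across replicates) and ``difference``.
    """
    grid = _rate_grid(rate_grid)
    m = theory.estimate_moments(x, max_lag=lag)
    rows = []
    root = np.random.SeedSequence(seed)
    for p, child in zip(grid, root.spawn(grid.size)):
        pred = theory.predicted_autocorrelation(m, lag, float(p))
        reps = sample_ensemble(
            x, SamplingConfig(rate=float(p), seed=int(child.generate_state(1)[0] % 2**31),
                              n_reps=n_reps)
        )
        vals = []
        for y in reps:
            try:
                vals.append(metrics.autocorrelation(y, lag))
            except ZeroDivisionError:
                continue
        emp = float(np.median(vals)) if vals else math.nan
        rows.append({"p": float(p), "predicted_acf": pred, "empirical_acf": emp,
                     "difference": emp - pred})
    return pd.DataFrame(rows).sort_values("p", ignore_index=True)


def external_sweep(
    x: CountSeries,
    s: RealSeries,
    rate_grid,
    n_reps: int = 100,
    seed: int | None = None,
    *,
    mi_bins="auto",
) -> pd.DataFrame:
    """Degradation of the external-signal association across sampling rates.

    Per rate: median over replicates of the covariance ratio
    ``Cov(Y,S)/Cov(X,S)``, of the Pearson correlation ``rho_{Y,S}``, and of
    the mutual information ``MI(Y,S)``; plus the theoretical line ``p`` for
    the covariance ratio. If ``Cov(X,S) = 0`` the ratio column is NaN (with
    a warning); correlation and MI are still reported.
    """
    grid = _rate_grid(rate_grid)
    if len(x) != len(s):
        raise ValueError(f"length mismatch: counts {len(x)} vs external {len(s)}")
    xv = x.values.astype(np.float64)
    sv = s.values
    cov_xs = float(np.cov(xv, sv, ddof=1)[0, 1])
    if cov_xs == 0.0:
        logger.warning("external_sweep: Cov(X,S)=0, covariance ratio undefined")
    rho_xs = (
        float(np.corrcoef(xv, sv)[0, 1]) if xv.std() > 0 and sv.std() > 0 else math.nan
    )
    mi_xs = metrics.mutual_information(x, s, bins=mi_bins)

    rows = []
    root = np.random.SeedSequence(seed)
    for p, child in zip(grid, root.spawn(grid.size)):
        if p == 1.0:
            rows.append({"p": 1.0, "cov_ratio": 1.0 if cov_xs != 0.0 else math.nan,
                         "corr": rho_xs, "mi": mi_xs, "theory_cov_ratio": 1.0})
            continue
        reps = sample_ensemble(
            x, SamplingConfig(rate=float(p), seed=int(child.generate_state(1)[0] % 2**31),
                              n_reps=n_reps)
        )
        ratios, corrs, mis = [], [], []
        for y in reps:
            yv = y.values.astype(np.float64)
            cov_ys = float(np.cov(yv, sv, ddof=1)[0, 1])
            if cov_xs != 0.0:
                ratios.append(cov_ys / cov_xs)
            if yv.std() > 0 and sv.std() > 0:
                corrs.append(float(np.corrcoef(yv, sv)[0, 1]))
            mis.append(metrics.mutual_information(y, s, bins=mi_bins))
        rows.append({
            "p": float(p),
            "cov_ratio": float(np.median(ratios)) if ratios else math.nan,
            "corr": float(np.median(corrs)) if corrs else math.nan,
            "mi": float(np.median(mis)),
            "theory_cov_ratio": float(p),
        })
    return pd.DataFrame(rows).sort_values("p", ignore_index=True)


def _ar_coefficients(train: np.ndarray, order: int) -> tuple[float, np.ndarray]:
    """Method-of-moments (Yule-Walker) AR fit; returns (mean, phi)."""
    mu = train.mean()
    c = train - mu
    n = c.size
    acov = np.array([np.dot(c[: n - k], c[k:]) / n for k in range(order + 1)])
    if acov[0] == 0.0:
        raise ZeroDivisionError("constant training segment: AR fit undefined")
    if order == 1:
        phi = np.array([acov[1] / acov[0]])
    else:
        from numpy.linalg import solve

        R = np.array([[acov[abs(i - j)] for j in range(order)] for i in range(order)])
        phi = solve(R, acov[1:])
    return float(mu), phi


def forecast_experiment(
    x: CountSeries,
    rate_grid,
    n_reps: int = 100,
    train_frac: float = 0.8,
    seed: int | None = None,
    *,
    ar_order: int = 1,
) -> ForecastResult:
    """One-step forecast error of an AR predictor vs a Poisson baseline.

    Per rate and replicate: thin the full series, fit an order-``ar_order``
    autoregressive predictor on the training prefix by method of moments
    (for order 1: slope = lag-1 autocorrelation, intercept from the mean),
    and score one-step-ahead RMSE on the test suffix. The Poisson baseline
    predicts the training mean everywhere. Both RMSEs are normalized by the
    test-segment standard deviation. Replicates with a constant training
    prefix are dropped and counted.
    """
    grid = _rate_grid(rate_grid)
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    n = len(x)
    n_train = int(round(n * train_frac))
    n_test = n - n_train
    if n_train < ar_order + 2 or n_test < 2:
        raise ValueError("series too short for the requested train/test split")

    ar_med = np.empty(grid.size)
    base_med = np.empty(grid.size)
    n_dropped = 0
    root = np.random.SeedSequence(seed)
    for i, (p, child) in enumerate(zip(grid, root.spawn(grid.size))):
        reps = sample_ensemble(
            x, SamplingConfig(rate=float(p), seed=int(child.generate_state(1)[0] % 2**31),
                              n_reps=n_reps)
        )
        ar_vals, base_vals = [], []
        for y in reps:
            yv = y.values.astype(np.float64)
            train, test = yv[:n_train], yv[n_train:]
            sd_test = test.std(ddof=1)
            if sd_test == 0.0:
                n_dropped += 1
                continue
            try:
                mu, phi = _ar_coefficients(train, ar_order)
            except ZeroDivisionError:
                n_dropped += 1
                continue
            # one-step predictions on the test suffix from observed history
            hist = yv[n_train - ar_order :]
            preds = np.full(n_test, mu)
            for k in range(ar_order):
                lagged = hist[ar_order - 1 - k : ar_order - 1 - k + n_test]
                preds = preds + phi[k] * (lagged - mu)
            ar_vals.append(float(np.sqrt(np.mean((test - preds) ** 2)) / sd_test))
            base_vals.append(float(np.sqrt(np.mean((test - train.mean()) ** 2)) / sd_test))
        if not ar_vals:
            raise ValueError(f"all forecast replicates degenerate at rate p={p}")
        ar_med[i] = np.median(ar_vals)
        base_med[i] = np.median(base_vals)
    if n_dropped:
        logger.info("forecast_experiment: dropped %d degenerate replicates", n_dropped)
    return ForecastResult(rates=grid, ar_rmse=ar_med, baseline_rmse=base_med,
                          n_train=n_train, n_test=n_test, n_reps=n_reps,
                          n_dropped=n_dropped)


def conditional_variance_regression(
    x: CountSeries, rate: float, n_reps: int = 1000, seed: int | None = None
) -> dict:
    """Recover the thinning heteroskedasticity law Var(Y_t | X_t) = p(1-p) X_t.

    Thin the fixed realization ``x`` ``n_reps`` times, estimate the
    conditional variance of ``Y_t`` across replicates at each ``t``, and
    regress it on ``X_t``. The slope estimates ``p(1-p)``; the conditional
    variance varies with ``t`` whenever ``X`` does — the heteroskedasticity
    that thinning injects into the observed series.
    """
    if not (0.0 < rate < 1.0):
        raise ValueError("rate must lie strictly in (0, 1) for a nontrivial check")
    rng = np.random.default_rng(seed)
    ys = rng.binomial(x.values[None, :], rate, size=(n_reps, len(x)))
    cond_var = ys.var(axis=0, ddof=1)
    xv = x.values.astype(np.float64)
    slope, intercept = np.polyfit(xv, cond_var, 1)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "expected_slope": rate * (1.0 - rate),
        "n_reps": n_reps,
        "conditional_variance": cond_var,
    }
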