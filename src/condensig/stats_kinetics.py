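"""Resampling statistics and dissociation kinetics.

Implements the bootstrap comparison of group medians used for the
translocation-suppression and neighbor-enrichment summaries, the exponential
fit that extracts the adapter dissociation half-life after kinase inhibition,
and a Wilson score interval for fractions.  Routine two-sample tests
(Kolmogorov-Smirnov, t, Wilcoxon) are exposed as thin pass-throughs to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps
from statsmodels.stats.proportion import proportion_confint

LN2 = float(np.log(2.0))


class StatsError(ValueError):
    pass


class FitError(RuntimeError):
    """Raised when a dissociation fit cannot produce a meaningful decay."""


@dataclass
class BootstrapResult:
    """Outcome of a bootstrap median comparison."""

    observed_stat: float
    p_value: float
    quartiles: tuple[float, float, float]
    n_boot: int
    alternative: str
    seed: int | None
    paired: bool = False


@dataclass
class HalfLifeFit:
    """Exponential dissociation fit I(t) = offset + amplitude * 2^(-t / t_half)."""

    rate_k: float
    t_half_min: float
    amplitude: float
    offset: float
    rmse: float
    n_traces: int
    t_half_se_min: float | None = None


def bootstrap_median_test(
    a,
    b,
    n_boot: int = 1000,
    alternative: str = "greater",
    seed: int | None = None,
    paired: bool = False,
) -> BootstrapResult:
    """Bootstrap test for a difference of group medians.

    The statistic is ``median(a) - median(b)``.  Each group is resampled with
    replacement ``n_boot`` times (pairs are resampled jointly when
    ``paired=True``) and the one-sided p-value is the fraction of bootstrap
    statistics falling on the null side of zero, with a ``1/(n_boot+1)``
    continuity correction so p is never exactly 0.  Quartiles of the
    bootstrap distribution of the statistic are reported for error bars.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("both samples must have size >= 2")
    if alternative not in ("greater", "less", "two-sided"):
        raise StatsError(f"unknown alternative {alternative!r}")
    if n_boot < 1:
        raise StatsError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(np.median(a) - np.median(b))
    if paired:
        if a.size != b.size:
            raise StatsError("paired test requires equal sample sizes")
        idx = rng.integers(0, a.size, size=(n_boot, a.size))
        boot = np.median(a[idx], axis=1) - np.median(b[idx], axis=1)
    else:
        ia = rng.integers(0, a.size, size=(n_boot, a.size))
        ib = rng.integers(0, b.size, size=(n_boot, b.size))
        boot = np.median(a[ia], axis=1) - np.median(b[ib], axis=1)
    p_greater = (np.count_nonzero(boot <= 0) + 1) / (n_boot + 1)
    p_less = (np.count_nonzero(boot >= 0) + 1) / (n_boot + 1)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    q1, q2, q3 = np.percentile(boot, [25, 50, 75])
    return BootstrapResult(
        observed_stat=observed,
        p_value=float(p),
        quartiles=(float(q1), float(q2), float(q3)),
        n_boot=n_boot,
        alternative=alternative,
        seed=seed,
        paired=paired,
    )


def _decay_model(t, offset, amplitude, rate_k):
    return offset + amplitude * np.exp(-rate_k * t)


def fit_dissociation(
    time_min,
    traces,
    n_boot_se: int = 200,
    seed: int | None = None,
) -> HalfLifeFit:
    """Fit an exponential dissociation to condensate adapter intensity.

    ``traces`` is an (n_traces, n_timepoints) array (or a single 1D trace) of
    normalized condensate intensities; the model
    ``I(t) = offset + amplitude * 2^(-t / t_half)`` is least-squares fitted to
    the mean trace.  The free offset accommodates the residual adapter signal
    in condensates that do not fully dissolve after kinase inhibition.  The
    half-life standard error comes from bootstrap resampling of traces.

    Raises :class:`FitError` for non-decaying or degenerate data.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.atleast_2d(np.asarray(traces, dtype=float))
    if t.size < 4:
        raise StatsError("need at least 4 time points")
    if y.shape[1] != t.size:
        raise StatsError("trace length must match time vector")
    if np.any(y < 0):
        raise StatsError("intensities must be nonnegative")

    def _fit_mean(mean_trace):
        span = float(mean_trace.max() - mean_trace.min())
        if span <= 0:
            raise FitError("constant trace: no decay to fit")
        p0 = (float(mean_trace.min()), span, LN2 / max(t.max() / 3.0, 1e-6))
        popt, _ = optimize.curve_fit(
            _decay_model,
            t,
            mean_trace,
            p0=p0,
            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        return popt

    mean_trace = y.mean(axis=0)
    try:
        offset, amplitude, rate_k = _fit_mean(mean_trace)
    except (RuntimeError, ValueError) as exc:  # curve_fit non-convergence
        raise FitError(f"dissociation fit failed: {exc}") from exc
    resid = mean_trace - _decay_model(t, offset, amplitude, rate_k)
    rmse = float(np.sqrt(np.mean(resid**2)))
    # a genuine decay must stand clear of the residual noise and resolve
    # within (a generous multiple of) the observation window
    if amplitude <= max(3.0 * rmse, 1e-12) or rate_k <= 1e-8:
        raise FitError("no decaying component detected")
    t_half = LN2 / rate_k
    if t_half > 50.0 * t.max():
        raise FitError("decay too slow to be resolved by the observation window")

    se = None
    if y.shape[0] > 1 and n_boot_se > 0:
        rng = np.random.default_rng(seed)
        boot_thalf = []
        for _ in range(n_boot_se):
            idx = rng.integers(0, y.shape[0], size=y.shape[0])
            try:
                _, _, k_b = _fit_mean(y[idx].mean(axis=0))
                boot_thalf.append(LN2 / k_b)
            except (FitError, RuntimeError, ValueError):
                continue
        if len(boot_thalf) >= 2:
            se = float(np.std(boot_thalf, ddof=1))
    return HalfLifeFit(
        rate_k=float(rate_k),
        t_half_min=float(t_half),
        amplitude=float(amplitude),
        offset=float(offset),
        rmse=rmse,
        n_traces=int(y.shape[0]),
        t_half_se_min=se,
    )


def fraction_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score 95% (by default) confidence interval for k successes in n."""
    if n <= 0:
        raise StatsError("n must be positive")
    if not 0 <= k <= n:
        raise StatsError("k must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


# -- thin pass-throughs for the routine tests the pipeline reports ----------


def ks_test(a, b):
    """Two-sample Kolmogorov-Smirnov test (scipy pass-through)."""
    return sps.ks_2samp(a, b)


def t_test(a, b, alternative: str = "greater"):
    """Welch two-sample t-test (scipy pass-through)."""
    return sps.ttest_ind(a, b, equal_var=False, alternative=alternative)


def wilcoxon_test(a, b=None, alternative: str = "two-sided"):
    """Wilcoxon signed-rank test (scipy pass-through)."""
    return sps.wilcoxon(a, b, alternative=alternative)
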