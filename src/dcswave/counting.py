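"""Photon counting, intensity-autocorrelation estimation and decay fitting.

The speckle intensity is rescaled so its mean equals the expected photon
number per bin (flux * Tb) and each bin receives an independent Poisson draw,
which injects shot noise. g2 is the linear lagged-product estimator
<x(t) x(t+tau)> / <x>^2 with the full-series mean in the denominator; for
count series the tau = 0 point is excluded (Poisson self-pairing), for
intensity series it is kept. Decay times are obtained by fitting the Siegert
form g2 = 1 + beta exp(-2 tau / tau_c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from ._errors import ConfigurationError, ContractError, FitError
from .speckle import SpeckleSeries


@dataclass
class CountSeries:
    """Poisson photon counts per bin."""

    tb_s: float
    counts: np.ndarray
    nbin_target: float  # expected mean counts per bin, flux * Tb

    @property
    def n_bins(self) -> int:
        return self.counts.size


@dataclass
class G2Curve:
    """Lagged intensity autocorrelation estimate."""

    lags_s: np.ndarray
    values: np.ndarray
    source: str                        # "intensity" | "counts"
    n_pairs: np.ndarray = field(default=None, repr=False)


@dataclass
class FitResult:
    """Siegert-model fit g2 = 1 + beta exp(-2 tau / tau_c)."""

    tau_c_s: float
    beta: float
    resid_norm: float
    n_lags_used: int
    lag_window_s: tuple

    @property
    def gamma(self) -> float:
        """Decay rate 1/tau_c (1/s)."""
        return 1.0 / self.tau_c_s


def to_counts(series: SpeckleSeries, flux: float, rng) -> CountSeries:
    """Poisson photon counts from a speckle intensity series.

    The intensity is normalized so that its mean equals Nbin = flux * Tb,
    then each bin is drawn as Poisson with that bin's value as its mean.
    """
    if not flux > 0:
        raise ConfigurationError("flux must be > 0 photons/s")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    nbin = flux * series.tb_s
    mean = series.intensity.mean()
    if not mean > 0:
        raise ContractError("intensity series has zero mean")
    lam = series.intensity * (nbin / mean)
    return CountSeries(tb_s=series.tb_s, counts=rng.poisson(lam),
                       nbin_target=nbin)


def g2_estimate(series, max_lag: int) -> G2Curve:
    """Linear (non-circular) g2 estimator.

    Intensity sources include tau = 0; count sources start at tau = Tb
    because the tau = 0 product is dominated by the Poisson self-pairing
    term. Lags are multiples of the bin time.
    """
    if isinstance(series, SpeckleSeries):
        x = np.asarray(series.intensity, float)
        source = "intensity"
        lag0 = 0
    elif isinstance(series, CountSeries):
        x = np.asarray(series.counts, float)
        source = "counts"
        lag0 = 1
    else:
        raise ContractError("series must be a SpeckleSeries or CountSeries")
    n = x.size
    if max_lag < lag0 or n < 2 * max_lag:
        raise ContractError("series length must be >= 2 * max_lag")
    mean = x.mean()
    if mean == 0:
        raise ContractError("zero-mean series: g2 estimator undefined")
    lags = np.arange(lag0, max_lag + 1)
    vals = np.empty(lags.size)
    pairs = np.empty(lags.size, np.int64)
    for i, m in enumerate(lags):
        if m == 0:
            vals[i] = np.mean(x * x) / mean ** 2
            pairs[i] = n
        else:
            vals[i] = np.mean(x[:-m] * x[m:]) / mean ** 2
            pairs[i] = n - m
    return G2Curve(lags_s=lags * series.tb_s, values=vals,
                   source=source, n_pairs=pairs)


def average_g2(curves) -> G2Curve:
    """Pointwise mean of replicate g2 curves (shared lag grid required)."""
    curves = list(curves)
    lags = curves[0].lags_s
    for c in curves[1:]:
        if c.lags_s.shape != lags.shape or not np.allclose(c.lags_s, lags):
            raise ContractError("g2 curves must share one lag grid")
    vals = np.mean([c.values for c in curves], axis=0)
    return G2Curve(lags_s=lags.copy(), values=vals, source=curves[0].source,
                   n_pairs=curves[0].n_pairs)


def _fit_window(lags, y, beta0):
    """Lags from the start up to where a 5-point moving average of (g2-1)
    first drops below 0.05 * beta0."""
    if y.size < 5:
        return y.size
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(y, kernel, mode="same")
    below = np.nonzero(smooth < 0.05 * beta0)[0]
    # ignore a dip at the very beginning (noise), require at least 5 lags
    for i in below:
        if i >= 5:
            return i
    return y.size


def fit_tau_c(curve: G2Curve,
              beta_fixed: float | None = None,
              sigma: np.ndarray | None = None) -> FitResult:
    """Fit g2 = 1 + beta exp(-2 tau / tau_c) by nonlinear least squares.

    The fit window runs from the first lag to the point where the smoothed
    (g2 - 1) falls below 5% of a log-linear pre-fit estimate of beta, which
    bounds the bias from the noise floor. Uniform weights by default;
    pass ``sigma`` (e.g. from the analytic noise model) to weight.
    Raises FitError for non-decaying or all-noise curves.
    """
    tau = np.asarray(curve.lags_s, float)
    y = np.asarray(curve.values, float) - 1.0
    pos_idx = np.nonzero(y > 1e-10)[0]
    if pos_idx.size < 5:
        raise FitError("fewer than 5 lags with g2 > 1: nothing to fit")
    # log-linear pre-fit on the leading positive lags
    lead = pos_idx[:max(10, pos_idx.size // 4)]
    slope, intc = np.polyfit(tau[lead], np.log(y[lead]), 1)
    if slope >= 0:
        raise FitError("non-decaying correlation curve")
    beta0 = float(np.exp(intc))
    tau0 = -2.0 / slope
    nwin = _fit_window(tau, y, beta0)
    tt, yy = tau[:nwin], y[:nwin]
    sig = None if sigma is None else np.asarray(sigma, float)[:nwin]
    try:
        if beta_fixed is None:
            popt, _ = curve_fit(lambda t, b, tc: b * np.exp(-2.0 * t / tc),
                                tt, yy, p0=(min(beta0, 1.0), tau0), sigma=sig,
                                bounds=([0.0, 0.0], [1.5, np.inf]), maxfev=10000)
            beta, tau_c = float(popt[0]), float(popt[1])
        else:
            popt, _ = curve_fit(
                lambda t, tc: beta_fixed * np.exp(-2.0 * t / tc),
                tt, yy, p0=(tau0,), sigma=sig,
                bounds=([0.0], [np.inf]), maxfev=10000)
            beta, tau_c = float(beta_fixed), float(popt[0])
    except RuntimeError as err:
        raise FitError(f"decay fit did not converge: {err}") from None
    if not (tau_c > 0 and np.isfinite(tau_c)):
        raise FitError("fit returned a non-positive decay time")
    if tau_c > 50.0 * tt[-1]:
        raise FitError("no resolvable decay within the lag window "
                       f"(tau_c = {tau_c:.3g} s, window ends {tt[-1]:.3g} s)")
    resid = yy - beta * np.exp(-2.0 * tt / tau_c)
    return FitResult(tau_c_s=tau_c, beta=beta,
                     resid_norm=float(np.sqrt(np.mean(resid ** 2))),
                     n_lags_used=int(nwin),
                     lag_window_s=(float(tt[0]), float(tt[-1])))
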