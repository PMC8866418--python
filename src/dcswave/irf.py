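"""Instrument response function (IRF) handling and arrival-time gating.

In time-domain DCS the photon arrival time is the sum of its transit time in
tissue and a random delay drawn from the IRF of the source + detection chain.
The IRF is represented as a normalized density on a time grid with its peak
shifted to t = 0; per-photon delays are drawn by inverse-transform sampling
of the tabulated CDF. A gate (ts, tw) then selects photons whose arrival
falls inside [ts - tw/2, ts + tw/2) — half-open so adjacent gates never
double-count a photon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._errors import ConfigurationError, ContractError, FormatError

_FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM of a Gaussian = this * sigma


@dataclass(frozen=True)
class Gate:
    """Arrival-time gate: delay ``ts`` and width ``tw`` (both ns)."""

    ts: float
    tw: float

    def __post_init__(self):
        if not self.tw > 0:
            raise ConfigurationError("gate width tw must be > 0")

    @property
    def window(self) -> tuple[float, float]:
        return (self.ts - 0.5 * self.tw, self.ts + 0.5 * self.tw)


@dataclass(frozen=True)
class IRFProfile:
    """Normalized IRF density on a time grid (ns), peak at t = 0."""

    time_grid: np.ndarray
    density: np.ndarray
    cdf: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_table(cls, times, intensities) -> "IRFProfile":
        t = np.asarray(times, float)
        y = np.asarray(intensities, float)
        if t.ndim != 1 or y.shape != t.shape or t.size < 3:
            raise FormatError("IRF table must be two equal columns with >= 3 rows")
        if not np.all(np.diff(t) > 0):
            raise FormatError("IRF times must be strictly increasing")
        if np.any(y < 0):
            raise FormatError("IRF intensities must be nonnegative")
        area = np.trapezoid(y, t)
        if not area > 0:
            raise FormatError("IRF profile is identically zero")
        dens = y / area
        t = t - t[np.argmax(dens)]  # global maximum; first occurrence on ties
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * np.diff(t))])
        cdf /= cdf[-1]
        return cls(time_grid=t, density=dens, cdf=cdf)


def load_irf(path) -> IRFProfile:
    """Read a two-column (time ns, intensity a.u.) text table.

    Whitespace- or comma-delimited; lines starting with '#' are ignored.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise FormatError(f"IRF table row has fewer than two columns: {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if len(rows) < 3:
        raise FormatError("IRF table needs at least 3 rows")
    arr = np.array(rows)
    return IRFProfile.from_table(arr[:, 0], arr[:, 1])


def synth_irf(shape: str = "gaussian",
              fwhm: float = 0.31,
              tail_tau: float | None = None,
              grid: np.ndarray | None = None) -> IRFProfile:
    """Synthetic IRF: Gaussian or exponentially modified Gaussian (ns units).

    ``fwhm`` is the target full width at half maximum of the resulting
    profile; for the exgaussian shape the Gaussian core width is solved by
    bisection so that the measured FWHM matches.
    """
    if not fwhm > 0:
        raise ConfigurationError("fwhm must be > 0")
    if shape == "gaussian":
        sigma = fwhm / _FWHM_SIGMA
        if grid is None:
            grid = np.linspace(-8 * sigma, 8 * sigma, 2001)
        dens = np.exp(-0.5 * (grid / sigma) ** 2)
        return IRFProfile.from_table(grid, dens)
    if shape == "exgaussian":
        if tail_tau is None or not tail_tau > 0:
            raise ConfigurationError("exgaussian shape requires tail_tau > 0")

        def build(sigma):
            g = grid
            if g is None:
                g = np.linspace(-8 * sigma, 8 * sigma + 12 * tail_tau, 4001)
            dens = stats.exponnorm.pdf(g, K=tail_tau / sigma, loc=0.0, scale=sigma)
            return IRFProfile.from_table(g, dens)

        lo, hi = 1e-4 * fwhm, fwhm / _FWHM_SIGMA * 1.0001
        if width_at_fraction(build(lo), 0.5) > fwhm:
            raise ConfigurationError(
                "tail_tau too large: exgaussian FWHM exceeds target even for "
                "a vanishing Gaussian core")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if width_at_fraction(build(mid), 0.5) > fwhm:
                hi = mid
            else:
                lo = mid
        return build(0.5 * (lo + hi))
    raise ConfigurationError(f"unknown IRF shape {shape!r}")


def width_at_fraction(irf: IRFProfile, fraction: float) -> float:
    """Width of the region where density >= fraction * peak density (ns).

    Outer crossings are located by linear interpolation between grid nodes.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    t, d = irf.time_grid, irf.density
    thr = fraction * d.max()
    above = d >= thr
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]
    if i0 == 0:
        left = t[0]
    else:
        f = (thr - d[i0 - 1]) / (d[i0] - d[i0 - 1])
        left = t[i0 - 1] + f * (t[i0] - t[i0 - 1])
    if i1 == t.size - 1:
        right = t[-1]
    else:
        f = (d[i1] - thr) / (d[i1] - d[i1 + 1])
        right = t[i1] + f * (t[i1 + 1] - t[i1])
    return right - left


def sample_irf_times(irf: IRFProfile, count: int, rng) -> np.ndarray:
    """Inverse-CDF draws of per-photon IRF delays (ns)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    u = rng.random(int(count))
    return np.interp(u, irf.cdf, irf.time_grid)


def arrival_times(transit: np.ndarray, irf_samples: np.ndarray) -> np.ndarray:
    """Photon arrival times t_a = t_L + t_IRF (ns, elementwise)."""
    transit = np.asarray(transit, float)
    irf_samples = np.asarray(irf_samples, float)
    if transit.shape != irf_samples.shape:
        raise ContractError("transit and irf_samples must have equal lengths")
    return transit + irf_samples


def select_gate(arrivals: np.ndarray, gate: Gate) -> np.ndarray:
    """Indices of photons arriving within [ts - tw/2, ts + tw/2)."""
    lo, hi = gate.window
    arrivals = np.asarray(arrivals, float)
    idx = np.nonzero((arrivals >= lo) & (arrivals < hi))[0]
    if idx.size == 0:
        warnings.warn(f"gate ts={gate.ts} ns, tw={gate.tw} ns selected no photons",
                      stacklevel=2)
    return idx
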