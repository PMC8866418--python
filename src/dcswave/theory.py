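"""Closed-form and quadrature reference models for a homogeneous
semi-infinite medium.

These are the independent predictions the simulator is validated against:
the correlation-diffusion field autocorrelation g1(rho, tau), the
pathlength-resolved decay g1(L, tau) = exp(-2 mu_s' D_B k0^2 L tau), the
detected-photon pathlength density P(L), the coherence-limited Siegert
intercept beta(lc), the gated (time-domain) g2(ts, tau) double quadrature,
and the correlator noise model sigma(tau) for photon counting.

All curves are deterministic; quadratures refine until self-convergent.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._errors import ConfigurationError, ContractError, NumericalError
from .counting import G2Curve
from .irf import Gate, IRFProfile
from .speckle import SpectrumModel
from .transport import SPEED_OF_LIGHT_MM_NS


@dataclass(frozen=True)
class SemiInfiniteParams:
    """Optical/dynamic parameters of the homogeneous semi-infinite medium.

    ``reff`` is the effective boundary reflectivity entering the
    extrapolated-boundary distance of the pathlength distribution,
    zb = 2 D (1 + Reff) / (1 - Reff). The conventional value for a
    tissue-air interface at n = 1.33 is 0.493; use 0 for an index-matched
    absorbing boundary (which is what the transport Monte Carlo implements).
    """

    rho: float                      # mm
    mu_s_prime: float               # 1/mm
    mu_a: float                     # 1/mm
    k0: float                       # 1/mm
    db: float                       # mm^2/s
    refractive_index: float = 1.33
    reff: float = 0.493
    zb_mode: str = "corrected"      # zb of the g1 dipole: "corrected" | "literal"

    def __post_init__(self):
        if not (self.rho > 0 and self.mu_s_prime > 0 and self.mu_a >= 0
                and self.k0 > 0 and self.db >= 0):
            raise ConfigurationError("invalid semi-infinite parameters")

    @property
    def v_mm_ns(self) -> float:
        return SPEED_OF_LIGHT_MM_NS / self.refractive_index

    @property
    def v_mm_s(self) -> float:
        return self.v_mm_ns * 1e9

    @property
    def z0(self) -> float:
        return 1.0 / self.mu_s_prime

    @property
    def D(self) -> float:
        """Diffusion length 1 / [3 (mu_a + mu_s')], mm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    @property
    def zb_diffusion(self) -> float:
        """Extrapolated-boundary distance of P(L), mm."""
        return 2.0 * self.D * (1.0 + self.reff) / (1.0 - self.reff)

    @property
    def zb_g1(self) -> float:
        """zb of the g1 dipole. The printed source form "(5/3) mu_s'" is
        dimensionally inconsistent; "corrected" uses (5/3) / mu_s'."""
        if self.zb_mode == "literal":
            return (5.0 / 3.0) * self.mu_s_prime
        if self.zb_mode == "corrected":
            return (5.0 / 3.0) / self.mu_s_prime
        raise ConfigurationError("zb_mode must be 'corrected' or 'literal'")

    @property
    def zminus_sq(self) -> float:
        return self.z0 ** 2 + self.rho ** 2

    @property
    def zplus_sq(self) -> float:
        return (self.z0 + 2.0 * self.zb_diffusion) ** 2 + self.rho ** 2


def g1_semi_infinite(params: SemiInfiniteParams, tau) -> np.ndarray:
    """Correlation-diffusion g1(rho, tau), normalized to g1(rho, 0) = 1.

    K^2(tau) = 3 mu_a mu_s' + 6 mu_s'^2 k0^2 D_B tau; the dipole is
    exp(-K r1)/r1 - exp(-K r2)/r2 with r1, r2 built from z0 and zb_g1.
    """
    tau = np.asarray(tau, float)
    if np.any(tau < 0):
        raise ContractError("tau must be >= 0")
    r1 = np.sqrt(params.rho ** 2 + params.z0 ** 2)
    r2 = np.sqrt(params.rho ** 2 + (params.z0 + 2.0 * params.zb_g1) ** 2)
    K = np.sqrt(3.0 * params.mu_a * params.mu_s_prime
                + 6.0 * params.mu_s_prime ** 2 * params.k0 ** 2 * params.db * tau)
    K0 = np.sqrt(3.0 * params.mu_a * params.mu_s_prime)
    val = np.exp(-K * r1) / r1 - np.exp(-K * r2) / r2
    norm = np.exp(-K0 * r1) / r1 - np.exp(-K0 * r2) / r2
    return val / norm


def g1_pathlength(L, tau, mu_s_prime: float, db: float, k0: float):
    """Pathlength-resolved field autocorrelation exp(-2 mu_s' D_B k0^2 L tau)."""
    L = np.asarray(L, float)
    tau = np.asarray(tau, float)
    return np.exp(-2.0 * mu_s_prime * db * k0 ** 2 * L * tau)


# -------------------------------------------------------- P(L) machinery

def _pl_kernel(params: SemiInfiniteParams, L: np.ndarray) -> np.ndarray:
    """Unnormalized P(L): L^{-3/2} e^{-mu_a L} [e^{-z-^2/4DL} - e^{-z+^2/4DL}].

    Constant prefactors (v, 4 pi D / v) are absorbed by the normalization.
    """
    L = np.asarray(L, float)
    out = np.zeros_like(L)
    pos = L > 0
    Lp = L[pos]
    D = params.D
    out[pos] = Lp ** -1.5 * np.exp(-params.mu_a * Lp) * (
        np.exp(-params.zminus_sq / (4.0 * D * Lp))
        - np.exp(-params.zplus_sq / (4.0 * D * Lp)))
    return out


@lru_cache(maxsize=32)
def _pl_table(params: SemiInfiniteParams):
    """Normalized P(L), its CDF and the normalization constant on a fine
    log grid (cached per parameter set)."""
    upper = 50.0 / params.mu_a if params.mu_a > 0 else 1e6
    upper = max(upper, 100.0 * params.zminus_sq)
    grid = np.geomspace(1e-3, upper, 16001)
    pdf = _pl_kernel(params, grid)
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    norm = cdf[-1]
    if not norm > 0:
        raise NumericalError("pathlength PDF normalization vanished")
    return grid, pdf / norm, cdf / norm, norm


def pathlength_pdf(params: SemiInfiniteParams, L) -> np.ndarray:
    """Detected-photon pathlength density P(L), normalized to unit integral."""
    _, _, _, norm = _pl_table(params)
    out = _pl_kernel(params, np.atleast_1d(np.asarray(L, float))) / norm
    return out if np.ndim(L) else float(out[0])


def pathlength_cdf(params: SemiInfiniteParams, L) -> np.ndarray:
    """CDF of P(L) by interpolation of the cached cumulative table."""
    grid, _, cdf, _ = _pl_table(params)
    out = np.interp(np.atleast_1d(np.asarray(L, float)), grid, cdf,
                    left=0.0, right=1.0)
    return out if np.ndim(L) else float(out[0])


def _quantile_nodes(grid, cdf, n: int, lo: float = 0.0, hi: float = 1.0):
    """n equal-probability nodes (midpoint quantiles) of a tabulated CDF."""
    q = lo + (hi - lo) * (np.arange(n) + 0.5) / n
    return np.interp(q, cdf, grid)


def beta_of_coherence(params: SemiInfiniteParams,
                      lc: float,
                      envelope: str = "printed",
                      spectrum: SpectrumModel | None = None,
                      tol: float = 1e-4) -> float:
    """Siegert intercept beta = g2(0) - 1 for a partially coherent source.

    Double quadrature of P(L) P(L') env(L - L') at tau = 0, where the
    envelope is either the printed Gaussian-spectrum form
    exp(-16 [(L - L') / (pi lc)]^2) or, with ``envelope='spectrum'``, the
    self-consistent envelope of a discretized spectrum (matching what the
    wave synthesis actually produces). Importance nodes at equal P(L)
    probability are doubled until |delta beta| < tol.
    """
    if not lc > 0:
        raise ConfigurationError("lc must be > 0")
    if envelope == "printed":
        def env(dl):
            return np.exp(-16.0 * (dl / (np.pi * lc)) ** 2)
    elif envelope == "spectrum":
        if spectrum is None:
            raise ContractError("envelope='spectrum' requires a SpectrumModel")
        env = spectrum.coherence_envelope
    else:
        raise ConfigurationError("envelope must be 'printed' or 'spectrum'")
    grid, _, cdf, _ = _pl_table(params)
    prev = None
    n = 256
    while n <= 8192:
        nodes = _quantile_nodes(grid, cdf, n)
        E = env(np.subtract.outer(nodes, nodes).ravel()).reshape(n, n)
        beta = float(E.mean())
        if prev is not None and abs(beta - prev) < tol:
            return beta
        prev = beta
        n *= 2
    raise NumericalError("beta(lc) quadrature did not converge")


def gated_g2_theory(params: SemiInfiniteParams,
                    irf: IRFProfile | None,
                    gate: Gate,
                    tau,
                    lc: float = np.inf,
                    spectrum: SpectrumModel | None = None,
                    envelope: str = "auto",
                    n_nodes: int = 512) -> G2Curve:
    """Gated intensity autocorrelation 1 + double quadrature over the
    effective pathlength distribution P(ts, L) = P(L) W(L).

    W(L) is the probability that a photon of pathlength L arrives in the
    gate: the IRF density integrated over [ts - tw/2 - L/v, ts + tw/2 - L/v]
    (for irf=None, the indicator of L/v inside the gate window). The
    pathlength-resolved decay uses g1(L, tau) and the coherence envelope
    either from ``spectrum`` (self-consistent with the synthesis;
    ``envelope='auto'`` picks this when a spectrum is given) or the printed
    Gaussian form with ``lc``.
    """
    tau = np.atleast_1d(np.asarray(tau, float))
    v = params.v_mm_ns  # mm/ns
    lo, hi = gate.window
    grid, pdf, cdf, _ = _pl_table(params)
    if irf is None:
        w = ((grid >= lo * v) & (grid < hi * v)).astype(float)
    else:
        icdf = np.interp  # CDF of the IRF density evaluated at gate edges
        w = (icdf(hi - grid / v, irf.time_grid, irf.cdf, left=0.0, right=1.0)
             - icdf(lo - grid / v, irf.time_grid, irf.cdf, left=0.0, right=1.0))
    eff = pdf * w
    ecdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (eff[1:] + eff[:-1]) * np.diff(grid))])
    if not ecdf[-1] > 0:
        raise ContractError("gate selects an empty effective pathlength support")
    ecdf /= ecdf[-1]
    nodes = _quantile_nodes(grid, ecdf, n_nodes)
    if envelope == "auto":
        envelope = "spectrum" if spectrum is not None else "printed"
    if envelope == "spectrum":
        if spectrum is None:
            raise ContractError("envelope='spectrum' requires a SpectrumModel")
        E = spectrum.coherence_envelope(
            np.subtract.outer(nodes, nodes).ravel()).reshape(n_nodes, n_nodes)
    elif envelope == "printed":
        if not lc > 0:
            raise ConfigurationError("lc must be > 0")
        dl = np.subtract.outer(nodes, nodes)
        E = np.exp(-16.0 * (dl / (np.pi * lc)) ** 2)
    else:
        raise ConfigurationError("envelope must be 'auto', 'printed' or 'spectrum'")
    k0 = spectrum.k0 if spectrum is not None else params.k0
    vals = np.empty(tau.size)
    for i, t in enumerate(tau):
        g = g1_pathlength(nodes, t, params.mu_s_prime, params.db, k0) / n_nodes
        vals[i] = 1.0 + float(g @ E @ g)
    return G2Curve(lags_s=tau, values=vals, source="intensity")


def sigma_noise_cw(tb_s: float, t_total_s: float, beta: float, gamma: float,
                   mean_counts: float, tau) -> np.ndarray:
    """Analytic std of (g2 - 1) for a linear correlator with photon counting.

    Correlator noise model for an exponential g2 - 1 = beta e^{-2 Gamma tau}
    measured over a window T with bin time Tb and mean counts <n> per bin:

    sigma(tau) = sqrt(Tb/T) * [ beta^2 ((1+e^{-2 G Tb})(1+e^{-2 G tau})
                 + 2 m (1-e^{-2 G Tb}) e^{-2 G tau}) / (1-e^{-2 G Tb})
                 + 2 <n>^-1 beta (1+e^{-2 G tau})
                 + <n>^-2 (1 + beta e^{-G tau}) ]^{1/2},   m = tau / Tb.
    """
    if not (t_total_s > tb_s > 0):
        raise ConfigurationError("need T > Tb > 0")
    if not gamma > 0:
        raise ConfigurationError("Gamma must be > 0")
    if not mean_counts > 0:
        raise ConfigurationError("mean_counts must be > 0")
    tau = np.asarray(tau, float)
    m = tau / tb_s
    e2b = np.exp(-2.0 * gamma * tb_s)
    e2t = np.exp(-2.0 * gamma * tau)
    e1t = np.exp(-gamma * tau)
    term1 = beta ** 2 * ((1.0 + e2b) * (1.0 + e2t)
                         + 2.0 * m * (1.0 - e2b) * e2t) / (1.0 - e2b)
    term2 = 2.0 * beta * (1.0 + e2t) / mean_counts
    term3 = (1.0 + beta * e1t) / mean_counts ** 2
    return np.sqrt(tb_s / t_total_s) * np.sqrt(term1 + term2 + term3)
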