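"""Speckle-intensity synthesis from photon records.

Each detected photon is treated as one partial wave. Its field contribution
for spectral line k_i is

    E_ni(t) = S(k_i) * w_n * exp(i[phi_n + k_i L_n - k_i X_n(t)])

with phi_n a random initial phase, L_n the static optical pathlength, w_n an
absorption amplitude weight, and X_n(t) the Brownian path-difference process
accumulated over the photon's scattering events: at event s the momentum
transfer is q_s = k_i (n_out - n_in)_s and the scatterer displacement is an
isotropic random walk with per-axis increment variance 2 D_B dt, so

    X_n(t) = sum_s (n_out - n_in)_s . dr_s(t),

a Wiener process with variance rate 2 * sum_layers D_B * sum_s |dn_s|^2.
The "aggregated" mode simulates X_n directly as that 1-D Wiener process
(exact in distribution); the "explicit" mode simulates every scatterer's 3-D
walk and projects it. Intensity is an incoherent sum over spectral lines of
the squared modulus of the coherent photon sum (the optical carrier is
dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import json
import numpy as np

from ._errors import ConfigurationError, ContractError
from .transport import PhotonRecordSet


@dataclass(frozen=True)
class SpectrumModel:
    """Discretized Gaussian source spectrum.

    The coherence length lc is defined as the width of the Gaussian envelope
    S(L) = exp(-L^2 / (2 lc^2)); the matching spectral width is
    kc = pi / (2 lc), i.e. kc^2 = pi^2 / (4 lc^2). ``k_lines`` holds the
    discrete wavevectors and ``weights`` the amplitude weights S(k_i); an
    infinite lc collapses to a single line of weight 1.

    ``k0 = 2 pi * medium_index / lambda0``; the default medium_index of 1
    gives the vacuum wavevector.
    """

    lambda0_nm: float
    k0: float                      # 1/mm
    lc: float                      # mm, may be inf
    kc: float                      # 1/mm, 0 for lc = inf
    k_lines: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)

    @property
    def n_lines(self) -> int:
        return len(self.k_lines)

    def coherence_envelope(self, delta_l) -> np.ndarray:
        """|g_spec|^2 between two paths separated by delta_l (mm).

        Computed from the discretized spectrum itself (power weights S^2),
        so simulation and analytic comparisons share one convention:
        env(dL) = |sum_i S_i^2 e^{i k_i dL}|^2 / (sum_i S_i^2)^2.
        """
        dl = np.atleast_1d(np.asarray(delta_l, float))
        p = self.weights ** 2
        ph = np.exp(1j * np.outer(dl, self.k_lines))
        num = np.abs(ph @ p) ** 2
        out = num / p.sum() ** 2
        return out if np.ndim(delta_l) else float(out[0])


def discretize_spectrum(lambda0_nm: float,
                        lc: float = np.inf,
                        n_lines: int = 21,
                        span_sigmas: float = 3.5,
                        medium_index: float = 1.0) -> SpectrumModel:
    """Build a SpectrumModel for a Gaussian source spectrum.

    ``n_lines`` must be odd so the central line sits exactly at k0. With
    ``lc=inf`` the spectrum collapses to that single central line.
    """
    if n_lines < 1 or n_lines % 2 == 0:
        raise ConfigurationError("n_lines must be odd (a central line is required)")
    if not lc > 0:
        raise ConfigurationError("coherence length lc must be > 0 (or inf)")
    lam_mm = lambda0_nm * 1e-6
    k0 = 2.0 * np.pi * medium_index / lam_mm
    if np.isinf(lc):
        return SpectrumModel(lambda0_nm=lambda0_nm, k0=k0, lc=np.inf, kc=0.0,
                             k_lines=np.array([k0]), weights=np.array([1.0]))
    kc = np.pi / (2.0 * lc)
    k = np.linspace(k0 - span_sigmas * kc, k0 + span_sigmas * kc, n_lines)
    w = np.exp(-(k - k0) ** 2 / (2.0 * kc ** 2))
    return SpectrumModel(lambda0_nm=lambda0_nm, k0=k0, lc=lc, kc=kc,
                         k_lines=k, weights=w)


@dataclass(frozen=True)
class DynamicsSpec:
    """Brownian diffusion coefficient per layer (mm^2/s) and a state label."""

    db: tuple
    state: str = "baseline"

    def __post_init__(self):
        if any(d < 0 for d in self.db):
            raise ConfigurationError("db must be >= 0")

    @classmethod
    def from_layers(cls, layers, state: str = "baseline") -> "DynamicsSpec":
        return cls(db=tuple(l.db for l in layers), state=state)

    def activated(self, factor: float = 2.25, layer: int | None = 1) -> "DynamicsSpec":
        """Scaled dynamics: deep-layer activation by default, or homogeneous
        scaling with ``layer=None``."""
        db = list(self.db)
        if layer is None:
            db = [d * factor for d in db]
        else:
            db[layer] *= factor
        return DynamicsSpec(db=tuple(db), state="activated")


@dataclass
class DirectionChanges:
    """Per-photon scattering direction-change statistics.

    ``sum_sq[n, i]`` = sum over photon n's events in layer i of
    |n_out - n_in|^2 = 2 (1 - cos theta). When ``events`` is kept, the
    per-event unit-vector differences are stored for the explicit mode.
    """

    sum_sq: np.ndarray                       # (N, n_layers)
    photon_idx: Optional[np.ndarray] = None  # (M,) event -> photon
    layer_idx: Optional[np.ndarray] = None   # (M,)
    dn: Optional[np.ndarray] = None          # (M, 3)
    dn_sq: Optional[np.ndarray] = None       # (M,)


def draw_direction_changes(records: PhotonRecordSet, rng,
                           keep_events: bool = False) -> DirectionChanges:
    """Sample isotropic scattering direction changes for every recorded event.

    In the local frame n_in = (0, 0, 1) and n_out is uniform on the sphere,
    so |n_out - n_in|^2 = 2 (1 - cos theta) with cos theta ~ U(-1, 1)
    (mean 2, range [0, 4]).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    counts = records.ns
    n, nlay = counts.shape
    m = int(counts.sum())
    cos = rng.uniform(-1.0, 1.0, m)
    dn_sq = 2.0 * (1.0 - cos)
    flat = np.repeat(np.arange(n * nlay), counts.reshape(-1))
    sum_sq = np.bincount(flat, weights=dn_sq, minlength=n * nlay).reshape(n, nlay)
    if not keep_events:
        return DirectionChanges(sum_sq=sum_sq)
    phi = rng.uniform(0.0, 2.0 * np.pi, m)
    sin = np.sqrt(1.0 - cos ** 2)
    dn = np.stack([sin * np.cos(phi), sin * np.sin(phi), cos - 1.0], axis=1)
    return DirectionChanges(sum_sq=sum_sq, photon_idx=flat // nlay,
                            layer_idx=flat % nlay, dn=dn, dn_sq=dn_sq)


@dataclass
class PhaseTrajectorySet:
    """Per-photon static phases and the Brownian path-difference process.

    ``x[n, j]`` is X_n at time-grid node j (mm); ``var_rate[n]`` its variance
    rate 2 * sum_i D_B,i * sum_sq[n, i] (mm^2/s). The phase of line k at time
    t is phi_n + k L_n - k X_n(t).
    """

    phi: np.ndarray
    pathlength: np.ndarray
    var_rate: np.ndarray
    time_grid: np.ndarray
    x: np.ndarray


def _check_uniform(time_grid: np.ndarray) -> float:
    dt = np.diff(time_grid)
    if dt.size == 0:
        return 0.0
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
        raise ContractError("time grid must be uniform")
    return float(dt[0])


def simulate_dynamic_phases(records: PhotonRecordSet,
                            dirchanges: DirectionChanges,
                            dynamics: DynamicsSpec,
                            time_grid: np.ndarray,
                            rng,
                            mode: str = "aggregated") -> PhaseTrajectorySet:
    """Initial phases and Brownian dynamic-phase drivers X_n(t).

    aggregated: X_n is drawn directly as a Wiener process with variance rate
    2 * sum_i D_B,i * sum_s|dn_s|^2 — exact in distribution, since a sum of
    independent Gaussian increments is Gaussian.

    explicit: every scattering event gets its own 3-D random walk (per-axis
    increment variance 2 D_B dt) projected onto its direction change; scales
    as n_events x n_times and is intended for validation at small sizes.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    time_grid = np.asarray(time_grid, float)
    dt = _check_uniform(time_grid)
    n = records.n_detected
    nb = time_grid.size
    db = np.asarray(dynamics.db, float)
    if db.size != records.n_layers:
        raise ContractError("dynamics.db length must equal the layer count")
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    var_rate = 2.0 * (dirchanges.sum_sq @ db)
    if mode == "aggregated":
        x = np.zeros((n, nb))
        if nb > 1:
            incr = rng.standard_normal((n, nb - 1))
            incr *= np.sqrt(var_rate * dt)[:, None]
            np.cumsum(incr, axis=1, out=incr)
            x[:, 1:] = incr
    elif mode == "explicit":
        if dirchanges.dn is None:
            raise ContractError("explicit mode needs draw_direction_changes("
                                "..., keep_events=True)")
        m = dirchanges.dn.shape[0]
        x = np.zeros((n, nb))
        if nb > 1 and m > 0:
            sig = np.sqrt(2.0 * db[dirchanges.layer_idx] * dt)
            # projected displacement of each scatterer is itself a 1-D walk
            # with per-step std sig * |dn| components summed over axes
            incr = rng.standard_normal((m, nb - 1, 3)) * sig[:, None, None]
            proj = np.einsum("mtc,mc->mt", incr, dirchanges.dn)
            np.cumsum(proj, axis=1, out=proj)
            acc = np.zeros((n, nb - 1))
            np.add.at(acc, dirchanges.photon_idx, proj)
            x[:, 1:] = acc
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    return PhaseTrajectorySet(phi=phi, pathlength=records.total_pathlength(),
                              var_rate=var_rate, time_grid=time_grid, x=x)


@dataclass
class SpeckleSeries:
    """Speckle intensity per time bin (arbitrary units)."""

    tb_s: float
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.intensity.size

    @property
    def duration_s(self) -> float:
        return self.tb_s * self.n_bins

    def save(self, path) -> None:
        np.savez(path, tb_s=self.tb_s, intensity=self.intensity,
                 meta=json.dumps(self.meta))

    @classmethod
    def load(cls, path) -> "SpeckleSeries":
        with np.load(path, allow_pickle=False) as z:
            return cls(tb_s=float(z["tb_s"]), intensity=z["intensity"],
                       meta=json.loads(str(z["meta"])))


def synthesize_intensity(records: PhotonRecordSet,
                         phases: PhaseTrajectorySet,
                         spectrum: SpectrumModel,
                         absorption: str = "intensity",
                         chunk: int = 2048) -> SpeckleSeries:
    """Assemble I(t) from phase trajectories.

    ``absorption`` selects the per-photon weight convention: "intensity"
    weights the field by exp(-mu_a L / 2) so photon intensity carries
    exp(-mu_a L), consistent with the pathlength distribution; "field"
    weights the field by exp(-mu_a L) (the literal field-attenuation
    reading, which doubles the absorption exponent in intensity).
    """
    n = records.n_detected
    if n == 0:
        raise ContractError("no photons in gate: cannot synthesize intensity")
    if absorption == "intensity":
        w = records.absorption_weight(intensity=False)
    elif absorption == "field":
        w = records.absorption_weight(intensity=True)
    else:
        raise ConfigurationError(f"unknown absorption convention {absorption!r}")
    nb = phases.time_grid.size
    tb = _check_uniform(phases.time_grid) if nb > 1 else 1.0
    amp = [spectrum.weights[i] * w * np.exp(1j * (phases.phi +
                                                  spectrum.k_lines[i] * phases.pathlength))
           for i in range(spectrum.n_lines)]
    out = np.empty(nb)
    for j0 in range(0, nb, chunk):
        j1 = min(j0 + chunk, nb)
        xs = phases.x[:, j0:j1]
        acc = np.zeros(j1 - j0)
        for i in range(spectrum.n_lines):
            fld = amp[i] @ np.exp(-1j * spectrum.k_lines[i] * xs)
            acc += np.abs(fld) ** 2
        out[j0:j1] = acc
    return SpeckleSeries(tb_s=tb, intensity=out,
                         meta={"n_photons": n, "n_lines": spectrum.n_lines,
                               "absorption": absorption})


def synthesize_speckle(records: PhotonRecordSet,
                       spectrum: SpectrumModel,
                       dynamics: DynamicsSpec,
                       tb_s: float,
                       n_bins: int,
                       rng_directions,
                       rng_phases,
                       rng_brownian,
                       absorption: str = "intensity",
                       chunk: int = 4096) -> SpeckleSeries:
    """Fused fast path: directions + aggregated Brownian phases + intensity.

    Equivalent to draw_direction_changes -> simulate_dynamic_phases
    (aggregated) -> synthesize_intensity, but streams the Brownian process
    through time chunks so memory stays at n_photons x chunk.
    """
    n = records.n_detected
    if n == 0:
        raise ContractError("no photons in gate: cannot synthesize intensity")
    for name, r in (("directions", rng_directions), ("phases", rng_phases),
                    ("brownian", rng_brownian)):
        if isinstance(r, (int, np.integer)):
            raise ContractError(f"rng_{name} must be a numpy Generator")
    dc = draw_direction_changes(records, rng_directions)
    db = np.asarray(dynamics.db, float)
    var_rate = 2.0 * (dc.sum_sq @ db)
    sig = np.sqrt(var_rate * tb_s)
    phi = rng_phases.uniform(0.0, 2.0 * np.pi, n)
    if absorption == "intensity":
        w = records.absorption_weight(intensity=False)
    elif absorption == "field":
        w = records.absorption_weight(intensity=True)
    else:
        raise ConfigurationError(f"unknown absorption convention {absorption!r}")
    L = records.total_pathlength()
    amp = [spectrum.weights[i] * w * np.exp(1j * (phi + spectrum.k_lines[i] * L))
           for i in range(spectrum.n_lines)]
    out = np.empty(n_bins)
    x_off = np.zeros(n)
    first = True
    j = 0
    while j < n_bins:
        c = min(chunk, n_bins - j)
        if first:
            xs = np.empty((n, c))
            xs[:, 0] = 0.0
            if c > 1:
                incr = rng_brownian.standard_normal((n, c - 1)) * sig[:, None]
                np.cumsum(incr, axis=1, out=incr)
                xs[:, 1:] = incr
            first = False
        else:
            xs = rng_brownian.standard_normal((n, c)) * sig[:, None]
            np.cumsum(xs, axis=1, out=xs)
            xs += x_off[:, None]
        x_off = xs[:, -1].copy()
        acc = np.zeros(c)
        for i in range(spectrum.n_lines):
            fld = amp[i] @ np.exp(-1j * spectrum.k_lines[i] * xs)
            acc += np.abs(fld) ** 2
        out[j:j + c] = acc
        j += c
    return SpeckleSeries(tb_s=tb_s, intensity=out,
                         meta={"n_photons": n, "n_lines": spectrum.n_lines,
                               "absorption": absorption,
                               "dynamics": list(dynamics.db),
                               "state": dynamics.state})
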