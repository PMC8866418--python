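"""Photon-migration Monte Carlo in a layered semi-infinite scattering medium.

Transport runs in isotropic mode (g = 0) with the reduced scattering
coefficient used as the scattering coefficient, which in the diffusive regime
is statistically equivalent to anisotropic scattering at the same mu_s'.
Absorption is *not* applied during transport: detected photons carry their
per-layer pathlengths so that absorption enters later as an intensity weight
exp(-sum_i mu_a_i * L_i), keeping one transport run reusable across
absorption settings.

The top surface z = 0 is an index-matched absorbing boundary: a photon is
terminated on its first crossing, and is "detected" if the crossing point
falls inside a disc detector on the surface. The source is a pencil beam
normally incident at the origin.

The kernel uses an inline xoshiro256++ generator and trig-free isotropic
direction sampling; a seeded run is bit-reproducible.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from ._errors import ConfigurationError, ContractError, FormatError
from ._rng import small_seed

SPEED_OF_LIGHT_MM_NS = 300.0  # vacuum, mm/ns


@dataclass(frozen=True)
class TissueLayer:
    """One plane-parallel tissue slab. The last layer of a stack is semi-infinite.

    Parameters
    ----------
    thickness : mm (use ``math.inf`` for the terminal layer)
    mu_s_prime : reduced scattering coefficient, 1/mm
    mu_a : absorption coefficient, 1/mm
    db : effective Brownian diffusion coefficient of the scatterers, mm^2/s
    anisotropy_g : must be 0 (isotropic transport mode only)
    refractive_index : shared across the stack; sets the photon speed c/n
    """

    thickness: float
    mu_s_prime: float
    mu_a: float = 0.01
    db: float = 1e-6
    anisotropy_g: float = 0.0
    refractive_index: float = 1.33


@dataclass(frozen=True)
class DetectionGeometry:
    """Surface disc detector centred at (rho, 0, 0).

    ``detector_size`` is interpreted per ``size_convention``: with the default
    ``"radius"`` a size of 2 mm means a disc of radius 2 mm. The alternative
    ``"diameter"`` reading is exposed because the literature is not consistent
    about what a detector "size" denotes; detected-photon counts scale with
    the disc area, so the choice matters for absolute count comparisons.
    """

    rho: float
    detector_size: float = 2.0
    size_convention: str = "radius"
    detector_shape: str = "disc"

    @property
    def detector_radius(self) -> float:
        if self.size_convention == "radius":
            return self.detector_size
        if self.size_convention == "diameter":
            return 0.5 * self.detector_size
        raise ConfigurationError(
            f"size_convention must be 'radius' or 'diameter', got {self.size_convention!r}")


def validate_layers(layers: Sequence[TissueLayer]) -> None:
    if len(layers) == 0:
        raise ConfigurationError("layer stack is empty")
    if len(layers) > 2:
        raise ConfigurationError("at most two layers are supported")
    n0 = layers[0].refractive_index
    mu_s = layers[0].mu_s_prime
    for i, lay in enumerate(layers):
        if not lay.mu_s_prime > 0:
            raise ConfigurationError(f"layer {i}: mu_s_prime must be > 0")
        if lay.mu_s_prime != mu_s:
            raise ConfigurationError(
                "transport requires equal mu_s_prime across layers")
        if lay.mu_a < 0:
            raise ConfigurationError(f"layer {i}: mu_a must be >= 0")
        if lay.db < 0:
            raise ConfigurationError(f"layer {i}: db must be >= 0")
        if lay.anisotropy_g != 0.0:
            raise ConfigurationError(
                f"layer {i}: only isotropic transport (g = 0) is supported")
        if lay.refractive_index != n0:
            raise ConfigurationError("refractive index must be shared across layers")
        last = i == len(layers) - 1
        if not last and not (0 < lay.thickness < math.inf):
            raise ConfigurationError(f"layer {i}: thickness must be finite and > 0")
        if last and not lay.thickness > 0:
            raise ConfigurationError("terminal layer thickness must be > 0 (or inf)")


def validate_geometry(geometry: DetectionGeometry) -> None:
    if not geometry.rho > 0:
        raise ConfigurationError("rho must be > 0")
    if not geometry.detector_size > 0:
        raise ConfigurationError("detector_size must be > 0")
    if geometry.detector_shape != "disc":
        raise ConfigurationError("only disc detectors are supported")
    geometry.detector_radius  # validates size_convention


@dataclass
class PhotonRecordSet:
    """Per-detected-photon scattering counts and pathlengths, by layer.

    ``ns[n, i]`` is the number of scattering events photon ``n`` underwent in
    layer ``i``; ``pathlengths[n, i]`` its geometric pathlength there (mm);
    ``exit_xy[n]`` the surface exit position (mm).
    """

    ns: np.ndarray                 # (N, n_layers) int64
    pathlengths: np.ndarray        # (N, n_layers) float64, mm
    exit_xy: np.ndarray            # (N, 2) float64, mm
    launched_count: int
    layers: tuple
    geometry: DetectionGeometry
    seed: int = 0
    max_pathlength: float = float("nan")

    @property
    def n_detected(self) -> int:
        return self.ns.shape[0]

    @property
    def n_layers(self) -> int:
        return self.ns.shape[1]

    def total_pathlength(self) -> np.ndarray:
        """Total pathlength L_n per photon, mm."""
        return self.pathlengths.sum(axis=1)

    def total_scatter_count(self) -> np.ndarray:
        return self.ns.sum(axis=1)

    def absorption_weight(self, intensity: bool = True) -> np.ndarray:
        """Per-photon absorption weight exp(-sum_i mu_a_i L_i).

        With ``intensity=False`` returns the square root, i.e. the field
        amplitude weight under the convention that per-photon *intensity*
        carries one factor of exp(-mu_a L).
        """
        mu_a = np.array([lay.mu_a for lay in self.layers])
        expo = self.pathlengths @ mu_a
        return np.exp(-expo) if intensity else np.exp(-0.5 * expo)

    def subset(self, index) -> "PhotonRecordSet":
        """Records restricted to the given photon indices (gating, subsampling)."""
        index = np.asarray(index)
        return PhotonRecordSet(
            ns=self.ns[index], pathlengths=self.pathlengths[index],
            exit_xy=self.exit_xy[index], launched_count=self.launched_count,
            layers=self.layers, geometry=self.geometry, seed=self.seed,
            max_pathlength=self.max_pathlength)

    # ---------------------------------------------------------------- IO
    def to_tsv(self, path) -> None:
        meta = {
            "launched_count": self.launched_count,
            "seed": self.seed,
            "max_pathlength_mm": self.max_pathlength,
            "geometry": {k: getattr(self.geometry, k)
                         for k in self.geometry.__dataclass_fields__},
            "layers": [{k: (None if (isinstance(getattr(l, k), float) and
                                     math.isinf(getattr(l, k))) else getattr(l, k))
                        for k in l.__dataclass_fields__} for l in self.layers],
        }
        nlay = self.n_layers
        cols = {"photon_id": np.arange(self.n_detected)}
        for i in range(nlay):
            cols[f"Ns_{i + 1}"] = self.ns[:, i]
        for i in range(nlay):
            cols[f"L_{i + 1}_mm"] = self.pathlengths[:, i]
        cols["exit_x_mm"] = self.exit_xy[:, 0]
        cols["exit_y_mm"] = self.exit_xy[:, 1]
        df = pd.DataFrame(cols)
        with open(path, "w") as fh:
            fh.write("# dcswave photon records\n")
            fh.write("# meta=" + json.dumps(meta) + "\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "PhotonRecordSet":
        with open(path) as fh:
            text = fh.read()
        meta = None
        body = []
        for line in text.splitlines():
            if line.startswith("# meta="):
                meta = json.loads(line[len("# meta="):])
            elif not line.startswith("#"):
                body.append(line)
        if meta is None:
            raise FormatError("missing '# meta=' header line")
        df = pd.read_csv(io.StringIO("\n".join(body)), sep="\t")
        nlay = len(meta["layers"])
        layers = tuple(
            TissueLayer(**{k: (math.inf if v is None else v) for k, v in d.items()})
            for d in meta["layers"])
        geometry = DetectionGeometry(**meta["geometry"])
        return cls(
            ns=df[[f"Ns_{i + 1}" for i in range(nlay)]].to_numpy(np.int64),
            pathlengths=df[[f"L_{i + 1}_mm" for i in range(nlay)]].to_numpy(float),
            exit_xy=df[["exit_x_mm", "exit_y_mm"]].to_numpy(float),
            launched_count=int(meta["launched_count"]),
            layers=layers, geometry=geometry, seed=int(meta["seed"]),
            max_pathlength=float(meta["max_pathlength_mm"]))


# ------------------------------------------------------------------ kernel

_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _rotl(x, k):
    return np.uint64((x << np.uint64(k)) | (x >> np.uint64(64 - k)))


@njit(cache=True, inline="always")
def _xs_next(s0, s1, s2, s3):
    """xoshiro256++ step: returns a uniform double in [0, 1) and new state."""
    r = _rotl(s0 + s3, 23) + s0
    t = s1 << np.uint64(17)
    s2 ^= s0
    s3 ^= s1
    s1 ^= s2
    s0 ^= s3
    s2 ^= t
    s3 = _rotl(s3, 45)
    return float(r >> np.uint64(11)) * _INV53, s0, s1, s2, s3


@njit(cache=True)
def _xs_seed(seed):
    """splitmix64 expansion of a seed into the 4-word xoshiro state."""
    s = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    st = np.empty(4, np.uint64)
    for i in range(4):
        z = s
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        st[i] = z ^ (z >> np.uint64(31))
        s += np.uint64(0x9E3779B97F4A7C15)
    return st


@njit(cache=True)
def _transport_chunk(n_launch, seed, mu_s, zb1, rho, rdet2, lmax):
    st = _xs_seed(seed)
    s0, s1, s2, s3 = st[0], st[1], st[2], st[3]
    ns1 = np.zeros(n_launch, np.int64)
    ns2 = np.zeros(n_launch, np.int64)
    l1 = np.zeros(n_launch, np.float64)
    l2 = np.zeros(n_launch, np.float64)
    ex = np.empty((n_launch, 2), np.float64)
    m = 0
    for _ in range(n_launch):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        L = 0.0
        ns1[m] = 0
        ns2[m] = 0
        l1[m] = 0.0
        l2[m] = 0.0
        while True:
            u, s0, s1, s2, s3 = _xs_next(s0, s1, s2, s3)
            if u <= 0.0:
                u = _INV53
            step = -math.log(u) / mu_s
            zn = z + uz * step
            if zn < 0.0:
                seg = -z / uz  # distance along the direction to z = 0
                exx = x + ux * seg
                eyy = y + uy * seg
                if z > zb1:  # upward exit segment crosses the interface
                    frac2 = (z - zb1) / z
                    l2[m] += seg * frac2
                    l1[m] += seg * (1.0 - frac2)
                else:
                    l1[m] += seg
                d2 = (exx - rho) * (exx - rho) + eyy * eyy
                if d2 <= rdet2:
                    ex[m, 0] = exx
                    ex[m, 1] = eyy
                    m += 1
                break
            lo = z if z < zn else zn
            hi = z if z > zn else zn
            if hi <= zb1:
                l1[m] += step
            elif lo >= zb1:
                l2[m] += step
            else:
                frac2 = (hi - zb1) / (hi - lo)
                l2[m] += step * frac2
                l1[m] += step * (1.0 - frac2)
            x += ux * step
            y += uy * step
            z = zn
            L += step
            if L > lmax:
                break
            if z < zb1:
                ns1[m] += 1
            else:
                ns2[m] += 1
            # isotropic scattering: uniform cos(theta); azimuth via rejection
            while True:
                a, s0, s1, s2, s3 = _xs_next(s0, s1, s2, s3)
                a = 2.0 * a - 1.0
                b, s0, s1, s2, s3 = _xs_next(s0, s1, s2, s3)
                b = 2.0 * b - 1.0
                rr = a * a + b * b
                if 1e-12 < rr <= 1.0:
                    break
            c, s0, s1, s2, s3 = _xs_next(s0, s1, s2, s3)
            cos = 2.0 * c - 1.0
            sin = math.sqrt(1.0 - cos * cos)
            inv = 1.0 / rr
            ux = sin * (a * a - b * b) * inv
            uy = sin * (2.0 * a * b) * inv
            uz = cos
    return m, ns1, ns2, l1, l2, ex


# ---------------------------------------------------------------- frontend

def simulate_photons(layers: Sequence[TissueLayer],
                     geometry: DetectionGeometry,
                     n_launch: int,
                     seed: int,
                     max_pathlength: float = 2000.0,
                     chunk_size: int = 4_000_000) -> PhotonRecordSet:
    """Run the transport Monte Carlo and return records of detected photons.

    Photons whose accumulated pathlength exceeds ``max_pathlength`` (mm) are
    dropped; at the default 2000 mm their later absorption weight would be
    below exp(-20) for mu_a = 0.01/mm, so the truncation is negligible for
    every weighted statistic.

    Reproducible bit-for-bit for given ``seed`` and ``chunk_size``.
    """
    validate_layers(layers)
    validate_geometry(geometry)
    if n_launch < 0:
        raise ConfigurationError("n_launch must be >= 0")
    layers = tuple(layers)
    nlay = len(layers)
    mu_s = layers[0].mu_s_prime
    zb1 = layers[0].thickness if nlay == 2 else math.inf
    rdet = geometry.detector_radius
    out = []
    done = 0
    chunk_i = 0
    while done < n_launch:
        this = min(chunk_size, n_launch - done)
        cseed = small_seed(seed, "transport", chunk_i)
        m, ns1, ns2, l1, l2, ex = _transport_chunk(
            this, cseed, mu_s, zb1, geometry.rho, rdet * rdet, max_pathlength)
        out.append((ns1[:m].copy(), ns2[:m].copy(),
                    l1[:m].copy(), l2[:m].copy(), ex[:m].copy()))
        done += this
        chunk_i += 1
    if out:
        ns1 = np.concatenate([o[0] for o in out])
        ns2 = np.concatenate([o[1] for o in out])
        l1 = np.concatenate([o[2] for o in out])
        l2 = np.concatenate([o[3] for o in out])
        ex = np.concatenate([o[4] for o in out])
    else:
        ns1 = ns2 = np.zeros(0, np.int64)
        l1 = l2 = np.zeros(0, float)
        ex = np.zeros((0, 2), float)
    if nlay == 2:
        ns = np.stack([ns1, ns2], axis=1)
        lp = np.stack([l1, l2], axis=1)
    else:
        ns = ns1[:, None]
        lp = l1[:, None]
    return PhotonRecordSet(ns=ns, pathlengths=lp, exit_xy=ex,
                           launched_count=n_launch, layers=layers,
                           geometry=geometry, seed=seed,
                           max_pathlength=max_pathlength)


def transit_times(records: PhotonRecordSet,
                  refractive_index: float | None = None) -> np.ndarray:
    """Transit time t_L = L / v per detected photon, in ns (v = c/n)."""
    if refractive_index is None:
        refractive_index = records.layers[0].refractive_index
    if refractive_index < 1:
        raise ContractError("refractive_index must be >= 1")
    v = SPEED_OF_LIGHT_MM_NS / refractive_index
    return records.total_pathlength() / v
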