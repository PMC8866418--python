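"""YAML configuration schema shared by the CLI.

A config file describes a measurement condition in named sections::

    layers:
      - {thickness_mm: 15.0, mu_s_prime: 1.0, mu_a: 0.01, db: 1.0e-6}
      - {thickness_mm: null, mu_s_prime: 1.0, mu_a: 0.01, db: 1.0e-6}
    geometry: {rho_mm: 20.0, detector_size_mm: 2.0, size_convention: radius}
    transport: {n_launch: 1000000, seed: 1, max_pathlength_mm: 2000.0}
    spectrum: {lambda0_nm: 800.0, lc_mm: null, n_lines: 21, medium_index: 1.33}
    irf: {shape: gaussian, fwhm_ns: 0.31}        # or {file: irf.txt} or null
    gate: {ts_ns: 1.5, tw_ns: 0.2}               # optional; absent = CW
    measurement: {tb_s: 1.0e-6, n_bins: 10000, source: intensity, flux: 100000.0}
    replicates: {n_reps: 50, label: cw_rho20, subset: null}
    activation: {factor: 2.25, layer: 2}         # optional; layer null = homogeneous

``null`` thickness or lc mean infinite.
"""

from __future__ import annotations

import math

import yaml

from ._errors import ConfigurationError
from .irf import Gate, IRFProfile, load_irf, synth_irf
from .speckle import DynamicsSpec, SpectrumModel, discretize_spectrum
from .transport import DetectionGeometry, TissueLayer


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("config root must be a mapping")
    return cfg


def _inf(x):
    return math.inf if x is None else float(x)


def build_layers(cfg: dict) -> tuple:
    try:
        items = cfg["layers"]
    except KeyError:
        raise ConfigurationError("config lacks a 'layers' section") from None
    layers = []
    for it in items:
        layers.append(TissueLayer(
            thickness=_inf(it.get("thickness_mm")),
            mu_s_prime=float(it["mu_s_prime"]),
            mu_a=float(it.get("mu_a", 0.01)),
            db=float(it.get("db", 1e-6)),
            refractive_index=float(it.get("refractive_index", 1.33))))
    return tuple(layers)


def build_geometry(cfg: dict) -> DetectionGeometry:
    g = cfg.get("geometry", {})
    return DetectionGeometry(
        rho=float(g.get("rho_mm", 20.0)),
        detector_size=float(g.get("detector_size_mm", 2.0)),
        size_convention=g.get("size_convention", "radius"))


def build_spectrum(cfg: dict) -> SpectrumModel:
    s = cfg.get("spectrum", {})
    return discretize_spectrum(
        lambda0_nm=float(s.get("lambda0_nm", 800.0)),
        lc=_inf(s.get("lc_mm")),
        n_lines=int(s.get("n_lines", 21)),
        span_sigmas=float(s.get("span_sigmas", 3.5)),
        medium_index=float(s.get("medium_index", 1.33)))


def build_gate(cfg: dict) -> Gate | None:
    g = cfg.get("gate")
    if g is None:
        return None
    return Gate(ts=float(g["ts_ns"]), tw=float(g["tw_ns"]))


def build_irf(cfg: dict) -> IRFProfile | None:
    i = cfg.get("irf")
    if i is None:
        return None
    if "file" in i:
        return load_irf(i["file"])
    return synth_irf(shape=i.get("shape", "gaussian"),
                     fwhm=float(i.get("fwhm_ns", 0.31)),
                     tail_tau=i.get("tail_tau_ns"))


def build_dynamics(cfg: dict, layers, activated: bool = False) -> DynamicsSpec:
    dyn = DynamicsSpec.from_layers(layers)
    if not activated:
        return dyn
    act = cfg.get("activation", {"factor": 2.25, "layer": 2})
    layer = act.get("layer", 2)
    return dyn.activated(factor=float(act.get("factor", 2.25)),
                         layer=None if layer is None else int(layer) - 1)
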