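"""Replicate orchestration and performance metrics (SNR, CNR, specificity).

A "condition" is one measurement configuration: shared photon records,
optional arrival-time gate (with or without an IRF), a source spectrum, a
dynamics state, the bin time and measurement window. Replicates are
independent speckle realizations of that condition (fresh initial phases,
direction draws, Brownian paths and, if counting, Poisson draws) which are
each fitted for tau_c.

Replicate substreams are indexed by replicate number only, not by dynamics
state, so baseline/activated ensembles generated from the same master seed
share their randomness. Contrasts of ensemble means are then paired
(common-random-number) estimates, which suppresses the speckle noise in
delta tau_c far below the single-ensemble spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._errors import ConfigurationError, ContractError, FitError
from ._rng import substream
from .counting import FitResult, average_g2, fit_tau_c, g2_estimate, to_counts
from .irf import Gate, IRFProfile, arrival_times, sample_irf_times, select_gate
from .speckle import DynamicsSpec, SpectrumModel, synthesize_speckle
from .transport import PhotonRecordSet, transit_times


@dataclass
class ReplicateEnsemble:
    """Fitted decay times from replicate syntheses of one condition."""

    label: str
    state: str
    tau_cs: np.ndarray
    betas: np.ndarray
    n_failures: int
    master_seed: int
    n_photons: int

    @property
    def n_reps(self) -> int:
        return self.tau_cs.size

    @property
    def failure_rate(self) -> float:
        total = self.n_reps + self.n_failures
        return self.n_failures / total if total else 0.0

    @property
    def tau_c_mean(self) -> float:
        return float(self.tau_cs.mean())

    @property
    def tau_c_std(self) -> float:
        if self.n_reps < 2:
            raise ContractError("std undefined for fewer than 2 replicates")
        return float(self.tau_cs.std(ddof=1))

    @property
    def snr(self) -> float:
        """tau_c mean over its replicate-to-replicate std."""
        return self.tau_c_mean / self.tau_c_std


@dataclass
class PerformanceMetrics:
    """Signal, noise, contrast and depth-specificity summary."""

    label: str
    tau_c_mean_s: float
    tau_c_std_s: float
    snr: float
    contrast_s: Optional[float] = None
    cnr: Optional[float] = None
    specificity: Optional[float] = None


def gate_records(records: PhotonRecordSet,
                 gate: Gate,
                 irf: IRFProfile | None,
                 master_seed: int) -> PhotonRecordSet:
    """Select the photon subset arriving inside the gate.

    Per-photon IRF delays are drawn once (from the 'irf' substream of the
    master seed): the arrival-time assignment is part of the measurement
    configuration, not of the speckle replication.
    """
    transit = transit_times(records)
    if irf is None:
        delays = np.zeros(records.n_detected)
    else:
        delays = sample_irf_times(irf, records.n_detected,
                                  substream(master_seed, "irf"))
    idx = select_gate(arrival_times(transit, delays), gate)
    return records.subset(idx)


def run_replicates(records: PhotonRecordSet,
                   spectrum: SpectrumModel,
                   dynamics: DynamicsSpec,
                   n_reps: int,
                   master_seed: int,
                   tb_s: float = 1e-6,
                   n_bins: int = 10_000,
                   gate: Gate | None = None,
                   irf: IRFProfile | None = None,
                   subset: int | None = None,
                   source: str = "intensity",
                   flux: float | None = None,
                   max_lag: int | None = None,
                   label: str = "condition") -> ReplicateEnsemble:
    """Fit tau_c on ``n_reps`` independent speckle realizations.

    ``subset`` randomly thins the (gated) photon set to at most that many
    photons — statistically a smaller detector — to bound synthesis cost.
    ``source='counts'`` applies Poisson counting at the given flux before
    correlation; the default uses the intensity directly (speckle-noise
    limit). Fit failures are excluded and counted; a failure rate above 20%
    flags the condition as invalid.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    if source not in ("intensity", "counts"):
        raise ConfigurationError("source must be 'intensity' or 'counts'")
    if source == "counts" and flux is None:
        raise ConfigurationError("counts source requires a flux")
    if gate is not None:
        records = gate_records(records, gate, irf, master_seed)
    if records.n_detected == 0:
        raise ContractError("no photons in gate: condition is empty")
    if subset is not None and records.n_detected > subset:
        pick = substream(master_seed, "subset").choice(
            records.n_detected, size=subset, replace=False)
        records = records.subset(np.sort(pick))
    if max_lag is None:
        max_lag = n_bins // 8
    tau_cs, betas = [], []
    failures = 0
    for rep in range(n_reps):
        series = synthesize_speckle(
            records, spectrum, dynamics, tb_s, n_bins,
            rng_directions=substream(master_seed, "directions", rep),
            rng_phases=substream(master_seed, "phases", rep),
            rng_brownian=substream(master_seed, "brownian", rep))
        if source == "counts":
            series = to_counts(series, flux,
                               substream(master_seed, "poisson", rep))
        try:
            fit = fit_tau_c(g2_estimate(series, max_lag))
        except FitError:
            failures += 1
            continue
        tau_cs.append(fit.tau_c_s)
        betas.append(fit.beta)
    ens = ReplicateEnsemble(label=label, state=dynamics.state,
                            tau_cs=np.array(tau_cs), betas=np.array(betas),
                            n_failures=failures, master_seed=master_seed,
                            n_photons=records.n_detected)
    if ens.failure_rate > 0.20:
        warnings.warn(f"condition {label!r}: fit failure rate "
                      f"{ens.failure_rate:.0%} exceeds 20%; flagged invalid",
                      stacklevel=2)
    return ens


def compute_contrast(baseline: ReplicateEnsemble,
                     activated: ReplicateEnsemble) -> float:
    """Activation contrast delta tau_c = tau_c(baseline) - tau_c(activated).

    Positive when activation (faster dynamics) speeds up the decay.
    """
    if baseline.label != activated.label:
        raise ContractError("contrast requires matched conditions "
                            f"({baseline.label!r} vs {activated.label!r})")
    if baseline.state == activated.state:
        raise ContractError("contrast requires different dynamics states")
    return baseline.tau_c_mean - activated.tau_c_mean


def compute_cnr(baseline: ReplicateEnsemble,
                activated: ReplicateEnsemble) -> float:
    """Contrast-to-noise ratio: delta tau_c over the baseline replicate std."""
    return compute_contrast(baseline, activated) / baseline.tau_c_std


def compute_specificity(layer_contrast: float,
                        homogeneous_contrast: float) -> float:
    """Depth specificity: deep-layer contrast over homogeneous contrast."""
    if homogeneous_contrast == 0:
        raise ContractError("homogeneous contrast is zero")
    return layer_contrast / homogeneous_contrast


@dataclass
class ShotNoiseResult:
    """Shot-noise component of std(tau_c) via averaged Poisson redraws.

    For each of ``n_outer`` fresh speckle series, ``n_avg`` independent
    Poisson count draws of the same intensity are correlated, their g2
    curves averaged and fitted once (tau_c_avg). Two scalings of
    std(tau_c_avg) to a single-draw shot std are reported: the literal
    multiplication by n_avg, and a variance-consistent one,
    var_shot = n_avg * (var(tau_c_avg) - var_speckle), which treats the
    averaged-curve variance as var_speckle + var_shot / n_avg.
    """

    tau_c_avg: np.ndarray
    tau_c_intensity: np.ndarray
    n_avg: int
    std_shot_literal: float
    std_shot_variance: float
    std_speckle: float


def shot_noise_decomposition(records: PhotonRecordSet,
                             spectrum: SpectrumModel,
                             dynamics: DynamicsSpec,
                             flux: float,
                             n_avg: int,
                             n_outer: int,
                             master_seed: int,
                             tb_s: float = 1e-6,
                             n_bins: int = 10_000,
                             max_lag: int | None = None) -> ShotNoiseResult:
    if n_avg < 1 or n_outer < 2:
        raise ConfigurationError("need n_avg >= 1 and n_outer >= 2")
    if max_lag is None:
        max_lag = n_bins // 8
    tau_avg, tau_int = [], []
    for outer in range(n_outer):
        series = synthesize_speckle(
            records, spectrum, dynamics, tb_s, n_bins,
            rng_directions=substream(master_seed, "directions", outer),
            rng_phases=substream(master_seed, "phases", outer),
            rng_brownian=substream(master_seed, "brownian", outer))
        try:
            tau_int.append(fit_tau_c(g2_estimate(series, max_lag)).tau_c_s)
        except FitError:
            tau_int.append(np.nan)
        curves = []
        for k in range(n_avg):
            counts = to_counts(series, flux,
                               substream(master_seed, "poisson",
                                         outer * n_avg + k))
            curves.append(g2_estimate(counts, max_lag))
        try:
            tau_avg.append(fit_tau_c(average_g2(curves)).tau_c_s)
        except FitError:
            tau_avg.append(np.nan)
    tau_avg = np.array(tau_avg)
    tau_int = np.array(tau_int)
    ok = np.isfinite(tau_int)
    var_speckle = float(np.var(tau_int[ok], ddof=1)) if ok.sum() >= 2 else np.nan
    oka = np.isfinite(tau_avg)
    if oka.sum() < 2:
        raise FitError("too few successful averaged-curve fits")
    std_avg = float(np.std(tau_avg[oka], ddof=1))
    var_shot = n_avg * max(std_avg ** 2 - var_speckle, 0.0) \
        if np.isfinite(var_speckle) else np.nan
    return ShotNoiseResult(
        tau_c_avg=tau_avg, tau_c_intensity=tau_int, n_avg=n_avg,
        std_shot_literal=n_avg * std_avg,
        std_shot_variance=float(np.sqrt(var_shot)),
        std_speckle=float(np.sqrt(var_speckle)))


def flux_for_condition(n_detected: int,
                       n_detected_reference: int,
                       reference_flux: float = 100_000.0) -> float:
    """Photon flux scaled by detected (or gated) counts relative to the
    reference condition (CW at the reference separation)."""
    if n_detected_reference <= 0:
        raise ContractError("reference condition detected no photons")
    if n_detected <= 0:
        raise ContractError("condition detected no photons")
    return reference_flux * n_detected / n_detected_reference


def summarize(baseline: ReplicateEnsemble,
              activated: ReplicateEnsemble | None = None,
              homogeneous: ReplicateEnsemble | None = None) -> PerformanceMetrics:
    """Assemble the metric set for one condition."""
    contrast = cnr = spec = None
    if activated is not None:
        contrast = compute_contrast(baseline, activated)
        cnr = compute_cnr(baseline, activated)
        if homogeneous is not None:
            spec = compute_specificity(
                contrast, compute_contrast(baseline, homogeneous))
    return PerformanceMetrics(
        label=baseline.label, tau_c_mean_s=baseline.tau_c_mean,
        tau_c_std_s=baseline.tau_c_std, snr=baseline.snr,
        contrast_s=contrast, cnr=cnr, specificity=spec)
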