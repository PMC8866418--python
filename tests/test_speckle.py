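import math

import numpy as np
import pytest
from scipy import stats

import dcswave as dw
from dcswave._errors import ConfigurationError, ContractError


def make_records(n_photons, mean_ns=100, seed=0, pathlength=300.0):
    """Hand-built record set for synthesis tests (no transport needed)."""
    rng = np.random.default_rng(seed)
    ns = np.stack([rng.poisson(mean_ns, n_photons) + 1,
                   rng.poisson(mean_ns // 2, n_photons)], axis=1)
    lp = np.stack([np.full(n_photons, 0.7 * pathlength),
                   np.full(n_photons, 0.3 * pathlength)], axis=1)
    lp *= rng.uniform(0.8, 1.2, n_photons)[:, None]
    layers = (dw.TissueLayer(15.0, 1.0, mu_a=0.01, db=1e-6),
              dw.TissueLayer(math.inf, 1.0, mu_a=0.01, db=1e-6))
    return dw.PhotonRecordSet(
        ns=ns, pathlengths=lp, exit_xy=np.zeros((n_photons, 2)),
        launched_count=n_photons, layers=layers,
        geometry=dw.DetectionGeometry(rho=20.0), seed=seed)


# ------------------------------------------------------------- spectrum

def test_spectrum_infinite_coherence_single_line():
    s = dw.discretize_spectrum(800.0)
    assert s.n_lines == 1
    assert s.weights[0] == 1.0
    assert s.k0 == pytest.approx(2 * math.pi / 8e-4, rel=1e-12)  # 7853.98/mm
    assert s.k_lines[0] == s.k0


def test_spectrum_width_and_medium_index():
    s = dw.discretize_spectrum(800.0, lc=90.0)
    assert s.kc == pytest.approx(math.pi / 180.0, rel=1e-12)  # 0.017453/mm
    assert s.kc ** 2 == pytest.approx(math.pi ** 2 / (4 * 90.0 ** 2), rel=1e-12)
    m = dw.discretize_spectrum(800.0, lc=90.0, medium_index=1.33)
    assert m.k0 == pytest.approx(1.33 * s.k0, rel=1e-12)
    # central line present, weights in (0, 1]
    assert np.any(np.isclose(m.k_lines, m.k0))
    assert np.all((m.weights > 0) & (m.weights <= 1.0))
    assert m.weights.max() == pytest.approx(1.0)


def test_spectrum_even_lines_rejected():
    with pytest.raises(ConfigurationError):
        dw.discretize_spectrum(800.0, lc=90.0, n_lines=20)


def test_coherence_envelope_limits():
    mono = dw.discretize_spectrum(800.0)
    assert mono.coherence_envelope(123.4) == pytest.approx(1.0)
    s = dw.discretize_spectrum(800.0, lc=50.0)
    dl = np.array([0.0, 10.0, 50.0, 150.0])
    env = s.coherence_envelope(dl)
    assert env[0] == pytest.approx(1.0)
    assert np.all(np.diff(env) < 0)
    # Gaussian spectrum with amplitude weights S(k): envelope
    # ~ exp(-kc^2 dl^2 / 2) for fine discretization
    fine = dw.discretize_spectrum(800.0, lc=50.0, n_lines=101, span_sigmas=5.0)
    expect = np.exp(-fine.kc ** 2 * dl ** 2 / 2.0)
    assert np.allclose(fine.coherence_envelope(dl), expect, atol=5e-3)


# ----------------------------------------------------- direction changes

def test_direction_change_statistics():
    rec = make_records(200, mean_ns=50, seed=1)
    dc = dw.draw_direction_changes(rec, rng=np.random.default_rng(2),
                                   keep_events=True)
    assert dc.dn_sq.min() >= 0.0
    assert dc.dn_sq.max() <= 4.0
    # E[|dn|^2] = 2 for isotropic scattering
    se = dc.dn_sq.std(ddof=1) / math.sqrt(dc.dn_sq.size)
    assert abs(dc.dn_sq.mean() - 2.0) < 3 * se
    # |n_out - n_in|^2 equals the stored squared magnitude
    assert np.allclose((dc.dn ** 2).sum(axis=1), dc.dn_sq)
    # per-photon/layer sums consistent with event lists
    resum = np.zeros_like(dc.sum_sq)
    np.add.at(resum, (dc.photon_idx, dc.layer_idx), dc.dn_sq)
    assert np.allclose(resum, dc.sum_sq)
    # event counts match the scattering records
    counts = np.zeros_like(rec.ns)
    np.add.at(counts, (dc.photon_idx, dc.layer_idx), 1)
    assert np.array_equal(counts, rec.ns)


# ------------------------------------------------------- dynamic phases

def test_wiener_variance_rate():
    rec = make_records(20_000, mean_ns=40, seed=3)
    dyn = dw.DynamicsSpec(db=(1e-6, 2e-6))
    grid = np.arange(0, 5) * 1e-6
    dc = dw.draw_direction_changes(rec, rng=np.random.default_rng(4))
    ph = dw.simulate_dynamic_phases(rec, dc, dyn, grid,
                                    rng=np.random.default_rng(5))
    assert np.all(ph.x[:, 0] == 0.0)
    assert np.all(ph.phi >= 0) and np.all(ph.phi < 2 * math.pi)
    expect = 2.0 * (dc.sum_sq @ np.array(dyn.db))
    assert np.allclose(ph.var_rate, expect)
    # normalized endpoint displacements are standard normal across photons
    z = ph.x[:, -1] / np.sqrt(ph.var_rate * grid[-1])
    assert abs(z.var(ddof=1) - 1.0) < 0.05
    assert abs(z.mean()) < 3.0 / math.sqrt(z.size)


def test_zero_db_freezes_speckle():
    rec = make_records(50, seed=6)
    dyn = dw.DynamicsSpec(db=(0.0, 0.0))
    spec = dw.discretize_spectrum(800.0, medium_index=1.33)
    s = dw.synthesize_speckle(rec, spec, dyn, 1e-6, 200,
                              rng_directions=np.random.default_rng(1),
                              rng_phases=np.random.default_rng(2),
                              rng_brownian=np.random.default_rng(3))
    assert np.allclose(s.intensity, s.intensity[0])


def test_explicit_matches_aggregated_in_distribution():
    """The per-event 3-D walk projection and the direct 1-D Wiener process
    produce indistinguishable increment ensembles (two-sample KS)."""
    rec = make_records(60, mean_ns=30, seed=7)
    dyn = dw.DynamicsSpec(db=(1e-6, 1e-6))
    grid = np.arange(0, 40) * 1e-6
    dc = dw.draw_direction_changes(rec, rng=np.random.default_rng(8),
                                   keep_events=True)
    pe = dw.simulate_dynamic_phases(rec, dc, dyn, grid,
                                    rng=np.random.default_rng(9),
                                    mode="explicit")
    pa = dw.simulate_dynamic_phases(rec, dc, dyn, grid,
                                    rng=np.random.default_rng(10),
                                    mode="aggregated")
    ie = np.diff(pe.x, axis=1)
    ia = np.diff(pa.x, axis=1)
    # per-photon scaling identical => compare pooled normalized increments
    ks = stats.ks_2samp(ie.ravel(), ia.ravel())
    assert ks.pvalue > 0.01
    # variances match photon by photon within sampling error
    ve = ie.var(axis=1, ddof=1)
    va = ia.var(axis=1, ddof=1)
    assert abs(np.log(ve / va).mean()) < 3.0 * math.sqrt(2.0 / ie.shape[1])


def test_explicit_requires_event_vectors():
    rec = make_records(5, seed=11)
    dc = dw.draw_direction_changes(rec, rng=np.random.default_rng(1))
    with pytest.raises(ContractError):
        dw.simulate_dynamic_phases(rec, dc, dw.DynamicsSpec(db=(1e-6, 1e-6)),
                                   np.arange(0, 4) * 1e-6,
                                   rng=np.random.default_rng(2),
                                   mode="explicit")
    with pytest.raises(ContractError):
        dw.simulate_dynamic_phases(rec, dc, dw.DynamicsSpec(db=(1e-6, 1e-6)),
                                   np.array([0.0, 1e-6, 3e-6]),
                                   rng=np.random.default_rng(2))


# ------------------------------------------------------------ intensity

def test_single_photon_intensity_constant():
    rec = make_records(1, seed=12)
    spec = dw.discretize_spectrum(800.0, medium_index=1.33)
    dyn = dw.DynamicsSpec(db=(1e-6, 1e-6))
    grid = np.arange(0, 100) * 1e-6
    dc = dw.draw_direction_changes(rec, rng=np.random.default_rng(1))
    ph = dw.simulate_dynamic_phases(rec, dc, dyn, grid,
                                    rng=np.random.default_rng(2))
    s = dw.synthesize_intensity(rec, ph, spec)
    w = rec.absorption_weight(intensity=False)[0]
    assert np.allclose(s.intensity, w ** 2, rtol=1e-12)


def test_two_photon_interference_bounds():
    rec = make_records(2, seed=13)
    rec.pathlengths[:] = 150.0  # equal weights
    spec = dw.discretize_spectrum(800.0, medium_index=1.33)
    dyn = dw.DynamicsSpec(db=(1e-6, 1e-6))
    grid = np.arange(0, 500) * 1e-6
    dc = dw.draw_direction_changes(rec, rng=np.random.default_rng(1))
    ph = dw.simulate_dynamic_phases(rec, dc, dyn, grid,
                                    rng=np.random.default_rng(2))
    s = dw.synthesize_intensity(rec, ph, spec)
    single = rec.absorption_weight(intensity=False)[0] ** 2
    assert s.intensity.min() >= 0.0
    assert s.intensity.max() <= 4.0 * single + 1e-12
    assert s.intensity.max() > 2.0 * single  # interference actually explored


def test_empty_photon_set_rejected():
    rec = make_records(3, seed=14).subset(np.array([], dtype=int))
    spec = dw.discretize_spectrum(800.0)
    with pytest.raises(ContractError, match="no photons"):
        dw.synthesize_speckle(rec, spec, dw.DynamicsSpec(db=(1e-6, 1e-6)),
                              1e-6, 10,
                              rng_directions=np.random.default_rng(1),
                              rng_phases=np.random.default_rng(2),
                              rng_brownian=np.random.default_rng(3))


def test_fused_path_matches_composed_path():
    """synthesize_speckle is the chunked composition of the three stages."""
    rec = make_records(40, seed=15)
    spec = dw.discretize_spectrum(800.0, lc=200.0, n_lines=5,
                                  medium_index=1.33)
    dyn = dw.DynamicsSpec(db=(1e-6, 1e-6))
    nb = 300
    a = dw.synthesize_speckle(rec, spec, dyn, 1e-6, nb,
                              rng_directions=np.random.default_rng(21),
                              rng_phases=np.random.default_rng(22),
                              rng_brownian=np.random.default_rng(23),
                              chunk=64)
    dc = dw.draw_direction_changes(rec, rng=np.random.default_rng(21))
    ph = dw.simulate_dynamic_phases(rec, dc, dyn, np.arange(nb) * 1e-6,
                                    rng=np.random.default_rng(23))
    ph.phi = np.random.default_rng(22).uniform(0, 2 * math.pi, 40)
    b = dw.synthesize_intensity(rec, ph, spec)
    # same substream draws happen in a different order; compare statistics
    assert a.intensity.shape == b.intensity.shape
    assert a.intensity.mean() == pytest.approx(b.intensity.mean(), rel=0.2)


def test_fully_developed_speckle_exponential():
    """One-time intensity of many-photon speckle is exponentially
    distributed (pooled over independent realizations)."""
    rec = make_records(600, seed=16)
    spec = dw.discretize_spectrum(800.0, medium_index=1.33)
    dyn = dw.DynamicsSpec(db=(1e-6, 1e-6))
    vals = []
    for i in range(400):
        s = dw.synthesize_speckle(rec, spec, dyn, 1e-6, 1,
                                  rng_directions=np.random.default_rng(100 + i),
                                  rng_phases=np.random.default_rng(500 + i),
                                  rng_brownian=np.random.default_rng(900 + i))
        vals.append(s.intensity[0])
    vals = np.asarray(vals)
    ks = stats.kstest(vals / vals.mean(), "expon")
    assert ks.pvalue > 0.01


def test_absorption_conventions():
    rec = make_records(30, seed=17)
    spec = dw.discretize_spectrum(800.0, medium_index=1.33)
    dyn = dw.DynamicsSpec(db=(1e-6, 1e-6))
    kw = dict(rng_directions=np.random.default_rng(1),
              rng_phases=np.random.default_rng(2),
              rng_brownian=np.random.default_rng(3))
    a = dw.synthesize_speckle(rec, spec, dyn, 1e-6, 50, **kw)
    kw = dict(rng_directions=np.random.default_rng(1),
              rng_phases=np.random.default_rng(2),
              rng_brownian=np.random.default_rng(3))
    b = dw.synthesize_speckle(rec, spec, dyn, 1e-6, 50,
                              absorption="field", **kw)
    # literal field weighting attenuates more strongly
    assert b.intensity.mean() < a.intensity.mean()
    with pytest.raises(ConfigurationError):
        dw.synthesize_speckle(rec, spec, dyn, 1e-6, 10,
                              absorption="nope",
                              rng_directions=np.random.default_rng(1),
                              rng_phases=np.random.default_rng(2),
                              rng_brownian=np.random.default_rng(3))


def test_series_roundtrip(tmp_path):
    s = dw.SpeckleSeries(tb_s=1e-6, intensity=np.arange(5.0),
                         meta={"n_photons": 5})
    p = tmp_path / "series.npz"
    s.save(p)
    back = dw.SpeckleSeries.load(p)
    assert back.tb_s == s.tb_s
    assert np.array_equal(back.intensity, s.intensity)
    assert back.meta["n_photons"] == 5
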