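"""Pulse-sequence simulation and 2D processing."""

import numpy as np
import pytest
import scipy.linalg

from exsy_kinetics.errors import DimensionError, GeneratorInstabilityError, ValidationError
from exsy_kinetics.exsy import (
    AcquisitionScheme,
    ProcessingScheme,
    ideal_pulse,
    phase_cycle_axial_suppression,
    process_1d,
    process_2d,
    pulse_superoperator,
    simulate_1d,
    simulate_exsy,
    simulate_exsy_scans,
)
from exsy_kinetics.liouville import BlockDiagonalPropagator, coherence_blocks
from exsy_kinetics.relaxation import RelaxationTheoryConfig
from exsy_kinetics.spin_model import (
    AnomerMixture,
    SpectrometerFrame,
    pauli_operators,
    unvec,
    vec,
)

from conftest import box_volume, geminal_pair, one_spin_system, single_anomer, two_site_assembly


def test_ideal_pulse_identity_and_composition():
    ops = pauli_operators(2)
    rng = np.random.default_rng(1)
    state = rng.standard_normal(32) + 1j * rng.standard_normal(32)
    np.testing.assert_allclose(ideal_pulse(state, "x", 0.0), state, atol=1e-12)
    two_90 = ideal_pulse(ideal_pulse(state, "x", np.pi / 2), "x", np.pi / 2)
    one_180 = ideal_pulse(state, "x", np.pi)
    np.testing.assert_allclose(two_90, one_180, atol=1e-10)
    assert np.linalg.norm(one_180) == pytest.approx(np.linalg.norm(state), rel=1e-12)
    with pytest.raises(ValidationError):
        ideal_pulse(state, "q", np.pi)
    with pytest.raises(DimensionError):
        ideal_pulse(np.ones(7), "x", np.pi)


def test_90x_rotates_z_order_to_minus_y():
    """Convention check against the 2x2 rotation oracle."""
    ops = pauli_operators(1)
    state = ideal_pulse(vec(ops.z[0]).astype(complex), "x", np.pi / 2)
    u = scipy.linalg.expm(-1j * (np.pi / 2) * np.asarray(ops.x[0]))
    oracle = u @ ops.z[0] @ u.conj().T
    np.testing.assert_allclose(unvec(state[:4]), oracle, atol=1e-12)
    np.testing.assert_allclose(oracle, -np.asarray(ops.y[0]), atol=1e-12)


def test_single_spin_diagonal_peak_position_and_sign(frame):
    """One uncoupled spin: a single positive diagonal peak at (delta, delta)."""
    delta = -118.0
    mix = single_anomer(two_site_assembly(delta, delta, 0.0))
    relax = RelaxationTheoryConfig(tau_c_s=1e-9, r2_ext_per_s=20.0)
    acq = AcquisitionScheme(sw1_hz=4000.0, sw2_hz=4000.0, n1=64, n2=128, t_mix_s=0.5)
    proc = ProcessingScheme(zerofill1=256, zerofill2=512)
    spec = process_2d(*simulate_exsy(mix, acq, frame, relax), acq, proc, frame)
    i1, i2 = np.unravel_index(np.argmax(np.abs(spec.values)), spec.shape)
    step1 = abs(spec.axis1_ppm[1] - spec.axis1_ppm[0])
    step2 = abs(spec.axis2_ppm[1] - spec.axis2_ppm[0])
    assert abs(spec.axis1_ppm[i1] - delta) <= step1
    assert abs(spec.axis2_ppm[i2] - delta) <= step2
    assert spec.values[i1, i2] > 0


def test_1d_peak_position_oracle(frame):
    """A decaying single resonance lands on its shift within one grid step."""
    delta = -120.0
    frame0 = SpectrometerFrame(carrier_ppm=-122.0)
    fid = simulate_1d(one_spin_system(delta), frame0, sw_hz=4000.0, n_points=512,
                      relax=RelaxationTheoryConfig(tau_c_s=1e-9, r2_ext_per_s=15.0))
    ppm, spec = process_1d(fid, 4000.0, frame0)
    step = abs(ppm[1] - ppm[0])
    assert abs(ppm[np.argmax(spec)] - delta) <= step


def test_1d_doublet_splitting_oracle(frame):
    """Weakly coupled doublet: line separation equals J within the grid step."""
    j = 250.0
    system = geminal_pair(shifts=(-116.0, -124.0), j_hz=j)
    fid = simulate_1d(system, frame, sw_hz=8000.0, n_points=1024,
                      relax=RelaxationTheoryConfig(tau_c_s=1e-9, r2_ext_per_s=10.0))
    ppm, spec = process_1d(fid, 8000.0, frame, zerofill=4096)
    hz = (ppm - frame.carrier_ppm) * frame.larmor_hz * 1e-6
    # doublet of spin 0: offset +1506 Hz, components split by J
    sel = (hz > 1250) & (hz < 1800)
    sub, subhz = spec[sel], hz[sel]
    local_max = (sub[1:-1] > sub[:-2]) & (sub[1:-1] > sub[2:])
    peaks = np.nonzero(local_max)[0] + 1
    tallest = peaks[np.argsort(sub[peaks])][-2:]
    lo, hi = np.sort(subhz[tallest])
    res = 8000.0 / 4096
    assert abs((hi - lo) - j) <= 2 * res


def test_strong_coupling_outer_lines_vanish(frame):
    """AB pattern: outer-line intensity falls monotonically as dnu -> 0 at fixed J."""
    j = 100.0
    ratios = []
    for dnu in (400.0, 200.0, 100.0, 50.0, 25.0):
        dppm = dnu / (frame.larmor_hz * 1e-6)
        system = geminal_pair(
            shifts=(frame.carrier_ppm + dppm / 2, frame.carrier_ppm - dppm / 2), j_hz=j)
        fid = simulate_1d(system, frame, sw_hz=4000.0, n_points=2048,
                          relax=RelaxationTheoryConfig(tau_c_s=1e-9, r2_ext_per_s=6.0))
        ppm, spec = process_1d(fid, 4000.0, frame, zerofill=8192)
        hz = (ppm - frame.carrier_ppm) * frame.larmor_hz * 1e-6
        c = np.hypot(dnu, j)
        outer = spec[np.argmin(np.abs(hz - (c + j) / 2))]
        inner = spec[np.argmin(np.abs(hz - (c - j) / 2))]
        ratios.append(outer / inner)
    assert all(b < a for a, b in zip(ratios, ratios[1:]))
    assert ratios[-1] < 0.2 * ratios[0]


def test_phase_cycle_cancels_t1_independent_component():
    rng = np.random.default_rng(0)
    signal = rng.standard_normal((8, 16)) + 1j * rng.standard_normal((8, 16))
    axial = np.tile(rng.standard_normal(16) + 1j * rng.standard_normal(16), (8, 1))
    combined = phase_cycle_axial_suppression(signal + axial, -signal + axial)
    np.testing.assert_allclose(combined, signal, atol=1e-12)
    with pytest.raises(DimensionError):
        phase_cycle_axial_suppression(signal, signal[:4])


def test_phase_cycle_suppresses_axial_ridge(frame):
    """With T1 recovery during mixing, cycling removes the F1 = 0 ridge."""
    delta = -117.0
    mix = single_anomer(two_site_assembly(delta, delta, 0.0))
    relax = RelaxationTheoryConfig(tau_c_s=1e-9, r1_ext_per_s=1.5, r2_ext_per_s=20.0)
    acq = AcquisitionScheme(sw1_hz=4000.0, sw2_hz=4000.0, n1=64, n2=128, t_mix_s=0.5)
    proc = ProcessingScheme(zerofill1=256, zerofill2=512)
    scans = simulate_exsy_scans(mix, acq, frame, relax)

    def axial_level(fc, fs):
        spec = process_2d(fc, fs, acq, proc, frame)
        ridge = (np.abs(spec.axis1_ppm - frame.carrier_ppm)
                 < 0.5)  # F1 = 0 offset band
        col = np.abs(spec.axis2_ppm - delta) < 0.5
        return np.abs(spec.values[np.ix_(ridge, col)]).max() / np.abs(spec.values).max()

    cycled = axial_level(*phase_cycle_axial_suppression_pair(scans))
    single = axial_level(scans["x"], scans["y"])
    assert cycled < 0.02 * single

    # no T1 recovery: the second step adds nothing, combined equals one scan
    relax0 = RelaxationTheoryConfig(tau_c_s=1e-9, r2_ext_per_s=20.0)
    scans0 = simulate_exsy_scans(mix, acq, frame, relax0)
    fc = phase_cycle_axial_suppression(scans0["x"], scans0["-x"])
    np.testing.assert_allclose(fc, scans0["x"], atol=1e-8 * np.abs(scans0["x"]).max())


def phase_cycle_axial_suppression_pair(scans):
    return (phase_cycle_axial_suppression(scans["x"], scans["-x"]),
            phase_cycle_axial_suppression(scans["y"], scans["-y"]))


def test_parseval_window_energy(frame):
    """Total spectral power equals N x windowed time-domain power (FFT norm)."""
    rng = np.random.default_rng(9)
    n, zf = 128, 512
    fid = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    from exsy_kinetics.exsy import _cos2_window
    x = fid * _cos2_window(n)
    x[0] *= 0.5
    spec = np.fft.fft(np.conj(x), n=zf)
    assert np.sum(np.abs(spec) ** 2) == pytest.approx(zf * np.sum(np.abs(x) ** 2), rel=1e-12)


def test_mixture_spectrum_is_linear_in_anomers(frame):
    a1 = two_site_assembly(-118.0, -118.2, 0.5)
    a2 = two_site_assembly(-122.0, -122.2, 1.0)
    relax = RelaxationTheoryConfig(tau_c_s=1e-9, r2_ext_per_s=15.0)
    acq = AcquisitionScheme(sw1_hz=5000.0, sw2_hz=5000.0, n1=32, n2=64, t_mix_s=0.4)
    proc = ProcessingScheme(zerofill1=64, zerofill2=128)
    mixed = AnomerMixture((("a", a1, 0.7), ("b", a2, 1.3)))
    spec_mixed = process_2d(*simulate_exsy(mixed, acq, frame, relax), acq, proc, frame)
    spec_a = process_2d(*simulate_exsy(single_anomer(a1, 0.7), acq, frame, relax),
                        acq, proc, frame)
    spec_b = process_2d(*simulate_exsy(single_anomer(a2, 1.3), acq, frame, relax),
                        acq, proc, frame)
    np.testing.assert_allclose(spec_mixed.values, spec_a.values + spec_b.values,
                               atol=1e-10 * np.abs(spec_mixed.values).max())


def test_exsy_volumes_match_bloch_mcconnell(frame):
    """Uncoupled two-site exchange: volume mixing matrix equals the analytic
    longitudinal propagator to 0.1 % once coherent pathways have dephased."""
    k_io, pop_in, pop_out = 1.0, 1.86, 1.0
    din, dout = -116.0, -124.0
    asm = two_site_assembly(din, dout, k_io, pop_in, pop_out)
    relax = RelaxationTheoryConfig(tau_c_s=1e-9, r2_ext_per_s=60.0)
    proc = ProcessingScheme(zerofill1=512, zerofill2=512)

    def volumes(t_mix):
        acq = AcquisitionScheme(sw1_hz=8000.0, sw2_hz=8000.0, n1=128, n2=128,
                                t_mix_s=t_mix)
        spec = process_2d(*simulate_exsy(single_anomer(asm), acq, frame, relax),
                          acq, proc, frame)
        return np.array([
            [box_volume(spec, din, din, 1.9), box_volume(spec, dout, din, 1.9)],
            [box_volume(spec, din, dout, 1.9), box_volume(spec, dout, dout, 1.9)],
        ]).T  # V[obs, origin]

    t_ref, t_mix = 0.15, 0.5
    v_ref, v = volumes(t_ref), volumes(t_mix)
    a_sim = v @ np.linalg.inv(v_ref)
    g = np.array([[-k_io, asm.k_oi_per_s], [k_io, -asm.k_oi_per_s]])
    a_bm = scipy.linalg.expm(g * (t_mix - t_ref))
    assert np.abs(a_sim - a_bm).max() < 1e-3


def test_no_exchange_cross_peaks_vanish(frame):
    """The inhibited (k = 0) limit: inter-compartment cross-peak volume
    collapses relative to both the diagonals and the active-transport case."""
    din, dout = -116.0, -124.0
    relax = RelaxationTheoryConfig(tau_c_s=1e-9, r2_ext_per_s=10.0)
    acq = AcquisitionScheme(sw1_hz=8000.0, sw2_hz=8000.0, n1=128, n2=256, t_mix_s=0.5)
    proc = ProcessingScheme(zerofill1=512, zerofill2=1024)

    def cross_and_diag(k_io):
        asm = two_site_assembly(din, dout, k_io)
        spec = process_2d(*simulate_exsy(single_anomer(asm), acq, frame, relax),
                          acq, proc, frame)
        cross = abs(box_volume(spec, din, dout, 1.8)) + abs(box_volume(spec, dout, din, 1.8))
        diag = box_volume(spec, din, din, 1.8) + box_volume(spec, dout, dout, 1.8)
        return cross, diag

    cross0, diag0 = cross_and_diag(0.0)
    cross1, _ = cross_and_diag(0.23)
    assert cross0 < 1e-3 * diag0
    assert cross0 < 1e-2 * cross1


def test_cross_peak_volume_monotone_in_k(frame):
    din, dout = -116.0, -124.0
    relax = RelaxationTheoryConfig(tau_c_s=1e-9, r2_ext_per_s=30.0)
    acq = AcquisitionScheme(sw1_hz=8000.0, sw2_hz=8000.0, n1=48, n2=96, t_mix_s=0.5)
    proc = ProcessingScheme(zerofill1=128, zerofill2=256)
    vols = []
    for k in (0.0, 0.5, 1.0, 1.5, 2.0):
        asm = two_site_assembly(din, dout, k)
        spec = process_2d(*simulate_exsy(single_anomer(asm), acq, frame, relax),
                          acq, proc, frame)
        vols.append(box_volume(spec, din, dout, 1.8))
    assert all(b >= a - 1e-9 for a, b in zip(vols, vols[1:]))


def test_unstable_generator_raises():
    gen = np.array([[0.1]])  # growing mode
    with pytest.raises(GeneratorInstabilityError):
        BlockDiagonalPropagator(gen, {0.0: np.array([0])})


def test_processing_validation(frame):
    acq = AcquisitionScheme(sw1_hz=4000.0, sw2_hz=4000.0, n1=16, n2=32)
    with pytest.raises(ValidationError):
        ProcessingScheme(zerofill1=8, zerofill2=64).check(acq)
    with pytest.raises(DimensionError):
        process_2d(np.zeros((4, 4), complex), np.zeros((4, 4), complex), acq,
                   ProcessingScheme(zerofill1=16, zerofill2=32), frame)
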