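"""Ground-truth fixtures and synthetic data generation.

Two fixtures emulate the study systems: a difluorinated glucose analogue
with one geminal CF2 group (``fdg33``, 2 fluorine spins per anomer) and a
tetrafluorinated analogue with a CF2-CF2 motif (``fdg2233``, 4 spins per
anomer).  Each exists as an alpha/beta anomer pair distributed over the
erythrocyte inside/outside compartments with distinct rotational
correlation times and anomer-specific translocation rate constants.

Kinetic and correlation-time truths are the study's fitted values; chemical
shifts, J-couplings, geometries and CSA tensors are literature-plausible
synthetic placeholders (geminal 2J_FF ~ 250 Hz, geminal F-F distance
2.16 A, vicinal 3J_FF in the 5-15 Hz range, inside/outside shift
separations of ~0.2 ppm), laid out so that every doublet component of
every species resolves on the reduced acquisition grids.  Recovery tests
target the kinetic/correlation-time truth only, never these placeholders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backtransform import PeakRegion
from .errors import ValidationError
from .exsy import AcquisitionScheme, ProcessingScheme, process_2d, simulate_exsy
from .fitting import SpectrumModel, pack_parameters, unpack_parameters
from .kinetics import influx_from_efflux
from .relaxation import RelaxationTheoryConfig
from .spectra import Spectrum2D
from .spin_model import (
    AnomerMixture,
    CompartmentAssembly,
    CsaTensor,
    SpectrometerFrame,
    SpinSystem,
)

__all__ = [
    "FixtureSpec",
    "NoiseModel",
    "make_fixture",
    "generate_dataset",
    "default_regions",
    "DEFAULT_FREE_SET",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("fdg33", "fdg2233")

#: Free parameters used in the standard recovery protocol: anomer-specific
#: efflux rates plus the two compartment correlation times; shifts, J,
#: amplitudes and populations stay frozen at truth.
DEFAULT_FREE_SET = ("k_io[alpha]", "k_io[beta]", "tau_c_in_log10", "tau_c_out_log10")

# haematocrit ~65 %: inside/outside amount ratio at equal concentration
_POP_IN, _POP_OUT = 1.86, 1.0

# synthetic placeholder CSA for CF2 fluorines
_CSA = dict(delta_sigma_ppm=60.0, eta=0.3)


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian noise in the time domain.

    ``snr`` is the target spectral signal-to-noise ratio: the noiseless
    spectrum's peak height divided by the standard deviation of the
    processed noise.  Injecting in the time domain (before processing)
    lets the apodisation shape the noise exactly as it does in real data.
    """

    snr: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if not (self.snr > 0):
            raise ValidationError("target SNR must be positive")


@dataclass(frozen=True)
class FixtureSpec:
    """A fully specified synthetic experiment with known ground truth."""

    name: str
    mixture: AnomerMixture
    acq: AcquisitionScheme
    proc: ProcessingScheme
    frame: SpectrometerFrame
    relax: RelaxationTheoryConfig
    truth: dict = field(default_factory=dict)

    def model(self, free_set=DEFAULT_FREE_SET) -> SpectrumModel:
        return SpectrumModel(self.mixture, self.acq, self.proc, self.frame,
                             self.relax, free_set)


def _geminal_pair_system(shifts, j_gem_hz):
    coords = ((0.0, 1.08, 0.50), (0.0, -1.08, 0.50))
    csa = (CsaTensor(euler_rad=(0.0, 1.02, 0.0), **_CSA),
           CsaTensor(euler_rad=(0.0, 2.12, 0.0), **_CSA))
    j = ((0.0, j_gem_hz), (j_gem_hz, 0.0))
    return SpinSystem(shifts_ppm=shifts, j_hz=j, coords_angstrom=coords, csa=csa)


def _tetrafluoro_system(shifts):
    coords = ((-0.45, 1.08, 0.62), (-0.45, -1.08, 0.62),
              (1.99, 1.08, -0.62), (1.99, -1.08, -0.62))
    csa = tuple(CsaTensor(euler_rad=(0.3 * i, 1.02 + 0.2 * i, 0.0), **_CSA)
                for i in range(4))
    j = np.zeros((4, 4))
    j[0, 1] = 252.0
    j[2, 3] = 248.0
    j[0, 2], j[0, 3], j[1, 2], j[1, 3] = 12.0, 5.0, 8.0, 14.0
    j = j + j.T
    return SpinSystem(shifts_ppm=shifts, j_hz=tuple(map(tuple, j)),
                      coords_angstrom=coords, csa=csa)


def _assembly(sys_in, sys_out, tau_in_log10, tau_out_log10, k_io):
    return CompartmentAssembly(
        sys_in, sys_out, tau_in_log10, tau_out_log10,
        k_io, influx_from_efflux(k_io, _POP_IN, _POP_OUT), _POP_IN, _POP_OUT)


def _out_shifts(shifts_in, seps):
    return tuple(s + d for s, d in zip(shifts_in, seps))


def _fdg33() -> tuple:
    # alpha: k_io = 0.23 /s; beta: 0.79 /s; tau_c 10^-9.03 (in), 10^-9.28 (out)
    a_in = (-118.00, -124.60)
    b_in = (-116.70, -122.90)
    alpha = _assembly(_geminal_pair_system(a_in, 250.0),
                      _geminal_pair_system(_out_shifts(a_in, (0.20, 0.19)), 250.0),
                      -9.03, -9.28, 0.23)
    beta = _assembly(_geminal_pair_system(b_in, 250.0),
                     _geminal_pair_system(_out_shifts(b_in, (0.20, 0.18)), 250.0),
                     -9.03, -9.28, 0.79)
    mixture = AnomerMixture((("alpha", alpha, 1.0), ("beta", beta, 1.6)))
    frame = SpectrometerFrame(carrier_ppm=-120.5)
    acq = AcquisitionScheme(sw1_hz=6000.0, sw2_hz=6000.0, n1=128, n2=256, t_mix_s=0.5)
    proc = ProcessingScheme(zerofill1=256, zerofill2=512)
    return mixture, frame, acq, proc


def _fdg2233() -> tuple:
    # alpha: k_io = 0.94 /s; beta: 0.87 /s; tau_c 10^-8.46 (in), 10^-9.09 (out)
    a_in = (-112.80, -116.20, -119.60, -123.00)
    b_in = (-114.50, -117.90, -121.30, -124.70)
    seps_a = (0.20, 0.21, 0.19, 0.20)
    seps_b = (0.20, 0.19, 0.21, 0.18)
    alpha = _assembly(_tetrafluoro_system(a_in),
                      _tetrafluoro_system(_out_shifts(a_in, seps_a)),
                      -8.46, -9.09, 0.94)
    beta = _assembly(_tetrafluoro_system(b_in),
                     _tetrafluoro_system(_out_shifts(b_in, seps_b)),
                     -8.46, -9.09, 0.87)
    mixture = AnomerMixture((("alpha", alpha, 1.0), ("beta", beta, 1.6)))
    frame = SpectrometerFrame(carrier_ppm=-118.6)
    acq = AcquisitionScheme(sw1_hz=7000.0, sw2_hz=7000.0, n1=128, n2=256, t_mix_s=0.5)
    proc = ProcessingScheme(zerofill1=256, zerofill2=512)
    return mixture, frame, acq, proc


_ACQ_KEYS = ("n1", "n2", "sw1_hz", "sw2_hz", "t_mix_s")
_PROC_KEYS = ("zerofill1", "zerofill2")


def make_fixture(name: str, overrides: dict | None = None) -> FixtureSpec:
    """Build a named fixture, optionally overriding parameters by name.

    Override keys may be mixture parameter names in the canonical fit
    layout (e.g. ``"k_io[alpha]"``, ``"tau_c_in_log10"``,
    ``"j[beta][0,1]"``) or acquisition/processing keys
    (``n1``, ``n2``, ``sw1_hz``, ``sw2_hz``, ``t_mix_s``, ``zerofill1``,
    ``zerofill2``).  Unknown keys raise.
    """
    if name == "fdg33":
        mixture, frame, acq, proc = _fdg33()
    elif name == "fdg2233":
        mixture, frame, acq, proc = _fdg2233()
    else:
        raise ValidationError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")

    overrides = dict(overrides or {})
    params = pack_parameters(mixture)
    param_updates = {k: overrides.pop(k) for k in list(overrides) if k in params.names}
    if param_updates:
        mixture = unpack_parameters(params.replace(**param_updates), mixture)
    acq_updates = {k: overrides.pop(k) for k in list(overrides) if k in _ACQ_KEYS}
    if acq_updates:
        from dataclasses import replace
        acq = replace(acq, **acq_updates)
    proc_updates = {k: overrides.pop(k) for k in list(overrides) if k in _PROC_KEYS}
    if proc_updates:
        from dataclasses import replace
        proc = replace(proc, **proc_updates)
    if overrides:
        raise ValidationError(f"unknown override(s): {sorted(overrides)}")

    relax = RelaxationTheoryConfig(tau_c_s=1e-9)  # tau_c comes from the assembly
    truth = pack_parameters(mixture).values()
    truth.update({"fixture": name, "t_mix_s": acq.t_mix_s})
    return FixtureSpec(name, mixture, acq, proc, frame, relax, truth)


def generate_dataset(fixture: FixtureSpec, noise: NoiseModel | None = None):
    """Simulate the fixture, optionally inject seeded time-domain noise.

    Returns ``(Spectrum2D, truth_record)``.  The truth record (ground-truth
    parameters, seed, target SNR) is also embedded in the spectrum metadata
    so a written spectrum file is self-describing.
    """
    fid_cos, fid_sin = simulate_exsy(fixture.mixture, fixture.acq, fixture.frame,
                                     fixture.relax)
    spec0 = process_2d(fid_cos, fid_sin, fixture.acq, fixture.proc, fixture.frame)
    truth = dict(fixture.truth)
    meta = {"fixture": fixture.name, "truth": {k: v for k, v in truth.items()
                                               if isinstance(v, (int, float, str))}}
    if noise is None:
        spec = process_2d(fid_cos, fid_sin, fixture.acq, fixture.proc, fixture.frame,
                          meta=meta)
        return spec, truth

    rng = np.random.default_rng(noise.seed)
    shape = fid_cos.shape
    draws = [rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
             for _ in range(2)]
    # calibrate the time-domain sigma against the processed unit-noise level
    noise_spec = process_2d(draws[0], draws[1], fixture.acq, fixture.proc, fixture.frame)
    unit_level = float(noise_spec.values.std())
    peak = float(np.abs(spec0.values).max())
    sigma = peak / (noise.snr * unit_level)
    meta.update({"seed": noise.seed, "snr": noise.snr, "noise_sigma_td": sigma})
    truth.update({"seed": noise.seed, "snr": noise.snr})
    spec = process_2d(fid_cos + sigma * draws[0], fid_sin + sigma * draws[1],
                      fixture.acq, fixture.proc, fixture.frame, meta=meta)
    return spec, truth


def _geminal_partner(system: SpinSystem, spin: int) -> int:
    j = np.abs(system.j[spin])
    return int(np.argmax(j))


def default_regions(fixture: FixtureSpec, half_width_ppm: float = 0.088) -> list:
    """Line-resolved integration rectangles for the classical analysis.

    One rectangle per pair of resolved doublet components (the geminal
    splitting separates the components by far more than the inside/outside
    shift difference, so multiplet-group boxes would mix the compartments).
    Labels encode the compartment of origin (F1) and observation (F2), so
    the rectangles assemble into per-anomer 2x2 volume matrices.
    """
    ppm_per_hz = 1.0 / (fixture.frame.larmor_hz * 1e-6)
    regions = []
    for label, asm, _amp in fixture.mixture.anomers:
        lines = []  # (site, center_ppm)
        for site, system in (("in", asm.system_in), ("out", asm.system_out)):
            for spin in range(asm.n_spins):
                partner = _geminal_partner(system, spin)
                j_gem = system.j[spin, partner]
                for comp in (-0.5, +0.5):
                    center = system.shifts[spin] + comp * j_gem * ppm_per_hz
                    lines.append((site, float(center)))
        for site1, c1 in lines:
            for site2, c2 in lines:
                regions.append(PeakRegion(
                    anomer=label, origin=site1, obs=site2,
                    f1_ppm_range=(c1 - half_width_ppm, c1 + half_width_ppm),
                    f2_ppm_range=(c2 - half_width_ppm, c2 + half_width_ppm)))
    return regions
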