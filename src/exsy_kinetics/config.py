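"""Structured text (YAML) configuration for spin systems, kinetics and
acquisition.

Dialect (all sections optional except ``spins`` and ``compartments``)::

    frame:
      larmor_hz: 376.46e6
      carrier_ppm: -120.5
    spins:                      # one entry per anomer
      alpha:
        j_hz: [[0, 250], [250, 0]]
        coords_angstrom: [[0, 1.08, 0.5], [0, -1.08, 0.5]]
        csa:                    # optional, one entry per spin
          - {delta_sigma_ppm: 60, eta: 0.3, euler_rad: [0, 1.02, 0]}
          - {delta_sigma_ppm: 60, eta: 0.3, euler_rad: [0, 2.12, 0]}
        shifts_in_ppm: [-118.0, -124.6]
        shifts_out_ppm: [-117.8, -124.41]
        amplitude: 1.0
    compartments:
      tau_c_in_log10: -9.03
      tau_c_out_log10: -9.28
      pop_in: 1.86
      pop_out: 1.0
    kinetics:
      equilibrium_constraint: true
      k_io_per_s: {alpha: 0.23, beta: 0.79}
      k_oi_per_s: {alpha: 0.43}   # only read when the constraint is off
    relaxation:
      include_dd: true
      include_csa: true
      include_cross_correlations: true
      secular_cutoff_rad_s: 1.0e3
      r1_ext_per_s: 0.0
      r2_ext_per_s: 0.0
    acquisition:
      sw1_hz: 6000.0
      sw2_hz: 6000.0
      n1: 128
      n2: 256
      t_mix_s: 0.5
    processing:
      zerofill1: 256
      zerofill2: 512
    regions:                    # optional, for back-transformation
      - {anomer: alpha, origin: in, obs: out,
         f1_ppm_range: [-118.1, -117.9], f2_ppm_range: [-117.9, -117.7]}
"""

from __future__ import annotations

import yaml

from .backtransform import PeakRegion
from .errors import ValidationError
from .exsy import AcquisitionScheme, ProcessingScheme
from .kinetics import influx_from_efflux
from .relaxation import RelaxationTheoryConfig
from .spin_model import (
    AnomerMixture,
    CompartmentAssembly,
    CsaTensor,
    SpectrometerFrame,
    SpinSystem,
)

__all__ = ["load_config", "parse_config", "ExperimentConfig"]


class ExperimentConfig:
    """Parsed configuration bundle."""

    def __init__(self, mixture, frame, acq, proc, relax, regions):
        self.mixture = mixture
        self.frame = frame
        self.acq = acq
        self.proc = proc
        self.relax = relax
        self.regions = regions


def _build_system(entry: dict, shifts_key: str) -> SpinSystem:
    csa = entry.get("csa")
    csa_t = tuple(CsaTensor(c.get("delta_sigma_ppm", 0.0), c.get("eta", 0.0),
                            tuple(c.get("euler_rad", (0.0, 0.0, 0.0))))
                  for c in csa) if csa else ()
    return SpinSystem(
        shifts_ppm=tuple(entry[shifts_key]),
        j_hz=tuple(map(tuple, entry["j_hz"])),
        coords_angstrom=tuple(map(tuple, entry["coords_angstrom"])),
        csa=csa_t,
    )


def parse_config(cfg: dict) -> ExperimentConfig:
    """Build domain objects from a parsed configuration dictionary."""
    try:
        spins = cfg["spins"]
        comp = cfg["compartments"]
    except KeyError as exc:
        raise ValidationError(f"missing config section: {exc}") from exc
    kin = cfg.get("kinetics", {})
    constraint = bool(kin.get("equilibrium_constraint", True))
    pop_in = float(comp.get("pop_in", 1.0))
    pop_out = float(comp.get("pop_out", 1.0))

    anomers = []
    for label, entry in spins.items():
        k_io = float(kin.get("k_io_per_s", {}).get(label, 0.0))
        if constraint:
            k_oi = influx_from_efflux(k_io, pop_in, pop_out)
        else:
            k_oi = float(kin.get("k_oi_per_s", {}).get(label, 0.0))
        assembly = CompartmentAssembly(
            _build_system(entry, "shifts_in_ppm"),
            _build_system(entry, "shifts_out_ppm"),
            float(comp["tau_c_in_log10"]), float(comp["tau_c_out_log10"]),
            k_io, k_oi, pop_in, pop_out, equilibrium_constraint=constraint)
        anomers.append((label, assembly, float(entry.get("amplitude", 1.0))))
    mixture = AnomerMixture(tuple(anomers))

    fr = cfg.get("frame", {})
    frame = SpectrometerFrame(float(fr.get("larmor_hz", SpectrometerFrame().larmor_hz)),
                              float(fr.get("carrier_ppm", 0.0)))

    acq = AcquisitionScheme(**cfg["acquisition"]) if "acquisition" in cfg else None
    proc = ProcessingScheme(**cfg["processing"]) if "processing" in cfg else ProcessingScheme()

    rx = cfg.get("relaxation", {})
    relax = RelaxationTheoryConfig(tau_c_s=1e-9, **{
        k: rx[k] for k in ("include_dd", "include_csa", "include_cross_correlations",
                           "secular_cutoff_rad_s", "r1_ext_per_s", "r2_ext_per_s")
        if k in rx})

    regions = [PeakRegion(r["anomer"], r["origin"], r["obs"],
                          tuple(r["f1_ppm_range"]), tuple(r["f2_ppm_range"]))
               for r in cfg.get("regions", [])]
    return ExperimentConfig(mixture, frame, acq, proc, relax, regions)


def load_config(path) -> ExperimentConfig:
    """Read and parse a YAML experiment configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config file must contain a mapping")
    return parse_config(cfg)
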