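"""Direct least-squares fitting of simulated 2D EXSY spectra to data.

The objective is the squared Frobenius norm of the difference between the
simulated and target spectra, minimised over a named parameter vector by
Nelder-Mead simplex.  Positivity of rates is enforced by a softplus
transform and correlation times are handled as log10(seconds).
Uncertainties come from a dropout bootstrap: repeated refits with a random
half of the spectrum pixels masked out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import scipy.optimize

from .errors import DimensionError, FitError, ValidationError
from .exsy import AcquisitionScheme, ProcessingScheme, process_2d, simulate_exsy
from .kinetics import influx_from_efflux
from .relaxation import RelaxationTheoryConfig
from .spectra import Spectrum2D
from .spin_model import AnomerMixture, CompartmentAssembly, SpectrometerFrame

__all__ = [
    "Parameter",
    "ParameterVector",
    "pack_parameters",
    "unpack_parameters",
    "SpectrumModel",
    "FitOptions",
    "FitResult",
    "objective",
    "fit",
    "bootstrap",
]


# ---------------------------------------------------------------------------
# parameter vector with transforms

def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(v):
    if v <= 0:
        raise ValidationError("softplus-transformed parameters must be positive")
    # log(e^v - 1), stable for small and large v
    return v + math.log(-math.expm1(-v))


_TRANSFORMS = {
    "identity": (lambda v: v, lambda x: x),
    "log10": (lambda v: math.log10(v), lambda x: 10.0 ** x),
    "softplus": (_softplus_inv, _softplus),
}


@dataclass(frozen=True)
class Parameter:
    """One named fit parameter with bounds, free flag and transform."""

    name: str
    value: float
    lower: float = -np.inf
    upper: float = np.inf
    free: bool = False
    transform: str = "identity"

    def __post_init__(self):
        if self.transform not in _TRANSFORMS:
            raise ValidationError(f"unknown transform {self.transform!r}")
        if not np.isfinite(self.value):
            raise ValidationError(f"parameter {self.name} must be finite")
        if self.free and not (self.lower <= self.value <= self.upper):
            raise ValidationError(
                f"free parameter {self.name}={self.value} outside bounds "
                f"[{self.lower}, {self.upper}]")

    @property
    def internal(self) -> float:
        return _TRANSFORMS[self.transform][0](self.value)

    def with_internal(self, x: float) -> "Parameter":
        return dc_replace(self, value=float(_TRANSFORMS[self.transform][1](x)))


class ParameterVector:
    """Ordered collection of :class:`Parameter` addressed by name."""

    def __init__(self, params):
        self._params = list(params)
        names = [p.name for p in self._params]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate parameter names")
        self._index = {p.name: i for i, p in enumerate(self._params)}

    def __iter__(self):
        return iter(self._params)

    def __len__(self):
        return len(self._params)

    def __getitem__(self, name: str) -> Parameter:
        return self._params[self._index[name]]

    @property
    def names(self):
        return tuple(p.name for p in self._params)

    @property
    def free_names(self):
        return tuple(p.name for p in self._params if p.free)

    def value(self, name: str) -> float:
        return self[name].value

    def values(self) -> dict:
        return {p.name: p.value for p in self._params}

    def replace(self, **updates) -> "ParameterVector":
        params = []
        unknown = set(updates) - set(self.names)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        for p in self._params:
            params.append(dc_replace(p, value=float(updates[p.name]))
                          if p.name in updates else p)
        return ParameterVector(params)

    def with_free(self, free_names) -> "ParameterVector":
        unknown = set(free_names) - set(self.names)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        return ParameterVector(
            [dc_replace(p, free=p.name in free_names) for p in self._params])

    def to_internal(self) -> np.ndarray:
        return np.array([p.internal for p in self._params if p.free], dtype=float)

    def from_internal(self, x: np.ndarray) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        free = [p for p in self._params if p.free]
        if x.size != len(free):
            raise DimensionError(f"expected {len(free)} internal values, got {x.size}")
        it = iter(x)
        return ParameterVector(
            [p.with_internal(next(it)) if p.free else p for p in self._params])


# ---------------------------------------------------------------------------
# packing a mixture into parameters and back

def pack_parameters(mixture: AnomerMixture, free_set=()) -> ParameterVector:
    """Canonical parameter layout for a two-compartment anomer mixture.

    Order: per-anomer efflux rates ``k_io[label]``; global correlation times
    ``tau_c_in_log10``/``tau_c_out_log10`` (compartment properties shared by
    the anomers); per-anomer amplitudes ``amp[label]``; global populations
    ``pop_in``/``pop_out``; per-anomer per-spin shifts
    ``shift_in[label][i]``/``shift_out[label][i]``; per-anomer couplings
    ``j[label][i,k]`` (upper triangle).  Influx rates are not parameters:
    they follow from detailed balance on unpacking (the equilibrium
    constraint), unless ``k_oi[label]`` parameters are added explicitly via
    assemblies with the constraint disabled.
    """
    params = []
    first = mixture.anomers[0][1]
    for label, asm, amp in mixture.anomers:
        params.append(Parameter(f"k_io[{label}]", asm.k_io_per_s, 0.0, np.inf,
                                transform="softplus"))
        if not asm.equilibrium_constraint:
            params.append(Parameter(f"k_oi[{label}]", asm.k_oi_per_s, 0.0, np.inf,
                                    transform="softplus"))
    params.append(Parameter("tau_c_in_log10", first.tau_c_in_log10, -12.0, -6.0))
    params.append(Parameter("tau_c_out_log10", first.tau_c_out_log10, -12.0, -6.0))
    for label, asm, amp in mixture.anomers:
        params.append(Parameter(f"amp[{label}]", amp, 0.0, np.inf, transform="softplus"))
    params.append(Parameter("pop_in", first.pop_in, 0.0, np.inf, transform="softplus"))
    params.append(Parameter("pop_out", first.pop_out, 0.0, np.inf, transform="softplus"))
    for label, asm, amp in mixture.anomers:
        for i, s in enumerate(asm.system_in.shifts_ppm):
            params.append(Parameter(f"shift_in[{label}][{i}]", s))
        for i, s in enumerate(asm.system_out.shifts_ppm):
            params.append(Parameter(f"shift_out[{label}][{i}]", s))
        j = asm.system_in.j
        for i in range(asm.n_spins):
            for k in range(i + 1, asm.n_spins):
                params.append(Parameter(f"j[{label}][{i},{k}]", j[i, k]))
    vec = ParameterVector(params)
    return vec.with_free(free_set) if free_set else vec


def unpack_parameters(params: ParameterVector, template: AnomerMixture) -> AnomerMixture:
    """Rebuild a mixture from a parameter vector (inverse of :func:`pack_parameters`).

    With the equilibrium constraint active, influx rates are recomputed from
    the unpacked efflux rates and populations.
    """
    vals = params.values()
    anomers = []
    for label, asm, amp in template.anomers:
        n = asm.n_spins
        shifts_in = [vals[f"shift_in[{label}][{i}]"] for i in range(n)]
        shifts_out = [vals[f"shift_out[{label}][{i}]"] for i in range(n)]
        j = asm.system_in.j.copy()
        for i in range(n):
            for k in range(i + 1, n):
                j[i, k] = j[k, i] = vals[f"j[{label}][{i},{k}]"]
        sys_in = dc_replace(asm.system_in, shifts_ppm=tuple(shifts_in),
                            j_hz=tuple(map(tuple, j)))
        sys_out = dc_replace(asm.system_out, shifts_ppm=tuple(shifts_out),
                             j_hz=tuple(map(tuple, j)))
        k_io = vals[f"k_io[{label}]"]
        pop_in, pop_out = vals["pop_in"], vals["pop_out"]
        if asm.equilibrium_constraint:
            k_oi = influx_from_efflux(k_io, pop_in, pop_out)
        else:
            k_oi = vals[f"k_oi[{label}]"]
        anomers.append((label, CompartmentAssembly(
            sys_in, sys_out,
            vals["tau_c_in_log10"], vals["tau_c_out_log10"],
            k_io, k_oi, pop_in, pop_out,
            equilibrium_constraint=asm.equilibrium_constraint,
        ), vals[f"amp[{label}]"]))
    return AnomerMixture(tuple(anomers))


# ---------------------------------------------------------------------------
# forward model and objective

class SpectrumModel:
    """Forward model: parameter vector -> processed 2D spectrum."""

    def __init__(self, mixture: AnomerMixture, acq: AcquisitionScheme,
                 proc: ProcessingScheme, frame: SpectrometerFrame,
                 relax: RelaxationTheoryConfig | None, free_set=()):
        self.template = mixture
        self.acq = acq
        self.proc = proc
        self.frame = frame
        self.relax = relax
        self.params0 = pack_parameters(mixture, free_set)

    def simulate(self, params: ParameterVector) -> Spectrum2D:
        mixture = unpack_parameters(params, self.template)
        fid_cos, fid_sin = simulate_exsy(mixture, self.acq, self.frame, self.relax)
        return process_2d(fid_cos, fid_sin, self.acq, self.proc, self.frame)


def objective(model: SpectrumModel, params: ParameterVector, target: Spectrum2D,
              mask: np.ndarray | None = None) -> float:
    """Squared Frobenius norm of (simulated - target) over unmasked pixels."""
    sim = model.simulate(params)
    if not sim.congruent_with(target):
        raise DimensionError("simulated and target spectra are not on the same grid")
    resid = sim.values - target.values
    if mask is not None:
        if mask.shape != resid.shape:
            raise DimensionError("mask shape must match the spectrum")
        resid = resid[mask]
    return float(np.sum(resid * resid))


# ---------------------------------------------------------------------------
# Nelder-Mead fit and dropout bootstrap

@dataclass(frozen=True)
class FitOptions:
    """Simplex convergence controls.

    ``xtol`` applies to the transformed (internal) coordinates; ``ftol_rel``
    scales with the objective at the initial point; ``initial_step`` sets
    the relative size of the starting simplex (smaller for refits that
    start near an optimum).
    """

    xtol: float = 1e-4
    ftol_rel: float = 1e-6
    max_evals: int = 1000
    initial_step: float = 0.05


@dataclass
class FitResult:
    estimates: ParameterVector
    objective: float
    n_evals: int
    converged: bool
    bootstrap_sd: dict | None = None
    bootstrap_replicates: np.ndarray | None = None
    n_failed_rounds: int = 0

    def value(self, name: str) -> float:
        return self.estimates.value(name)


def fit(model: SpectrumModel, initial: ParameterVector, target: Spectrum2D,
        options: FitOptions = FitOptions(), mask: np.ndarray | None = None) -> FitResult:
    """Nelder-Mead minimisation of the Frobenius objective over free parameters."""
    if not initial.free_names:
        raise FitError("no free parameters")
    x0 = initial.to_internal()
    n_evals = 0

    def fun(x):
        nonlocal n_evals
        n_evals += 1
        try:
            val = objective(model, initial.from_internal(x), target, mask)
        except (ValidationError, FloatingPointError):
            return 1e300
        if not np.isfinite(val):
            return 1e300
        return val

    f0 = fun(x0)
    # floor the objective tolerance at the roundoff scale of the data so a
    # start at (or convergence to) an exact optimum still terminates
    f_floor = 1e-16 * float(np.sum(target.values ** 2))
    res = scipy.optimize.minimize(
        fun, x0, method="Nelder-Mead",
        options={
            "xatol": options.xtol,
            "fatol": max(options.ftol_rel * f0, f_floor),
            "maxfev": options.max_evals,
            "initial_simplex": _initial_simplex(x0, options.initial_step),
        })
    return FitResult(
        estimates=initial.from_internal(res.x),
        objective=float(res.fun),
        n_evals=n_evals,
        converged=bool(res.success),
    )


def _initial_simplex(x0: np.ndarray, step_scale: float) -> np.ndarray:
    # fixed absolute steps keep the simplex sensible when a coordinate is ~0
    n = x0.size
    simplex = np.tile(x0, (n + 1, 1))
    for i in range(n):
        simplex[i + 1, i] += step_scale * max(abs(x0[i]), 1.0)
    return simplex


def bootstrap(model: SpectrumModel, fit_result: FitResult, target: Spectrum2D,
              n_rounds: int = 32, drop_fraction: float = 0.5, seed: int = 0,
              options: FitOptions = FitOptions(max_evals=400, initial_step=0.02)) -> FitResult:
    """Half-dropout bootstrap standard deviations for the free parameters.

    Each round masks a fresh random ``drop_fraction`` of the spectrum pixels
    and refits starting from the full-data optimum.  Rounds that fail to
    converge are excluded and counted.  Fully deterministic for a fixed seed.
    """
    if n_rounds < 2:
        raise ValidationError("bootstrap needs at least 2 rounds")
    if not 0.0 < drop_fraction < 1.0:
        raise ValidationError("drop_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    free = fit_result.estimates.free_names
    replicates = []
    n_failed = 0
    for _ in range(n_rounds):
        keep = rng.random(target.values.shape) >= drop_fraction
        res = fit(model, fit_result.estimates, target, options, mask=keep)
        if not res.converged:
            n_failed += 1
            continue
        replicates.append([res.estimates.value(name) for name in free])
    if len(replicates) < 2:
        raise FitError("too few converged bootstrap rounds")
    reps = np.array(replicates)
    sd = reps.std(axis=0, ddof=1)
    return dc_replace(
        fit_result,
        bootstrap_sd={name: float(s) for name, s in zip(free, sd)},
        bootstrap_replicates=reps,
        n_failed_rounds=n_failed,
    )
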