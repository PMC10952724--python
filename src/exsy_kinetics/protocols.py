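"""End-to-end quantification protocols.

These wire the pieces together the way the study uses them: the ideal
two-site back-transformation round trip, and the parameter-recovery
protocol (generate a fixture with known truth, fit with rates and
correlation times free from a perturbed start, optionally bootstrap).
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .backtransform import VolumeMatrix, backtransform_rates
from .fitting import FitOptions, FitResult, bootstrap, fit
from .kinetics import influx_from_efflux
from .synthetic import DEFAULT_FREE_SET, NoiseModel, generate_dataset, make_fixture

__all__ = ["ideal_backtransform_roundtrip", "recovery_protocol"]


def ideal_backtransform_roundtrip(k_io: float = 0.23, pop_in: float = 1.86,
                                  pop_out: float = 1.0, r1_per_s: float = 0.5,
                                  t_mix_s: float = 0.5):
    """Forward-simulate an ideal two-site volume matrix and back-transform it.

    Builds the longitudinal exchange generator with the influx rate from
    detailed balance and uniform longitudinal relaxation, computes
    ``V(t_mix) = expm(L t_mix) diag(M0)``, and extracts the rates by the
    principal matrix logarithm.  Exact up to numerical round-off.
    """
    k_oi = influx_from_efflux(k_io, pop_in, pop_out)
    gen = np.array([[-k_io - r1_per_s, k_oi], [k_io, -k_oi - r1_per_s]])
    m0 = np.array([pop_in, pop_out])
    volumes = VolumeMatrix("alpha", scipy.linalg.expm(gen * t_mix_s) @ np.diag(m0),
                           m0=m0)
    return backtransform_rates(volumes, t_mix_s)


def recovery_protocol(fixture_name: str, grid: dict | None = None,
                      noise: NoiseModel | None = None, start_factor: float = 1.5,
                      free_set=DEFAULT_FREE_SET,
                      options: FitOptions = FitOptions(max_evals=400),
                      n_bootstrap: int = 0, bootstrap_seed: int = 0,
                      bootstrap_options: FitOptions = FitOptions(
                          max_evals=250, xtol=1e-3, initial_step=0.02)):
    """Generate a fixture, fit it from a perturbed start, optionally bootstrap.

    Rates start at ``start_factor`` times truth and correlation times at
    ``log10(start_factor)`` above truth.  Returns ``(FitResult, truth)``.
    """
    fixture = make_fixture(fixture_name, grid)
    target, truth = generate_dataset(fixture, noise)
    model = fixture.model(free_set)
    start = model.params0.replace(**{
        name: (truth[name] + np.log10(start_factor) if "tau_c" in name
               else truth[name] * start_factor)
        for name in free_set})
    result = fit(model, start, target, options)
    if n_bootstrap:
        result = bootstrap(model, result, target, n_rounds=n_bootstrap,
                           drop_fraction=0.5, seed=bootstrap_seed,
                           options=bootstrap_options)
    return result, truth
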