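"""Parameter handling, Frobenius objective, simplex fit and bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exsy_kinetics.errors import DimensionError, FitError, ValidationError
from exsy_kinetics.fitting import (
    FitOptions,
    Parameter,
    ParameterVector,
    bootstrap,
    fit,
    objective,
    pack_parameters,
    unpack_parameters,
)
from exsy_kinetics.synthetic import (
    DEFAULT_FREE_SET,
    NoiseModel,
    generate_dataset,
    make_fixture,
)

SMALL_GRID = {"n1": 32, "n2": 64, "zerofill1": 64, "zerofill2": 128}
FIT_GRID = {"n1": 64, "n2": 128, "zerofill1": 128, "zerofill2": 256}


@pytest.fixture(scope="module")
def small_fixture():
    return make_fixture("fdg33", SMALL_GRID)


@pytest.fixture(scope="module")
def small_target(small_fixture):
    spec, truth = generate_dataset(small_fixture)
    return spec, truth


def perturbed_start(model, truth, factor=1.5):
    return model.params0.replace(**{
        "k_io[alpha]": truth["k_io[alpha]"] * factor,
        "k_io[beta]": truth["k_io[beta]"] * factor,
        "tau_c_in_log10": truth["tau_c_in_log10"] + np.log10(factor),
        "tau_c_out_log10": truth["tau_c_out_log10"] + np.log10(factor),
    })


# ---------------------------------------------------------------------------
# parameter vector mechanics

def test_parameter_transforms_roundtrip():
    p = Parameter("k", 0.23, 0.0, np.inf, free=True, transform="softplus")
    assert p.with_internal(p.internal).value == pytest.approx(0.23, rel=1e-12)
    p2 = Parameter("tau", 3.2e-9, free=True, transform="log10")
    assert p2.with_internal(p2.internal).value == pytest.approx(3.2e-9, rel=1e-12)
    with pytest.raises(ValidationError):
        Parameter("x", 1.0, transform="exp")
    with pytest.raises(ValidationError):
        Parameter("x", -1.0, 0.0, 1.0, free=True)


def test_parameter_vector_free_subset_and_internal():
    vec = ParameterVector([
        Parameter("a", 1.0, free=True),
        Parameter("b", 2.0),
        Parameter("c", 0.5, free=True, transform="softplus"),
    ])
    assert vec.free_names == ("a", "c")
    x = vec.to_internal()
    assert x.size == 2
    back = vec.from_internal(x)
    assert back.value("c") == pytest.approx(0.5, rel=1e-12)
    with pytest.raises(KeyError):
        vec.replace(zz=1.0)
    with pytest.raises(DimensionError):
        vec.from_internal(np.zeros(3))


def test_pack_layout_documented_count(small_fixture):
    """fdg33 canonical layout: 2 k_io + 2 tau_c + 2 amp + 2 pop + 8 shifts + 2 J."""
    params = pack_parameters(small_fixture.mixture)
    assert len(params) == 18
    assert params.names[:4] == ("k_io[alpha]", "k_io[beta]",
                                "tau_c_in_log10", "tau_c_out_log10")


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    k_a=st.floats(0.01, 3.0), k_b=st.floats(0.01, 3.0),
    tau_in=st.floats(-10.0, -8.0), tau_out=st.floats(-10.0, -8.0),
    shift=st.floats(-0.3, 0.3), jval=st.floats(-20.0, 20.0),
)
def test_pack_unpack_roundtrip_property(k_a, k_b, tau_in, tau_out, shift, jval):
    """unpack(pack(m)) == m for randomised parameter values."""
    fixture = make_fixture("fdg33", {
        "k_io[alpha]": k_a, "k_io[beta]": k_b,
        "tau_c_in_log10": tau_in, "tau_c_out_log10": tau_out,
        "shift_in[alpha][0]": -118.0 + shift, "j[beta][0,1]": 250.0 + jval,
    })
    params = pack_parameters(fixture.mixture)
    rebuilt = unpack_parameters(params, fixture.mixture)
    re_params = pack_parameters(rebuilt)
    for name in params.names:
        assert re_params.value(name) == pytest.approx(params.value(name),
                                                      rel=1e-12, abs=1e-12)
    assert rebuilt.assembly("alpha").k_oi_per_s == pytest.approx(
        k_a * rebuilt.assembly("alpha").pop_in / rebuilt.assembly("alpha").pop_out,
        rel=1e-12)


def test_unpack_with_empty_free_set_leaves_simulation_unchanged(small_fixture):
    model = small_fixture.model(free_set=())
    spec1 = model.simulate(model.params0)
    spec2 = model.simulate(model.params0)
    np.testing.assert_array_equal(spec1.values, spec2.values)
    with pytest.raises(FitError):
        fit(model, model.params0, spec1)


# ---------------------------------------------------------------------------
# objective

def test_objective_zero_at_truth_and_homogeneous(small_fixture, small_target):
    spec, truth = small_target
    model = small_fixture.model(DEFAULT_FREE_SET)
    assert objective(model, model.params0, spec) <= 1e-18 * np.sum(spec.values ** 2)
    # residual scaling: objective is quadratic in the residual
    sim = model.simulate(model.params0)
    rng = np.random.default_rng(0)
    noise = rng.standard_normal(sim.values.shape)
    from exsy_kinetics.spectra import Spectrum2D
    for c in (1.0, 3.0):
        target_c = Spectrum2D(sim.values + c * noise, sim.axis1_ppm, sim.axis2_ppm)
        assert objective(model, model.params0, target_c) == pytest.approx(
            c ** 2 * np.sum(noise ** 2), rel=1e-10)
    # perturbing a rate away from truth raises the objective
    bumped = model.params0.replace(**{"k_io[beta]": truth["k_io[beta]"] * 1.5})
    assert objective(model, bumped, spec) > 0
    # mask shape errors
    with pytest.raises(DimensionError):
        objective(model, model.params0, spec, mask=np.ones((3, 3), dtype=bool))


def test_objective_rejects_incongruent_grids(small_fixture, small_target):
    spec, _ = small_target
    other = make_fixture("fdg33", {"n1": 32, "n2": 64, "zerofill1": 64,
                                   "zerofill2": 128, "sw1_hz": 5000.0})
    model = other.model(DEFAULT_FREE_SET)
    with pytest.raises(DimensionError):
        objective(model, model.params0, spec)


# ---------------------------------------------------------------------------
# fit

def test_fit_from_truth_converges_immediately(small_fixture, small_target):
    spec, truth = small_target
    model = small_fixture.model(DEFAULT_FREE_SET)
    res = fit(model, model.params0, spec, FitOptions(max_evals=400))
    assert res.converged
    for name in DEFAULT_FREE_SET:
        assert res.value(name) == pytest.approx(truth[name], rel=1e-3, abs=1e-3)


def test_fit_recovers_perturbed_parameters(small_fixture, small_target):
    """Noiseless target, start at 1.5x truth: rates to 1 %, log tau to 0.02."""
    spec, truth = small_target
    model = small_fixture.model(DEFAULT_FREE_SET)
    res = fit(model, perturbed_start(model, truth), spec, FitOptions(max_evals=400))
    assert res.converged
    assert res.value("k_io[alpha]") == pytest.approx(truth["k_io[alpha]"], rel=0.01)
    assert res.value("k_io[beta]") == pytest.approx(truth["k_io[beta]"], rel=0.01)
    assert abs(res.value("tau_c_in_log10") - truth["tau_c_in_log10"]) < 0.02
    assert abs(res.value("tau_c_out_log10") - truth["tau_c_out_log10"]) < 0.02


def test_identifiability_1d_scans():
    """The objective is minimised at the generating value along each free
    parameter, for both fixture families (11-point scans)."""
    for name, grid in (("fdg33", SMALL_GRID),
                       ("fdg2233", {"n1": 16, "n2": 32, "zerofill1": 32,
                                    "zerofill2": 64})):
        fx = make_fixture(name, grid)
        spec, truth = generate_dataset(fx)
        model = fx.model(DEFAULT_FREE_SET)
        for pname in DEFAULT_FREE_SET:
            t = truth[pname]
            if "tau" in pname:
                values = t + np.linspace(-0.15, 0.15, 11)
            else:
                values = t * np.linspace(0.7, 1.3, 11)
            objs = [objective(model, model.params0.replace(**{pname: v}), spec)
                    for v in values]
            assert np.argmin(objs) == 5, f"{name}/{pname}: {objs}"


def test_recovery_under_noise_eight_replicates():
    """SNR 50: median relative error of recovered k_io stays within 5 %."""
    fx = make_fixture("fdg33", FIT_GRID)
    model = fx.model(DEFAULT_FREE_SET)
    errs = []
    for seed in range(8):
        spec, truth = generate_dataset(fx, NoiseModel(snr=50.0, seed=seed))
        res = fit(model, perturbed_start(model, truth, 1.3), spec,
                  FitOptions(max_evals=300))
        errs.append(abs(res.value("k_io[beta]") / truth["k_io[beta]"] - 1.0))
    assert np.median(errs) <= 0.05


# ---------------------------------------------------------------------------
# bootstrap

def test_bootstrap_noiseless_determinism_and_noise_scaling(small_fixture, small_target):
    spec, truth = small_target
    model = small_fixture.model(DEFAULT_FREE_SET)
    base = fit(model, model.params0, spec, FitOptions(max_evals=150))

    res1 = bootstrap(model, base, spec, n_rounds=4, drop_fraction=0.5, seed=11,
                     options=FitOptions(max_evals=300, xtol=1e-3, initial_step=0.02))
    res2 = bootstrap(model, base, spec, n_rounds=4, drop_fraction=0.5, seed=11,
                     options=FitOptions(max_evals=300, xtol=1e-3, initial_step=0.02))
    # noiseless data: dropout changes nothing measurable
    for name in DEFAULT_FREE_SET:
        assert res1.bootstrap_sd[name] <= 1e-3 * max(abs(base.value(name)), 1e-6)
    # fixed seed: bit-identical replicate table
    np.testing.assert_array_equal(res1.bootstrap_replicates, res2.bootstrap_replicates)

    # bootstrap spread grows with the noise level
    sds = []
    for snr in (200.0, 50.0, 12.0):
        speck, truth_k = generate_dataset(small_fixture, NoiseModel(snr=snr, seed=3))
        fitted = fit(model, model.params0, speck, FitOptions(max_evals=200))
        booted = bootstrap(model, fitted, speck, n_rounds=6, drop_fraction=0.5,
                           seed=5, options=FitOptions(max_evals=250, xtol=1e-3,
                                                      initial_step=0.02))
        sds.append(booted.bootstrap_sd["k_io[beta]"])
    assert sds[0] < sds[1] < sds[2]


def test_bootstrap_replicate_spread_stabilises():
    """At 32 rounds the SD estimate is stable across seed groups (< 30 %)."""
    fx = make_fixture("fdg33", {"n1": 16, "n2": 32, "zerofill1": 32, "zerofill2": 64})
    spec, truth = generate_dataset(fx, NoiseModel(snr=50.0, seed=21))
    model = fx.model(DEFAULT_FREE_SET)
    base = fit(model, model.params0, spec, FitOptions(max_evals=200))
    sds = []
    for seed in (1, 2, 3):
        res = bootstrap(model, base, spec, n_rounds=32, drop_fraction=0.5,
                        seed=seed, options=FitOptions(max_evals=250, xtol=1e-3,
                                                      initial_step=0.02))
        sds.append(res.bootstrap_sd["k_io[beta]"])
    sds = np.array(sds)
    assert sds.std(ddof=1) < 0.3 * sds.mean()


def test_bootstrap_argument_validation(small_fixture, small_target):
    spec, _ = small_target
    model = small_fixture.model(DEFAULT_FREE_SET)
    base = fit(model, model.params0, spec, FitOptions(max_evals=50))
    with pytest.raises(ValidationError):
        bootstrap(model, base, spec, n_rounds=1)
    with pytest.raises(ValidationError):
        bootstrap(model, base, spec, drop_fraction=1.5)
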