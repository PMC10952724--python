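import numpy as np
import pytest

from exsy_kinetics.spin_model import (
    AnomerMixture,
    CompartmentAssembly,
    CsaTensor,
    SpectrometerFrame,
    SpinSystem,
)
from exsy_kinetics.kinetics import influx_from_efflux


@pytest.fixture(scope="session")
def frame():
    return SpectrometerFrame(carrier_ppm=-120.0)


def one_spin_system(delta_ppm):
    return SpinSystem(shifts_ppm=(delta_ppm,), j_hz=((0.0,),),
                      coords_angstrom=((0.0, 0.0, 0.0),))


def geminal_pair(shifts=(-118.0, -124.0), j_hz=250.0, with_csa=False):
    csa = (CsaTensor(60.0, 0.3, (0.1, 0.5, 0.9)),
           CsaTensor(55.0, 0.2, (1.0, 0.4, 0.2))) if with_csa else ()
    return SpinSystem(
        shifts_ppm=shifts,
        j_hz=((0.0, j_hz), (j_hz, 0.0)),
        coords_angstrom=((0.0, 1.08, 0.5), (0.0, -1.08, 0.5)),
        csa=csa,
    )


def two_site_assembly(delta_in, delta_out, k_io, pop_in=1.86, pop_out=1.0,
                      tau_in=-9.0, tau_out=-9.3):
    return CompartmentAssembly(
        one_spin_system(delta_in), one_spin_system(delta_out),
        tau_in, tau_out, k_io, influx_from_efflux(k_io, pop_in, pop_out),
        pop_in, pop_out)


def single_anomer(assembly, amplitude=1.0, label="a"):
    return AnomerMixture(((label, assembly, amplitude),))


def box_volume(spec, p1, p2, half1, half2=None):
    """Signed rectangle volume around (F1, F2) = (p1, p2) ppm."""
    half2 = half1 if half2 is None else half2
    m1 = (spec.axis1_ppm >= p1 - half1) & (spec.axis1_ppm <= p1 + half1)
    m2 = (spec.axis2_ppm >= p2 - half2) & (spec.axis2_ppm <= p2 + half2)
    return float(spec.values[np.ix_(m1, m2)].sum() * spec.pixel_area_ppm2())
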