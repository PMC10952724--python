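"""Anatomy of the relaxation pathways that contaminate EXSY integrals.

Prints the Solomon auto/cross relaxation rates of a geminal F-F pair as a
function of rotational correlation time, the NOE zero crossing, and the
partner-spin-flip rate responsible for doublet-component cross-peaks.
"""

import numpy as np

from exsy_kinetics.constants import GAMMA_F19
from exsy_kinetics.relaxation import (RelaxationTheoryConfig, dipolar_constant,
                                      noe_zero_crossing, partner_flip_rate,
                                      solomon_rates)
from exsy_kinetics.spin_model import SpectrometerFrame, SpinSystem

frame = SpectrometerFrame(carrier_ppm=-120.0)
b = dipolar_constant(2.16, GAMMA_F19, GAMMA_F19)
print(f"geminal F-F dipolar constant (r = 2.16 A): b = {b:.0f} rad/s")

tc_cross = noe_zero_crossing(frame.larmor_hz)
print(f"NOE zero crossing at 376.46 MHz: tau_c = {tc_cross:.3e} s "
      f"(log10 = {np.log10(tc_cross):.2f}; w0*tau_c = "
      f"{frame.omega0_rad_s * tc_cross:.4f})\n")

print(f"{'log10 tau_c':>12s} {'rho (auto)':>12s} {'sigma (NOE)':>12s} {'W1 (flip)':>12s}")
pair = SpinSystem(shifts_ppm=(-120.0, -120.0),
                  j_hz=((0.0, 250.0), (250.0, 0.0)),
                  coords_angstrom=((0.0, 1.08, 0.5), (0.0, -1.08, 0.5)))
for logtc in (-10.0, -9.5, -9.33, -9.0, -8.5):
    tau = 10.0 ** logtc
    rho, sigma = solomon_rates(b, tau, frame.omega0_rad_s)
    w1 = partner_flip_rate(pair, tau, frame,
                           config=RelaxationTheoryConfig(tau_c_s=tau,
                                                         include_csa=False))
    print(f"{logtc:12.2f} {rho:12.3f} {sigma:12.3f} {w1:12.3f}")

print("\nrates in /s.  sigma changes sign near log10(tau_c) = -9.33: NOE")
print("cross-peaks flip sign between the viscous cell interior (slow")
print("tumbling, sigma < 0) and the suspension medium (fast tumbling).")
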