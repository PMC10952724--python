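"""Direct least-squares fit of a simulated 2D EXSY spectrum.

Generates a noiseless reduced-grid spectrum of the difluorinated fixture,
then recovers the anomer-specific efflux rate constants and the two
compartment rotational correlation times by Frobenius-norm Nelder-Mead
fitting, starting all four free parameters 50 % away from truth.
"""

import numpy as np

from exsy_kinetics.fitting import FitOptions
from exsy_kinetics.protocols import recovery_protocol

result, truth = recovery_protocol(
    "fdg33", {"n1": 64, "n2": 128, "zerofill1": 128, "zerofill2": 256},
    options=FitOptions(max_evals=400))

print(f"converged: {result.converged} after {result.n_evals} evaluations; "
      f"residual norm^2 = {result.objective:.3e}\n")
print(f"{'parameter':22s} {'recovered':>12s} {'truth':>12s}")
for name in ("k_io[alpha]", "k_io[beta]", "tau_c_in_log10", "tau_c_out_log10"):
    print(f"{name:22s} {result.value(name):12.4f} {truth[name]:12.4f}")
print("\nrates are in /s; correlation times as log10 of seconds.")
print("On noiseless data the fit recovers the generating values almost exactly.")
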