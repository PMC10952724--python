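"""Two-compartment translocation kinetics in Liouville space.

Exchange across the membrane moves whole molecules, so it acts identically
on every spin-space coordinate: the generator is the 2x2 first-order
kinetic matrix tensored with the identity on the spin Liouville space.
States are amount-weighted (populations carried in the state), which makes
the kinetic matrix's columns sum to zero — total amount is conserved
exactly — and makes 2D peak volumes directly proportional to compartment
amounts.
"""

from __future__ import annotations

import numpy as np

from .errors import DimensionError, ValidationError
from .relaxation import RelaxationTheoryConfig, redfield_superoperator
from .spin_model import (
    CompartmentAssembly,
    SpectrometerFrame,
    build_hamiltonian,
    commutation_superoperator,
    pauli_operators,
)

__all__ = [
    "kinetic_matrix",
    "exchange_superoperator",
    "influx_from_efflux",
    "assemble_liouvillian",
    "build_full_liouvillian",
]


def kinetic_matrix(k_io: float, k_oi: float) -> np.ndarray:
    """Compartment kinetic matrix [[-k_io, k_oi], [k_io, -k_oi]] (site order in, out)."""
    if k_io < 0 or k_oi < 0:
        raise ValidationError("rate constants must be non-negative")
    return np.array([[-k_io, k_oi], [k_io, -k_oi]], dtype=float)


def exchange_superoperator(k_io: float, k_oi: float, block_dim: int) -> np.ndarray:
    """Exchange generator K = kinetic_matrix (x) I_block_dim.

    Acts identically on every spin-space coordinate, conserves total amount
    (columns of the compartment factor sum to zero) and, for positive rates,
    has the unique stationary compartment distribution proportional to
    (k_oi, k_io).
    """
    if block_dim < 1:
        raise DimensionError("block_dim must be >= 1")
    return np.kron(kinetic_matrix(k_io, k_oi), np.eye(block_dim))


def influx_from_efflux(k_io: float, pop_in: float, pop_out: float) -> float:
    """Detailed-balance influx rate k_oi = k_io * pop_in / pop_out.

    The efflux rate constant is an intrinsic property of the transporter,
    while the apparent influx rate scales with the compartment amount ratio
    (haematocrit) at equilibrium.
    """
    if pop_out <= 0:
        raise ValidationError("pop_out must be positive")
    if k_io < 0:
        raise ValidationError("k_io must be non-negative")
    return k_io * pop_in / pop_out


def assemble_liouvillian(assembly: CompartmentAssembly,
                         r_in: np.ndarray, r_out: np.ndarray,
                         h_in: np.ndarray, h_out: np.ndarray) -> np.ndarray:
    """Full magnetokinetic generator L = -i H^ + R + K over stacked compartments.

    Block structure::

        [[-i H^_in + R_in - k_io I,              k_oi I],
         [              k_io I,  -i H^_out + R_out - k_oi I]]

    L annihilates the equilibrium deviation state (which is zero) and, more
    usefully, the amount-weighted equilibrium z-order under the detailed
    balance constraint.
    """
    dl = r_in.shape[0]
    ih_in = commutation_superoperator(h_in)
    ih_out = commutation_superoperator(h_out)
    for mat, name in ((r_in, "R_in"), (r_out, "R_out"), (ih_in, "H_in"), (ih_out, "H_out")):
        if mat.shape != (dl, dl):
            raise DimensionError(f"{name} has shape {mat.shape}, expected {(dl, dl)}")
    k_io, k_oi = assembly.k_io_per_s, assembly.k_oi_per_s
    eye = np.eye(dl)
    top = np.hstack([ih_in + r_in - k_io * eye, k_oi * eye])
    bot = np.hstack([k_io * eye, ih_out + r_out - k_oi * eye])
    return np.vstack([top, bot]).astype(complex)


def build_full_liouvillian(assembly: CompartmentAssembly, frame: SpectrometerFrame,
                           relax: RelaxationTheoryConfig | None = None) -> np.ndarray:
    """Convenience: Hamiltonians + Redfield + exchange for one anomer.

    ``relax`` supplies the Redfield switches; its correlation time is
    overridden per compartment by the assembly's tau_c values.  ``None``
    disables relaxation entirely.
    """
    ops = pauli_operators(assembly.n_spins)
    h_in = build_hamiltonian(assembly.system_in, frame, ops)
    h_out = build_hamiltonian(assembly.system_out, frame, ops)
    dl = ops.dim ** 2
    if relax is None:
        r_in = np.zeros((dl, dl), dtype=complex)
        r_out = np.zeros((dl, dl), dtype=complex)
    else:
        r_in = redfield_superoperator(assembly.system_in, frame,
                                      relax.with_tau(assembly.tau_c_in_s))
        r_out = redfield_superoperator(assembly.system_out, frame,
                                       relax.with_tau(assembly.tau_c_out_s))
    return assemble_liouvillian(assembly, r_in, r_out, h_in, h_out)
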