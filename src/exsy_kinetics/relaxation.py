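"""Redfield relaxation superoperator for isotropic rotational diffusion.

Builds the semi-classical (Bloch-Wangsness-Redfield) relaxation
superoperator from rank-2 spherical-tensor decompositions of every
dipole-dipole and CSA interaction in the spin system, including all
auto- and cross-correlations (DD-DD, CSA-CSA and DD-CSA interference).
Spectral densities follow the reduced convention

    j(omega) = tau_c / (1 + (omega tau_c)^2)    [seconds],

so closed-form oracles such as the Solomon rates
``rho = (b^2/10) (j(0) + 3 j(w0) + 6 j(2 w0))`` and the CSA rate
``R1 = (2/15) (dsigma w0)^2 (1 + eta^2/3) j(w0)`` hold with no hidden
prefactors.

The superoperator is assembled in the eigenbasis of the lab-frame static
Hamiltonian (Zeeman + offsets + J), secularised there, Hermitised, and
transformed back to the product basis.  The secular filter drops elements
connecting coherences whose eigenfrequencies differ by more than a cutoff;
the zero-quantum/longitudinal block is always kept intact because its
internal couplings generate the NOE and partner-flip mixing-time effects
this package exists to model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .constants import MU0_OVER_4PI, HBAR
from .errors import DimensionError, ValidationError
from .spin_model import (
    SpinOperators,
    SpinSystem,
    SpectrometerFrame,
    build_hamiltonian,
    pauli_operators,
)
from .liouville import basis_quantum_numbers

__all__ = [
    "RelaxationTheoryConfig",
    "spectral_density",
    "dipolar_constant",
    "redfield_superoperator",
    "noe_zero_crossing",
    "solomon_rates",
    "partner_flip_rate",
    "longitudinal_block",
]


@dataclass(frozen=True)
class RelaxationTheoryConfig:
    """Switches and scales of the Redfield treatment.

    Attributes
    ----------
    tau_c_s:
        Rotational correlation time, seconds.
    include_dd, include_csa, include_cross_correlations:
        Interaction switches.  With cross-correlations off only
        auto-correlated (a == a) terms are kept.
    secular_cutoff_rad_s:
        Eigenfrequency gap above which superoperator elements are dropped.
        The zero-quantum/longitudinal block is always retained whole.
    r1_ext_per_s, r2_ext_per_s:
        Optional isotropic random-field rates added to the diagonal,
        modelling relaxation sources outside the explicit spin system
        (e.g. remote protons).  Default 0.
    """

    tau_c_s: float
    include_dd: bool = True
    include_csa: bool = True
    include_cross_correlations: bool = True
    secular_cutoff_rad_s: float = 1e3
    r1_ext_per_s: float = 0.0
    r2_ext_per_s: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.tau_c_s) and self.tau_c_s > 0):
            raise ValidationError("tau_c_s must be positive and finite")
        if self.secular_cutoff_rad_s < 0:
            raise ValidationError("secular cutoff must be >= 0")
        if self.r1_ext_per_s < 0 or self.r2_ext_per_s < 0:
            raise ValidationError("external random-field rates must be >= 0")

    def with_tau(self, tau_c_s: float) -> "RelaxationTheoryConfig":
        return replace(self, tau_c_s=tau_c_s)


def spectral_density(omega_rad_s, tau_c_s: float):
    """Reduced spectral density j(omega) = tau_c / (1 + (omega tau_c)^2), s."""
    x = np.asarray(omega_rad_s, dtype=float) * tau_c_s
    return tau_c_s / (1.0 + x * x)


def dipolar_constant(r_angstrom: float, gamma1: float, gamma2: float) -> float:
    """Dipole-dipole coupling constant b = -(mu0/4pi) gamma1 gamma2 hbar / r^3, rad/s."""
    if not (np.isfinite(r_angstrom) and r_angstrom > 0):
        raise ValidationError("internuclear distance must be positive")
    r_m = r_angstrom * 1e-10
    return -MU0_OVER_4PI * gamma1 * gamma2 * HBAR / r_m ** 3


# ---------------------------------------------------------------------------
# spatial tensors: Cartesian (symmetric traceless) -> rank-2 spherical

def _spherical_components(a: np.ndarray) -> np.ndarray:
    """Spherical components (q = -2..+2) of a symmetric traceless 3x3 tensor.

    Normalisation: a_{2,0} = sqrt(3/2) A_zz, a_{2,+-1} = -+(A_xz +- i A_yz),
    a_{2,+-2} = (A_xx - A_yy +- 2 i A_xy)/2, chosen so that together with the
    spin tensors below the closed-form relaxation rates hold exactly.
    """
    out = np.empty(5, dtype=complex)
    out[2 + 0] = np.sqrt(1.5) * a[2, 2]
    out[2 + 1] = -(a[0, 2] + 1j * a[1, 2])
    out[2 - 1] = +(a[0, 2] - 1j * a[1, 2])
    out[2 + 2] = 0.5 * (a[0, 0] - a[1, 1] + 2j * a[0, 1])
    out[2 - 2] = 0.5 * (a[0, 0] - a[1, 1] - 2j * a[0, 1])
    return out


def _dd_cartesian(coords: np.ndarray, i: int, j: int, gamma: float) -> np.ndarray:
    rvec = coords[j] - coords[i]
    r = np.linalg.norm(rvec)
    b = dipolar_constant(r, gamma, gamma)
    e = rvec / r
    return b * (3.0 * np.outer(e, e) - np.eye(3))


def _csa_cartesian(csa, omega0_rad_s: float) -> np.ndarray:
    # Haeberlen: axiality dsigma = sigma_zz - (sigma_xx+sigma_yy)/2 = (3/2) zeta.
    zeta = (2.0 / 3.0) * csa.delta_sigma_ppm * 1e-6 * omega0_rad_s
    pas = np.diag([zeta * (csa.eta - 1.0) / 2.0, -zeta * (csa.eta + 1.0) / 2.0, zeta])
    rot = Rotation.from_euler("ZYZ", csa.euler_rad).as_matrix()
    return rot @ pas @ rot.T


# ---------------------------------------------------------------------------
# spin tensors (rank-2 irreducible, m = -2..+2) as lists of 2**n matrices

def _dd_spin_tensors(ops: SpinOperators, i: int, j: int) -> list:
    iz, jz = ops.z[i], ops.z[j]
    ip, im = ops.p[i], ops.m[i]
    jp, jm = ops.p[j], ops.m[j]
    t = [None] * 5
    t[2 + 0] = np.sqrt(2.0 / 3.0) * iz @ jz - (ip @ jm + im @ jp) / (2.0 * np.sqrt(6.0))
    t[2 + 1] = -0.5 * (iz @ jp + ip @ jz)
    t[2 - 1] = +0.5 * (iz @ jm + im @ jz)
    t[2 + 2] = 0.5 * ip @ jp
    t[2 - 2] = 0.5 * im @ jm
    return t


def _csa_spin_tensors(ops: SpinOperators, i: int) -> list:
    zero = np.zeros_like(ops.z[i])
    t = [None] * 5
    t[2 + 0] = np.sqrt(2.0 / 3.0) * ops.z[i]
    t[2 + 1] = -0.5 * ops.p[i]
    t[2 - 1] = +0.5 * ops.m[i]
    t[2 + 2] = zero
    t[2 - 2] = zero
    return t


def _interactions(system: SpinSystem, frame: SpectrometerFrame,
                  config: RelaxationTheoryConfig, ops: SpinOperators) -> list:
    """List of (spherical spatial components, spin tensor list) pairs."""
    out = []
    coords = system.coords
    if config.include_dd and system.n_spins > 1:
        if coords.shape[0] != system.n_spins:
            raise DimensionError("geometry required for dipolar relaxation")
        for i in range(system.n_spins):
            for j in range(i + 1, system.n_spins):
                cart = _dd_cartesian(coords, i, j, system.gamma)
                out.append((_spherical_components(cart), _dd_spin_tensors(ops, i, j)))
    if config.include_csa:
        if len(system.csa) != system.n_spins:
            raise DimensionError("CSA tensors required for CSA relaxation")
        for i, csa in enumerate(system.csa):
            if csa.delta_sigma_ppm == 0.0:
                continue
            cart = _csa_cartesian(csa, frame.omega0_rad_s)
            out.append((_spherical_components(cart), _csa_spin_tensors(ops, i)))
    return out


def _lab_frame_eigensystem(system: SpinSystem, frame: SpectrometerFrame,
                           ops: SpinOperators):
    """Eigenbasis of H0 = omega0 sum Lz + rotating-frame H, resolved by M.

    Diagonalising within each total-M sector keeps eigenvectors at a sharp
    magnetic quantum number even in the presence of accidental degeneracies,
    which the coherence-order bookkeeping of the secular filter relies on.
    """
    h_rot = build_hamiltonian(system, frame, ops)
    h_lab = h_rot + frame.omega0_rad_s * ops.total("z")
    m = basis_quantum_numbers(system.n_spins)
    dim = ops.dim
    energies = np.empty(dim)
    vectors = np.zeros((dim, dim), dtype=complex)
    for mval in np.unique(m):
        ix = np.nonzero(m == mval)[0]
        w, v = scipy.linalg.eigh(h_lab[np.ix_(ix, ix)])
        energies[ix] = w
        vectors[np.ix_(ix, ix)] = v
    return energies, vectors, m


def redfield_superoperator(system: SpinSystem, frame: SpectrometerFrame,
                           config: RelaxationTheoryConfig) -> np.ndarray:
    """Relaxation superoperator R (rad/s) acting on the deviation state.

    R is real on the longitudinal subspace, Hermitian in the Hilbert-Schmidt
    inner product, and dissipative; it drives the deviation from thermal
    equilibrium to zero (thermalisation is handled by propagating the
    deviation, which is exact in the high-temperature limit).
    """
    ops = pauli_operators(system.n_spins)
    dim = ops.dim
    dl = dim * dim
    interactions = _interactions(system, frame, config, ops)
    if not interactions:
        r_site = np.zeros((dl, dl), dtype=complex)
        return _add_external(r_site, ops, config)

    energies, v, m = _lab_frame_eigensystem(system, frame, ops)
    omega = energies[:, None] - energies[None, :]          # omega_{alpha beta}
    jmat = spectral_density(omega, config.tau_c_s)

    # spin tensors in the H0 eigenbasis
    eig_tensors = []
    for sph, tset in interactions:
        eig_tensors.append((sph, [v.conj().T @ t @ v for t in tset]))

    eye = np.eye(dim)

    def _kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # fast 2D Kronecker product (avoids numpy.kron's per-call overhead)
        return (a[:, None, :, None] * b[None, :, None, :]).reshape(dim * dim, dim * dim)

    def commutator_product(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # C[a] @ C[b] for column-major vectorisation, via four Kronecker terms
        ab = a @ b
        ba = b @ a
        return (_kron(eye, ab) + _kron(ba.T, eye)
                - _kron(b.T, a) - _kron(a.T, b))

    r_eig = np.zeros((dl, dl), dtype=complex)
    if config.include_cross_correlations:
        # factor the interaction double sum over the molecular-frame
        # spherical index q: g_ab = (1/5) sum_q a^a_q conj(a^b_q)
        for mi in range(5):
            for q in range(5):
                a_mq = sum(sph[q] * tset[mi] for sph, tset in eig_tensors)
                if not np.any(a_mq):
                    continue
                b_mq = jmat * a_mq.conj().T
                r_eig -= 0.2 * commutator_product(a_mq, b_mq)
    else:
        for sph, tset in eig_tensors:
            g_aa = 0.2 * float(np.sum(np.abs(sph) ** 2))
            for mi in range(5):
                t = tset[mi]
                if not np.any(t):
                    continue
                lam = jmat * t.conj().T
                r_eig -= g_aa * commutator_product(t, lam)

    # secular filter in the eigenbasis: element (ab),(cd) survives if the
    # eigenfrequency gap is below the cutoff, or both sit in the p = 0 block
    p = (m[:, None] - m[None, :]).reshape(-1, order="F")
    omega_l = omega.reshape(-1, order="F")
    gap = np.abs(omega_l[:, None] - omega_l[None, :])
    keep = gap <= config.secular_cutoff_rad_s
    zq = p == 0
    keep |= zq[:, None] & zq[None, :]
    r_eig *= keep

    # semi-classical R is self-adjoint; enforce exactly
    r_eig = 0.5 * (r_eig + r_eig.conj().T)

    # back to the product basis: rho_site = V rho_eig V^dagger
    w = np.kron(v.conj(), v)
    r_site = w @ r_eig @ w.conj().T
    return _add_external(r_site, ops, config)


def _add_external(r_site: np.ndarray, ops: SpinOperators,
                  config: RelaxationTheoryConfig) -> np.ndarray:
    """Phenomenological random-field rates on the Liouville diagonal."""
    if config.r1_ext_per_s == 0.0 and config.r2_ext_per_s == 0.0:
        return r_site
    dim = ops.dim
    i_idx, j_idx = np.meshgrid(np.arange(dim), np.arange(dim), indexing="ij")
    diagonal = (i_idx == j_idx).reshape(-1, order="F")
    rates = np.where(diagonal, config.r1_ext_per_s, config.r2_ext_per_s)
    return r_site - np.diag(rates.astype(complex))


# ---------------------------------------------------------------------------
# closed-form diagnostics

def solomon_rates(b_rad_s: float, tau_c_s: float, omega0_rad_s: float) -> tuple:
    """Solomon auto- and cross-relaxation rates of a like-spin dipolar pair.

    Returns (rho_auto, sigma_cross) in the reduced-spectral-density
    convention of this module.
    """
    j0 = spectral_density(0.0, tau_c_s)
    j1 = spectral_density(omega0_rad_s, tau_c_s)
    j2 = spectral_density(2.0 * omega0_rad_s, tau_c_s)
    rho = (b_rad_s ** 2 / 10.0) * (j0 + 3.0 * j1 + 6.0 * j2)
    sigma = (b_rad_s ** 2 / 10.0) * (6.0 * j2 - j0)
    return rho, sigma


def noe_zero_crossing(larmor_hz: float) -> float:
    """Correlation time at which the homonuclear NOE changes sign.

    Solves 6 j(2 w0) = j(0) by root bracketing; the crossing satisfies
    w0 tau_c = sqrt(5)/2.
    """
    if larmor_hz <= 0:
        raise ValidationError("larmor_hz must be positive")
    w0 = 2.0 * np.pi * larmor_hz

    def sigma(tau):
        return 6.0 * spectral_density(2.0 * w0, tau) - spectral_density(0.0, tau)

    return brentq(sigma, 1e-15 / (w0 * 1e-9), 1e3 / w0, xtol=1e-18, rtol=1e-12)


def longitudinal_block(r_site: np.ndarray, ops: SpinOperators) -> np.ndarray:
    """Project R onto the per-spin longitudinal (Liz) subspace.

    Returns the n x n matrix B with d<Liz>/dt = sum_j B_ij <Ljz> for the
    deviation state; for a two-spin dipolar pair -B equals the Solomon
    matrix [[rho1, sigma], [sigma, rho2]].
    """
    n = ops.n_spins
    basis = np.stack([ops.z[i].reshape(-1, order="F") for i in range(n)], axis=1)
    norms = np.real(np.sum(basis.conj() * basis, axis=0))
    proj = basis.conj().T @ r_site @ basis
    return np.real(proj / norms[:, None])


def partner_flip_rate(system: SpinSystem, tau_c_s: float,
                      frame: SpectrometerFrame | None = None,
                      spin: int = 0, partner: int = 1,
                      config: RelaxationTheoryConfig | None = None) -> float:
    """Single-partner-spin-flip longitudinal rate (W1 transition probability).

    This is the population rate that connects the two components of spin
    ``spin``'s J-doublet via a flip of ``partner`` during the mixing time,
    producing the intra-compartment doublet-component cross-peaks.  For an
    isolated dipolar pair it equals the Solomon single-quantum rate
    W1 = (3/20) b^2 j(w0).
    """
    if system.n_spins < 2:
        raise DimensionError("partner flips require at least two spins")
    frame = frame or SpectrometerFrame()
    config = (config or RelaxationTheoryConfig(tau_c_s=tau_c_s)).with_tau(tau_c_s)
    ops = pauli_operators(system.n_spins)
    r = redfield_superoperator(system, frame, config)
    dim = ops.dim
    # population Liouville index of basis state k is k * (dim + 1)
    rates = []
    for s_state in (0, 1):
        bits_a = [0] * system.n_spins
        bits_a[spin] = s_state
        bits_b = list(bits_a)
        bits_b[partner] = 1
        ka = sum(b << (system.n_spins - 1 - i) for i, b in enumerate(bits_a))
        kb = sum(b << (system.n_spins - 1 - i) for i, b in enumerate(bits_b))
        rates.append(np.real(r[ka * (dim + 1), kb * (dim + 1)]))
    return float(np.mean(rates))
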