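"""Spin-system and compartment data types, Hilbert-space operators and
Liouville-space coherent generators.

The model targets small homonuclear 19F spin systems (n <= 6 spins, in
practice 2 or 4) that exist in two copies — one per membrane compartment —
with compartment-dependent chemical shifts and rotational correlation
times.  States live in Liouville space as column-major vectorised density
matrices of dimension 4**n per compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import DEFAULT_F19_LARMOR_HZ, GAMMA_F19
from .errors import DimensionError, ValidationError

__all__ = [
    "CsaTensor",
    "SpinSystem",
    "CompartmentAssembly",
    "AnomerMixture",
    "SpectrometerFrame",
    "SpinOperators",
    "pauli_operators",
    "build_hamiltonian",
    "commutation_superoperator",
    "vec",
    "unvec",
    "left_superoperator",
    "right_superoperator",
    "rotation_sandwich_superoperator",
    "detection_state",
    "thermal_equilibrium",
]

MAX_SPINS = 6


# ---------------------------------------------------------------------------
# vectorisation helpers (column-major convention throughout)

def vec(rho: np.ndarray) -> np.ndarray:
    """Column-major vectorisation of a square matrix."""
    return np.asarray(rho).reshape(-1, order="F")


def unvec(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vec`."""
    v = np.asarray(v)
    n = int(round(np.sqrt(v.size)))
    if n * n != v.size:
        raise DimensionError(f"vector of length {v.size} is not a vectorised square matrix")
    return v.reshape((n, n), order="F")


def left_superoperator(a: np.ndarray) -> np.ndarray:
    """Superoperator of left multiplication, vec(A rho) = (I (x) A) vec(rho)."""
    a = np.asarray(a)
    return np.kron(np.eye(a.shape[0]), a)


def right_superoperator(b: np.ndarray) -> np.ndarray:
    """Superoperator of right multiplication, vec(rho B) = (B^T (x) I) vec(rho)."""
    b = np.asarray(b)
    return np.kron(b.T, np.eye(b.shape[0]))


def commutator_superoperator(x: np.ndarray) -> np.ndarray:
    """Superoperator of [X, .] (no -i factor)."""
    x = np.asarray(x)
    eye = np.eye(x.shape[0])
    return np.kron(eye, x) - np.kron(x.T, eye)


def commutation_superoperator(h: np.ndarray) -> np.ndarray:
    """Liouville-space generator of coherent evolution, -i[H, .].

    Acting on a column-major vectorised density matrix this reproduces
    ``-1j * (H @ rho - rho @ H)``.
    """
    h = np.asarray(h)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise DimensionError("Hamiltonian must be a square matrix")
    if not np.allclose(h, h.conj().T, atol=1e-10 * max(1.0, np.abs(h).max())):
        raise ValidationError("Hamiltonian must be Hermitian")
    return -1j * commutator_superoperator(h)


def rotation_sandwich_superoperator(u: np.ndarray) -> np.ndarray:
    """Superoperator of rho -> U rho U^dagger for unitary U (column-major vec)."""
    u = np.asarray(u)
    return np.kron(u.conj(), u)


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class CsaTensor:
    """Chemical-shift anisotropy of one spin.

    Parameters
    ----------
    delta_sigma_ppm:
        Axiality of the shielding tensor, ``sigma_zz - (sigma_xx + sigma_yy)/2``
        in ppm (Haeberlen convention).
    eta:
        Asymmetry parameter in [0, 1].
    euler_rad:
        zyz Euler angles (alpha, beta, gamma) of the tensor principal axis
        frame in the molecular frame, radians.
    """

    delta_sigma_ppm: float = 0.0
    eta: float = 0.0
    euler_rad: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not np.isfinite(self.delta_sigma_ppm):
            raise ValidationError("CSA axiality must be finite")
        if not (0.0 <= self.eta <= 1.0):
            raise ValidationError(f"CSA asymmetry eta must be in [0, 1], got {self.eta}")
        if len(self.euler_rad) != 3 or not np.all(np.isfinite(self.euler_rad)):
            raise ValidationError("CSA Euler angles must be three finite numbers")


@dataclass(frozen=True)
class SpinSystem:
    """A set of spin-1/2 19F nuclei: shifts, scalar couplings, geometry, CSA.

    Attributes
    ----------
    shifts_ppm:
        Isotropic chemical shift of each spin, ppm.
    j_hz:
        Symmetric scalar-coupling matrix with zero diagonal, Hz.
    coords_angstrom:
        Cartesian positions, Angstrom; used to build dipolar tensors.
    csa:
        Per-spin :class:`CsaTensor`.
    """

    shifts_ppm: tuple
    j_hz: tuple
    coords_angstrom: tuple
    csa: tuple = ()
    gamma: float = GAMMA_F19

    def __post_init__(self):
        shifts = np.asarray(self.shifts_ppm, dtype=float)
        j = np.asarray(self.j_hz, dtype=float)
        xyz = np.asarray(self.coords_angstrom, dtype=float)
        n = shifts.size
        if not 1 <= n <= MAX_SPINS:
            raise DimensionError(f"n_spins must be in [1, {MAX_SPINS}], got {n}")
        if j.shape != (n, n):
            raise DimensionError(f"J matrix must be {n}x{n}, got {j.shape}")
        if xyz.shape != (n, 3):
            raise DimensionError(f"coordinates must be {n}x3, got {xyz.shape}")
        if not (np.all(np.isfinite(shifts)) and np.all(np.isfinite(j)) and np.all(np.isfinite(xyz))):
            raise ValidationError("all numeric fields must be finite")
        if not np.allclose(j, j.T, atol=1e-12 * max(1.0, np.abs(j).max())):
            raise ValidationError("J-coupling matrix must be symmetric")
        if np.any(np.abs(np.diag(j)) > 0):
            raise ValidationError("J-coupling matrix must have zero diagonal")
        if n > 1:
            d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() <= 1.0:
                raise ValidationError(
                    f"pairwise internuclear distances must exceed 1 Angstrom (min {d.min():.3f})"
                )
        csa = tuple(self.csa) if self.csa else tuple(CsaTensor() for _ in range(n))
        if len(csa) != n:
            raise DimensionError(f"need {n} CSA tensors, got {len(csa)}")
        # normalise to immutable containers
        object.__setattr__(self, "shifts_ppm", tuple(shifts.tolist()))
        object.__setattr__(self, "j_hz", tuple(map(tuple, j.tolist())))
        object.__setattr__(self, "coords_angstrom", tuple(map(tuple, xyz.tolist())))
        object.__setattr__(self, "csa", csa)

    @property
    def n_spins(self) -> int:
        return len(self.shifts_ppm)

    @property
    def shifts(self) -> np.ndarray:
        return np.asarray(self.shifts_ppm, dtype=float)

    @property
    def j(self) -> np.ndarray:
        return np.asarray(self.j_hz, dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.coords_angstrom, dtype=float)

    def with_shifts(self, shifts_ppm: Sequence[float]) -> "SpinSystem":
        return replace(self, shifts_ppm=tuple(float(s) for s in shifts_ppm))


@dataclass(frozen=True)
class SpectrometerFrame:
    """Rotating-frame reference: 19F transmitter frequency and carrier."""

    larmor_hz: float = DEFAULT_F19_LARMOR_HZ
    carrier_ppm: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.larmor_hz) and self.larmor_hz > 0):
            raise ValidationError("larmor_hz must be positive and finite")

    def offset_rad_s(self, shift_ppm) -> np.ndarray:
        """Rotating-frame offset 2 pi nu0 (delta - carrier) 1e-6, rad/s."""
        return 2.0 * np.pi * self.larmor_hz * (np.asarray(shift_ppm, dtype=float) - self.carrier_ppm) * 1e-6

    def ppm_from_offset_hz(self, freq_hz) -> np.ndarray:
        return self.carrier_ppm + np.asarray(freq_hz, dtype=float) / (self.larmor_hz * 1e-6)

    @property
    def omega0_rad_s(self) -> float:
        """Magnitude of the Larmor angular frequency, rad/s."""
        return 2.0 * np.pi * self.larmor_hz


@dataclass(frozen=True)
class CompartmentAssembly:
    """Inside/outside variants of one anomer's spin system plus kinetics.

    ``tau_c`` values are stored as log10 of seconds (they span orders of
    magnitude and are fitted on a log scale).  Populations are equilibrium
    amounts in arbitrary units; with the equilibrium constraint enabled the
    influx rate follows from detailed balance,
    ``k_oi = k_io * pop_in / pop_out``.
    """

    system_in: SpinSystem
    system_out: SpinSystem
    tau_c_in_log10: float
    tau_c_out_log10: float
    k_io_per_s: float
    k_oi_per_s: float
    pop_in: float = 1.0
    pop_out: float = 1.0
    equilibrium_constraint: bool = True

    def __post_init__(self):
        if self.system_in.n_spins != self.system_out.n_spins:
            raise DimensionError("inside and outside systems must have equal n_spins")
        if not np.allclose(self.system_in.j, self.system_out.j):
            raise ValidationError("inside and outside systems must share the J matrix")
        for name in ("tau_c_in_log10", "tau_c_out_log10", "k_io_per_s", "k_oi_per_s",
                     "pop_in", "pop_out"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if self.k_io_per_s < 0 or self.k_oi_per_s < 0:
            raise ValidationError("rate constants must be non-negative")
        if self.pop_in <= 0 or self.pop_out <= 0:
            raise ValidationError("populations must be positive")
        if self.equilibrium_constraint:
            flux_in = self.k_io_per_s * self.pop_in
            flux_out = self.k_oi_per_s * self.pop_out
            if abs(flux_in - flux_out) > 1e-10 * max(flux_in, 1.0):
                raise ValidationError(
                    "equilibrium constraint violated: k_io*pop_in != k_oi*pop_out "
                    f"({flux_in:.6g} vs {flux_out:.6g})"
                )

    @property
    def n_spins(self) -> int:
        return self.system_in.n_spins

    @property
    def tau_c_in_s(self) -> float:
        return 10.0 ** self.tau_c_in_log10

    @property
    def tau_c_out_s(self) -> float:
        return 10.0 ** self.tau_c_out_log10


@dataclass(frozen=True)
class AnomerMixture:
    """Independent anomers (alpha/beta) sharing a spectrum.

    Each entry is (label, :class:`CompartmentAssembly`, amplitude).  Anomers
    do not interconvert on the experimental timescale, so each is simulated
    in its own Liouville space and the signals are summed.
    """

    anomers: tuple

    def __post_init__(self):
        if not self.anomers:
            raise ValidationError("mixture must contain at least one anomer")
        norm = []
        labels = set()
        for entry in self.anomers:
            label, assembly, amplitude = entry
            if label in labels:
                raise ValidationError(f"duplicate anomer label {label!r}")
            labels.add(label)
            if not (np.isfinite(amplitude) and amplitude >= 0):
                raise ValidationError("anomer amplitudes must be finite and >= 0")
            if not isinstance(assembly, CompartmentAssembly):
                raise ValidationError("mixture entries must hold CompartmentAssembly objects")
            norm.append((str(label), assembly, float(amplitude)))
        object.__setattr__(self, "anomers", tuple(norm))

    @property
    def labels(self):
        return tuple(label for label, _, _ in self.anomers)

    def assembly(self, label: str) -> CompartmentAssembly:
        for lab, assembly, _ in self.anomers:
            if lab == label:
                return assembly
        raise KeyError(label)

    def amplitude(self, label: str) -> float:
        for lab, _, amp in self.anomers:
            if lab == label:
                return amp
        raise KeyError(label)


# ---------------------------------------------------------------------------
# operator construction

@dataclass(frozen=True)
class SpinOperators:
    """Per-spin x/y/z/+/- operators in the 2**n product Hilbert space."""

    n_spins: int
    x: tuple
    y: tuple
    z: tuple
    p: tuple
    m: tuple

    @property
    def dim(self) -> int:
        return 2 ** self.n_spins

    def total(self, axis: str) -> np.ndarray:
        comps = getattr(self, axis)
        return np.sum(comps, axis=0)


_SIGMA = {
    "x": np.array([[0.0, 0.5], [0.5, 0.0]], dtype=complex),
    "y": np.array([[0.0, -0.5j], [0.5j, 0.0]], dtype=complex),
    "z": np.array([[0.5, 0.0], [0.0, -0.5]], dtype=complex),
    "p": np.array([[0.0, 1.0], [0.0, 0.0]], dtype=complex),
    "m": np.array([[0.0, 0.0], [1.0, 0.0]], dtype=complex),
}


import functools


@functools.lru_cache(maxsize=None)
def pauli_operators(n_spins: int) -> SpinOperators:
    """Build spin-1/2 operators for each spin embedded in the 2**n space.

    Spin ``i`` occupies the i-th Kronecker factor counted from the left, so
    basis index bits read spin 0 first.  Operators satisfy
    ``[Lz, L+-] = +-L+-`` and x, y, z are Hermitian.
    """
    if not isinstance(n_spins, (int, np.integer)) or not 1 <= n_spins <= MAX_SPINS:
        raise DimensionError(f"n_spins must be an integer in [1, {MAX_SPINS}], got {n_spins}")
    ops = {k: [] for k in _SIGMA}
    for i in range(n_spins):
        for key, sigma in _SIGMA.items():
            op = np.eye(1, dtype=complex)
            for j in range(n_spins):
                op = np.kron(op, sigma if j == i else np.eye(2, dtype=complex))
            ops[key].append(op)
    return SpinOperators(
        n_spins=int(n_spins),
        x=tuple(ops["x"]),
        y=tuple(ops["y"]),
        z=tuple(ops["z"]),
        p=tuple(ops["p"]),
        m=tuple(ops["m"]),
    )


def build_hamiltonian(system: SpinSystem, frame: SpectrometerFrame,
                      ops: SpinOperators | None = None) -> np.ndarray:
    """Rotating-frame isotropic Hamiltonian, rad/s.

    ``H = sum_i Omega_i Liz + sum_{i<j} 2 pi J_ij (Li . Lj)`` with offsets
    ``Omega_i = 2 pi nu0 (delta_i - carrier) 1e-6``.  The full isotropic
    scalar coupling is kept — no weak-coupling truncation — so strong-coupling
    (AB) effects are exact.
    """
    ops = ops or pauli_operators(system.n_spins)
    offsets = frame.offset_rad_s(system.shifts)
    h = np.zeros((ops.dim, ops.dim), dtype=complex)
    for i in range(system.n_spins):
        h += offsets[i] * ops.z[i]
    j = system.j
    for i in range(system.n_spins):
        for k in range(i + 1, system.n_spins):
            if j[i, k] != 0.0:
                h += 2.0 * np.pi * j[i, k] * (
                    ops.x[i] @ ops.x[k] + ops.y[i] @ ops.y[k] + ops.z[i] @ ops.z[k]
                )
    return h


# ---------------------------------------------------------------------------
# states over the two-compartment Liouville space

def _single_compartment_vec(ops: SpinOperators, kind: str) -> np.ndarray:
    if kind == "z":
        return vec(ops.total("z"))
    if kind == "p":
        return vec(ops.total("p"))
    raise ValueError(kind)


def thermal_equilibrium(assembly: CompartmentAssembly, amplitude: float = 1.0) -> np.ndarray:
    """High-temperature equilibrium deviation state (unit background dropped).

    Returns the stacked (inside, outside) vectorised state
    ``amplitude * [pop_in * vec(sum_i Liz), pop_out * vec(sum_i Liz)]``.
    Amounts are carried in the state itself, so exchange conserves the total
    and peak integrals are proportional to compartment amounts.
    """
    if assembly.pop_in <= 0 or assembly.pop_out <= 0:
        raise ValidationError("populations must be positive")
    ops = pauli_operators(assembly.n_spins)
    z = _single_compartment_vec(ops, "z")
    return amplitude * np.concatenate([assembly.pop_in * z, assembly.pop_out * z])


def detection_state(assembly: CompartmentAssembly, which: str = "all") -> np.ndarray:
    """Vectorised ``sum_i Li+`` observable over the stacked compartments.

    The complex FID sample is the inner product ``vec(D)^dagger state``.
    ``which`` selects ``"all"`` (both compartments), ``"in"`` or ``"out"``.
    """
    ops = pauli_operators(assembly.n_spins)
    p = _single_compartment_vec(ops, "p")
    zero = np.zeros_like(p)
    if which == "all":
        return np.concatenate([p, p])
    if which == "in":
        return np.concatenate([p, zero])
    if which == "out":
        return np.concatenate([zero, p])
    raise ValueError(f"unknown compartment selector {which!r}")


def mixture_detection(mixture: AnomerMixture, which: str = "all") -> dict:
    """Per-anomer detection vectors (anomers live in separate spaces)."""
    return {label: detection_state(assembly, which) for label, assembly, _ in mixture.anomers}


def mixture_equilibrium(mixture: AnomerMixture) -> dict:
    """Per-anomer equilibrium deviation states, amplitude-weighted."""
    return {label: thermal_equilibrium(assembly, amp) for label, assembly, amp in mixture.anomers}
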