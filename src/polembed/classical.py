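"""Constrained FQ / FQFμ linear response: assembly, solution, energy.

The fluctuating-charge energy is a quadratic form in the charges (and, for
FQFμ, the induced dipoles),

    E = χᵀq + ½ qᵀ T^qq q + μᵀ D q + ½ μᵀ T^μμ μ + qᵀV − μᵀE ,

where the diagonal of T^qq is the atomic hardness η, the diagonal of T^μμ is
the inverse polarizability 1/α, and (V, E) is an optional external source
(the QM potential and field at the MM sites).  Per-fragment total charges are
fixed by Lagrange multipliers, which prevents intermolecular charge transfer.
Stationarity of the Lagrangian gives one symmetric indefinite (KKT) linear
system, solved directly — systems of interest stay well below 10⁴ unknowns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from . import units
from .kernels import erf_coulomb, gaussian_kernels, ohno_kernel
from .system import ClassicalSystem, GeometryError


class NumericalError(RuntimeError):
    """Singular or ill-conditioned polarization system."""


@dataclass
class SourceField:
    """External potential/field at the MM sites (a.u.), e.g. from the QM layer."""

    potential_at_sites: np.ndarray          # (N,)
    field_at_sites: np.ndarray | None = None  # (N, 3)

    def __post_init__(self):
        self.potential_at_sites = np.asarray(self.potential_at_sites, dtype=float)
        if self.field_at_sites is not None:
            self.field_at_sites = np.asarray(self.field_at_sites, dtype=float)
            if self.field_at_sites.shape != (len(self.potential_at_sites), 3):
                raise ValueError("field_at_sites must be (n_sites, 3)")


@dataclass
class PolarizationState:
    """Solved charges (e), Lagrange multipliers, and dipoles (a.u., FQFμ)."""

    charges: np.ndarray
    multipliers: np.ndarray
    dipoles: np.ndarray | None = None


@dataclass
class InteractionMatrix:
    """Blocks of the FQ(Fμ) response matrix.

    ``charge_block`` is T^qq with the hardness diagonal; ``constraint_block``
    holds one fragment-membership incidence row per fragment;
    ``charge_dipole_block`` (3N×N) and ``dipole_block`` (3N×3N, with the 1/α
    diagonal) are present only for FQFμ.
    """

    charge_block: np.ndarray
    constraint_block: np.ndarray
    charge_dipole_block: np.ndarray | None = None
    dipole_block: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return self.charge_block.shape[0]

    @property
    def n_fragments(self) -> int:
        return self.constraint_block.shape[0]

    def full(self) -> np.ndarray:
        """Assemble the symmetric KKT matrix over (q, λ[, μ])."""
        n, f = self.n_sites, self.n_fragments
        has_mu = self.dipole_block is not None
        dim = n + f + (3 * n if has_mu else 0)
        m = np.zeros((dim, dim))
        m[:n, :n] = self.charge_block
        m[n:n + f, :n] = self.constraint_block
        m[:n, n:n + f] = self.constraint_block.T
        if has_mu:
            m[n + f:, :n] = self.charge_dipole_block
            m[:n, n + f:] = self.charge_dipole_block.T
            m[n + f:, n + f:] = self.dipole_block
        return m


def _check_geometry(positions_bohr: np.ndarray, min_sep_bohr: float) -> None:
    n = len(positions_bohr)
    if n < 2:
        return
    d = np.linalg.norm(positions_bohr[:, None] - positions_bohr[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < min_sep_bohr:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise GeometryError(
            f"MM sites {i} and {j} are {d.min():.4f} bohr apart "
            f"(minimum {min_sep_bohr:.4f})")


def assemble_matrix(system: ClassicalSystem) -> InteractionMatrix:
    """Build the interaction-matrix blocks for ``system``.

    Off-diagonal charge couplings use the system's kernel (Ohno or
    erf-screened Gaussian); diagonals are the atomic hardnesses.  For FQFμ
    the charge–dipole and dipole–dipole tensors use the Gaussian family with
    the per-element charge/dipole widths.
    """
    pos = units.angstrom_to_bohr(system.positions_angstrom())
    _check_geometry(pos, units.angstrom_to_bohr(system.min_separation))
    params = system.site_params()
    n = system.n_sites

    a = np.zeros((n, n))
    for i in range(n):
        a[i, i] = params[i].eta
        for j in range(i + 1, n):
            rv = pos[i] - pos[j]
            if system.kernel == "ohno":
                tij = ohno_kernel(np.linalg.norm(rv), params[i].eta, params[j].eta)
            else:
                tij, _, _ = gaussian_kernels(rv, params[i].r_q, params[j].r_q)
            a[i, j] = a[j, i] = tij

    frag_idx = system.fragment_index()
    g = np.zeros((system.n_fragments, n))
    g[frag_idx, np.arange(n)] = 1.0

    d_block = c_block = None
    if system.model == "FQFmu":
        d_block = np.zeros((3 * n, n))
        c_block = np.zeros((3 * n, 3 * n))
        for i in range(n):
            c_block[3 * i:3 * i + 3, 3 * i:3 * i + 3] = np.eye(3) / params[i].alpha
            for j in range(n):
                if i == j:
                    continue
                rv = pos[i] - pos[j]
                # dipole μ_i couples to charge q_j through −T^qμ(r_i − r_j)
                _, t_qmu, _ = gaussian_kernels(rv, params[i].r_mu, params[j].r_q)
                d_block[3 * i:3 * i + 3, j] = -t_qmu
                if j > i:
                    _, _, t_mumu = gaussian_kernels(rv, params[i].r_mu, params[j].r_mu)
                    c_block[3 * i:3 * i + 3, 3 * j:3 * j + 3] = t_mumu
                    c_block[3 * j:3 * j + 3, 3 * i:3 * i + 3] = t_mumu.T
    return InteractionMatrix(a, g, d_block, c_block)


def _rhs(system: ClassicalSystem, source: SourceField | None,
         has_mu: bool) -> np.ndarray:
    n, f = system.n_sites, system.n_fragments
    chi = np.array([p.chi for p in system.site_params()])
    b = np.zeros(n + f + (3 * n if has_mu else 0))
    b[:n] = -chi
    b[n:n + f] = system.constraints()
    if source is not None:
        b[:n] -= source.potential_at_sites
        if has_mu and source.field_at_sites is not None:
            b[n + f:] = source.field_at_sites.reshape(-1)
    return b


def solve_polarization(system: ClassicalSystem,
                       source: SourceField | None = None,
                       matrix: InteractionMatrix | None = None) -> PolarizationState:
    """Solve the constrained FQ(Fμ) stationarity equations M·x = −C_Q + source.

    The external potential drives the charges and the external field drives
    the dipoles.  Per-fragment charge sums satisfy the constraints to solver
    (machine) precision because the constraints are rows of the linear system.
    """
    if matrix is None:
        matrix = assemble_matrix(system)
    has_mu = matrix.dipole_block is not None
    m = matrix.full()
    b = _rhs(system, source, has_mu)
    try:
        x = scipy.linalg.solve(m, b, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(f"singular FQ(Fμ) system: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise NumericalError("non-finite solution; check for coincident sites")
    n, f = matrix.n_sites, matrix.n_fragments
    dip = x[n + f:].reshape(n, 3) if has_mu else None
    return PolarizationState(charges=x[:n], multipliers=x[n:n + f], dipoles=dip)


def classical_energy(system: ClassicalSystem, state: PolarizationState,
                     source: SourceField | None = None,
                     matrix: InteractionMatrix | None = None) -> float:
    """Total classical energy E_FQ(Fμ) + E^int at the given state (a.u.).

    Frame-invariant (depends only on interatomic distances) and stationary,
    on the charge-constraint manifold, at the solved state.
    """
    if matrix is None:
        matrix = assemble_matrix(system)
    q = np.asarray(state.charges, dtype=float)
    if q.shape != (matrix.n_sites,):
        raise ValueError("charge vector has wrong length")
    chi = np.array([p.chi for p in system.site_params()])
    e = chi @ q + 0.5 * q @ matrix.charge_block @ q
    mu = None
    if matrix.dipole_block is not None:
        mu = (np.zeros((matrix.n_sites, 3)) if state.dipoles is None
              else np.asarray(state.dipoles, dtype=float)).reshape(-1)
        e += mu @ matrix.charge_dipole_block @ q + 0.5 * mu @ matrix.dipole_block @ mu
    if source is not None:
        e += q @ source.potential_at_sites
        if mu is not None and source.field_at_sites is not None:
            e -= mu @ source.field_at_sites.reshape(-1)
    return float(e)


def mm_potential_on_points(state: PolarizationState, system: ClassicalSystem,
                           points: np.ndarray,
                           points_in_bohr: bool = True) -> np.ndarray:
    """Electrostatic potential of the solved MM layer on arbitrary points (a.u.).

    φ(r) = Σ_i q_i T^qq(r−r_i) + μ_i·T^qμ(r−r_i), using the same kernel
    family as matrix assembly: erf-damped for Gaussian systems (the probe is
    a point, so the combined width is the site width), bare Coulomb for Ohno
    systems — where a probe point coincident with an MM site is an error.

    This is the static potential handed to the quantum backend.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if not points_in_bohr:
        pts = units.angstrom_to_bohr(pts)
    pos = units.angstrom_to_bohr(system.positions_angstrom())
    params = system.site_params()
    q = np.asarray(state.charges, dtype=float)
    out = np.zeros(len(pts))
    for i in range(system.n_sites):
        rv = pts - pos[i]
        r = np.linalg.norm(rv, axis=1)
        if system.kernel == "gaussian":
            out += q[i] * erf_coulomb(r, params[i].r_q)
        else:
            if np.any(r < 1e-8):
                raise GeometryError(
                    f"evaluation point coincides with MM site {i} "
                    "(bare-Coulomb kernel)")
            out += q[i] / r
        if state.dipoles is not None:
            # potential of a Gaussian dipole: μ·T^qμ with the site's μ-width
            w = params[i].r_mu
            _, t1 = _erf_pot_deriv(r, w)
            rhat = rv / r[:, None]
            out += -(t1 * np.einsum("pj,j->p", rhat, state.dipoles[i]))
    return out


def _erf_pot_deriv(r: np.ndarray, width: float):
    """erf(r/w)/r and its radial derivative, vectorized (r > 0)."""
    from scipy.special import erf as _erf
    u = r / width
    g = (2.0 / np.sqrt(np.pi)) * np.exp(-u * u) / width
    e = _erf(u)
    return e / r, g / r - e / r**2
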