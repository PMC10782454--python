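"""Mutual polarization between the quantum layers and the FQ(Fμ) shell.

The quantum side is a pluggable *backend contract* of three callables:

    relax_density(embedding: EmbeddingPotential) -> GridDensity
    shieldings(embedding, nuclei) -> {nucleus: 3x3 tensor}
    couplings(embedding, pairs)  -> {(a, b): 3x3 tensor}

The orchestration alternates (i) solving the classical charges/dipoles in
the potential and field of the current total quantum density and (ii)
rebuilding the density in the static potential of the classical shell, until
charges and dipoles stop moving.  Magnetic properties carry no explicit
embedding contribution — the polarizable shell has no dependence on nuclear
magnetic moments — so the embedding enters the backend exclusively as the
static one-electron potential of the converged shell, and the returned
tensors pass through unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from . import units
from .classical import (PolarizationState, SourceField, assemble_matrix,
                        classical_energy, mm_potential_on_points,
                        solve_polarization)
from .fde import EmbeddingPotential, GridDensity
from .system import AtomSite, ClassicalSystem, GeometryError


class QuantumBackend(Protocol):
    def relax_density(self, embedding: EmbeddingPotential) -> GridDensity: ...
    def shieldings(self, embedding: EmbeddingPotential,
                   nuclei: Sequence[int]) -> dict: ...
    def couplings(self, embedding: EmbeddingPotential,
                  pairs: Sequence[tuple]) -> dict: ...


@dataclass
class QMSourceEvaluator:
    """Evaluates the potential and field of a quantum charge distribution.

    The distribution is a gridded electron density (charge −1 per electron)
    plus its nuclear point charges Z_α.
    """

    density: GridDensity | None
    nuclei: list[AtomSite] = field(default_factory=list)
    nuclei_in_bohr: bool = True
    damping: float | None = None

    def nuclear_positions_bohr(self) -> np.ndarray:
        if not self.nuclei:
            return np.zeros((0, 3))
        pos = np.array([a.position for a in self.nuclei])
        return pos if self.nuclei_in_bohr else units.angstrom_to_bohr(pos)


@dataclass
class CouplingResult:
    state: PolarizationState
    embedding: EmbeddingPotential
    scf_cycles: int
    interaction_energy: float
    converged: bool
    history: list[float] = field(default_factory=list)


def qm_potential_field_at_sites(evaluator: QMSourceEvaluator,
                                sites_bohr: np.ndarray) -> SourceField:
    """QM potential V[ρ_tot] and field E[ρ_tot] at MM site positions (a.u.).

    Both split into nuclear and electronic parts: V = Σ_α Z_α/|r−R_α|
    − Σ_g w_g ρ_g/|r−r_g|, with E = −∇V evaluated in closed form (and
    optionally erf-damped at short range).
    """
    pts = np.asarray(sites_bohr, dtype=float).reshape(-1, 3)
    v = np.zeros(len(pts))
    e = np.zeros((len(pts), 3))
    w = evaluator.damping

    def _accumulate(src_pos: np.ndarray, charges: np.ndarray):
        rv = pts[:, None, :] - src_pos[None, :, :]           # (P, S, 3)
        r = np.linalg.norm(rv, axis=-1)
        if w is None:
            if np.any(r < 1e-10):
                raise GeometryError(
                    "MM site inside the source region with undamped kernel")
            t = r ** -1
            t1 = -r ** -2
        else:
            from .classical import _erf_pot_deriv
            t, t1 = _erf_pot_deriv(np.maximum(r, 1e-300), w)
        v_part = t @ charges
        rhat = rv / np.maximum(r, 1e-300)[..., None]
        # E = −∇V; for radial t, ∇_r t(|r−s|) = t'(r) r̂
        e_part = -np.einsum("ps,psj,s->pj", t1, rhat, charges)
        return v_part, e_part

    if evaluator.nuclei:
        z = np.array([a.nuclear_charge for a in evaluator.nuclei], dtype=float)
        vp, ep = _accumulate(evaluator.nuclear_positions_bohr(), z)
        v += vp
        e += ep
    if evaluator.density is not None and np.any(evaluator.density.values != 0):
        rho = evaluator.density
        vp, ep = _accumulate(rho.points, -(rho.weights * rho.values))
        v += vp
        e += ep
    return SourceField(potential_at_sites=v, field_at_sites=e)


def interaction_energy(state: PolarizationState, source: SourceField) -> float:
    """E^int = Σ_i q_i V(r_i) − μ_i · E(r_i)  (a.u.)."""
    e = float(state.charges @ source.potential_at_sites)
    if state.dipoles is not None and source.field_at_sites is not None:
        e -= float(np.sum(state.dipoles * source.field_at_sites))
    return e


def mutual_polarization_scf(system: ClassicalSystem,
                            evaluator_factory: Callable[[np.ndarray | None],
                                                        QMSourceEvaluator],
                            tol: float = 1e-6, max_cycles: int = 50
                            ) -> CouplingResult:
    """Converge the coupled quantum/classical polarization.

    ``evaluator_factory(mm_potential_on_grid)`` must return a
    QMSourceEvaluator for the quantum density rebuilt in that MM potential;
    called with ``None`` it returns the unpolarized (gas-phase) source.  An
    empty QM region (factory returns an evaluator with no density and no
    nuclei) reduces to the pure classical solution in one cycle.

    Iterates until max |Δq|, |Δμ| < tol; non-convergence is flagged with the
    cycle history attached.
    """
    matrix = assemble_matrix(system)
    sites = units.angstrom_to_bohr(system.positions_angstrom())
    mm_on_grid = None
    prev_q = np.zeros(system.n_sites)
    prev_mu = np.zeros((system.n_sites, 3))
    history: list[float] = []
    converged = False
    state = None
    source = None
    evaluator = None
    for cycle in range(1, max_cycles + 1):
        evaluator = evaluator_factory(mm_on_grid)
        empty_qm = evaluator.density is None and not evaluator.nuclei
        source = (None if empty_qm
                  else qm_potential_field_at_sites(evaluator, sites))
        state = solve_polarization(system, source, matrix=matrix)
        dq = np.max(np.abs(state.charges - prev_q))
        dmu = (np.max(np.abs(state.dipoles - prev_mu))
               if state.dipoles is not None else 0.0)
        history.append(max(dq, dmu))
        prev_q = state.charges.copy()
        if state.dipoles is not None:
            prev_mu = state.dipoles.copy()
        if empty_qm or max(dq, dmu) < tol:
            converged = True
            break
        mm_on_grid = (mm_potential_on_points(state, system,
                                             evaluator.density.points)
                      if evaluator.density is not None else None)
    e_int = interaction_energy(state, source) if source is not None else 0.0
    grid_pts = (evaluator.density.points if evaluator.density is not None
                else np.zeros((0, 3)))
    v_mm = (mm_potential_on_points(state, system, grid_pts)
            if len(grid_pts) else np.zeros(0))
    return CouplingResult(state=state, embedding=EmbeddingPotential(v_mm),
                          scf_cycles=len(history),
                          interaction_energy=e_int, converged=converged,
                          history=history)


def isotropic(tensor: np.ndarray) -> float:
    """Isotropic part of a 3×3 property tensor: trace/3."""
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("expected a 3x3 tensor")
    return float(np.trace(t) / 3.0)


def request_magnetic_properties(backend: QuantumBackend,
                                embedding: EmbeddingPotential,
                                nuclei: Sequence[int],
                                pairs: Sequence[tuple] = (),
                                snapshot_id: str | None = None):
    """Collect shielding and reduced-coupling tensors from the backend.

    The embedding enters only as the static one-electron potential; tensors
    are passed through unmodified, with isotropic values (trace/3) attached.
    Backend failures surface with the snapshot identifier.
    """
    try:
        sigma = backend.shieldings(embedding, nuclei)
        kappa = backend.couplings(embedding, pairs) if pairs else {}
    except Exception as exc:
        tag = f" (snapshot {snapshot_id})" if snapshot_id else ""
        raise RuntimeError(f"quantum backend failed{tag}: {exc}") from exc
    sigma_iso = {k: isotropic(v) for k, v in sigma.items()}
    kappa_iso = {k: isotropic(v) for k, v in kappa.items()}
    return sigma, kappa, sigma_iso, kappa_iso
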