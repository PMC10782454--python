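"""Synthetic inputs and brute-force oracles.

Everything the other modules need can be generated here without a
quantum-chemistry run: rigid water clusters, Gaussian model densities with
closed-form potentials, noisy per-snapshot NMR tables, mock quantum
backends, and a black-box constrained minimizer of the explicit FQ(Fμ)
energy that serves as the independent reference for the linear solver.

The oracle deliberately shares no code with the production kernels: its
energy expression is written out with inline Ohno / erf formulas, the
charge constraints are eliminated through a null-space parametrization, and
the quadratic minimum is extracted from central finite differences of the
energy (exact for a quadratic form) followed by one dense solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.special

from . import units
from .classical import PolarizationState, SourceField
from .fde import EmbeddingPotential, GridDensity
from .system import AtomSite, ClassicalSystem, MolecularFragment


# --------------------------------------------------------------------------
# geometry generators
# --------------------------------------------------------------------------

# rigid TIP3P-geometry water in its local frame (Å): r(OH)=0.9572, HOH=104.52°
_TIP3P_LOCAL = np.array([
    [0.0, 0.0, 0.0],
    [0.9572, 0.0, 0.0],
    [0.9572 * np.cos(np.deg2rad(104.52)), 0.9572 * np.sin(np.deg2rad(104.52)), 0.0],
])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_water_cluster(n: int, geometry: str = "shell", seed: int = 0,
                       r_min: float = 3.0, r_max: float = 8.0,
                       box: float = 12.0, min_oo: float = 1.5,
                       max_tries: int = 20000) -> list[MolecularFragment]:
    """Place ``n`` rigid TIP3P-geometry waters without O–O overlaps.

    ``shell`` draws oxygen positions uniformly in the radial band
    [r_min, r_max] Å around the origin; ``box`` draws them uniformly in a
    cube of the given edge.  Candidates with an O–O distance below
    ``min_oo`` Å are rejected.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("need n >= 1 waters")
    rng = np.random.default_rng(seed)
    oxygens: list[np.ndarray] = []
    frags: list[MolecularFragment] = []
    tries = 0
    while len(frags) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"packing failed after {max_tries} tries "
                               f"({len(frags)}/{n} placed)")
        if geometry == "shell":
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = (r_min**3 + rng.random() * (r_max**3 - r_min**3)) ** (1.0 / 3.0)
            o_pos = r * u
        elif geometry == "box":
            o_pos = (rng.random(3) - 0.5) * box
        else:
            raise ValueError(f"unknown geometry {geometry!r}")
        if any(np.linalg.norm(o_pos - o) < min_oo for o in oxygens):
            continue
        rot = _random_rotation(rng)
        pos = o_pos + _TIP3P_LOCAL @ rot.T
        sites = (AtomSite("O", pos[0], 8), AtomSite("H", pos[1], 1),
                 AtomSite("H", pos[2], 1))
        frags.append(MolecularFragment(sites=sites, total_charge_constraint=0.0))
        oxygens.append(o_pos)
    return frags


# --------------------------------------------------------------------------
# Gaussian model densities
# --------------------------------------------------------------------------

@dataclass
class GaussianModelDensity:
    """Sum of normalized 3D Gaussians: analytic density, gradient, potential.

    ρ(r) = Σ_k A_k (2π w_k²)^{-3/2} exp(−|r−c_k|²/(2 w_k²)), integrating to
    Σ_k A_k electrons; the electrostatic potential of each term is the
    closed form A_k erf(|r−c_k|/(√2 w_k))/|r−c_k|.  All a.u.
    """

    centers: np.ndarray    # (K, 3)
    amplitudes: np.ndarray  # (K,)
    widths: np.ndarray      # (K,)

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).reshape(-1)
        self.widths = np.asarray(self.widths, dtype=float).reshape(-1)
        if np.any(self.widths <= 0):
            raise ValueError("Gaussian widths must be positive")

    @property
    def total_electrons(self) -> float:
        return float(self.amplitudes.sum())

    def density(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        out = np.zeros(len(pts))
        for c, a, w in zip(self.centers, self.amplitudes, self.widths):
            r2 = np.sum((pts - c) ** 2, axis=1)
            out += a * (2 * np.pi * w * w) ** -1.5 * np.exp(-r2 / (2 * w * w))
        return out

    def gradient(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        out = np.zeros_like(pts)
        for c, a, w in zip(self.centers, self.amplitudes, self.widths):
            d = pts - c
            r2 = np.sum(d * d, axis=1)
            rho = a * (2 * np.pi * w * w) ** -1.5 * np.exp(-r2 / (2 * w * w))
            out += -d * (rho / (w * w))[:, None]
        return out

    def potential(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        out = np.zeros(len(pts))
        for c, a, w in zip(self.centers, self.amplitudes, self.widths):
            r = np.linalg.norm(pts - c, axis=1)
            small = r < 1e-10
            safe = np.where(small, 1.0, r)
            v = scipy.special.erf(safe / (np.sqrt(2) * w)) / safe
            v[small] = np.sqrt(2.0 / np.pi) / w
            out += a * v
        return out


def hermite_grid(n_per_dim: int = 14, scale: float = 2.0,
                 center=(0.0, 0.0, 0.0)):
    """Product Gauss–Hermite quadrature for smooth integrands over R³.

    Returns (points (N,3), weights (N,)); weights carry the e^{+x²} factor
    so that Σ w f(p) ≈ ∫ f.  ``scale`` stretches the nodes (a.u.).
    """
    x, w = np.polynomial.hermite.hermgauss(n_per_dim)
    wx = w * np.exp(x * x) * scale
    xs = x * scale
    px, py, pz = np.meshgrid(xs, xs, xs, indexing="ij")
    wxx, wyy, wzz = np.meshgrid(wx, wx, wx, indexing="ij")
    pts = np.stack([px.ravel(), py.ravel(), pz.ravel()], axis=1)
    pts = pts + np.asarray(center, dtype=float)
    return pts, (wxx * wyy * wzz).ravel()


def model_density_on_grid(model: GaussianModelDensity,
                          n_per_dim: int = 14, scale: float | None = None,
                          center=None, nuclei=()) -> GridDensity:
    """Sample a Gaussian model density (values + analytic gradients) on a
    Gauss–Hermite product grid sized to cover the model."""
    if center is None:
        center = np.average(model.centers, axis=0, weights=model.amplitudes)
    if scale is None:
        span = (np.max(np.linalg.norm(model.centers - center, axis=1))
                if len(model.centers) > 1 else 0.0)
        scale = float(np.max(model.widths) + 0.5 * span)
    pts, wts = hermite_grid(n_per_dim, scale, center)
    return GridDensity(points=pts, weights=wts,
                       values=model.density(pts),
                       gradients=model.gradient(pts),
                       nuclei=list(nuclei))


# --------------------------------------------------------------------------
# brute-force constrained minimizer (the explicit-energy oracle)
# --------------------------------------------------------------------------

def _oracle_energy(system: ClassicalSystem, x: np.ndarray,
                   source: SourceField | None) -> float:
    """Explicit FQ(Fμ) energy with inline kernel formulas (oracle path)."""
    n = system.n_sites
    has_mu = system.model == "FQFmu"
    q = x[:n]
    mu = x[n:].reshape(n, 3) if has_mu else None
    pos = units.angstrom_to_bohr(system.positions_angstrom())
    params = system.site_params()

    e = 0.0
    for i, p in enumerate(params):
        e += p.chi * q[i] + 0.5 * p.eta * q[i] * q[i]
        if has_mu:
            e += float(mu[i] @ mu[i]) / (2.0 * p.alpha)
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            r = math.sqrt(float(d @ d))
            if system.kernel == "ohno":
                em = 0.5 * (params[i].eta + params[j].eta)
                e += q[i] * q[j] * em / math.sqrt(1.0 + em * em * r * r)
            else:
                rq = math.sqrt(params[i].r_q**2 + params[j].r_q**2)
                e += q[i] * q[j] * math.erf(r / rq) / r
            if has_mu:
                # charge j -- dipole i, and charge i -- dipole j
                for (a, b) in ((i, j), (j, i)):
                    rv = pos[a] - pos[b]
                    rr = math.sqrt(float(rv @ rv))
                    w = math.sqrt(params[a].r_mu**2 + params[b].r_q**2)
                    u = rr / w
                    tp = (2.0 / math.sqrt(math.pi)) * math.exp(-u * u) / (w * rr) \
                        - math.erf(u) / (rr * rr)
                    e += q[b] * tp * float(mu[a] @ rv) / rr
                # dipole-dipole (count each pair once)
                rv = pos[i] - pos[j]
                rr = math.sqrt(float(rv @ rv))
                w = math.sqrt(params[i].r_mu**2 + params[j].r_mu**2)
                u = rr / w
                g = (2.0 / math.sqrt(math.pi)) * math.exp(-u * u) / w
                t1 = g / rr - math.erf(u) / rr**2
                t2 = (-2.0 * u / w * g / rr - 2.0 * g / rr**2
                      + 2.0 * math.erf(u) / rr**3)
                rhat = rv / rr
                tens = -((t2 - t1 / rr) * np.outer(rhat, rhat)
                         + (t1 / rr) * np.eye(3))
                e += float(mu[i] @ tens @ mu[j])
    if source is not None:
        e += float(q @ source.potential_at_sites)
        if has_mu and source.field_at_sites is not None:
            e -= float(np.sum(mu * source.field_at_sites))
    return e


def brute_force_minimizer(system: ClassicalSystem,
                          source: SourceField | None = None
                          ) -> PolarizationState:
    """Numerically minimize the explicit FQ(Fμ) energy under the per-fragment
    charge constraints; the reference implementation for solver tests.

    Constraints are eliminated exactly: charges are written as a particular
    solution (Q_f/n_f on each atom) plus null-space coordinates of the
    fragment incidence matrix.  The reduced energy is quadratic, so its
    gradient and Hessian follow exactly from central differences of the
    black-box energy, and one dense solve yields the minimizer.
    """
    n = system.n_sites
    has_mu = system.model == "FQFmu"
    dim = n + (3 * n if has_mu else 0)
    if dim > 60:
        raise ValueError("oracle limited to small systems (<= ~20 unknowns)")

    frag_idx = system.fragment_index()
    g = np.zeros((system.n_fragments, n))
    g[frag_idx, np.arange(n)] = 1.0
    null = scipy.linalg.null_space(g)              # (n, n - F)
    q_part = np.zeros(n)
    for f, frag in enumerate(system.fragments):
        members = frag_idx == f
        q_part[members] = frag.total_charge_constraint / members.sum()

    k = null.shape[1] + (3 * n if has_mu else 0)

    def lift(y: np.ndarray) -> np.ndarray:
        x = np.zeros(dim)
        x[:n] = q_part + null @ y[:null.shape[1]]
        if has_mu:
            x[n:] = y[null.shape[1]:]
        return x

    def energy(y: np.ndarray) -> float:
        return _oracle_energy(system, lift(y), source)

    h = 0.25
    y0 = np.zeros(k)
    e0 = energy(y0)
    grad = np.zeros(k)
    hess = np.zeros((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        ep, em = energy(ei), energy(-ei)
        grad[i] = (ep - em) / (2 * h)
        hess[i, i] = (ep - 2 * e0 + em) / (h * h)
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ei[i] = h
            ej = np.zeros(k)
            ej[j] = h
            hess[i, j] = hess[j, i] = (
                energy(ei + ej) - energy(ei - ej)
                - energy(-ei + ej) + energy(-ei - ej)) / (4 * h * h)
    y_star = np.linalg.solve(hess, -grad)
    x = lift(y_star)
    # recover multipliers from stationarity of the full Lagrangian: not
    # needed by any oracle comparison; report the least-squares values
    mult = np.zeros(system.n_fragments)
    return PolarizationState(charges=x[:n], multipliers=mult,
                             dipoles=x[n:].reshape(n, 3) if has_mu else None)


# --------------------------------------------------------------------------
# mock quantum backends
# --------------------------------------------------------------------------

class MockBackend:
    """Backend-contract stand-in for tests and desk-scale pipelines.

    ``fixed`` returns a constant density and constant tensors regardless of
    the embedding; ``linear_response`` returns ρ = ρ₀ + k·v_emb and
    σ_iso = σ₀ + s·⟨v_emb⟩, which makes the coupled quantum/classical fixed
    point an analytically solvable linear system.
    """

    def __init__(self, kind: str, rho0: GridDensity,
                 k: float = 0.0, sigma0: float = 30.0, s: float = 0.0,
                 kappa0: float = 0.0):
        if kind not in ("fixed", "linear_response"):
            raise ValueError(f"unknown mock backend kind {kind!r}")
        self.kind = kind
        self.rho0 = rho0
        self.k = k
        self.sigma0 = sigma0
        self.s = s
        self.kappa0 = kappa0
        self.calls = 0

    def relax_density(self, embedding: EmbeddingPotential | None) -> GridDensity:
        self.calls += 1
        if self.kind == "fixed" or embedding is None:
            return self.rho0
        vals = self.rho0.values + self.k * embedding.values
        return self.rho0.replace_values(np.maximum(vals, 0.0))

    def shieldings(self, embedding: EmbeddingPotential | None, nuclei):
        shift = 0.0 if (self.kind == "fixed" or embedding is None) \
            else self.s * embedding.mean()
        return {a: (self.sigma0 + shift) * np.eye(3) for a in nuclei}

    def couplings(self, embedding: EmbeddingPotential | None, pairs):
        return {tuple(p): self.kappa0 * np.eye(3) for p in pairs}


def mock_backend(kind: str, rho0: GridDensity, **params) -> MockBackend:
    return MockBackend(kind, rho0, **params)


def synthetic_snapshot_tables(group_means: dict[str, float],
                              groups,  # EquivalenceGroups
                              n_snapshots: int = 200, noise: float = 0.05,
                              seed: int = 0):
    """Per-snapshot σ_iso tables: group mean + i.i.d. Gaussian noise.

    The ensemble mean of the tables converges to the programmed group means
    as the snapshot count grows — the recovery property tested on the
    averaging pipeline.
    """
    rng = np.random.default_rng(seed)
    import pandas as pd
    index = sorted(i for idx in groups.groups.values() for i in idx)
    base = pd.Series({i: group_means[groups.group_of(i)] for i in index})
    return [base + rng.normal(0.0, noise, size=len(base))
            for _ in range(n_snapshots)]
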