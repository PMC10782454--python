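"""Atomistic containers for the classical (FQ / FQFμ) layer.

The classical layer is a set of rigid molecular fragments.  Each atom carries
a fluctuating charge; in the FQFμ model it additionally carries a fluctuating
point dipole.  Per-element parameters (electronegativity χ, hardness η,
polarizability α, Gaussian widths) live in :class:`FQParameters`; each
fragment carries a total-charge constraint Q so that charge can flow within a
molecule but never between molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np


class ParameterError(ValueError):
    """Missing or unphysical force-field parameters."""


class GeometryError(ValueError):
    """Degenerate or inconsistent geometry."""


@dataclass(frozen=True)
class AtomSite:
    """One atomic site: element, position (Å), nuclear charge."""

    element: str
    position: np.ndarray  # shape (3,), Å
    nuclear_charge: int = 1

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise GeometryError(f"invalid position for {self.element}: {self.position}")
        object.__setattr__(self, "position", pos)
        if self.nuclear_charge < 1:
            raise ParameterError("nuclear_charge must be >= 1")


@dataclass(frozen=True)
class MolecularFragment:
    """An ordered group of sites sharing one total-charge constraint Q (e)."""

    sites: tuple[AtomSite, ...]
    total_charge_constraint: float = 0.0

    def __post_init__(self):
        if len(self.sites) == 0:
            raise ValueError("fragment needs at least one site")
        if not np.isfinite(self.total_charge_constraint):
            raise ValueError("charge constraint must be finite")
        object.__setattr__(self, "sites", tuple(self.sites))

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])


@dataclass(frozen=True)
class ElementParams:
    """Per-element FQ(Fμ) parameters, atomic units."""

    chi: float           # electronegativity
    eta: float           # hardness
    alpha: float | None = None   # polarizability (FQFμ)
    r_q: float | None = None     # Gaussian charge width
    r_mu: float | None = None    # Gaussian dipole width

    def __post_init__(self):
        if self.eta <= 0:
            raise ParameterError(f"hardness must be positive, got {self.eta}")
        if self.alpha is not None and self.alpha <= 0:
            raise ParameterError(f"polarizability must be positive, got {self.alpha}")
        for name in ("r_q", "r_mu"):
            w = getattr(self, name)
            if w is not None and w <= 0:
                raise ParameterError(f"{name} must be positive, got {w}")


class FQParameters:
    """Per-element parameter table for the FQ / FQFμ force fields."""

    def __init__(self, table: dict[str, ElementParams]):
        self._table = dict(table)

    def __contains__(self, element: str) -> bool:
        return element in self._table

    def __getitem__(self, element: str) -> ElementParams:
        try:
            return self._table[element]
        except KeyError:
            raise ParameterError(f"no FQ parameters for element {element!r}") from None

    def elements(self) -> Sequence[str]:
        return list(self._table)


Kernel = Literal["ohno", "gaussian"]
Model = Literal["FQ", "FQFmu"]


@dataclass
class ClassicalSystem:
    """The full classical layer: fragments + parameters + model choice.

    ``kernel`` selects the charge-charge interaction family (Ohno for FQ,
    erf-screened Gaussian for FQFμ); ``model`` selects whether fluctuating
    dipoles are carried.
    """

    fragments: list[MolecularFragment]
    parameters: FQParameters
    kernel: Kernel = "ohno"
    model: Model = "FQ"
    min_separation: float = 0.1  # Å; closer MM sites are a geometry error

    def __post_init__(self):
        if self.kernel not in ("ohno", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.model not in ("FQ", "FQFmu"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "FQFmu" and self.kernel != "gaussian":
            raise ParameterError("FQFmu requires the gaussian kernel family")
        for frag in self.fragments:
            for site in frag.sites:
                p = self.parameters[site.element]  # raises ParameterError if absent
                if self.model == "FQFmu":
                    if p.alpha is None:
                        raise ParameterError(
                            f"FQFmu requires polarizability for {site.element}")
                if self.kernel == "gaussian" and p.r_q is None:
                    raise ParameterError(
                        f"gaussian kernel requires charge width for {site.element}")
                if self.model == "FQFmu" and p.r_mu is None:
                    raise ParameterError(
                        f"FQFmu requires dipole width for {site.element}")

    # --- flat views over all atoms ------------------------------------
    def iter_sites(self) -> Iterator[AtomSite]:
        for frag in self.fragments:
            yield from frag.sites

    @property
    def n_sites(self) -> int:
        return sum(len(f) for f in self.fragments)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def positions_angstrom(self) -> np.ndarray:
        return np.array([s.position for s in self.iter_sites()])

    def site_params(self) -> list[ElementParams]:
        return [self.parameters[s.element] for s in self.iter_sites()]

    def fragment_index(self) -> np.ndarray:
        """Fragment id per flat atom index."""
        idx = np.empty(self.n_sites, dtype=int)
        k = 0
        for fi, frag in enumerate(self.fragments):
            idx[k:k + len(frag)] = fi
            k += len(frag)
        return idx

    def constraints(self) -> np.ndarray:
        return np.array([f.total_charge_constraint for f in self.fragments])
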