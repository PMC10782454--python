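"""File I/O: geometries (XYZ/PDB/GRO), parameter files, grids, cube import.

XYZ files carry no molecule records, so fragments are recovered from an
explicit list of fragment sizes (or a water heuristic of O-H-H triplets);
PDB and GRO go through MDAnalysis and use residue records as fragment
boundaries.  Positions are Å everywhere at this boundary.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np

from .fde import GridDensity
from .partition import Molecule, Snapshot
from .system import AtomSite, ElementParams, FQParameters, MolecularFragment
from .units import atomic_number

# ---------------------------------------------------------------- geometries


def read_xyz(path) -> tuple[list[str], np.ndarray, str]:
    """Read one XYZ frame: (elements, positions Å, comment line)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    comment = lines[1] if len(lines) > 1 else ""
    elements, coords = [], []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return elements, np.array(coords), comment


def write_xyz(path, elements, positions, comment: str = "") -> None:
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write(f"{len(elements)}\n{comment}\n")
        for el, (x, y, z) in zip(elements, positions):
            fh.write(f"{el:<3s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def molecules_from_xyz(path, fragment_sizes=None) -> list[Molecule]:
    """Split an XYZ file into molecules by explicit fragment sizes, or by
    grouping O-H-H triplets when every atom pattern matches water."""
    elements, coords, _ = read_xyz(path)
    if fragment_sizes is None:
        if len(elements) % 3 == 0 and all(
                elements[i] == "O" and elements[i + 1] == "H"
                and elements[i + 2] == "H"
                for i in range(0, len(elements), 3)):
            fragment_sizes = [3] * (len(elements) // 3)
        else:
            raise ValueError("fragment_sizes required for non-water XYZ input")
    mols, k = [], 0
    for size in fragment_sizes:
        mols.append(Molecule(elements=elements[k:k + size],
                             positions=coords[k:k + size]))
        k += size
    return mols


def read_snapshot(path, solute_resname: str | None = None,
                  solute_size: int | None = None,
                  fragment_sizes=None, identifier: str = "") -> Snapshot:
    """Read a snapshot; the solute is the first ``solute_size`` atoms (XYZ)
    or the residue named ``solute_resname`` (PDB/GRO via MDAnalysis)."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        if solute_size is None:
            raise ValueError("solute_size required for XYZ snapshots")
        elements, coords, _ = read_xyz(path)
        solute = Molecule(elements[:solute_size], coords[:solute_size], "solute")
        rest = Molecule(elements[solute_size:], coords[solute_size:])
        if fragment_sizes is None:
            fragment_sizes = [3] * (len(rest) // 3)
        solvent, k = [], 0
        for size in fragment_sizes:
            solvent.append(Molecule(rest.elements[k:k + size],
                                    rest.positions[k:k + size]))
            k += size
        return Snapshot(solute=solute, solvent=solvent,
                        identifier=identifier or path.stem)
    import MDAnalysis as mda
    u = mda.Universe(str(path))
    solute = None
    solvent = []
    for res in u.residues:
        mol = Molecule(elements=[_guess_element(a) for a in res.atoms],
                       positions=res.atoms.positions.astype(float),
                       name=res.resname)
        if solute is None and (solute_resname is None
                               or res.resname == solute_resname):
            solute = mol
        else:
            solvent.append(mol)
    if solute is None:
        raise ValueError(f"no residue named {solute_resname!r} in {path}")
    return Snapshot(solute=solute, solvent=solvent,
                    identifier=identifier or path.stem)


def _guess_element(atom) -> str:
    try:
        el = atom.element
        if el:
            return el.capitalize()
    except Exception:
        pass
    name = atom.name.strip()
    return (name[:2].capitalize() if len(name) > 1 and name[:2].capitalize()
            in ("Cl", "Br", "Na", "Mg") else name[0].upper())


def fragments_from_molecules(molecules, charges=None) -> list[MolecularFragment]:
    """Molecules → charge-constrained MM fragments (default Q = 0)."""
    out = []
    for i, mol in enumerate(molecules):
        q = 0.0 if charges is None else charges[i]
        sites = tuple(AtomSite(el, pos, atomic_number(el))
                      for el, pos in zip(mol.elements, mol.positions))
        out.append(MolecularFragment(sites=sites, total_charge_constraint=q))
    return out


# ---------------------------------------------------------------- parameters

def read_parameters(path_or_text) -> FQParameters:
    """Parse a plain-text parameter table.

    One line per element: ``element chi eta [alpha r_q r_mu]``, atomic
    units; '#' comments and blank lines ignored; '-' marks an absent value.
    """
    if isinstance(path_or_text, str) and "\n" in path_or_text:
        text = path_or_text
    else:
        text = Path(path_or_text).read_text()
    table = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        el = parts[0]
        vals = [None if p == "-" else float(p) for p in parts[1:6]]
        vals += [None] * (5 - len(vals))
        table[el] = ElementParams(chi=vals[0], eta=vals[1], alpha=vals[2],
                                  r_q=vals[3], r_mu=vals[4])
    return FQParameters(table)


def load_named_parameters(name: str) -> FQParameters:
    """Load a packaged parameter set: 'FQa', 'FQb', or 'FQFmu'.

    The shipped tables are synthetic placeholders with physically plausible
    magnitudes (clearly labelled in the files); production work should load
    a fitted parameter file via :func:`read_parameters`.
    """
    fname = {"FQa": "fqa.txt", "FQb": "fqb.txt", "FQFmu": "fqfmu.txt"}.get(name)
    if fname is None:
        raise KeyError(f"unknown parameter set {name!r}")
    text = resources.files("polembed.data").joinpath(fname).read_text()
    return read_parameters(text)


# ---------------------------------------------------------------- grids

def save_grid(path, rho: GridDensity) -> None:
    """Columnar container (.npz) + JSON sidecar for the nuclei."""
    path = Path(path)
    np.savez(path, points=rho.points, weights=rho.weights, values=rho.values,
             **({"gradients": rho.gradients} if rho.gradients is not None else {}))
    sidecar = [{"element": a.element, "position": list(map(float, a.position)),
                "Z": a.nuclear_charge} for a in rho.nuclei]
    path.with_suffix(".json").write_text(json.dumps(
        {"nuclei": sidecar, "nuclei_in_bohr": rho.nuclei_in_bohr}))


def load_grid(path) -> GridDensity:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    data = np.load(path)
    nuclei = []
    in_bohr = True
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        in_bohr = meta.get("nuclei_in_bohr", True)
        nuclei = [AtomSite(d["element"], np.array(d["position"]), d["Z"])
                  for d in meta["nuclei"]]
    return GridDensity(points=data["points"], weights=data["weights"],
                       values=data["values"],
                       gradients=data["gradients"] if "gradients" in data else None,
                       nuclei=nuclei, nuclei_in_bohr=in_bohr)


def read_cube(path) -> GridDensity:
    """Import a Gaussian cube file as a GridDensity (uniform product weights)."""
    lines = Path(path).read_text().splitlines()
    natoms_line = lines[2].split()
    natoms = int(natoms_line[0])
    origin = np.array([float(x) for x in natoms_line[1:4]])
    counts, axes = [], []
    for i in range(3):
        parts = lines[3 + i].split()
        counts.append(abs(int(parts[0])))
        axes.append([float(x) for x in parts[1:4]])
    axes = np.array(axes)
    nuclei = []
    for i in range(natoms):
        parts = lines[6 + i].split()
        z = int(parts[0])
        pos = np.array([float(x) for x in parts[2:5]])
        sym = {1: "H", 6: "C", 7: "N", 8: "O"}.get(z, f"Z{z}")
        nuclei.append(AtomSite(sym, pos, z))
    vals = []
    for ln in lines[6 + natoms:]:
        vals.extend(float(x) for x in ln.split())
    values = np.array(vals).reshape(counts)
    nx, ny, nz = counts
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    pts = (origin + ii[..., None] * axes[0] + jj[..., None] * axes[1]
           + kk[..., None] * axes[2]).reshape(-1, 3)
    voxel = abs(np.linalg.det(axes))
    return GridDensity(points=pts, weights=np.full(pts.shape[0], voxel),
                       values=values.ravel(), nuclei=nuclei)
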