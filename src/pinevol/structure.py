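"""Structures, trajectories, and the geometry kernels used on them.

Coordinates are in Angstrom throughout; trajectory frame times are in ns.
PDB reading/writing goes through Biopython; the numerical kernels (Kabsch
superposition, Shrake-Rupley solvent-accessible surface area, backbone
dihedrals) are implemented here with fully documented, deterministic
conventions so that results are reproducible bit-for-bit.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "dihedral_angle",
    "kabsch_superpose",
    "trajectory_rmsd",
    "sasa",
    "backbone_dihedrals",
    "VDW_RADII",
]

#: Default van der Waals radii (Angstrom) for SASA; overridable per call.
VDW_RADII: dict[str, float] = {
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "H": 1.2,
    "P": 1.8,
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str


class Structure:
    """Atom records plus an (N, 3) coordinate array in Angstrom."""

    def __init__(self, atoms: Sequence[Atom], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(atoms)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        keys = {(a.chain, a.res_id, a.name) for a in atoms}
        if len(keys) != len(atoms):
            raise ValueError("duplicate (chain, residue, atom name) records")
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        self.coords: np.ndarray = coords

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def residues(self, chain: Optional[str] = None) -> list[tuple[str, int, str]]:
        """Ordered (chain, res_id, res_name) triples."""
        out: list[tuple[str, int, str]] = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            key = (a.chain, a.res_id, a.res_name)
            if not out or out[-1] != key:
                if key not in out:
                    out.append(key)
        return out

    def atom_index(self, chain: str, res_id: int, name: str) -> Optional[int]:
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.res_id == res_id and a.name == name:
                return i
        return None

    def subset(self, selection: "Selection") -> "Structure":
        idx = selection.indices(self)
        return Structure([self.atoms[i] for i in idx], self.coords[idx])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(self.atoms, coords)


class Trajectory:
    """A topology plus (F, N, 3) frame coordinates and per-frame times in ns."""

    def __init__(
        self,
        topology: Structure,
        frames: np.ndarray,
        times: Optional[Sequence[float]] = None,
    ):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != (len(topology), 3):
            raise ValueError(
                f"frames shape {frames.shape} inconsistent with topology of "
                f"{len(topology)} atoms"
            )
        if times is None:
            times = list(range(frames.shape[0]))
        times = [float(t) for t in times]
        if len(times) != frames.shape[0]:
            raise ValueError("one time per frame required")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be non-decreasing")
        self.topology = topology
        self.frames = frames
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class Selection:
    """Atom filter by chain, closed residue range, and/or atom names.

    Residue numbering is the author numbering of the structure and ranges are
    closed intervals, matching how subdomain selections are printed in the
    literature (e.g. K1 = residues 98-111).  ``atom_names={"CA"}`` restricts
    to C-alpha atoms.
    """

    chain: Optional[str] = None
    res_range: Optional[tuple[int, int]] = None
    atom_names: Optional[frozenset[str]] = None

    @staticmethod
    def ca(chain: Optional[str] = None, res_range: Optional[tuple[int, int]] = None) -> "Selection":
        return Selection(chain=chain, res_range=res_range, atom_names=frozenset({"CA"}))

    def matches(self, atom: Atom) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.res_range is not None:
            lo, hi = self.res_range
            if not (lo <= atom.res_id <= hi):
                return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True

    def indices(self, structure: Structure) -> np.ndarray:
        idx = [i for i, a in enumerate(structure.atoms) if self.matches(a)]
        return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# PDB I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def _biopython_models(source) -> list:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    if hasattr(source, "read"):
        handle = source
    else:
        handle = open(source)
    try:
        struct = parser.get_structure("s", handle)
    finally:
        if handle is not source:
            handle.close()
    models = list(struct)
    if not models:
        raise ValueError("no ATOM records found")
    return models


def _model_to_structure(model) -> Structure:
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                # Disordered atoms: Biopython's DisorderedAtom exposes the
                # highest-occupancy altloc (ties resolved toward 'A') as the
                # selected child, which is the deterministic policy here.
                if atom.is_disordered():
                    atom = atom.selected_child
                element = (atom.element or atom.get_name()[0]).strip().upper()
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        element=element,
                        res_name=residue.get_resname().strip(),
                        res_id=residue.get_id()[1],
                        chain=chain.get_id(),
                    )
                )
                coords.append(np.asarray(atom.get_coord(), dtype=float))
    if not atoms:
        raise ValueError("no ATOM records found")
    return Structure(atoms, np.asarray(coords))


def read_structure(source) -> Structure:
    """Read a (single-model) PDB file or stream into a Structure."""
    return _model_to_structure(_biopython_models(source)[0])


def read_trajectory(source, times: Optional[Sequence[float]] = None) -> Trajectory:
    """Read a multi-model PDB as a trajectory (one frame per MODEL)."""
    models = _biopython_models(source)
    structures = [_model_to_structure(m) for m in models]
    topo = structures[0]
    key = [(a.chain, a.res_id, a.name) for a in topo.atoms]
    frames = np.empty((len(structures), len(topo), 3))
    for fi, s in enumerate(structures):
        if [(a.chain, a.res_id, a.name) for a in s.atoms] != key:
            raise ValueError(f"model {fi + 1} atom records do not match model 1")
        frames[fi] = s.coords
    return Trajectory(topo, frames, times)


def write_pdb(obj: Union[Structure, Trajectory], target) -> None:
    """Write a Structure (single model) or Trajectory (multi-model) as PDB."""
    from Bio.PDB import PDBIO, StructureBuilder

    if isinstance(obj, Structure):
        structures = [obj]
    else:
        structures = [obj.frame(i) for i in range(obj.n_frames)]

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("s")
    for mi, s in enumerate(structures):
        builder.init_model(mi)
        current_chain = None
        current_res = None
        for atom, xyz in zip(s.atoms, s.coords):
            if atom.chain != current_chain:
                builder.init_chain(atom.chain)
                builder.init_seg("    ")
                current_chain = atom.chain
                current_res = None
            if (atom.res_id, atom.res_name) != current_res:
                builder.init_residue(atom.res_name, " ", atom.res_id, " ")
                current_res = (atom.res_id, atom.res_name)
            builder.init_atom(
                atom.name,
                np.asarray(xyz, dtype=float),
                0.0,
                1.0,
                " ",
                atom.name.center(4)[:4],
                element=atom.element,
            )
    pdbio = PDBIO()
    pdbio.set_structure(builder.get_structure())
    if hasattr(target, "write"):
        pdbio.save(target)
    else:
        with open(target, "w") as fh:
            pdbio.save(fh)


# ---------------------------------------------------------------------------
# Geometry kernels
# ---------------------------------------------------------------------------

def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral in degrees, IUPAC convention, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def kabsch_superpose(
    mobile: Union[Structure, np.ndarray],
    reference: Union[Structure, np.ndarray],
    selection: Optional[Selection] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition (Kabsch algorithm).

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits the reference over the
    selection; the rotation is proper (det = +1) and the rmsd is computed
    after superposition over the selected atoms.
    """
    def _pick(obj):
        if isinstance(obj, Structure):
            if selection is not None:
                idx = selection.indices(obj)
                return obj.coords[idx]
            return obj.coords
        arr = np.asarray(obj, dtype=float)
        return arr

    x = _pick(mobile)
    y = _pick(reference)
    if x.shape != y.shape:
        raise ValueError(f"selected atom counts differ: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 atom pairs for superposition")
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    # Collinearity guard: rank of the centered cloud must be >= 2.
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2 or np.linalg.matrix_rank(y0, tol=1e-8) < 2:
        raise ValueError("selection is collinear; superposition is degenerate")
    h = x0.T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = yc - rot @ xc
    fitted = x @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rot, trans, rmsd


def rmsd_no_fit(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def trajectory_rmsd(
    traj: Trajectory,
    reference: Union[int, Structure] = 0,
    selection: Optional[Selection] = None,
    superpose: bool = True,
) -> list[tuple[float, float]]:
    """Per-frame RMSD (Angstrom) against a reference, as (time ns, rmsd) pairs.

    ``reference`` is a frame index or an explicit Structure with the same
    topology.  With ``superpose=True`` every frame is first optimally
    superposed onto the reference over the selection; otherwise raw
    coordinate deviations are used.
    """
    if isinstance(reference, int):
        ref_coords = traj.frames[reference]
    else:
        if len(reference) != len(traj.topology):
            raise ValueError("reference atom count does not match trajectory")
        ref_coords = reference.coords
    if selection is not None:
        idx = selection.indices(traj.topology)
        if idx.size == 0:
            raise ValueError("selection matches no atoms")
    else:
        idx = np.arange(len(traj.topology))
    ref_sel = ref_coords[idx]
    out: list[tuple[float, float]] = []
    for fi in range(traj.n_frames):
        mob = traj.frames[fi][idx]
        if superpose:
            _, _, r = kabsch_superpose(mob, ref_sel)
        else:
            r = rmsd_no_fit(mob, ref_sel)
        out.append((traj.times[fi], r))
    return out


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    selection: Optional[Selection] = None,
    radii: Optional[dict[str, float]] = None,
) -> tuple[float, dict[tuple[str, int], float]]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom is expanded by the probe radius and sampled with a
    deterministic golden-spiral point lattice of ``n_points`` points; a point
    is accessible when it lies outside every other expanded atom.  All atoms
    of the structure occlude, but only selected atoms contribute area.

    Returns (total SASA, per-residue SASA) in Angstrom^2.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a usable quadrature")
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    try:
        r_atom = np.array([table[a.element.upper()] for a in structure.atoms])
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc}") from exc
    r_exp = r_atom + probe_radius
    coords = structure.coords
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    if selection is not None:
        contrib = set(selection.indices(structure).tolist())
        if not contrib:
            raise ValueError("selection matches no atoms")
    else:
        contrib = set(range(len(structure)))

    per_res: dict[tuple[str, int], float] = {}
    total = 0.0
    max_r = r_exp.max()
    for i in sorted(contrib):
        ri = r_exp[i]
        sphere = coords[i] + ri * pts
        neigh = [j for j in tree.query_ball_point(coords[i], ri + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            # Degenerate duplicate centers: the union surface is one sphere,
            # attributed to the lowest-index (or largest) atom.
            if np.allclose(coords[j], coords[i], atol=1e-9) and r_exp[j] >= ri:
                if r_exp[j] > ri or j < i:
                    accessible[:] = False
                    break
                continue
            d2 = np.sum((sphere - coords[j]) ** 2, axis=1)
            accessible &= d2 > r_exp[j] ** 2 - 1e-9
        area = 4.0 * np.pi * ri**2 * accessible.sum() / n_points
        total += area
        atom = structure.atoms[i]
        key = (atom.chain, atom.res_id)
        per_res[key] = per_res.get(key, 0.0) + area
    return float(total), per_res


#: Maximum C(i)-N(i+1) distance (Angstrom) treated as a continuous peptide bond.
PEPTIDE_BOND_MAX = 2.0


def backbone_dihedrals(
    structure: Structure, chain: Optional[str] = None
) -> dict[int, dict[str, Optional[float]]]:
    """Per-residue backbone torsions (phi, psi, omega) in degrees.

    IUPAC sign convention.  phi of the first residue and psi/omega across
    chain termini or gaps (C-N distance above ~2 A) are reported as None,
    never interpolated.  omega(i) is the CA(i-1)-C(i-1)-N(i)-CA(i) torsion,
    so cis-peptide bonds preceding residue i give omega(i) near 0.
    """
    if chain is None:
        chains = structure.chains
        if len(chains) != 1:
            raise ValueError("chain must be given for a multi-chain structure")
        chain = chains[0]
    residues = structure.residues(chain)
    if not residues:
        raise ValueError(f"no residues in chain {chain!r}")

    def atom(res_id: int, name: str) -> Optional[np.ndarray]:
        i = structure.atom_index(chain, res_id, name)
        return None if i is None else structure.coords[i]

    out: dict[int, dict[str, Optional[float]]] = {}
    for k, (_, rid, _) in enumerate(residues):
        n, ca, c = atom(rid, "N"), atom(rid, "CA"), atom(rid, "C")
        phi = psi = omega = None
        if k > 0:
            prev_rid = residues[k - 1][1]
            c_prev = atom(prev_rid, "C")
            ca_prev = atom(prev_rid, "CA")
            bonded = (
                c_prev is not None
                and n is not None
                and np.linalg.norm(n - c_prev) <= PEPTIDE_BOND_MAX
            )
            if bonded and all(x is not None for x in (c_prev, n, ca, c)):
                phi = dihedral_angle(c_prev, n, ca, c)
            if bonded and all(x is not None for x in (ca_prev, c_prev, n, ca)):
                omega = dihedral_angle(ca_prev, c_prev, n, ca)
        if k + 1 < len(residues):
            next_rid = residues[k + 1][1]
            n_next = atom(next_rid, "N")
            bonded = (
                c is not None
                and n_next is not None
                and np.linalg.norm(n_next - c) <= PEPTIDE_BOND_MAX
            )
            if bonded and all(x is not None for x in (n, ca, c, n_next)):
                psi = dihedral_angle(n, ca, c, n_next)
        out[rid] = {"phi": phi, "psi": psi, "omega": omega}
    return out
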