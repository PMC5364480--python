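"""Backbone turn classification and polar-contact detection.

Beta-turns are four-residue chain reversals gated on the C-alpha(i) to
C-alpha(i+3) distance (< 7 A) with the two inner residues not both helical.
Canonical types are assigned from the (phi, psi) of residues i+1 and i+2
against the standard Hutchinson-Thornton table, each angle within a
tolerance (default 30 deg) with a single angle allowed to deviate up to
1.5x the tolerance.  The cis-proline types VIa1/VIa2/VIb additionally
require a cis peptide bond (|omega| < 30 deg) at a proline in position i+2;
conversely a window with a cis-proline at i+2 can only match a type VI
entry — if none fits, the turn is type IV (the residual class).  Gamma
(3-residue) and alpha (5-residue) turns are gated on the i->i+2 and i->i+4
geometry; "pseudo" variants are windows that pass the geometric gate without
the canonical dihedral signature.  The pseudo gates are implementation
definitions (documented in the methods note), since no community standard
fixes them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .structure import Structure, backbone_dihedrals

__all__ = [
    "TurnAssignment",
    "ContactRecord",
    "classify_turns",
    "detect_polar_contacts",
    "CANONICAL_BETA_TURNS",
]

#: Canonical beta-turn (phi_i+1, psi_i+1, phi_i+2, psi_i+2) in degrees
#: (Hutchinson-Thornton convention).  Types VIa1/VIa2/VIb require cis-Pro at i+2.
CANONICAL_BETA_TURNS: dict[str, tuple[float, float, float, float]] = {
    "I": (-60.0, -30.0, -90.0, 0.0),
    "I'": (60.0, 30.0, 90.0, 0.0),
    "II": (-60.0, 120.0, 80.0, 0.0),
    "II'": (60.0, -120.0, -80.0, 0.0),
    "VIII": (-60.0, -30.0, -120.0, 120.0),
    "VIa1": (-60.0, 120.0, -90.0, 0.0),
    "VIa2": (-120.0, 120.0, -60.0, 0.0),
    "VIb": (-135.0, 135.0, -75.0, 160.0),
}
CIS_PRO_TYPES = frozenset({"VIa1", "VIa2", "VIb"})

#: Classic and inverse gamma-turn (phi, psi) of the central residue.
GAMMA_TURNS: dict[str, tuple[float, float]] = {
    "gamma-classic": (75.0, -64.0),
    "gamma-inverse": (-79.0, 69.0),
}

BETA_CA_GATE = 7.0  # Angstrom, CA(i)-CA(i+3)
GAMMA_CA_GATE = 5.8  # Angstrom, CA(i)-CA(i+2)
ALPHA_CA_GATE = 6.5  # Angstrom, CA(i)-CA(i+4)
HBOND_MAX = 3.5  # Angstrom, heavy-atom N...O


@dataclass(frozen=True)
class TurnAssignment:
    chain: str
    start_res: int
    length: int  # 3 (gamma), 4 (beta), 5 (alpha)
    turn_type: str
    dihedrals: tuple[tuple[float, float], ...]  # (phi, psi) per inner residue
    hbond_distance: Optional[float] = None  # N(i+len-1)...O(i), Angstrom


@dataclass(frozen=True)
class ContactRecord:
    chain_a: str
    res_a: int
    atom_a: str
    chain_b: str
    res_b: int
    atom_b: str
    distance: float
    kind: str  # "salt_bridge" | "hydrogen_bond"

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")


def _angle_dev(value: float, target: float) -> float:
    d = abs(value - target) % 360.0
    return min(d, 360.0 - d)


def _matches(angles, targets, tolerance: float) -> bool:
    """All angles within tolerance, a single one allowed up to 1.5x tolerance."""
    devs = [_angle_dev(a, t) for a, t in zip(angles, targets)]
    over = [d for d in devs if d > tolerance]
    if not over:
        return True
    return len(over) == 1 and over[0] <= 1.5 * tolerance


def _is_helix_core(phi: Optional[float], psi: Optional[float]) -> bool:
    """Tight ideal-helix box (within 15 deg of phi=-57, psi=-47).

    Used to suppress windows that are interiors of regular helices; the box
    is deliberately narrow so that near-helical turn conformations (e.g. a
    type I i+1 at (-60, -30)) still classify as turns.
    """
    if phi is None or psi is None:
        return False
    return -72.0 <= phi <= -42.0 and -62.0 <= psi <= -32.0


def _is_helical_broad(phi: Optional[float], psi: Optional[float]) -> bool:
    """Permissive alpha-region box used to type alpha vs pseudo-alpha turns."""
    if phi is None or psi is None:
        return False
    return -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0


def classify_turns(
    structure: Structure, chain: Optional[str] = None, tolerance: float = 30.0
) -> list[TurnAssignment]:
    """Assign beta, gamma/pseudo-gamma and alpha/pseudo-alpha turns.

    See the module docstring for the gates.  Overlapping assignments from
    different window lengths are all reported — a segment can form a beta
    turn in one state and a pseudo-gamma in another, and callers filter by
    ``length``/``turn_type`` as needed.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if chain is None:
        chains = structure.chains
        if len(chains) != 1:
            raise ValueError("chain must be given for a multi-chain structure")
        chain = chains[0]
    torsions = backbone_dihedrals(structure, chain)
    residues = structure.residues(chain)
    rids = [rid for _, rid, _ in residues]
    names = {rid: name for _, rid, name in residues}

    def ca(rid: int) -> Optional[np.ndarray]:
        i = structure.atom_index(chain, rid, "CA")
        return None if i is None else structure.coords[i]

    def heavy(rid: int, name: str) -> Optional[np.ndarray]:
        i = structure.atom_index(chain, rid, name)
        return None if i is None else structure.coords[i]

    def hbond(rid_o: int, rid_n: int) -> Optional[float]:
        o, n = heavy(rid_o, "O"), heavy(rid_n, "N")
        if o is None or n is None:
            return None
        d = float(np.linalg.norm(o - n))
        return d if d < HBOND_MAX else None

    out: list[TurnAssignment] = []

    # --- beta turns (4-residue windows) ------------------------------------
    for k in range(len(rids) - 3):
        w = rids[k : k + 4]
        cas = [ca(r) for r in w]
        if any(c is None for c in cas):
            continue
        if float(np.linalg.norm(cas[0] - cas[3])) >= BETA_CA_GATE:
            continue
        inner = [torsions[w[1]], torsions[w[2]]]
        if any(t["phi"] is None or t["psi"] is None for t in inner):
            continue
        if all(_is_helix_core(t["phi"], t["psi"]) for t in inner):
            continue  # interior of a regular helix, not a turn
        angles = (
            inner[0]["phi"], inner[0]["psi"], inner[1]["phi"], inner[1]["psi"],
        )
        cis_pro_i2 = (
            names.get(w[2]) == "PRO"
            and torsions[w[2]]["omega"] is not None
            and abs(torsions[w[2]]["omega"]) < 30.0
        )
        assigned = "IV"
        candidates = CIS_PRO_TYPES if cis_pro_i2 else (
            set(CANONICAL_BETA_TURNS) - CIS_PRO_TYPES
        )
        for t in ("I", "I'", "II", "II'", "VIII", "VIa1", "VIa2", "VIb"):
            if t in candidates and _matches(angles, CANONICAL_BETA_TURNS[t], tolerance):
                assigned = t
                break
        out.append(
            TurnAssignment(
                chain=chain,
                start_res=w[0],
                length=4,
                turn_type=assigned,
                dihedrals=((angles[0], angles[1]), (angles[2], angles[3])),
                hbond_distance=hbond(w[0], w[3]),
            )
        )

    # --- gamma turns (3-residue windows) -----------------------------------
    for k in range(len(rids) - 2):
        w = rids[k : k + 3]
        cas = [ca(r) for r in w]
        if any(c is None for c in cas):
            continue
        if float(np.linalg.norm(cas[0] - cas[2])) >= GAMMA_CA_GATE:
            continue
        t1 = torsions[w[1]]
        if t1["phi"] is None or t1["psi"] is None:
            continue
        hb = hbond(w[0], w[2])
        label = None
        for name, target in GAMMA_TURNS.items():
            if _matches((t1["phi"], t1["psi"]), target, tolerance):
                label = name
                break
        if label is None:
            # Pseudo-gamma: the i->i+2 hydrogen-bond geometry without the
            # canonical central dihedrals (and not a plain helix interior).
            if hb is None or _is_helix_core(t1["phi"], t1["psi"]):
                continue
            label = "pseudo-gamma"
        out.append(
            TurnAssignment(
                chain=chain,
                start_res=w[0],
                length=3,
                turn_type=label,
                dihedrals=((t1["phi"], t1["psi"]),),
                hbond_distance=hb,
            )
        )

    # --- alpha turns (5-residue windows) -----------------------------------
    def _helix_run_flag(rid: int) -> bool:
        """Broad helical flag; a terminus with one undefined torsion counts
        when its defined torsion is helical (so helix ends extend the run)."""
        phi, psi = torsions[rid]["phi"], torsions[rid]["psi"]
        if phi is None and psi is None:
            return False
        if phi is None:
            return -80.0 <= psi <= -5.0
        if psi is None:
            return -100.0 <= phi <= -30.0
        return _is_helical_broad(phi, psi)

    helical_flags = {rid: _helix_run_flag(rid) for rid in rids}
    for k in range(len(rids) - 4):
        w = rids[k : k + 5]
        cas = [ca(r) for r in w]
        if any(c is None for c in cas):
            continue
        if float(np.linalg.norm(cas[0] - cas[4])) >= ALPHA_CA_GATE:
            continue
        inner = [torsions[r] for r in w[1:4]]
        if any(t["phi"] is None or t["psi"] is None for t in inner):
            continue
        # A window buried in a longer helix is secondary structure, not a turn.
        run = all(helical_flags.get(r, False) for r in w)
        before = k > 0 and helical_flags.get(rids[k - 1], False)
        after = k + 5 < len(rids) and helical_flags.get(rids[k + 5], False)
        if run and (before or after):
            continue
        all_helical = all(_is_helical_broad(t["phi"], t["psi"]) for t in inner)
        hb = hbond(w[0], w[4])
        if all_helical and hb is not None:
            label = "alpha"
        elif not all_helical:
            label = "pseudo-alpha"
        else:
            continue
        out.append(
            TurnAssignment(
                chain=chain,
                start_res=w[0],
                length=5,
                turn_type=label,
                dihedrals=tuple((t["phi"], t["psi"]) for t in inner),
                hbond_distance=hb,
            )
        )
    return out


# --- polar contacts --------------------------------------------------------

ACIDIC_O = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
BASIC_N = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
#: Heavy-atom hydrogen-bond donors/acceptors per residue (side chains), plus
#: the backbone N (donor) and O (acceptor) of every residue.
SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "TRP": ("NE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}


def detect_polar_contacts(
    structure: Structure,
    salt_bridge_cutoff: float = 4.0,
    hbond_cutoff: float = 3.5,
) -> list[ContactRecord]:
    """Salt bridges and hydrogen bonds from heavy-atom distances.

    A salt bridge is the minimum distance between an Asp/Glu carboxylate
    oxygen and an Arg/Lys/His side-chain nitrogen below the cutoff; one
    record per residue pair carries that minimal distance.  Hydrogen bonds
    are donor-acceptor heavy-atom pairs (backbone N/O plus the documented
    side-chain tables) below the cutoff, excluding intra-residue and
    backbone-backbone pairs of adjacent residues; residue pairs already
    recorded as salt bridges are not re-reported.
    """
    atoms = structure.atoms
    coords = structure.coords

    def find(res_filter, name_table):
        hits = []
        for i, a in enumerate(atoms):
            wanted = name_table.get(a.res_name)
            if wanted and a.name in wanted:
                hits.append(i)
        return hits

    records: list[ContactRecord] = []
    bridged: set[tuple] = set()

    acid = find(ACIDIC_O, ACIDIC_O)
    base = find(BASIC_N, BASIC_N)
    best: dict[tuple, tuple[float, int, int]] = {}
    for i in acid:
        for j in base:
            ai, aj = atoms[i], atoms[j]
            if (ai.chain, ai.res_id) == (aj.chain, aj.res_id):
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d >= salt_bridge_cutoff:
                continue
            key = tuple(sorted([(ai.chain, ai.res_id), (aj.chain, aj.res_id)]))
            if key not in best or d < best[key][0]:
                best[key] = (d, i, j)
    for key, (d, i, j) in sorted(best.items()):
        ai, aj = atoms[i], atoms[j]
        records.append(
            ContactRecord(ai.chain, ai.res_id, ai.name, aj.chain, aj.res_id, aj.name, d, "salt_bridge")
        )
        bridged.add(key)

    donors = [
        i for i, a in enumerate(atoms)
        if a.name == "N" or a.name in SIDECHAIN_DONORS.get(a.res_name, ())
    ]
    acceptors = [
        i for i, a in enumerate(atoms)
        if a.name == "O" or a.name in SIDECHAIN_ACCEPTORS.get(a.res_name, ())
    ]
    best_hb: dict[tuple, tuple[float, int, int]] = {}
    for i in donors:
        for j in acceptors:
            ai, aj = atoms[i], atoms[j]
            if (ai.chain, ai.res_id) == (aj.chain, aj.res_id):
                continue
            if (
                ai.name == "N" and aj.name == "O"
                and ai.chain == aj.chain and abs(ai.res_id - aj.res_id) == 1
            ):
                continue  # the peptide bond itself is not an H-bond
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d >= hbond_cutoff:
                continue
            key = tuple(sorted([(ai.chain, ai.res_id), (aj.chain, aj.res_id)]))
            if key in bridged:
                continue
            if key not in best_hb or d < best_hb[key][0]:
                best_hb[key] = (d, i, j)
    for key, (d, i, j) in sorted(best_hb.items()):
        ai, aj = atoms[i], atoms[j]
        records.append(
            ContactRecord(ai.chain, ai.res_id, ai.name, aj.chain, aj.res_id, aj.name, d, "hydrogen_bond")
        )
    return records
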