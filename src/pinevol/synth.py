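"""Synthetic inputs with known ground truth for every pipeline stage.

Generates (a) evolving interaction networks under a whole-genome-duplication
plus gain/loss plus subfunctionalization model, (b) quantitative
beta-galactosidase assay tables (Miller units) with replicate noise, leaky
background, auto-activating baits and empty-vector controls, (c) conformer
energy ensembles with an attached direct-evaluation reference entropy, and
(d) backbone structures built from dihedrals plus rigid-motion/noise
trajectories for the geometry stages.

The generative network model: start from an Erdos-Renyi graph over ordered
protein ids (self-pairs included as potential edges), evolve edge presence in
1-mya steps (each absent pair gains with probability ``gain_rate`` per mya,
each present edge is lost with probability ``loss_rate`` per mya), and at
each polyploidy event copy every node ``multiplicity`` times with
all-versus-all edge inheritance; with probability ``subfunc_prob`` a
duplicated node's family instead partitions the parent's partner set among
the copies (union of copy partner sets equals the parent's, pairwise
disjoint, in ancestral coordinates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .flexibility import ConformerEnsemble, R_CAL, KB_KCAL
from .network import PIN, OrthologMap, Edge, copy_name, edge_key
from .structure import Atom, Structure, Trajectory, dihedral_angle

__all__ = [
    "EvolutionParams",
    "EvolutionTruth",
    "simulate_pin_evolution",
    "simulate_assay_table",
    "simulate_conformer_ensemble",
    "build_backbone_from_dihedrals",
    "perturb_structure",
]


# ---------------------------------------------------------------------------
# Network evolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolutionParams:
    """Parameters of the generative network-evolution model.

    Times are in mya and decrease toward the present; ``epochs`` are the
    snapshot times and ``events`` the (time, multiplicity) polyploidy events.
    ``gain_rate`` is the per-mya gain probability for an absent potential
    pair, ``loss_rate`` the per-mya loss probability for an existing edge.
    """

    n0: int = 10
    p0: float = 0.25
    events: tuple[tuple[float, int], ...] = ()
    gain_rate: float = 0.001
    loss_rate: float = 0.005
    subfunc_prob: float = 0.0
    epochs: tuple[float, ...] = (120.0, 109.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must lie in [0, 1]")
        if not (0.0 <= self.subfunc_prob <= 1.0):
            raise ValueError("subfunc_prob must lie in [0, 1]")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if len(self.epochs) < 1:
            raise ValueError("at least one snapshot epoch required")
        if any(b >= a for a, b in zip(self.epochs, self.epochs[1:])):
            raise ValueError(
                "epoch times must be strictly decreasing toward the present"
            )
        for t, m in self.events:
            if m < 2:
                raise ValueError("event multiplicity must be >= 2")
            if not (self.epochs[-1] <= t <= self.epochs[0]):
                raise ValueError(
                    f"event at {t} mya lies outside the simulated interval"
                )


@dataclass(frozen=True)
class EvolutionTruth:
    """Emitted history: snapshots, maps between consecutive snapshots, truth.

    ``true_gain_rate``/``true_loss_rate`` are the expected comparison-based
    rates (per potential pair of the descendant frame per mya), obtained by
    propagating the realized start-of-window edge density through the exact
    per-pair two-state Markov chain, averaged over event-free windows; when
    every window contains a polyploidy event they fall back to the raw
    per-mya hazards.
    """

    snapshots: tuple[PIN, ...]
    ortholog_maps: tuple[OrthologMap, ...]
    true_gain_rate: float
    true_loss_rate: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.ortholog_maps) != max(len(self.snapshots) - 1, 0):
            raise ValueError("need one ortholog map per consecutive snapshot pair")


def _all_pairs(nodes: Sequence[str]) -> list[Edge]:
    ns = sorted(nodes)
    return [(a, b) for i, a in enumerate(ns) for b in ns[i:]]


def _expected_window_rates(
    d0: float, g: float, l: float, steps: int
) -> tuple[float, float]:
    """Exact E[gained]/(potential*dt) and E[lost]/(potential*dt).

    Per pair, presence evolves as a two-state chain with per-step gain g and
    loss l.  "Gained" in a snapshot comparison means absent at the window
    start and present at the end; "lost" the reverse.
    """
    # P(present at end | start state) after `steps` steps.
    p_pres_given_absent = 0.0
    p_pres_given_present = 1.0
    for _ in range(steps):
        p_pres_given_absent = p_pres_given_absent * (1 - l) + (1 - p_pres_given_absent) * g
        p_pres_given_present = p_pres_given_present * (1 - l) + (1 - p_pres_given_present) * g
    e_gain = (1 - d0) * p_pres_given_absent
    e_loss = d0 * (1 - p_pres_given_present)
    return e_gain / steps, e_loss / steps


def simulate_pin_evolution(params: EvolutionParams) -> EvolutionTruth:
    """Simulate a network history and return snapshots with ground truth."""
    rng = np.random.default_rng(params.seed)
    width = len(str(max(params.n0 - 1, 1)))
    nodes: list[str] = [f"P{i:0{width}d}" for i in range(params.n0)]
    edges: set[Edge] = set()
    for pair in _all_pairs(nodes):
        if rng.random() < params.p0:
            edges.add(pair)

    # Timeline: integer 1-mya steps from the oldest epoch to the youngest.
    t0, t_end = params.epochs[0], params.epochs[-1]
    events = sorted(params.events, key=lambda e: -e[0])
    epoch_iter = list(params.epochs)

    snapshots: list[PIN] = []
    maps: list[OrthologMap] = []
    # Identity-so-far map from the previous snapshot's nodes to current nodes.
    window_map: dict[str, set[str]] = {}
    window_has_event: list[bool] = []
    window_start_density: list[float] = []
    window_steps: list[int] = []

    def take_snapshot(t: float) -> None:
        pin = PIN(
            epoch_label=f"t{t:g}",
            time_mya=t,
            nodes=frozenset(nodes),
            edges=frozenset(edges),
        )
        if snapshots:
            maps.append(
                OrthologMap({a: frozenset(d) for a, d in window_map.items()})
            )
        snapshots.append(pin)
        # Start a fresh identity map for the next window.
        window_map.clear()
        window_map.update({n: {n} for n in nodes})

    def apply_event(multiplicity: int) -> None:
        nonlocal edges
        parent_partners: dict[str, set[str]] = {n: set() for n in nodes}
        for a, b in edges:
            parent_partners[a].add(b)
            parent_partners[b].add(a)
        copies = {n: [copy_name(n, k) for k in range(1, multiplicity + 1)] for n in nodes}
        # Subfunctionalization decision per parent family.
        partition: dict[str, dict[str, str]] = {}
        for n in nodes:
            if parent_partners[n] and rng.random() < params.subfunc_prob:
                assign = {}
                for partner in sorted(parent_partners[n]):
                    assign[partner] = copies[n][rng.integers(multiplicity)]
                partition[n] = assign
        new_edges: set[Edge] = set()
        for a, b in edges:
            for ca in copies[a]:
                for cb in copies[b]:
                    # A partitioned family keeps an edge only via the copy
                    # that was assigned this ancestral partner.
                    if a in partition and partition[a][b] != ca:
                        continue
                    if b in partition and partition[b][a] != cb:
                        continue
                    new_edges.add(edge_key(ca, cb))
        new_nodes = [c for n in nodes for c in copies[n]]
        # Extend the in-window descent map.
        for anc, descs in list(window_map.items()):
            window_map[anc] = {c for d in descs for c in copies.get(d, [d])}
        nodes.clear()
        nodes.extend(sorted(new_nodes))
        edges = new_edges

    def step_once() -> None:
        nonlocal edges
        pairs = _all_pairs(nodes)
        new_edges = set()
        for pair in pairs:
            if pair in edges:
                if rng.random() >= params.loss_rate:
                    new_edges.add(pair)
            else:
                if rng.random() < params.gain_rate:
                    new_edges.add(pair)
        edges = new_edges

    t = t0
    window_map = {n: {n} for n in nodes}
    had_event = False
    start_density = len(edges) / max(len(_all_pairs(nodes)), 1)
    steps_in_window = 0
    pending_events = list(events)
    pending_epochs = list(epoch_iter)
    if pending_epochs and pending_epochs[0] == t0:
        take_snapshot(t0)
        pending_epochs.pop(0)
        had_event = False
        start_density = len(edges) / max(len(_all_pairs(nodes)), 1)
        steps_in_window = 0
    while t > t_end:
        # Events scheduled at this instant (after the snapshot at t, before stepping).
        while pending_events and math.isclose(pending_events[0][0], t):
            apply_event(pending_events.pop(0)[1])
            had_event = True
        step_once()
        steps_in_window += 1
        t -= 1.0
        while pending_events and pending_events[0][0] > t and not math.isclose(pending_events[0][0], t):
            # Event time fell inside the step interval; apply it now.
            apply_event(pending_events.pop(0)[1])
            had_event = True
        while pending_epochs and (math.isclose(pending_epochs[0], t) or pending_epochs[0] > t):
            window_has_event.append(had_event)
            window_start_density.append(start_density)
            window_steps.append(steps_in_window)
            take_snapshot(pending_epochs.pop(0))
            had_event = False
            start_density = len(edges) / max(len(_all_pairs(nodes)), 1)
            steps_in_window = 0
    while pending_events and math.isclose(pending_events[0][0], t_end):
        apply_event(pending_events.pop(0)[1])
        had_event = True
    if pending_epochs:
        window_has_event.append(had_event)
        window_start_density.append(start_density)
        window_steps.append(steps_in_window)
        for te in pending_epochs:
            take_snapshot(te)

    free = [
        _expected_window_rates(d, params.gain_rate, params.loss_rate, max(s, 1))
        for d, s, ev in zip(window_start_density, window_steps, window_has_event)
        if not ev and s > 0
    ]
    if free:
        true_gain = float(np.mean([g for g, _ in free]))
        true_loss = float(np.mean([l for _, l in free]))
    else:
        true_gain, true_loss = params.gain_rate, params.loss_rate
    return EvolutionTruth(
        snapshots=tuple(snapshots),
        ortholog_maps=tuple(maps),
        true_gain_rate=true_gain,
        true_loss_rate=true_loss,
        seed=params.seed,
    )


# ---------------------------------------------------------------------------
# Assay tables
# ---------------------------------------------------------------------------

EMPTY_BAIT = "empty_BD"
EMPTY_PREY = "empty_AD"


def _lognormal_reps(rng, mean: float, cv: float, n: int) -> np.ndarray:
    """Log-normal replicates with the requested mean and coefficient of variation."""
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def simulate_assay_table(
    pin: PIN,
    signal_mu: float = 8.0,
    background_mu: float = 1.0,
    noise_cv: float = 0.15,
    n_reps: int = 3,
    autoactive_baits: Sequence[str] = (),
    mediator: Optional[str] = None,
    enhancement: float = 1.0,
    seed: int = 0,
    n_background_rows: int = 8,
) -> pd.DataFrame:
    """Simulate a quantitative beta-galactosidase assay table for a network.

    One row per ordered bait-prey combination over ``pin.nodes`` (self-pairs
    included), with ``n_reps`` log-normally perturbed Miller-unit replicates:
    edges of ``pin`` read at ``signal_mu`` (times ``enhancement`` when a
    mediator is present), non-edges at the leaky background ``background_mu``.
    Auto-active baits read at signal level regardless of prey.  Control rows:
    empty-vector (bait and prey both empty; reporter leakiness, the pooled
    background) and one auto-activation row per bait (bait vs empty prey).
    When ``mediator`` is given the table is a three-hybrid table and includes
    the mediator auto-activation control (mediator + empty prey).

    Wide format: columns bait, prey, mediator, assay_mode, is_control,
    control_kind, rep1..repN.
    """
    if not (signal_mu > background_mu > 0):
        raise ValueError("need signal_mu > background_mu > 0")
    if n_reps < 2:
        raise ValueError("interaction calling needs >= 2 replicates")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    mode = "Y3H" if mediator is not None else "Y2H"
    auto = set(autoactive_baits)
    bad = auto - set(pin.nodes)
    if bad:
        raise ValueError(f"autoactive_baits not in network: {sorted(bad)}")

    rows: list[dict] = []

    def add_row(bait, prey, mean, is_control=False, control_kind="none"):
        reps = _lognormal_reps(rng, mean, noise_cv, n_reps)
        row = {
            "bait": bait,
            "prey": prey,
            "mediator": mediator if mode == "Y3H" else "",
            "assay_mode": mode,
            "is_control": is_control,
            "control_kind": control_kind,
        }
        row.update({f"rep{i + 1}": float(v) for i, v in enumerate(reps)})
        rows.append(row)

    for _ in range(n_background_rows):
        add_row(EMPTY_BAIT, EMPTY_PREY, background_mu, True, "empty_vector")
    for bait in sorted(pin.nodes):
        mean = signal_mu if bait in auto else background_mu
        add_row(bait, EMPTY_PREY, mean, True, "autoactivation")
    if mode == "Y3H":
        # Mediator auto-activation control (mediator vector + empty prey).
        add_row(mediator, EMPTY_PREY, background_mu, True, "mediator_autoactivation")
    signal_level = signal_mu * (enhancement if mode == "Y3H" else 1.0)
    for bait in sorted(pin.nodes):
        for prey in sorted(pin.nodes):
            if bait in auto:
                mean = signal_level
            elif pin.has_edge(bait, prey):
                mean = signal_level
            else:
                mean = background_mu
            add_row(bait, prey, mean)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Conformer ensembles
# ---------------------------------------------------------------------------

def simulate_conformer_ensemble(
    n: int,
    energy_scale: float = 1.0,
    distribution: Literal["uniform-window", "exponential", "gaussian"] = "exponential",
    temperature: float = 298.15,
    seed: int = 0,
    label: str = "",
) -> tuple[ConformerEnsemble, float]:
    """Draw ``n`` conformer energies (kcal/mol) and attach a reference entropy.

    The reference entropy (cal K^-1 mol^-1) is computed by direct evaluation
    of the Boltzmann weights, in long-double precision, independently of the
    analysis module.  Returns (ensemble, reference_entropy).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if energy_scale < 0:
        raise ValueError("energy_scale must be >= 0")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    if distribution == "uniform-window":
        e = rng.uniform(0.0, energy_scale, size=n) if energy_scale > 0 else np.zeros(n)
    elif distribution == "exponential":
        e = rng.exponential(energy_scale, size=n) if energy_scale > 0 else np.zeros(n)
    elif distribution == "gaussian":
        e = rng.normal(0.0, energy_scale, size=n) if energy_scale > 0 else np.zeros(n)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    ensemble = ConformerEnsemble.from_energies(e, temperature, label)
    # Direct long-double evaluation of S = -R sum p ln p.
    el = np.asarray(e, dtype=np.longdouble)
    beta = 1.0 / (np.longdouble(KB_KCAL) * np.longdouble(temperature))
    w = np.exp(-(el - el.min()) * beta)
    p = w / w.sum()
    ref_entropy = float(-np.longdouble(R_CAL) * np.sum(p * np.log(p)))
    return ensemble, ref_entropy


# ---------------------------------------------------------------------------
# Backbone fixtures
# ---------------------------------------------------------------------------

THREE_LETTER = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Ideal backbone geometry (Engh-Huber-style averages), Angstrom / degrees.
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
B_CA_CB = 1.521
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.8
A_N_CA_CB = 110.5


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Natural-extension-reference-frame placement of the next atom.

    Positions atom d with |cd| = bond, angle b-c-d = angle_deg and torsion
    a-b-c-d = torsion_deg.
    """
    ang = math.radians(angle_deg)
    tor = -math.radians(torsion_deg)  # sign matches the IUPAC convention of dihedral_angle
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_backbone_from_dihedrals(
    residues: Sequence[tuple[str, float, float, float]],
    chain: str = "A",
    start_res_id: int = 1,
) -> Structure:
    """Build an ideal-geometry backbone from (name, phi, psi, omega) tuples.

    Chain extension uses ideal bond lengths/angles; phi of the first residue
    is unused (no preceding carbonyl) and omega(i) is the peptide torsion
    preceding residue i (omega = 0 builds a cis peptide bond, as in
    cis-proline).  Atoms built per residue: N, CA, C, O, and CB for non-Gly.
    Recomputing phi/psi/omega from the output reproduces the inputs to well
    under a degree (the construction is exact up to floating point).
    """
    if len(residues) < 2:
        raise ValueError("need at least 2 residues")
    for name, phi, psi, omega in residues:
        if name.upper() not in THREE_LETTER:
            raise ValueError(f"unknown residue name {name!r}")
        for ang in (phi, psi, omega):
            if not (-180.0 < ang <= 180.0):
                raise ValueError(f"angle {ang} outside (-180, 180]")

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []

    def emit(name: str, res_name: str, res_id: int, xyz: np.ndarray, element=None):
        atoms.append(Atom(name, element or name[0], res_name, res_id, chain))
        coords.append(np.asarray(xyz, dtype=float))

    n_pos = np.array([0.0, 0.0, 0.0])
    ca_pos = np.array([B_N_CA, 0.0, 0.0])
    ang = math.radians(A_N_CA_C)
    c_pos = ca_pos + B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])

    backbone: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for i, (name, phi, psi, omega) in enumerate(residues):
        rn = name.upper()
        rid = start_res_id + i
        if i > 0:
            n_prev, ca_prev, c_prev = backbone[-1]
            psi_prev = residues[i - 1][2]
            n_pos = _place_atom(n_prev, ca_prev, c_prev, B_C_N, A_CA_C_N, psi_prev)
            ca_pos = _place_atom(ca_prev, c_prev, n_pos, B_N_CA, A_C_N_CA, omega)
            c_pos = _place_atom(c_prev, n_pos, ca_pos, B_CA_C, A_N_CA_C, phi)
        backbone.append((n_pos, ca_pos, c_pos))
        emit("N", rn, rid, n_pos)
        emit("CA", rn, rid, ca_pos, "C")
        if rn != "GLY":
            # CB off the N-CA-C frame; torsion chosen for an L-amino acid.
            cb = _place_atom(c_pos, n_pos, ca_pos, B_CA_CB, A_N_CA_CB, 122.6)
            emit("CB", rn, rid, cb, "C")
        emit("C", rn, rid, c_pos)
        # Carbonyl O in the peptide plane: torsion N-CA-C-O = psi + 180.
        o = _place_atom(n_pos, ca_pos, c_pos, B_C_O, A_CA_C_O, residues[i][2] + 180.0)
        emit("O", rn, rid, o)
    return Structure(atoms, np.asarray(coords))


def perturb_structure(
    s: Structure,
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise_sigma: float = 0.0,
    n_frames: int = 1,
    seed: int = 0,
    dt_ns: float = 1.0,
) -> Trajectory:
    """Rigid transform of ``s`` plus per-frame isotropic Gaussian noise.

    Euler angles are intrinsic x-y-z, degrees.  Frame 0 is always noise-free
    (exactly the transform of ``s``); frames 1..n-1 add N(0, noise_sigma^2)
    per coordinate.  Times run 0, dt_ns, 2*dt_ns, ...
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    rot = Rotation.from_euler("xyz", rotation, degrees=True).as_matrix()
    base = s.coords @ rot.T + np.asarray(translation, dtype=float)
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    if noise_sigma > 0 and n_frames > 1:
        frames[1:] += rng.normal(0.0, noise_sigma, size=frames[1:].shape)
    times = [i * dt_ns for i in range(n_frames)]
    return Trajectory(s, frames, times)
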