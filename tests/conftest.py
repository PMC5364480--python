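"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from pinevol import (
    PIN,
    EvolutionParams,
    build_backbone_from_dihedrals,
    simulate_pin_evolution,
)


@pytest.fixture(scope="session")
def helix_structure():
    """12-residue ideal alpha-helix (phi=-57, psi=-47, trans peptide bonds)."""
    return build_backbone_from_dihedrals([("ALA", -57.0, -47.0, 180.0)] * 12)


def make_turn_structure(
    phi1: float, psi1: float, phi2: float, psi2: float,
    names=("ALA", "ALA", "ALA", "ALA"),
    omega2: float = 180.0,
):
    """4-residue window with flanking extended residues; omega2 is the
    peptide torsion preceding the i+2 residue (0 builds cis)."""
    residues = [
        (names[0], 180.0, 120.0, 180.0),
        (names[1], phi1, psi1, 180.0),
        (names[2], phi2, psi2, omega2),
        (names[3], 180.0, 140.0, 180.0),
    ]
    return build_backbone_from_dihedrals(residues)


@pytest.fixture(scope="session")
def small_pin():
    """Static 12-node network with ~30% of pairs interacting."""
    params = EvolutionParams(
        n0=12, p0=0.3, gain_rate=0.0, loss_rate=0.0, epochs=(120.0,), seed=42
    )
    return simulate_pin_evolution(params).snapshots[0]


@pytest.fixture(scope="session")
def two_epoch_truth():
    """Evolving 20-node history over an 11-mya window, no polyploidy."""
    params = EvolutionParams(
        n0=20, p0=0.25, gain_rate=0.004, loss_rate=0.02,
        epochs=(120.0, 109.0), seed=7,
    )
    return simulate_pin_evolution(params)
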