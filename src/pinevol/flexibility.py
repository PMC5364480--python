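"""Conformational flexibility descriptors from conformer-energy ensembles.

A conformational search yields a set of local-minimum conformers with
potential energies E_i (kcal/mol).  Assuming a Boltzmann distribution at
temperature T, each conformer has probability

    P_i = exp(-(E_i - E_min) / kT) / sum_j exp(-(E_j - E_min) / kT)

and the conformational entropy, used here as a flexibility descriptor, is

    S = -R * sum_i P_i ln P_i        [cal K^-1 mol^-1]

with the gas constant R = 1.98720 cal mol^-1 K^-1.  S ranges from 0 (a single
dominant conformer, rigid) to R ln N (N equiprobable conformers, maximally
flexible).  The size of the accessible conformational space is additionally
summarised by the number of low-energy minima within a window above the
global minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "R_CAL",
    "KB_KCAL",
    "ConformerEnsemble",
    "FlexibilityReport",
    "boltzmann_probabilities",
    "conformational_entropy",
    "count_low_energy_minima",
    "compare_flexibility",
]

#: Gas constant in cal mol^-1 K^-1 (entropies are molar).
R_CAL = 1.98720
#: Boltzmann/gas constant in kcal mol^-1 K^-1, for Boltzmann weights.
KB_KCAL = R_CAL / 1000.0


@dataclass(frozen=True)
class ConformerEnsemble:
    """Potential energies (kcal/mol) of a conformer set at temperature T (K)."""

    energies: tuple[float, ...]
    temperature: float = 298.15
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.energies) == 0:
            raise ValueError("ensemble must contain at least one conformer")
        arr = np.asarray(self.energies, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("all conformer energies must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")

    @staticmethod
    def from_energies(
        energies: Sequence[float], temperature: float = 298.15, label: str = ""
    ) -> "ConformerEnsemble":
        return ConformerEnsemble(tuple(float(e) for e in energies), temperature, label)

    @property
    def n(self) -> int:
        return len(self.energies)


@dataclass(frozen=True)
class FlexibilityReport:
    probabilities: tuple[float, ...]
    entropy: float  # cal K^-1 mol^-1
    n_minima: int
    max_entropy: float  # R ln N

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities)
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("probabilities must sum to 1")
        if not (-1e-12 <= self.entropy <= self.max_entropy + 1e-9):
            raise ValueError("entropy outside [0, R ln N]")


def boltzmann_probabilities(ensemble: ConformerEnsemble) -> np.ndarray:
    """Boltzmann conformer probabilities, stabilised by shifting to the minimum.

    Invariant to adding any constant to all energies (the shift cancels in the
    normalisation), which also makes the computation overflow-safe.
    """
    e = np.asarray(ensemble.energies, dtype=float)
    kt = KB_KCAL * ensemble.temperature
    w = np.exp(-(e - e.min()) / kt)
    return w / w.sum()


def conformational_entropy(probabilities: Sequence[float]) -> float:
    """S = -R sum P_i ln P_i in cal K^-1 mol^-1; P_i = 0 terms contribute 0."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"probabilities must sum to 1 (got {total})")
    nz = p[p > 0]
    s = float(-R_CAL * np.sum(nz * np.log(nz)))
    return 0.0 if s == 0 else s


def count_low_energy_minima(ensemble: ConformerEnsemble, window: float = 5.0) -> int:
    """Conformers within ``window`` kcal/mol of the global minimum.

    ``window = inf`` returns the full ensemble size.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    e = np.asarray(ensemble.energies, dtype=float)
    return int(np.count_nonzero(e - e.min() <= window))


def flexibility_report(ensemble: ConformerEnsemble, window: float = 5.0) -> FlexibilityReport:
    """Full flexibility descriptor set for one ensemble."""
    p = boltzmann_probabilities(ensemble)
    return FlexibilityReport(
        probabilities=tuple(float(x) for x in p),
        entropy=conformational_entropy(p),
        n_minima=count_low_energy_minima(ensemble, window),
        max_entropy=float(R_CAL * np.log(ensemble.n)),
    )


def compare_flexibility(
    a: ConformerEnsemble, b: ConformerEnsemble, window: float = 5.0
) -> dict:
    """Compare two ensembles as flexibility descriptors.

    Reports the fold-change in low-energy minima counts (b relative to a),
    the entropy difference dS = S_b - S_a, and which ensemble is more
    flexible (higher conformational entropy).  Ensembles must share a
    temperature; comparing across temperatures requires explicit
    re-evaluation and is refused.
    """
    if a.temperature != b.temperature:
        raise ValueError(
            "ensembles have different temperatures; re-evaluate at a common T"
        )
    s_a = conformational_entropy(boltzmann_probabilities(a))
    s_b = conformational_entropy(boltzmann_probabilities(b))
    n_a = count_low_energy_minima(a, window)
    n_b = count_low_energy_minima(b, window)
    delta = s_b - s_a
    if s_b > s_a:
        more = b.label or "b"
    elif s_a > s_b:
        more = a.label or "a"
    else:
        more = "equal"
    return {
        "label_a": a.label or "a",
        "label_b": b.label or "b",
        "n_minima_a": n_a,
        "n_minima_b": n_b,
        "minima_fold_change": n_b / n_a if n_a else float("inf"),
        "entropy_a": s_a,
        "entropy_b": s_b,
        "delta_entropy": delta,
        "more_flexible": more,
        "temperature": a.temperature,
        "window_kcal": window,
    }


__all__.append("flexibility_report")
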