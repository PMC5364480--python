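"""Quantitative yeast two-/three-hybrid interaction calling.

Input tables carry beta-galactosidase activity in Miller units per
bait-prey(-mediator) combination with replicates, plus control rows:
empty-vector co-transformations measure reporter leakiness (the pooled
background) and bait + empty-prey rows measure bait auto-activation.

A dimeric (Y2H) pair is called positive when a one-sided Welch t-test of its
replicates against the pooled background rejects at ``alpha`` AND its mean
exceeds ``min_fold`` times the background mean; pairs whose bait
auto-activates are excluded from calling.  A mediated (Y3H) interaction is
positive when the pair is Y2H-negative but Y3H-positive, or when the
three-hybrid signal significantly exceeds the two-hybrid signal (delta above
``min_delta`` with a one-sided test) — i.e. an interaction that was not
present as a dimer or was significantly enhanced by the mediator.  Negative
deltas (three-hybrid below two-hybrid) are lost/false-positive signals and
always yield a negative call.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .network import edge_key

__all__ = [
    "AssayMeasurement",
    "InteractionCall",
    "read_assay_table",
    "call_dimeric_interactions",
    "call_mediated_interactions",
]


@dataclass(frozen=True)
class AssayMeasurement:
    bait: str
    prey: str
    mediator: Optional[str]
    assay_mode: str  # "Y2H" | "Y3H"
    replicates: tuple[float, ...]
    is_control: bool = False
    control_kind: str = "none"  # autoactivation | empty_vector | mediator_autoactivation | none

    def __post_init__(self) -> None:
        if self.assay_mode not in ("Y2H", "Y3H"):
            raise ValueError(f"unknown assay mode {self.assay_mode!r}")
        if not self.replicates:
            raise ValueError("replicates must be non-empty")
        if any(r <= 0 for r in self.replicates):
            raise ValueError("Miller units must be positive")
        if (self.mediator is not None) != (self.assay_mode == "Y3H"):
            raise ValueError("mediator present iff assay_mode is Y3H")

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))


@dataclass(frozen=True)
class InteractionCall:
    pair: tuple[str, str]  # canonical unordered; self-pairs allowed
    mode: str  # "dimeric" | "mediated"
    mediator: Optional[str]
    mean_signal: float  # Miller units
    delta: float  # vs background (dimeric) or Y3H - Y2H (mediated)
    status: str  # positive | negative | autoactive_excluded
    p_value: Optional[float]
    background_mean: float = float("nan")

    def __post_init__(self) -> None:
        if self.status == "positive" and not self.delta > 0:
            raise ValueError("positive calls require delta > 0")
        if self.status == "autoactive_excluded" and self.p_value is not None:
            raise ValueError("autoactive_excluded pairs carry no p_value")


_DEFAULT_DIALECT = {
    "bait": "bait",
    "prey": "prey",
    "mediator": "mediator",
    "assay_mode": "assay_mode",
    "is_control": "is_control",
    "control_kind": "control_kind",
    "replicate": "replicate",
    "value": "value",
    "rep_prefix": "rep",
}


def read_assay_table(
    source: Union[str, io.TextIOBase, pd.DataFrame],
    dialect: Optional[dict] = None,
    sep: Optional[str] = None,
) -> list[AssayMeasurement]:
    """Parse a wide- or long-format assay table into measurements.

    Wide format has replicate columns ``rep1, rep2, ...``; long format has a
    replicate-index column and a value column, one row per replicate.
    ``dialect`` remaps column names.  Malformed numeric cells and
    non-positive Miller values are hard errors naming the offending row
    (1-based, excluding the header).
    """
    d = dict(_DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        if sep is None:
            sep = None  # let pandas sniff csv/tsv
        df = pd.read_csv(source, sep=sep, engine="python")
    for required in ("bait", "prey"):
        if d[required] not in df.columns:
            raise ValueError(f"missing required column {d[required]!r}")

    rep_cols = [c for c in df.columns if str(c).startswith(d["rep_prefix"]) and str(c)[len(d["rep_prefix"]):].isdigit()]
    long_format = not rep_cols
    if long_format and (d["replicate"] not in df.columns or d["value"] not in df.columns):
        raise ValueError(
            "table has neither wide replicate columns "
            f"({d['rep_prefix']}1, ...) nor long-format "
            f"({d['replicate']!r}, {d['value']!r}) columns"
        )

    def parse_value(v, row_number: int) -> float:
        try:
            x = float(v)
        except (TypeError, ValueError):
            raise ValueError(f"row {row_number}: malformed Miller value {v!r}")
        if not math.isfinite(x) or x <= 0:
            raise ValueError(f"row {row_number}: non-positive Miller value {v!r}")
        return x

    def meta(row):
        mediator = row.get(d["mediator"], "")
        if pd.isna(mediator) or mediator == "":
            mediator = None
        mode = row.get(d["assay_mode"], None)
        if mode is None or pd.isna(mode):
            mode = "Y3H" if mediator is not None else "Y2H"
        is_control = bool(row.get(d["is_control"], False))
        kind = row.get(d["control_kind"], "none")
        if pd.isna(kind) or kind == "":
            kind = "none"
        return mediator, str(mode), is_control, str(kind)

    measurements: list[AssayMeasurement] = []
    if not long_format:
        for i, row in df.iterrows():
            reps = tuple(
                parse_value(row[c], i + 1)
                for c in rep_cols
                if not (pd.isna(row[c]))
            )
            mediator, mode, is_control, kind = meta(row)
            measurements.append(
                AssayMeasurement(
                    bait=str(row[d["bait"]]),
                    prey=str(row[d["prey"]]),
                    mediator=mediator,
                    assay_mode=mode,
                    replicates=reps,
                    is_control=is_control,
                    control_kind=kind,
                )
            )
    else:
        groups: dict[tuple, list[tuple[int, float]]] = {}
        metas: dict[tuple, tuple] = {}
        for i, row in df.iterrows():
            mediator, mode, is_control, kind = meta(row)
            key = (str(row[d["bait"]]), str(row[d["prey"]]), mediator, mode, is_control, kind)
            rep_idx = int(row[d["replicate"]])
            groups.setdefault(key, []).append((rep_idx, parse_value(row[d["value"]], i + 1)))
            metas[key] = (mediator, mode, is_control, kind)
        for key, vals in groups.items():
            vals.sort(key=lambda t: t[0])
            mediator, mode, is_control, kind = metas[key]
            measurements.append(
                AssayMeasurement(
                    bait=key[0],
                    prey=key[1],
                    mediator=mediator,
                    assay_mode=mode,
                    replicates=tuple(v for _, v in vals),
                    is_control=is_control,
                    control_kind=kind,
                )
            )
    return measurements


def _pooled_background(measurements: Sequence[AssayMeasurement]) -> np.ndarray:
    vals: list[float] = []
    for m in measurements:
        if m.is_control and m.control_kind == "empty_vector":
            vals.extend(m.replicates)
    if not vals:
        raise ValueError("no empty-vector background controls in table")
    return np.asarray(vals, dtype=float)


def _one_sided_greater(sample: np.ndarray, reference: np.ndarray) -> float:
    """One-sided Welch t-test p-value for mean(sample) > mean(reference)."""
    if np.ptp(sample) == 0 and np.ptp(reference) == 0:
        # Degenerate zero-variance case: equal means are a non-rejection,
        # strictly larger means a rejection at any level.
        return 1.0 if sample.mean() <= reference.mean() else 0.0
    res = stats.ttest_ind(sample, reference, equal_var=False, alternative="greater")
    return float(res.pvalue)


def _autoactive_baits(
    measurements: Sequence[AssayMeasurement],
    background: np.ndarray,
    alpha: float,
    min_fold: float,
) -> set[str]:
    auto: set[str] = set()
    bg_mean = background.mean()
    for m in measurements:
        if m.is_control and m.control_kind == "autoactivation":
            reps = np.asarray(m.replicates)
            p = _one_sided_greater(reps, background)
            if p < alpha and reps.mean() > min_fold * bg_mean:
                auto.add(m.bait)
    return auto


def call_dimeric_interactions(
    measurements: Sequence[AssayMeasurement],
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> list[InteractionCall]:
    """Call dimeric interactions against the pooled empty-vector background.

    A pair is positive iff the one-sided Welch test of its replicates against
    pooled background rejects at ``alpha`` and its mean exceeds
    ``min_fold`` x background mean; calling is symmetric in bait/prey (a pair
    is positive if either orientation is).  Pairs whose bait auto-activates
    (bait + empty prey significantly above background) are excluded.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if min_fold < 1.0:
        raise ValueError("min_fold must be >= 1")
    background = _pooled_background(measurements)
    bg_mean = float(background.mean())
    auto = _autoactive_baits(measurements, background, alpha, min_fold)

    per_pair: dict[tuple[str, str], list[AssayMeasurement]] = {}
    for m in measurements:
        if m.is_control or m.assay_mode != "Y2H":
            continue
        per_pair.setdefault(edge_key(m.bait, m.prey), []).append(m)

    calls: list[InteractionCall] = []
    for pair in sorted(per_pair):
        orients = per_pair[pair]
        if any(m.bait in auto for m in orients):
            usable = [m for m in orients if m.bait not in auto]
            if not usable:
                calls.append(
                    InteractionCall(
                        pair=pair,
                        mode="dimeric",
                        mediator=None,
                        mean_signal=float(np.mean([m.mean for m in orients])),
                        delta=float(np.mean([m.mean for m in orients])) - bg_mean,
                        status="autoactive_excluded",
                        p_value=None,
                        background_mean=bg_mean,
                    )
                )
                continue
            orients = usable  # judge the pair from the clean orientation(s)
        best_p = 1.0
        best_mean = -np.inf
        positive = False
        for m in orients:
            reps = np.asarray(m.replicates)
            p = _one_sided_greater(reps, background)
            ok = p < alpha and reps.mean() > min_fold * bg_mean
            if ok:
                positive = True
            if reps.mean() > best_mean:
                best_mean = float(reps.mean())
                best_p = p
        calls.append(
            InteractionCall(
                pair=pair,
                mode="dimeric",
                mediator=None,
                mean_signal=best_mean,
                delta=best_mean - bg_mean,
                status="positive" if positive else "negative",
                p_value=best_p,
                background_mean=bg_mean,
            )
        )
    return calls


def call_mediated_interactions(
    y3h_measurements: Sequence[AssayMeasurement],
    y2h_calls: Sequence[InteractionCall],
    alpha: float = 0.05,
    min_delta: float = 0.0,
) -> list[InteractionCall]:
    """Subtract the two-hybrid network from three-hybrid measurements.

    For each pair, delta = mean(Y3H) - Y2H baseline, where the baseline is
    the pair's Y2H mean when it was Y2H-positive and the pooled background
    mean otherwise (a Y2H-negative pair has no dimer signal beyond
    leakiness).  Positive iff the pair is Y2H-negative and Y3H-positive
    against the Y3H background, or delta > ``min_delta`` with a one-sided
    one-sample t-test of the Y3H replicates against the baseline rejecting at
    ``alpha``.  Requires the mediator auto-activation control; an
    auto-active mediator invalidates the whole table.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    background = _pooled_background(y3h_measurements)
    bg_mean = float(background.mean())
    med_controls = [
        m for m in y3h_measurements
        if m.is_control and m.control_kind == "mediator_autoactivation"
    ]
    if not med_controls:
        raise ValueError("mediator auto-activation control missing from Y3H table")
    mediator_autoactive = any(
        _one_sided_greater(np.asarray(m.replicates), background) < alpha
        and m.mean > 2.0 * bg_mean
        for m in med_controls
    )
    auto = _autoactive_baits(y3h_measurements, background, alpha, 2.0)

    y2h_by_pair = {c.pair: c for c in y2h_calls}

    per_pair: dict[tuple[str, str], list[AssayMeasurement]] = {}
    mediators: dict[tuple[str, str], Optional[str]] = {}
    for m in y3h_measurements:
        if m.is_control or m.assay_mode != "Y3H":
            continue
        k = edge_key(m.bait, m.prey)
        per_pair.setdefault(k, []).append(m)
        mediators[k] = m.mediator

    calls: list[InteractionCall] = []
    for pair in sorted(per_pair):
        orients = per_pair[pair]
        mediator = mediators[pair]
        reps_all = np.concatenate([np.asarray(m.replicates) for m in orients])
        y3h_mean = float(reps_all.mean())
        y2h = y2h_by_pair.get(pair)
        y2h_positive = y2h is not None and y2h.status == "positive"
        baseline = float(y2h.mean_signal) if y2h_positive else bg_mean
        delta = y3h_mean - baseline
        if mediator_autoactive or any(m.bait in auto for m in orients):
            calls.append(
                InteractionCall(
                    pair=pair,
                    mode="mediated",
                    mediator=mediator,
                    mean_signal=y3h_mean,
                    delta=delta,
                    status="autoactive_excluded",
                    p_value=None,
                    background_mean=bg_mean,
                )
            )
            continue
        positive = False
        p_report: Optional[float] = None
        if not y2h_positive:
            # Not present as a dimer: positive iff Y3H-positive vs background.
            ps = []
            for m in orients:
                reps = np.asarray(m.replicates)
                p = _one_sided_greater(reps, background)
                ps.append(p)
                if p < alpha and reps.mean() > 2.0 * bg_mean:
                    positive = True
            p_report = min(ps)
        else:
            # Present as a dimer: positive iff significantly enhanced.
            ps = []
            for m in orients:
                reps = np.asarray(m.replicates)
                if np.ptp(reps) == 0:
                    p = 1.0 if reps.mean() <= baseline else 0.0
                else:
                    p = float(
                        stats.ttest_1samp(
                            reps, baseline, alternative="greater"
                        ).pvalue
                    )
                ps.append(p)
                if p < alpha and (reps.mean() - baseline) > min_delta:
                    positive = True
            p_report = min(ps)
        if delta <= 0:
            positive = False  # negative delta: lost/false-positive signal
        calls.append(
            InteractionCall(
                pair=pair,
                mode="mediated",
                mediator=mediator,
                mean_signal=y3h_mean,
                delta=delta,
                status="positive" if positive else "negative",
                p_value=p_report,
                background_mean=bg_mean,
            )
        )
    return calls
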