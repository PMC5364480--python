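#!/usr/bin/env python
"""Quantitative assay simulation and interaction calling for the youngest epoch.

Simulates Miller-unit beta-galactosidase tables for the 109-mya snapshot —
a two-hybrid table for the dimeric network and a three-hybrid table with a
mediator ("glue") protein whose ternary network adds extra pairs — then
calls interactions and reports recovery against the planted truth.
Run 01_simulate_network_history.py first.
"""

from pathlib import Path

from pinevol.assay import (
    call_dimeric_interactions,
    call_mediated_interactions,
    read_assay_table,
)
from pinevol.io import read_edge_list, write_calls_tsv, write_json_report
from pinevol.network import PIN, build_network, density, edge_key
from pinevol.synth import simulate_assay_table

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "calls"
# Bulky intermediates (full assay tables, per-pair call lists) go to scratch/.
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "calls"
SEED = 2018


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    y2h_pin = read_edge_list(BASE / "history" / "snapshot_2.tsv")

    # Ternary network: the mediator glues together ~15 extra protein pairs
    # that cannot dimerize on their own.
    import numpy as np

    rng = np.random.default_rng(SEED)
    nodes = sorted(y2h_pin.nodes)
    non_edges = sorted(
        {edge_key(a, b) for i, a in enumerate(nodes) for b in nodes[i:]}
        - y2h_pin.edges
    )
    mediated_only = [non_edges[i] for i in rng.choice(len(non_edges), 15, replace=False)]
    y3h_pin = PIN.from_edges(
        y2h_pin.epoch_label, y2h_pin.time_mya, nodes,
        list(y2h_pin.edges) + mediated_only,
    )

    y2h_df = simulate_assay_table(y2h_pin, 8.0, 1.0, 0.15, 3, seed=SEED)
    y3h_df = simulate_assay_table(y3h_pin, 8.0, 1.0, 0.15, 3, mediator="GLUE", seed=SEED + 1)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    y2h_df.to_csv(SCRATCH / "assay_y2h.csv", index=False)
    y3h_df.to_csv(SCRATCH / "assay_y3h.csv", index=False)

    y2h_calls = call_dimeric_interactions(read_assay_table(y2h_df))
    mediated_calls = call_mediated_interactions(
        read_assay_table(y3h_df), y2h_calls, min_delta=1.5
    )
    write_calls_tsv(y2h_calls, SCRATCH / "calls_dimeric.tsv", seed=SEED)
    write_calls_tsv(mediated_calls, SCRATCH / "calls_mediated.tsv", seed=SEED)

    dimeric_net, _ = build_network(y2h_calls, "Y2H-109", 109.0, "dimeric")
    mediated_pos = {c.pair for c in mediated_calls if c.status == "positive"}
    planted_mediated = {edge_key(a, b) for a, b in mediated_only}

    recovery = {
        "dimeric_recall": len(dimeric_net.edges & y2h_pin.edges) / len(y2h_pin.edges),
        "dimeric_false_positives": len(dimeric_net.edges - y2h_pin.edges),
        "mediated_recall": len(mediated_pos & planted_mediated) / len(planted_mediated),
        "mediated_false_positives": len(mediated_pos - planted_mediated),
        "y2h_density": density(dimeric_net),
        "n_mediated_planted": len(planted_mediated),
    }
    write_json_report(recovery, OUT / "recovery.json", seed=SEED)
    print(
        f"dimeric: recovered {len(dimeric_net.edges)} of {len(y2h_pin.edges)} "
        f"planted edges (recall {recovery['dimeric_recall']:.1%}, "
        f"{recovery['dimeric_false_positives']} false positives)"
    )
    print(
        f"mediated: recovered {len(mediated_pos)} of {len(planted_mediated)} "
        f"glue-dependent pairs (recall {recovery['mediated_recall']:.1%}, "
        f"{recovery['mediated_false_positives']} false positives)"
    )


if __name__ == "__main__":
    main()
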