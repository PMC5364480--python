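"""Readers/writers for networks, ortholog maps, calls and reports.

Edge lists and ortholog maps are plain TSV (with a ``#``-prefixed metadata
header carrying the tool version and config hash when provided); networks
also export to GraphML via networkx.  All writers round-trip through the
corresponding readers bit-exactly for text fields.
"""

from __future__ import annotations

import json
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from . import __version__
from .assay import InteractionCall
from .network import PIN, NetworkComparison, OrthologMap, edge_key

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
    "write_ortholog_map",
    "read_ortholog_map",
    "write_calls_tsv",
    "write_json_report",
    "meta_block",
]


def meta_block(config_hash: Optional[str] = None, seed: Optional[int] = None) -> dict:
    meta = {"tool": "pinevol", "version": __version__}
    if config_hash is not None:
        meta["config_hash"] = config_hash
    if seed is not None:
        meta["seed"] = seed
    return meta


def _header_lines(config_hash: Optional[str], seed: Optional[int]) -> list[str]:
    meta = meta_block(config_hash, seed)
    return ["# " + " ".join(f"{k}={v}" for k, v in meta.items())]


def write_edge_list(
    pin: PIN, path, config_hash: Optional[str] = None, seed: Optional[int] = None
) -> None:
    """TSV edge list: node_a, node_b, weight, epoch (+ one node-list line)."""
    lines = _header_lines(config_hash, seed)
    lines.append(f"# time_mya={pin.time_mya:g}")
    lines.append("# nodes=" + ",".join(sorted(pin.nodes)))
    lines.append("node_a\tnode_b\tweight\tepoch")
    for a, b in sorted(pin.edges):
        w = ""
        if pin.edge_weights is not None and (a, b) in pin.edge_weights:
            w = repr(float(pin.edge_weights[(a, b)]))
        lines.append(f"{a}\t{b}\t{w}\t{pin.epoch_label}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_edge_list(path) -> PIN:
    nodes: list[str] = []
    time_mya = 0.0
    edges = []
    weights = {}
    epoch = ""
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("# nodes="):
                nodes = line[len("# nodes="):].split(",") if line != "# nodes=" else []
                continue
            if line.startswith("# time_mya="):
                time_mya = float(line[len("# time_mya="):])
                continue
            if line.startswith("#") or line.startswith("node_a\t") or not line:
                continue
            a, b, w, epoch = line.split("\t")
            k = edge_key(a, b)
            edges.append(k)
            if w:
                weights[k] = float(w)
    return PIN(
        epoch_label=epoch,
        time_mya=time_mya,
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        edge_weights=weights or None,
    )


def write_graphml(pin: PIN, path) -> None:
    nx.write_graphml(pin.to_networkx(), path)


def write_ortholog_map(
    omap: OrthologMap, path, config_hash: Optional[str] = None, seed: Optional[int] = None
) -> None:
    """Two-column TSV of (ancestor, descendant) pairs."""
    lines = _header_lines(config_hash, seed)
    lines.append("ancestor\tdescendant")
    for anc in sorted(omap.forward):
        for desc in sorted(omap.forward[anc]):
            lines.append(f"{anc}\t{desc}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_ortholog_map(path) -> OrthologMap:
    pairs = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#") or line == "ancestor\tdescendant" or not line:
                continue
            anc, desc = line.split("\t")
            pairs.append((anc, desc))
    return OrthologMap.from_pairs(pairs)


def write_calls_tsv(
    calls: Sequence[InteractionCall],
    path,
    config_hash: Optional[str] = None,
    seed: Optional[int] = None,
) -> None:
    lines = _header_lines(config_hash, seed)
    lines.append("protein_a\tprotein_b\tmode\tmediator\tmean_signal\tdelta\tp_value\tstatus")
    for c in calls:
        a, b = c.pair
        p = "" if c.p_value is None else repr(float(c.p_value))
        med = c.mediator or ""
        lines.append(
            f"{a}\t{b}\t{c.mode}\t{med}\t{c.mean_signal!r}\t{c.delta!r}\t{p}\t{c.status}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def comparison_to_dict(cmp: NetworkComparison) -> dict:
    return {
        "conserved": sorted(list(e) for e in cmp.conserved),
        "gained": sorted(list(e) for e in cmp.gained),
        "lost": sorted(list(e) for e in cmp.lost),
        "n_conserved": len(cmp.conserved),
        "n_gained": len(cmp.gained),
        "n_lost": len(cmp.lost),
        "potential_edges": cmp.potential_edges,
        "divergence_mya": cmp.divergence_mya,
        "gain_rate": cmp.gain_rate,
        "loss_rate": cmp.loss_rate,
        "density_a": cmp.density_a,
        "density_b": cmp.density_b,
    }


def write_json_report(
    payload: dict, path, config_hash: Optional[str] = None, seed: Optional[int] = None
) -> None:
    doc = {"_meta": meta_block(config_hash, seed)}
    doc.update(payload)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


__all__.append("comparison_to_dict")
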