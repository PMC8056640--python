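"""Bipartite lncRNA-mRNA regulatory networks, their intersection and hubs."""
from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import networkx as nx

from .flowering import FloweringCall
from .targets import TargetPair


class RegulatoryNetwork:
    """Bipartite network of labelled lncRNAs and their target mRNAs.

    Backed by a :class:`networkx.MultiGraph` keyed by edge mode, so one
    lncRNA-mRNA pair may carry both a cis and a trans edge but never a
    duplicate (lncrna, mrna, mode) edge.
    """

    def __init__(self, label: str):
        self.label = label
        self.graph = nx.MultiGraph()

    def add_lncrna(self, lncrna_id: str) -> None:
        self.graph.add_node(lncrna_id, role="lncRNA", label=self.label)

    def add_edge(self, pair: TargetPair) -> None:
        self.add_lncrna(pair.lncrna_id)
        self.graph.add_node(pair.mrna_id, role="mRNA")
        self.graph.add_edge(pair.lncrna_id, pair.mrna_id, key=pair.mode, pair=pair)

    def iter_edges(self) -> Iterator[tuple[str, str, str, TargetPair]]:
        for u, v, mode, data in self.graph.edges(keys=True, data=True):
            pair = data["pair"]
            yield pair.lncrna_id, pair.mrna_id, mode, pair

    @property
    def lncrna_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["role"] == "lncRNA"}

    @property
    def mrna_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["role"] == "mRNA"}

    def target_set(self, modes: Sequence[str] = ("cis", "trans")) -> set[str]:
        return {
            pair.mrna_id
            for _, _, mode, pair in self.iter_edges()
            if mode in modes
        }

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    calls: Iterable[FloweringCall],
    pairs: Iterable[TargetPair],
    label: str,
) -> RegulatoryNetwork:
    """Subnetwork induced by lncRNAs carrying the given flowering label.

    Both cis and trans edges of those lncRNAs are retained, mode-tagged.
    A label with no lncRNAs yields an empty network.
    """
    if label not in ("positive", "negative"):
        raise ValueError(f"label must be 'positive' or 'negative', got {label!r}")
    wanted = {c.lncrna_id for c in calls if c.label == label}
    net = RegulatoryNetwork(label)
    for lnc in sorted(wanted):
        net.add_lncrna(lnc)
    for pair in pairs:
        if pair.lncrna_id in wanted:
            net.add_edge(pair)
    return net


def common_targets(
    pos: RegulatoryNetwork,
    neg: RegulatoryNetwork,
    modes: Sequence[str] = ("cis", "trans"),
) -> dict:
    """Intersection of the two networks' target mRNA sets and the shares.

    Shares are 100 * |common| / |targets(side)| rounded to 2 decimals;
    a side with no targets reports a missing (None) share.
    """
    t_pos = pos.target_set(modes)
    t_neg = neg.target_set(modes)
    common = t_pos & t_neg

    def share(denom: set[str]) -> float | None:
        if not denom:
            return None
        return round(100.0 * len(common) / len(denom), 2)

    return {
        "common": common,
        "n_common": len(common),
        "n_pos_targets": len(t_pos),
        "n_neg_targets": len(t_neg),
        "share_of_pos_pct": share(t_pos),
        "share_of_neg_pct": share(t_neg),
    }


def hub_report(net: RegulatoryNetwork, k: int) -> dict[str, list[tuple[str, int]]]:
    """Top-k nodes by degree on each side; ties break lexicographically."""
    if k <= 0:
        raise ValueError("k must be positive")
    if net.graph.number_of_nodes() == 0:
        raise ValueError("network is empty")

    def top(nodes: set[str]) -> list[tuple[str, int]]:
        ranked = sorted(nodes, key=lambda n: (-net.degree(n), n))
        return [(n, net.degree(n)) for n in ranked[:k]]

    return {"lncRNA": top(net.lncrna_nodes), "mRNA": top(net.mrna_nodes)}
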