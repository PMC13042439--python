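"""Charge-redistribution network analysis.

Guest binding does not only polarize the fragments that touch the ligand:
electron density is passed along chains of fragments.  The flow graph makes
this explicit: nodes are fragments (annotated with their apo-to-holo charge
change), and a directed edge I -> J of weight w means the dimer calculation
moved w electrons from I to J relative to the frozen monomers.  A *hub* is
a fragment k that mediates an indirect coupling: fragments i and j both
couple to k but share no direct edge (the mediation triplet i-k-j).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .fmo import FMO1Result, PairInteraction

__all__ = ["FlowGraph", "HubReport", "charge_flow_graph", "detect_hubs"]


@dataclass
class FlowGraph:
    graph: nx.DiGraph          # nodes: fragment ids; edges carry weight (e)
    threshold: float
    metadata: dict = field(default_factory=dict)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "weight_e": d["weight"],
                "derived_from": d["derived_from"],
            }
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight_e", "derived_from"])

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "fragment_id": n,
                "name": d.get("name", ""),
                "rmin_A": d.get("rmin", float("nan")),
                "delta_q_e": d.get("delta_q", float("nan")),
            }
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["fragment_id", "name", "rmin_A", "delta_q_e"])


def charge_flow_graph(
    apo: FMO1Result | None,
    holo: FMO1Result,
    pairs: list[PairInteraction],
    rmin: dict[int, float],
    threshold: float = 0.005,
) -> FlowGraph:
    """Directed fragment-level charge-flow graph.

    Node attribute ``delta_q`` is the holo-minus-apo fragment charge (for
    the guest, which has no apo state, holo charge minus formal charge).
    Edges come from the FMO2 dimer charge shifts: for a dimer pair (I, J)
    whose charge shift dq_I exceeds ``threshold``, an edge is drawn from the
    fragment that loses electron density to the one that gains it, weighted
    by |dq_I| (e).  If no dimer data is present, edges fall back to the
    delta_q difference heuristic (flagged in the metadata).
    """
    if threshold <= 0:
        raise ValueError("edge threshold must be positive")
    g = nx.DiGraph()
    apo_ids = (
        {f.id for f in apo.fragmap if f.role != "guest"} if apo is not None else set()
    )
    for f in holo.fragmap:
        q_holo = holo.fragment_charge(f.id)
        if apo is not None and f.id in apo_ids:
            dq = q_holo - apo.fragment_charge(f.id)
        else:
            dq = q_holo - f.formal_charge
        g.add_node(f.id, name=f.name, rmin=rmin.get(f.id, float("nan")), delta_q=dq)

    meta: dict = {"edge_source": "dimer"}
    dimers = [p for p in pairs if p.method == "dimer"]
    if dimers:
        for p in dimers:
            w = abs(p.charge_shift)
            if w < threshold or p.i == p.j:
                continue
            # charge_shift > 0: fragment i became more positive, i.e. lost
            # electron density to j.
            src, dst = (p.i, p.j) if p.charge_shift > 0 else (p.j, p.i)
            g.add_edge(src, dst, weight=w, derived_from="dimer")
    else:
        warnings.warn(
            "no dimer pairs available; deriving edges from the delta_q "
            "difference heuristic"
        )
        meta["edge_source"] = "delta_q"
        dq = nx.get_node_attributes(g, "delta_q")
        for p in pairs:
            if p.i not in dq or p.j not in dq:
                continue
            w = 0.5 * abs(dq[p.i] - dq[p.j])
            if w < threshold:
                continue
            src, dst = (p.i, p.j) if dq[p.i] > dq[p.j] else (p.j, p.i)
            g.add_edge(src, dst, weight=w, derived_from="delta_q")
    # Conservation diagnostic: the sum of node delta_q equals the net
    # host<->guest charge transfer on all-QM runs.
    meta["sum_delta_q"] = float(sum(nx.get_node_attributes(g, "delta_q").values()))
    return FlowGraph(graph=g, threshold=threshold, metadata=meta)


@dataclass
class HubReport:
    ranking: pd.DataFrame      # fragment_id, triplet_count, betweenness
    triplets: list[tuple[int, int, int]]   # (i, k, j), i < j, mediated by k
    top_k: int

    @property
    def hub_ids(self) -> list[int]:
        return self.ranking["fragment_id"].tolist()


def detect_hubs(flow: FlowGraph, top_k: int = 10) -> HubReport:
    """Mediation-triplet hubs of the thresholded graph.

    Works on the undirected skeleton: k mediates (i, k, j) when edges i-k
    and k-j exist but i-j does not.  Nodes are ranked by (triplet count,
    betweenness centrality) lexicographically, ties broken by fragment id;
    only nodes participating in at least one triplet are reported, capped
    at ``top_k``.
    """
    u = flow.graph.to_undirected()
    counts: dict[int, int] = {}
    triplets: list[tuple[int, int, int]] = []
    for k in sorted(u.nodes):
        nbrs = sorted(u.neighbors(k))
        for a_i in range(len(nbrs)):
            for b_i in range(a_i + 1, len(nbrs)):
                i, j = nbrs[a_i], nbrs[b_i]
                if not u.has_edge(i, j):
                    counts[k] = counts.get(k, 0) + 1
                    triplets.append((i, k, j))
    bc = nx.betweenness_centrality(u, normalized=True) if u.number_of_nodes() else {}
    ranked = sorted(
        counts,
        key=lambda n: (-counts[n], -bc.get(n, 0.0), n),
    )[: max(0, top_k)]
    ranking = pd.DataFrame(
        [
            {
                "fragment_id": n,
                "triplet_count": counts[n],
                "betweenness": bc.get(n, 0.0),
            }
            for n in ranked
        ],
        columns=["fragment_id", "triplet_count", "betweenness"],
    )
    return HubReport(ranking=ranking, triplets=triplets, top_k=top_k)
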