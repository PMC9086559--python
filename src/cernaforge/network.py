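"""ceRNA network assembly and hub-gene ranking.

A (circRNA, mRNA) pair enters the competing-endogenous-RNA network when
the two transcripts share at least one predicted miRNA, change in the
same direction between tumor and normal (the sponge logic: a circRNA that
sequesters a miRNA relieves repression of the mRNA, so their levels move
together), and bind their shared miRNAs strongly enough: summing, over
the shared miRNAs, the most-negative site energy on each molecule must
fall below the energy-sum threshold (default -90 kcal/mol, strict).

Hub genes in the protein-protein interaction graph are ranked by Maximal
Clique Centrality: MCC(v) = sum over maximal cliques C containing v of
(|C|-1)!.  Maximal cliques come from Bron-Kerbosch with pivoting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx

from .errors import InvalidArgumentError, ResourceError
from .expression import DEResult
from .mirtarget import TargetHit


@dataclass
class CeRNATriple:
    """One retained (circRNA, miRNA, mRNA) interaction."""

    circ_id: str
    mir_id: str
    mrna_id: str
    circ_direction: str
    mrna_direction: str
    sum_max_energy: float  # pair-level energy sum, replicated on the pair's triples


@dataclass
class CeRNANetwork:
    """Typed tripartite network: circRNA -- miRNA -- mRNA."""

    graph: nx.Graph
    triples: list[CeRNATriple]
    provenance: dict = field(default_factory=dict)

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("kind") == kind)


@dataclass
class HubScore:
    gene_id: str
    mcc: int
    rank: int


def _best_energy(hits: list[TargetHit]) -> dict[tuple[str, str], float]:
    """Most-negative site energy per (miRNA, target)."""
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        key = (h.mirna_id, h.target_id)
        if key not in best or h.energy < best[key]:
            best[key] = h.energy
    return best


def build_cerna(circ_de: list[DEResult], mrna_de: list[DEResult],
                circ_hits: list[TargetHit], mrna_hits: list[TargetHit],
                energy_sum_max: float = -90.0,
                require_concordant: bool = True,
                ) -> tuple[CeRNANetwork, list[CeRNATriple]]:
    """Join circRNA-miRNA and miRNA-mRNA pairs into the ceRNA network.

    ``circ_de`` / ``mrna_de`` are the *called* differential features (their
    ``direction`` set to up/down); hits must reference only those features.
    For each (circ, mRNA) pair sharing miRNAs, the pair is retained iff the
    directions agree and the energy sum over shared miRNAs (best circ site
    + best mRNA site per miRNA) is < ``energy_sum_max`` (strict).  One
    triple is emitted per (circ, shared miRNA, mRNA).
    """
    circ_dir = {r.feature_id: r.direction for r in circ_de if r.direction in ("up", "down")}
    mrna_dir = {r.feature_id: r.direction for r in mrna_de if r.direction in ("up", "down")}
    for h in circ_hits:
        if h.target_id not in circ_dir:
            raise InvalidArgumentError(f"circRNA hit references non-DE feature {h.target_id!r}")
    for h in mrna_hits:
        if h.target_id not in mrna_dir:
            raise InvalidArgumentError(f"mRNA hit references non-DE feature {h.target_id!r}")

    circ_best = _best_energy(circ_hits)
    mrna_best = _best_energy(mrna_hits)
    mir_to_circs: dict[str, set[str]] = {}
    mir_to_mrnas: dict[str, set[str]] = {}
    for (mir, circ) in circ_best:
        mir_to_circs.setdefault(mir, set()).add(circ)
    for (mir, mrna) in mrna_best:
        mir_to_mrnas.setdefault(mir, set()).add(mrna)

    pair_mirs: dict[tuple[str, str], set[str]] = {}
    for mir in set(mir_to_circs) & set(mir_to_mrnas):
        for circ in mir_to_circs[mir]:
            for mrna in mir_to_mrnas[mir]:
                pair_mirs.setdefault((circ, mrna), set()).add(mir)

    triples: list[CeRNATriple] = []
    for (circ, mrna) in sorted(pair_mirs):
        shared = pair_mirs[(circ, mrna)]
        if require_concordant and circ_dir[circ] != mrna_dir[mrna]:
            continue
        esum = sum(circ_best[(mir, circ)] + mrna_best[(mir, mrna)] for mir in shared)
        if not esum < energy_sum_max:
            continue
        for mir in sorted(shared):
            triples.append(CeRNATriple(circ, mir, mrna, circ_dir[circ], mrna_dir[mrna],
                                       float(esum)))

    g = nx.Graph()
    for t in triples:
        g.add_node(t.circ_id, kind="circRNA", direction=t.circ_direction)
        g.add_node(t.mir_id, kind="miRNA")
        g.add_node(t.mrna_id, kind="mRNA", direction=t.mrna_direction)
        g.add_edge(t.circ_id, t.mir_id, relation="sponges",
                   energy=circ_best[(t.mir_id, t.circ_id)])
        g.add_edge(t.mir_id, t.mrna_id, relation="targets",
                   energy=mrna_best[(t.mir_id, t.mrna_id)])
    net = CeRNANetwork(g, triples,
                       provenance={"energy_sum_max": energy_sum_max,
                                   "require_concordant": require_concordant})
    return net, triples


def mcc_scores(edges: list[tuple[str, str]] | nx.Graph,
               max_cliques: int = 1_000_000) -> list[HubScore]:
    """Maximal Clique Centrality for every node of a simple graph.

    MCC(v) = sum over maximal cliques C containing v of (|C|-1)!; an
    isolated node sits in only its singleton maximal clique and scores 1.
    Ranked descending, ties broken lexicographically by id.  Raises a
    resource error when clique enumeration exceeds ``max_cliques``.
    """
    g = edges.copy() if isinstance(edges, nx.Graph) else nx.Graph(edges)
    g.remove_edges_from(nx.selfloop_edges(g))
    scores = {n: 0 for n in g.nodes}
    for count, clique in enumerate(nx.find_cliques(g), 1):
        if count > max_cliques:
            raise ResourceError(f"clique enumeration exceeded budget of {max_cliques}")
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [HubScore(gene, mcc, rank + 1) for rank, (gene, mcc) in enumerate(ordered)]


def top_hubs(scores: list[HubScore], k: int = 10) -> list[str]:
    """First k gene ids by MCC rank (deterministic under ties)."""
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if not scores:
        warnings.warn("empty graph: no hub genes")
        return []
    if k > len(scores):
        warnings.warn(f"k={k} exceeds node count {len(scores)}; returning all")
        k = len(scores)
    return [s.gene_id for s in sorted(scores, key=lambda s: s.rank)[:k]]


def subnetwork(net: CeRNANetwork, keep_mrnas: list[str]) -> CeRNANetwork:
    """Restrict to triples whose mRNA is kept; drop orphaned nodes."""
    mrna_nodes = set(net.nodes_of_kind("mRNA"))
    unknown = [g for g in keep_mrnas if g not in mrna_nodes]
    if unknown:
        raise InvalidArgumentError(f"unknown mRNA node(s): {unknown}")
    keep = set(keep_mrnas)
    triples = [t for t in net.triples if t.mrna_id in keep]
    g = nx.Graph()
    for t in triples:
        for n in (t.circ_id, t.mir_id, t.mrna_id):
            g.add_node(n, **net.graph.nodes[n])
        g.add_edge(t.circ_id, t.mir_id, **net.graph.edges[t.circ_id, t.mir_id])
        g.add_edge(t.mir_id, t.mrna_id, **net.graph.edges[t.mir_id, t.mrna_id])
    return CeRNANetwork(g, triples, provenance=dict(net.provenance, subnetwork=sorted(keep)))


def triples_table(triples: list[CeRNATriple]):
    import pandas as pd
    return pd.DataFrame(
        [(t.circ_id, t.mir_id, t.mrna_id, t.circ_direction, t.mrna_direction,
          t.sum_max_energy) for t in triples],
        columns=["circ_id", "mir_id", "mrna_id", "circ_direction", "mrna_direction",
                 "sum_max_energy"])
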