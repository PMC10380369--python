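"""Molecular networking: modified-cosine similarity and graph construction.

The network links MS/MS spectra whose fragment patterns agree either
directly or after shifting one spectrum by the precursor mass difference
(so a glycoside and its extended homologue align on the ions that retain
the aglycone).  Edges are kept when the score and matched-peak count pass
the thresholds *and* the two nodes appear in each other's top-K most
similar spectra; connected components are the molecular families, probed
via seed spectra of reference sapogenins.

Defaults follow standard GNPS-style networking practice: fragment
tolerance 0.02 Da, minimum cosine 0.6, minimum matched peaks 3, mutual
top-10, singletons retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .spectra import Spectrum

__all__ = ["modified_cosine", "SimilarityEdge", "MolecularNetwork",
           "build_network", "seeded_clusters", "export_network", "read_edge_list"]


def modified_cosine(s1: Spectrum, s2: Spectrum,
                    frag_tol: float = 0.02) -> Tuple[float, int]:
    """Modified cosine score and matched-peak count between two spectra.

    Peaks pair either directly (|Δm/z| <= tol) or shifted by the precursor
    mass difference; intensities are square-root transformed; a one-to-one
    assignment is built greedily by descending pair score.  Returns
    (cosine in [0, 1], number of matched peaks).
    """
    if not s1.peaks or not s2.peaks:
        raise ValueError("modified_cosine requires non-empty spectra")
    shift = s1.precursor_mz - s2.precursor_mz
    u1 = [math.sqrt(p.intensity) for p in s1.peaks]
    u2 = [math.sqrt(p.intensity) for p in s2.peaks]
    norm = math.sqrt(sum(x * x for x in u1)) * math.sqrt(sum(x * x for x in u2))
    if norm == 0:
        return 0.0, 0

    candidates = []  # (score, i, j)
    for i, p1 in enumerate(s1.peaks):
        for j, p2 in enumerate(s2.peaks):
            d = p1.mz - p2.mz
            if abs(d) <= frag_tol or abs(d - shift) <= frag_tol:
                candidates.append((u1[i] * u2[j], i, j))
    # greedy: best-scoring pairs first; deterministic tie-break on indices
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_i: Set[int] = set()
    used_j: Set[int] = set()
    total = 0.0
    matched = 0
    for score, i, j in candidates:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        total += score
        matched += 1
    return min(total / norm, 1.0), matched


@dataclass(frozen=True)
class SimilarityEdge:
    a: str
    b: str
    cosine: float
    matched_peaks: int


@dataclass
class MolecularNetwork:
    nodes: List[str]
    edges: List[SimilarityEdge]
    graph: nx.Graph = field(repr=False, default_factory=nx.Graph)

    @property
    def components(self) -> List[Set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]


def build_network(spectra: Sequence[Spectrum], min_cosine: float = 0.6,
                  min_matched: int = 3, top_k: int = 10,
                  frag_tol: float = 0.02,
                  node_attrs: Optional[Dict[str, Dict]] = None) -> MolecularNetwork:
    """All-pairs modified-cosine network with threshold and mutual top-K
    pruning; deterministic for a fixed input order.

    ``node_attrs`` optionally maps spectrum id -> attribute dict carried
    into the graph (annotations, plant-part flags).
    """
    ids = [s.id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate spectrum ids")
    raw: List[SimilarityEdge] = []
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            cos, matched = modified_cosine(spectra[i], spectra[j], frag_tol)
            if cos >= min_cosine and matched >= min_matched:
                raw.append(SimilarityEdge(ids[i], ids[j], cos, matched))

    # mutual top-K rule: each endpoint must rank the other within its top_k
    neighbors: Dict[str, List[Tuple[float, str]]] = {i: [] for i in ids}
    for e in raw:
        neighbors[e.a].append((e.cosine, e.b))
        neighbors[e.b].append((e.cosine, e.a))
    topk: Dict[str, Set[str]] = {}
    for node, items in neighbors.items():
        items.sort(key=lambda t: (-t[0], t[1]))
        topk[node] = {other for _, other in items[:top_k]}
    edges = [e for e in raw if e.b in topk[e.a] and e.a in topk[e.b]]

    g = nx.Graph()
    for s in spectra:
        attrs = dict(node_attrs.get(s.id, {})) if node_attrs else {}
        attrs.setdefault("precursor_mz", s.precursor_mz)
        if s.sample_part:
            attrs.setdefault("sample_part", s.sample_part)
        g.add_node(s.id, **attrs)
    for e in edges:
        g.add_edge(e.a, e.b, cosine=round(e.cosine, 6), matched_peaks=e.matched_peaks)
    return MolecularNetwork(nodes=ids, edges=edges, graph=g)


def seeded_clusters(network: MolecularNetwork,
                    seed_ids: Sequence[str]) -> Dict[str, Set[str]]:
    """Connected component containing each seed spectrum (reference
    sapogenins probe their glycoside families).  Seeds in one family map
    to the same component set."""
    out: Dict[str, Set[str]] = {}
    for seed in seed_ids:
        if seed not in network.graph:
            raise KeyError(f"seed id {seed!r} is not a network node")
        out[seed] = set(nx.node_connected_component(network.graph, seed))
    return out


def export_network(network: MolecularNetwork, graphml_path,
                   edges_path=None, header_lines: Sequence[str] = ()) -> None:
    """Write GraphML (node attributes + edge scores) and, optionally, a
    flat tab-separated edge list."""
    lines = nx.generate_graphml(network.graph)
    with open(graphml_path, "w") as fh:
        first = True
        for line in lines:
            fh.write(line + "\n")
            if first:
                for h in header_lines:
                    fh.write(f"<!-- {h} -->\n")
                first = False
    if edges_path is not None:
        with open(edges_path, "w") as fh:
            for h in header_lines:
                fh.write(f"# {h}\n")
            fh.write("source\ttarget\tcosine\tmatched_peaks\n")
            for e in network.edges:
                fh.write(f"{e.a}\t{e.b}\t{e.cosine:.6f}\t{e.matched_peaks}\n")


def read_edge_list(path) -> List[SimilarityEdge]:
    """Read back an edge list written by :func:`export_network`."""
    edges = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("source\t") or not line.strip():
                continue
            a, b, cos, matched = line.rstrip("\n").split("\t")
            edges.append(SimilarityEdge(a, b, float(cos), int(matched)))
    return edges
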