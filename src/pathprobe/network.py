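"""Spectral similarity and molecular-network construction.

Implements the modified cosine score (peaks pair directly or offset by the
precursor mass difference, optimal one-to-one assignment), the spectral
entropy similarity, GNPS-style network topology constraints (top-K neighbour
filtering, component size cap) and the pathway-cluster filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .chem import ModificationRegistry
from .msio import MsmsSpectrum
from .screen import ModificationHit

__all__ = [
    "modified_cosine",
    "entropy_similarity",
    "SpectralEdge",
    "NetworkNode",
    "MolecularNetwork",
    "build_network",
    "PathwayCluster",
    "filter_pathway_clusters",
]

SimilarityFn = Callable[[MsmsSpectrum, MsmsSpectrum], tuple[float, int]]


def _weights(spectrum: MsmsSpectrum, weighting: str) -> np.ndarray:
    intensity = spectrum.intensity
    if weighting == "sqrt":
        w = np.sqrt(intensity)
    elif weighting == "intensity":
        w = intensity.astype(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def _candidate_pairs(
    a: MsmsSpectrum, b: MsmsSpectrum, fragment_tol_da: float
) -> list[tuple[int, int]]:
    shift = a.precursor_mz - b.precursor_mz
    mz_a, mz_b = a.mz, b.mz
    pairs: list[tuple[int, int]] = []
    for i, ma in enumerate(mz_a):
        direct = np.abs(ma - mz_b) <= fragment_tol_da
        shifted = np.abs(ma - mz_b - shift) <= fragment_tol_da
        for j in np.nonzero(direct | shifted)[0]:
            pairs.append((i, int(j)))
    return pairs


def modified_cosine(
    a: MsmsSpectrum,
    b: MsmsSpectrum,
    fragment_tol_da: float = 0.02,
    weighting: str = "sqrt",
    assignment: str = "optimal",
) -> tuple[float, int]:
    """Modified cosine similarity and the number of matched peak pairs.

    Peaks may pair directly (|dmz| <= tol) or offset by the precursor mass
    difference; each peak is used at most once and the pairing maximises the
    summed products of the (sqrt-transformed, unit-normalised) intensities.
    ``assignment="greedy"`` picks pairs best-score-first instead of solving
    the optimal assignment.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("modified_cosine requires non-empty spectra")
    pairs = _candidate_pairs(a, b, fragment_tol_da)
    if not pairs:
        return 0.0, 0
    wa, wb = _weights(a, weighting), _weights(b, weighting)
    if assignment == "optimal":
        score_matrix = np.zeros((len(a), len(b)))
        for i, j in pairs:
            score_matrix[i, j] = wa[i] * wb[j]
        rows, cols = linear_sum_assignment(score_matrix, maximize=True)
        allowed = set(pairs)
        score = 0.0
        matched = 0
        for i, j in zip(rows, cols):
            if (i, int(j)) in allowed:
                score += score_matrix[i, j]
                matched += 1
    elif assignment == "greedy":
        ranked = sorted(pairs, key=lambda ij: (-wa[ij[0]] * wb[ij[1]], ij))
        used_a: set[int] = set()
        used_b: set[int] = set()
        score = 0.0
        matched = 0
        for i, j in ranked:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            score += wa[i] * wb[j]
            matched += 1
    else:
        raise ValueError(f"unknown assignment {assignment!r}")
    return float(min(score, 1.0)), matched


def _merge_within_tol(
    mz: np.ndarray, intensity: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Single-linkage merge of peaks closer than ``tol`` (intensity-weighted m/z)."""
    order = np.argsort(mz)
    mz, intensity = mz[order], intensity[order]
    out_mz: list[float] = []
    out_int: list[float] = []
    for m, h in zip(mz, intensity):
        if out_mz and m - out_mz[-1] <= tol:
            total = out_int[-1] + h
            out_mz[-1] = (out_mz[-1] * out_int[-1] + m * h) / total if total > 0 else m
            out_int[-1] = total
        else:
            out_mz.append(float(m))
            out_int.append(float(h))
    return np.asarray(out_mz), np.asarray(out_int)


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def entropy_similarity(
    a: MsmsSpectrum, b: MsmsSpectrum, fragment_tol_da: float = 0.02
) -> float:
    """Spectral entropy similarity: 1 - (2*S_AB - S_A - S_B) / ln 4.

    Each spectrum is tol-merged and normalised to summed intensity 1; S_AB is
    the Shannon entropy of the 1:1 merged spectrum. Result clamped to [0, 1].
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("entropy_similarity requires non-empty spectra")
    mz_a, int_a = _merge_within_tol(a.mz, a.intensity, fragment_tol_da)
    mz_b, int_b = _merge_within_tol(b.mz, b.intensity, fragment_tol_da)
    pa = int_a / int_a.sum()
    pb = int_b / int_b.sum()
    s_a, s_b = _shannon(pa), _shannon(pb)
    mz_ab = np.concatenate([mz_a, mz_b])
    int_ab = np.concatenate([pa, pb]) / 2.0
    mz_ab, int_ab = _merge_within_tol(mz_ab, int_ab, fragment_tol_da)
    s_ab = _shannon(int_ab)
    sim = 1.0 - (2.0 * s_ab - s_a - s_b) / math.log(4.0)
    return float(min(1.0, max(0.0, sim)))


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectralEdge:
    node_a: str
    node_b: str
    similarity: float
    matched_peaks: int
    precursor_delta: float  # signed, a - b

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError("self-edge")


@dataclass(frozen=True)
class NetworkNode:
    id: str
    kind: str  # "probe" | "experimental"
    spectrum: MsmsSpectrum
    hits: tuple[ModificationHit, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("probe", "experimental"):
            raise ValueError(f"unknown node kind {self.kind!r}")


@dataclass
class MolecularNetwork:
    nodes: dict[str, NetworkNode]
    edges: list[SpectralEdge]
    merged: dict[str, str] = field(default_factory=dict)  # absorbed id -> representative

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for nid in sorted(self.nodes):
            node = self.nodes[nid]
            g.add_node(
                nid,
                kind=node.kind,
                precursor_mz=node.spectrum.precursor_mz,
                n_hits=len(node.hits),
                modifications=";".join(sorted({h.modification.name for h in node.hits})),
            )
        for e in self.edges:
            g.add_edge(
                e.node_a,
                e.node_b,
                similarity=e.similarity,
                matched_peaks=e.matched_peaks,
                precursor_delta=e.precursor_delta,
            )
        return g

    @property
    def components(self) -> list[frozenset[str]]:
        comps = [frozenset(c) for c in nx.connected_components(self.graph())]
        comps.sort(key=lambda c: min(c))
        return comps

    def neighbors(self, node_id: str) -> list[str]:
        out = [e.node_b for e in self.edges if e.node_a == node_id]
        out += [e.node_a for e in self.edges if e.node_b == node_id]
        return sorted(out)

    def edge_between(self, a: str, b: str) -> SpectralEdge | None:
        for e in self.edges:
            if {e.node_a, e.node_b} == {a, b}:
                return e
        return None

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph(), str(path))

    def write_edge_table(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("node_a\tnode_b\tsimilarity\tmatched_peaks\tprecursor_delta\n")
            for e in sorted(self.edges, key=lambda e: (e.node_a, e.node_b)):
                fh.write(
                    f"{e.node_a}\t{e.node_b}\t{e.similarity:.6f}\t"
                    f"{e.matched_peaks}\t{e.precursor_delta:.6f}\n"
                )


def _edge_sort_key(e: SpectralEdge) -> tuple:
    # lowest-quality first: used when shaving oversized components
    return (e.similarity, e.matched_peaks, e.node_a, e.node_b)


def build_network(
    nodes: Sequence[NetworkNode],
    sim_fn: SimilarityFn | None = None,
    threshold: float = 0.7,
    min_matched: int = 6,
    precursor_merge_tol_da: float = 0.01,
    max_neighbors: int = 50,
    max_component: int = 500,
) -> MolecularNetwork:
    """Build a molecular network under the published topology constraints.

    1. Near-duplicate nodes (precursor m/z within ``precursor_merge_tol_da``
       and similarity >= threshold) are collapsed onto the more intense /
       lexicographically earlier node.
    2. Edges require similarity >= ``threshold`` and >= ``min_matched``
       matched peaks.
    3. An edge survives only if it ranks in the top ``max_neighbors`` of both
       endpoints.
    4. Oversized components are split by removing their weakest edges until
       every component has <= ``max_component`` nodes.
    """
    if sim_fn is None:
        sim_fn = modified_cosine
    ids = [n.id for n in nodes]
    if len(set(ids)) != len(ids):
        raise ValueError("node ids must be unique")
    nodes = sorted(nodes, key=lambda n: n.id)
    n = len(nodes)

    sims: dict[tuple[int, int], tuple[float, int]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            sims[(i, j)] = sim_fn(nodes[i].spectrum, nodes[j].spectrum)

    # 1. duplicate collapse
    uf_parent = list(range(n))

    def find(i: int) -> int:
        while uf_parent[i] != i:
            uf_parent[i] = uf_parent[uf_parent[i]]
            i = uf_parent[i]
        return i

    for (i, j), (sim, _) in sims.items():
        da = abs(nodes[i].spectrum.precursor_mz - nodes[j].spectrum.precursor_mz)
        if da <= precursor_merge_tol_da and sim >= threshold:
            ri, rj = find(i), find(j)
            if ri != rj:
                uf_parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged: dict[str, str] = {}
    keep: list[int] = []
    for members in groups.values():
        members.sort(key=lambda i: (-nodes[i].spectrum.total_intensity, nodes[i].id))
        rep = members[0]
        keep.append(rep)
        for other in members[1:]:
            merged[nodes[other].id] = nodes[rep].id
    keep.sort()

    # 2. raw edges among representatives
    edges: list[SpectralEdge] = []
    for a_pos, i in enumerate(keep):
        for j in keep[a_pos + 1 :]:
            sim, matched = sims[(i, j)]
            if sim >= threshold and matched >= min_matched:
                edges.append(
                    SpectralEdge(
                        node_a=nodes[i].id,
                        node_b=nodes[j].id,
                        similarity=sim,
                        matched_peaks=matched,
                        precursor_delta=nodes[i].spectrum.precursor_mz
                        - nodes[j].spectrum.precursor_mz,
                    )
                )

    # 3. mutual top-K neighbour filter
    by_node: dict[str, list[SpectralEdge]] = {}
    for e in edges:
        by_node.setdefault(e.node_a, []).append(e)
        by_node.setdefault(e.node_b, []).append(e)
    rank: dict[tuple[str, int], int] = {}
    for nid, incident in by_node.items():
        incident.sort(key=lambda e: (-e.similarity, -e.matched_peaks, e.node_a, e.node_b))
        for pos, e in enumerate(incident):
            rank[(nid, id(e))] = pos
    edges = [
        e
        for e in edges
        if rank[(e.node_a, id(e))] < max_neighbors and rank[(e.node_b, id(e))] < max_neighbors
    ]

    # 4. component size cap
    g = nx.Graph()
    kept_nodes = {nodes[i].id: nodes[i] for i in keep}
    g.add_nodes_from(kept_nodes)
    edge_by_pair = {}
    for e in edges:
        g.add_edge(e.node_a, e.node_b)
        edge_by_pair[frozenset((e.node_a, e.node_b))] = e
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > max_component]
        if not oversized:
            break
        comp = min(oversized, key=min)
        comp_edges = [edge_by_pair[frozenset((u, v))] for u, v in g.subgraph(comp).edges]
        worst = min(comp_edges, key=_edge_sort_key)
        g.remove_edge(worst.node_a, worst.node_b)
        del edge_by_pair[frozenset((worst.node_a, worst.node_b))]
    edges = sorted(edge_by_pair.values(), key=lambda e: (e.node_a, e.node_b))
    return MolecularNetwork(nodes=kept_nodes, edges=edges, merged=merged)


# ---------------------------------------------------------------------------
# Pathway-cluster filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwayCluster:
    """A connected component qualifying as a target-pathway cluster."""

    component_id: int
    members: frozenset[str]
    qualification: str  # "probe+modified" | "specific-modification-only"
    probe_members: frozenset[str]
    specific_modifications: frozenset[str]


def filter_pathway_clusters(
    network: MolecularNetwork,
    modified_ids: Iterable[str],
    registry: ModificationRegistry | None = None,
) -> list[PathwayCluster]:
    """Keep components that plausibly belong to the target pathway.

    A component qualifies if it contains both a probe node and a modified
    metabolite, or — lacking probes — at least one node carrying a
    pathway-specific modification hit. ``registry`` is accepted for interface
    symmetry; categories are read from the hits themselves.
    """
    modified = set(modified_ids)
    clusters: list[PathwayCluster] = []
    for comp_id, comp in enumerate(network.components):
        probes = frozenset(
            nid for nid in comp if network.nodes[nid].kind == "probe"
        )
        has_modified = any(nid in modified for nid in comp)
        specific = frozenset(
            h.modification.name
            for nid in comp
            for h in network.nodes[nid].hits
            if h.modification.category == "specific"
        )
        if probes and has_modified and len(comp) > 1:
            qual = "probe+modified"
        elif specific:
            qual = "specific-modification-only"
        else:
            continue
        clusters.append(
            PathwayCluster(
                component_id=comp_id,
                members=frozenset(comp),
                qualification=qual,
                probe_members=probes,
                specific_modifications=specific,
            )
        )
    return clusters
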