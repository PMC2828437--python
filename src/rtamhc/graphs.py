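"""Similarity-reduced cross-validation splits via spectral sparsest cuts.

Peptides sharing any exact 9-mer are connected in a similarity graph; the
connected components are groups that must stay within one fold to avoid
train/test leakage.  A component holding more than one fold's share of the
data is split recursively at an approximate sparsest cut found by sweeping
the Fiedler vector of the component's Laplacian: nodes are ordered by
their second-eigenvector components and the |V| - 1 prefix cuts are
scored by

    sp(S) = (edges crossing S) / min(|S|, |V \\ S|),

keeping the minimum.  Groups are then dealt greedily, largest first, onto
the currently smallest fold.  Every edge removed by a cut is a cross-fold
pair of similar peptides, so the overlap report equals the cut-edge total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse.linalg

from .alphabet import CORE_LENGTH
from .data import Peptide

logger = logging.getLogger(__name__)

__all__ = [
    "CutResult",
    "FoldAssignment",
    "ninemers",
    "shared_ninemers",
    "build_similarity_graph",
    "connected_components",
    "laplacian",
    "fiedler_vector",
    "sparsity",
    "sweep_cut",
    "partition_groups",
    "assign_folds",
    "overlap_report",
    "build_fold_assignment",
]

#: Components larger than this use an iterative eigensolver.
DENSE_EIG_LIMIT = 2000


def ninemers(sequence: str) -> set[str]:
    """The set of 9-residue windows of a sequence."""
    if len(sequence) < CORE_LENGTH:
        raise ValueError(f"sequence shorter than {CORE_LENGTH}: {sequence!r}")
    return {sequence[i : i + CORE_LENGTH] for i in range(len(sequence) - CORE_LENGTH + 1)}


def shared_ninemers(seq_a: str, seq_b: str) -> set[str]:
    """Exact 9-mers common to two sequences."""
    return ninemers(seq_a) & ninemers(seq_b)


def build_similarity_graph(peptides: Sequence[Peptide]) -> nx.Graph:
    """Graph with peptides as nodes and an edge for every shared 9-mer pair.

    Built through a 9-mer -> peptide inverted index rather than an
    all-pairs scan; the edge set equals the all-pairs definition exactly.
    """
    ids = [p.id for p in peptides]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate peptide ids")
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    index: dict[str, list[str]] = {}
    for p in peptides:
        for mer in ninemers(p.sequence):
            index.setdefault(mer, []).append(p.id)
    for members in index.values():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                graph.add_edge(a, b)
    return graph


def connected_components(graph: nx.Graph) -> list[list]:
    """Components sorted by decreasing size, then smallest member id."""
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def laplacian(graph: nx.Graph, component: Sequence) -> np.ndarray:
    """Dense graph Laplacian L = D - A over ``component`` (given node order)."""
    nodes = list(component)
    sub = graph.subgraph(nodes)
    return nx.laplacian_matrix(sub, nodelist=nodes).toarray().astype(float)


def fiedler_vector(graph: nx.Graph, component: Sequence) -> tuple[float, np.ndarray]:
    """Second-smallest Laplacian eigenvalue and its unit eigenvector.

    Dense symmetric eigendecomposition up to ``DENSE_EIG_LIMIT`` nodes,
    shift-invert Lanczos above.  The sign is fixed so the first strictly
    nonzero component is positive (deterministic output); lambda_2 > 0 iff
    the component is connected.
    """
    nodes = list(component)
    if len(nodes) < 2:
        raise ValueError("Fiedler vector needs at least 2 nodes")
    L = laplacian(graph, nodes)
    if len(nodes) <= DENSE_EIG_LIMIT:
        eigvals, eigvecs = np.linalg.eigh(L)
        lam2, v2 = float(eigvals[1]), eigvecs[:, 1]
    else:
        eigvals, eigvecs = scipy.sparse.linalg.eigsh(
            scipy.sparse.csr_matrix(L), k=2, sigma=-1e-3, which="LM", tol=1e-8
        )
        order = np.argsort(eigvals)
        lam2, v2 = float(eigvals[order[1]]), eigvecs[:, order[1]]
    v2 = v2 / np.linalg.norm(v2)
    nz = np.flatnonzero(np.abs(v2) > 1e-12)
    if nz.size and v2[nz[0]] < 0:
        v2 = -v2
    return lam2, v2


def sparsity(graph: nx.Graph, S: Iterable, component: Sequence) -> float:
    """sp(S) = crossing edges / min(|S|, |complement|)."""
    nodes = set(component)
    S = set(S)
    if not S or S == nodes:
        raise ValueError("S must be a proper nonempty subset of the component")
    if not S <= nodes:
        raise ValueError("S must lie inside the component")
    comp = nodes - S
    crossing = sum(1 for u, v in graph.subgraph(nodes).edges() if (u in S) != (v in S))
    return crossing / min(len(S), len(comp))


@dataclass
class CutResult:
    """Outcome of one spectral sweep cut of a connected component."""

    side_S: list
    side_complement: list
    cut_edges: int
    sparsity: float
    lambda2: float
    fiedler: np.ndarray
    nodes: list = field(default_factory=list)


def sweep_cut(graph: nx.Graph, component: Sequence) -> CutResult:
    """Best of the |V| - 1 Fiedler-order prefix cuts.

    Nodes are sorted by Fiedler component (ties by node id); prefix cuts at
    every distinct threshold are scored by :func:`sparsity`.  Ties prefer
    the cut with the larger smaller side, then the smaller threshold index.
    """
    nodes = sorted(component)
    lam2, v2 = fiedler_vector(graph, nodes)
    order = sorted(range(len(nodes)), key=lambda i: (v2[i], nodes[i]))
    sub = graph.subgraph(nodes)
    adj = {u: set(sub.neighbors(u)) for u in nodes}

    best = None
    in_S: set = set()
    crossing = 0
    for cut_idx in range(len(nodes) - 1):
        u = nodes[order[cut_idx]]
        crossing += sum(1 for w in adj[u] if w not in in_S) - sum(
            1 for w in adj[u] if w in in_S
        )
        in_S.add(u)
        size_S = cut_idx + 1
        # identical v2 values on both sides of the boundary give the same
        # threshold cut; any prefix is still a valid sweep cut, so keep all
        sp_val = crossing / min(size_S, len(nodes) - size_S)
        key = (sp_val, -min(size_S, len(nodes) - size_S), cut_idx)
        if best is None or key < best[0]:
            best = (key, sorted(in_S), crossing)
    _, side, cut_edges = best
    side_set = set(side)
    return CutResult(
        side_S=side,
        side_complement=sorted(set(nodes) - side_set),
        cut_edges=cut_edges,
        sparsity=best[0][0],
        lambda2=lam2,
        fiedler=v2,
        nodes=nodes,
    )


def partition_groups(
    graph: nx.Graph, max_group_size: int
) -> tuple[list[list], int, int]:
    """Split oversized components until every group fits a single fold.

    Returns (groups, total cut edges, number of sweep-cut invocations).
    Each cut's removed edges become unavoidable cross-fold similar pairs.
    """
    if max_group_size < 1:
        raise ValueError("max_group_size must be >= 1")
    groups: list[list] = []
    cut_edges = 0
    n_splits = 0
    stack = connected_components(graph)
    while stack:
        comp = stack.pop(0)
        if len(comp) <= max_group_size:
            groups.append(comp)
            continue
        cut = sweep_cut(graph, comp)
        if not cut.side_S or not cut.side_complement:  # pragma: no cover
            raise RuntimeError("sweep cut failed to reduce component size")
        n_splits += 1
        cut_edges += cut.cut_edges
        stack.extend([cut.side_S, cut.side_complement])
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups, cut_edges, n_splits


@dataclass
class FoldAssignment:
    """A k-fold partition of peptide ids with overlap accounting."""

    k: int
    fold_of: dict[str, int]
    fold_sizes: list[int]
    cross_fold_shared_9mer_pairs: int = 0
    cross_fold_shared_fraction: float = 0.0
    n_splits: int = 0
    has_empty_folds: bool = False

    def test_indices(self, ids: Sequence[str], fold: int) -> np.ndarray:
        return np.flatnonzero([self.fold_of[i] == fold for i in ids])


def assign_folds(groups: Sequence[Sequence], k: int) -> FoldAssignment:
    """Greedy longest-processing-time packing of groups into k folds.

    Groups in decreasing size (ties by smallest member id) each go whole to
    the currently smallest fold (ties to the lowest fold index).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ordered = sorted((sorted(g) for g in groups), key=lambda g: (-len(g), g[0]))
    sizes = [0] * k
    fold_of: dict[str, int] = {}
    for group in ordered:
        fold = min(range(k), key=lambda f: (sizes[f], f))
        for node in group:
            fold_of[node] = fold + 1
        sizes[fold] += len(group)
    if 0 in sizes:
        logger.warning("fewer groups than folds: %d empty fold(s)", sizes.count(0))
    return FoldAssignment(
        k=k,
        fold_of=fold_of,
        fold_sizes=sizes,
        has_empty_folds=0 in sizes,
    )


def overlap_report(
    folds: FoldAssignment, peptides: Sequence[Peptide]
) -> tuple[int, float]:
    """Cross-fold similar pairs: count and fraction of all cross-fold pairs."""
    by_id = {p.id: p for p in peptides}
    missing = set(folds.fold_of) - set(by_id)
    if missing:
        raise ValueError(f"fold assignment references unknown peptides: {sorted(missing)[:5]}")
    graph = build_similarity_graph([by_id[i] for i in folds.fold_of])
    shared = sum(
        1 for u, v in graph.edges() if folds.fold_of[u] != folds.fold_of[v]
    )
    n = len(folds.fold_of)
    total_pairs = n * (n - 1) // 2
    same_pairs = sum(s * (s - 1) // 2 for s in folds.fold_sizes)
    cross_pairs = total_pairs - same_pairs
    return shared, (shared / cross_pairs) if cross_pairs else 0.0


def build_fold_assignment(
    peptides: Sequence[Peptide],
    k: int = 5,
    max_group_size: int | None = None,
) -> FoldAssignment:
    """End-to-end split: graph -> groups -> folds -> overlap accounting.

    ``max_group_size`` defaults to ceil(N / k) (one fold's share).  A
    leave-one-out-style request (k = N) is allowed but logged as a caution:
    with many folds the cross-fold overlap necessarily grows.
    """
    n = len(peptides)
    if k == n:
        logger.warning(
            "k equals the number of peptides (leave-one-out); expect large "
            "cross-fold sequence overlap"
        )
    if max_group_size is None:
        max_group_size = math.ceil(n / k)
    graph = build_similarity_graph(peptides)
    groups, cut_edges, n_splits = partition_groups(graph, max_group_size)
    assignment = assign_folds(groups, k)
    shared, fraction = overlap_report(assignment, peptides)
    assignment.cross_fold_shared_9mer_pairs = shared
    assignment.cross_fold_shared_fraction = fraction
    assignment.n_splits = n_splits
    return assignment
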