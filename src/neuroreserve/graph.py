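"""Skeleton graphs over grey-matter measures and their Laplacians.

The graph encodes which measures are expected to co-vary: left-right
homologues (strongly correlated in healthy anatomy) and anatomically
adjacent structures. Its combinatorial Laplacian ``L = D - W`` supplies the
smoothness penalty used by graph-Laplacian PCA.

Two constructions are provided: a fixed anatomical template, and a
data-driven graph thresholding absolute Pearson correlations.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .parcellation import ParcellationScheme

__all__ = [
    "RegionGraph",
    "build_template_graph",
    "build_correlation_graph",
    "laplacian",
    "read_edge_list",
    "write_edge_list",
    "template_edge_list_path",
]

# Within-hemisphere anatomical adjacency between cortical lobes.
CORTICOCORTICAL_ADJACENCY = (
    ("frontal", "parietal"), ("frontal", "temporal"), ("frontal", "cingulate"),
    ("frontal", "insula"), ("temporal", "parietal"), ("temporal", "insula"),
    ("temporal", "occipital"), ("parietal", "occipital"), ("parietal", "cingulate"),
    ("cingulate", "insula"),
)
# Within-hemisphere adjacency between subcortical structures.
SUBCORTICAL_ADJACENCY = (
    ("hippocampus", "amygdala"), ("caudate", "putamen"), ("putamen", "pallidum"),
    ("putamen", "accumbens"), ("caudate", "accumbens"), ("thalamus", "pallidum"),
    ("hippocampus", "thalamus"),
)
# Each subcortical structure is tied to one cortical lobe of its hemisphere:
# medial-temporal structures to the temporal lobe, basal ganglia and thalamus
# to the frontal lobe.
SUBCORTICAL_CORTICAL_LINKS = (
    ("hippocampus", "temporal"), ("amygdala", "temporal"), ("caudate", "frontal"),
    ("putamen", "frontal"), ("accumbens", "frontal"), ("pallidum", "frontal"),
    ("thalamus", "frontal"),
)
# The cerebellum connects to both thalami (its main diencephalic relay).
CEREBELLAR_LINKS = (("cerebellum", "thalamus"),)


@dataclass(frozen=True)
class RegionGraph:
    """Undirected weighted graph over grey-matter measures.

    ``weights`` is the symmetric non-negative adjacency matrix W with zero
    diagonal, ordered like ``nodes``.
    """

    nodes: tuple[str, ...]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        p = len(self.nodes)
        if W.shape != (p, p):
            raise ValueError(f"weight matrix shape {W.shape} does not match {p} nodes")
        if not np.allclose(W, W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        if np.any(W < 0):
            raise ValueError("edge weights must be non-negative")
        object.__setattr__(self, "weights", W)

    @property
    def degree(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights)))

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        iu = zip(*np.triu_indices(len(self.nodes), k=1))
        for i, j in iu:
            w = self.weights[i, j]
            if w != 0:
                out.append((self.nodes[i], self.nodes[j], float(w)))
        return out

    def has_edge(self, a: str, b: str) -> bool:
        i, j = self.nodes.index(a), self.nodes.index(b)
        return self.weights[i, j] != 0

    def is_connected(self) -> bool:
        g = nx.from_numpy_array(self.weights)
        return nx.is_connected(g) if len(self.nodes) else True


def laplacian(graph: RegionGraph) -> np.ndarray:
    """Combinatorial Laplacian L = D - W."""
    return np.diag(graph.degree) - graph.weights


def build_template_graph(scheme: ParcellationScheme) -> RegionGraph:
    """Anatomical skeleton graph for *scheme* with unit edge weights.

    Edges: every left-right homologue pair; within-hemisphere adjacency
    between cortical lobes and between subcortical structures; one
    subcortical-to-cortical link per structure; cerebellum to both thalami.
    Structure pairs absent from the scheme are silently skipped, but a scheme
    with no homologue pairs is rejected (the template is anchored on
    bilateral symmetry).
    """
    pairs = scheme.homologue_pairs()
    if not pairs:
        raise ValueError("scheme has no left-right homologue pairs; template graph undefined")
    names = scheme.names
    index = {n: i for i, n in enumerate(names)}
    W = np.zeros((len(names), len(names)))

    def connect(a: str, b: str) -> None:
        W[index[a], index[b]] = W[index[b], index[a]] = 1.0

    for left, right in pairs:
        connect(left, right)
    by_struct_hemi = {(r.structure, r.hemisphere): r.name for r in scheme.regions}
    for hemi in ("left", "right"):
        for sa, sb in CORTICOCORTICAL_ADJACENCY + SUBCORTICAL_ADJACENCY + SUBCORTICAL_CORTICAL_LINKS:
            a, b = by_struct_hemi.get((sa, hemi)), by_struct_hemi.get((sb, hemi))
            if a is not None and b is not None:
                connect(a, b)
        for sa, sb in CEREBELLAR_LINKS:
            a = by_struct_hemi.get((sa, "bilateral"))
            b = by_struct_hemi.get((sb, hemi))
            if a is not None and b is not None:
                connect(a, b)
    return RegionGraph(tuple(names), W)


def build_correlation_graph(
    normalized: pd.DataFrame, scheme: ParcellationScheme, tau: float
) -> RegionGraph:
    """Data-driven graph: unit edge where |Pearson r| >= *tau*.

    Constant columns contribute no edges (their correlations are treated
    as zero). Requires at least 3 subjects and ``0 < tau <= 1``.
    """
    if not 0 < tau <= 1:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    X = normalized[scheme.names].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("correlation graph needs at least 3 subjects")
    sd = X.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R[~np.isfinite(R)] = 0.0
    R[sd == 0, :] = 0.0
    R[:, sd == 0] = 0.0
    W = (np.abs(R) >= tau - 1e-12).astype(float)  # tolerate rounding at |r| = tau
    np.fill_diagonal(W, 0.0)
    return RegionGraph(tuple(scheme.names), W)


def write_edge_list(graph: RegionGraph, path) -> None:
    """Write tab-separated ``node_a  node_b  weight`` lines (isolated nodes omitted)."""
    df = pd.DataFrame(graph.edges(), columns=["node_a", "node_b", "weight"])
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path, scheme: ParcellationScheme) -> RegionGraph:
    """Read an edge-list file into a graph over the scheme's measures."""
    df = pd.read_csv(path, sep="\t")
    expected = {"node_a", "node_b", "weight"}
    if set(df.columns) != expected:
        raise ValueError(f"edge list must have columns {sorted(expected)}, got {list(df.columns)}")
    names = scheme.names
    index = {n: i for i, n in enumerate(names)}
    W = np.zeros((len(names), len(names)))
    for a, b, w in df.itertuples(index=False):
        if a not in index or b not in index:
            bad = a if a not in index else b
            raise ValueError(f"edge list node {bad!r} is not a measure of the scheme")
        W[index[a], index[b]] = W[index[b], index[a]] = float(w)
    return RegionGraph(tuple(names), W)


def template_edge_list_path():
    """Path-like handle to the shipped default-scheme adjacency template."""
    return importlib.resources.files("neuroreserve").joinpath("data/template_edges.tsv")
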