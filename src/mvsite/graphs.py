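"""View graphs over the nucleotides of one RNA chain.

Three undirected graphs share the same node set (the nucleotides):

* **P** — primary view: k-nearest neighbors by sequence separation
  (default k=13);
* **S** — secondary view: backbone adjacency plus every annotated
  base-pair / base-ribose / base-phosphate interaction;
* **T** — tertiary view: k-nearest neighbors by Euclidean distance
  between representative atoms (default k=8).

Binding-site labels follow the contact rule: a nucleotide is positive iff
any of its atoms lies within 4 Angstrom (inclusive) of any ligand atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import SecondaryAnnotation, StructureRecord

VIEWS = ("P", "S", "T")
DEFAULT_K_PRIMARY = 13
DEFAULT_K_TERTIARY = 8
CONTACT_CUTOFF = 4.0               # Angstrom, inclusive


@dataclass
class ViewGraph:
    view: str
    n: int
    edges: set[tuple[int, int]]

    def __post_init__(self):
        self.edges = {(min(i, j), max(i, j)) for i, j in self.edges}
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loops are not stored")
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise ValueError(f"edge ({i},{j}) outside [0,{self.n})")

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n, self.n))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a


def _knn_edges(dist: np.ndarray, k: int) -> set[tuple[int, int]]:
    """Union-symmetrized k-NN edge set; ties break toward the lower index."""
    n = dist.shape[0]
    kk = min(k, n - 1)
    edges: set[tuple[int, int]] = set()
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, dist[i]))
        chosen = [j for j in order if j != i][:kk]
        for j in chosen:
            edges.add((min(i, j), max(i, j)))
    return edges


def build_primary_graph(n: int, k: int = DEFAULT_K_PRIMARY) -> ViewGraph:
    """Sequence-distance k-NN graph (|i - j| metric)."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be positive")
    pos = np.arange(n, dtype=float).reshape(-1, 1)
    dist = np.abs(pos - pos.T)
    return ViewGraph("P", n, _knn_edges(dist, k))


def build_tertiary_graph(coords: np.ndarray, k: int = DEFAULT_K_TERTIARY) -> ViewGraph:
    """Euclidean k-NN graph over one representative coordinate per nucleotide."""
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    dist = cdist(coords, coords)
    return ViewGraph("T", coords.shape[0], _knn_edges(dist, k))


def build_contact_graph(coords: np.ndarray, cutoff: float = 8.0) -> ViewGraph:
    """Distance-cutoff alternative to the tertiary k-NN graph."""
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    dist = cdist(coords, coords)
    n = coords.shape[0]
    edges = {(i, j) for i in range(n) for j in range(i + 1, n)
             if dist[i, j] <= cutoff}
    return ViewGraph("T", n, edges)


def build_secondary_graph(annotation: SecondaryAnnotation) -> ViewGraph:
    """Backbone path plus all annotated interaction pairs, deduplicated."""
    n = annotation.n
    edges = {(i, i + 1) for i in range(n - 1)}
    edges |= {(i, j) for i, j, _ in annotation.interactions}
    return ViewGraph("S", n, edges)


def representative_coords(structure: StructureRecord,
                          atom: str = "C4'") -> np.ndarray:
    """One coordinate per nucleotide: the named atom, else the residue centroid."""
    out = np.zeros((structure.n, 3))
    for r in structure.residues:
        match = [a for a in r.atoms if a[0] == atom]
        if match:
            out[r.index] = match[0][1:]
        else:
            out[r.index] = r.coords().mean(axis=0)
    return out


def assign_labels(structure: StructureRecord,
                  cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """y_i = 1 iff any atom of residue i is within `cutoff` of any ligand atom."""
    y = np.zeros(structure.n, dtype=int)
    lig_coords = [lig.coords() for lig in structure.ligands if lig.atoms]
    if not lig_coords:
        warnings.warn("no ligand atoms present; all labels are 0", stacklevel=2)
        return y
    lig = np.vstack(lig_coords)
    for r in structure.residues:
        d = cdist(r.coords(), lig)
        if d.min() <= cutoff:
            y[r.index] = 1
    return y


def normalized_adjacency(graph: ViewGraph) -> np.ndarray:
    """Kipf-style renormalized adjacency D^{-1/2} (A + I) D^{-1/2}."""
    a = graph.adjacency() + np.eye(graph.n)
    dinv = 1.0 / np.sqrt(a.sum(axis=1))
    return a * dinv[:, None] * dinv[None, :]


@dataclass
class MultiViewGraph:
    """One RNA as a shared node set with three edge sets, features and labels."""

    chain_id: str
    features: "NodeFeatureMatrix"      # forward ref into mvsite.features
    graphs: dict[str, ViewGraph]
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        n = self.features.n
        for view, g in self.graphs.items():
            if g.n != n:
                raise ValueError(f"view {view} has n={g.n}, features have n={n}")
        if self.y.shape != (n,):
            raise ValueError("label vector length must equal node count")
        self._ahat_cache: dict[str, np.ndarray] = {}

    @property
    def n(self) -> int:
        return self.features.n

    def normalized_adjacency(self, view: str) -> np.ndarray:
        if view not in self._ahat_cache:
            self._ahat_cache[view] = normalized_adjacency(self.graphs[view])
        return self._ahat_cache[view]
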