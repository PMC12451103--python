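"""Per-nucleotide feature blocks for the three structural views.

The initial node-feature matrix ``X_init`` concatenates, in fixed order:

======================  =====  ==========================================
block                   width  source
======================  =====  ==========================================
conservation            1      1 - H/2 from the MSA column entropy
embedding               d_emb  precomputed language-model embedding
one_hot                 4      base identity, channel order (A, U, G, C)
secondary               5      degree + four base-interaction flags
topological             5      degree, neighborhood connectivity,
                               betweenness, clustering, eccentricity
asa                     1      solvent accessibility scalar
======================  =====  ==========================================

Continuous columns are z-scored with statistics fitted on the training
split only; binary flag columns are left untouched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import MsaRecord, SecondaryAnnotation, STANDARD_BASES

BASE_ORDER = ("A", "U", "G", "C")
H_MAX = 2.0                         # log2(4), four-letter alphabet


@dataclass
class ConservationProfile:
    """Per-position conservation scores in [0, 1] for the ungapped query."""

    scores: np.ndarray
    entropy: np.ndarray             # Shannon entropy (bits) per position

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.entropy = np.asarray(self.entropy, dtype=float)
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("conservation scores must lie in [0, 1]")


def conservation_scores(msa: MsaRecord) -> ConservationProfile:
    """Column-entropy conservation: ``score = 1 - H / log2(4)``.

    Only MSA columns where the query has a nucleotide contribute; gaps are
    excluded from the column frequencies so the four-letter maximum entropy
    of 2 bits is the correct normalizer.  Columns where no row other than
    the query holds a nucleotide get score 0 with a warning.
    """
    if msa.depth == 0 or msa.n_cols == 0:
        raise ValueError("empty alignment")
    query = msa.rows[msa.query_row]
    scores, entropies = [], []
    lonely = 0
    for col in range(msa.n_cols):
        if query[col] == "-":
            continue
        counts = {b: 0 for b in BASE_ORDER}
        others = 0
        for r, row in enumerate(msa.rows):
            ch = row[col]
            if ch in counts:
                counts[ch] += 1
                if r != msa.query_row:
                    others += 1
        total = sum(counts.values())
        if others == 0:
            lonely += 1
            scores.append(0.0)
            entropies.append(float("nan"))
            continue
        h = -sum((c / total) * math.log2(c / total)
                 for c in counts.values() if c > 0)
        entropies.append(h)
        scores.append(min(1.0, max(0.0, 1.0 - h / H_MAX)))
    if lonely:
        warnings.warn(f"{lonely} column(s) held only the query nucleotide; "
                      "conservation set to 0 there", stacklevel=2)
    return ConservationProfile(np.array(scores), np.array(entropies))


def one_hot_encode(bases) -> np.ndarray:
    """n x 4 one-hot in channel order (A, U, G, C); unknown bases -> zeros."""
    out = np.zeros((len(bases), 4), dtype=float)
    for i, b in enumerate(bases):
        if b in BASE_ORDER:
            out[i, BASE_ORDER.index(b)] = 1.0
    return out


def secondary_feature_vector(annotation: SecondaryAnnotation) -> np.ndarray:
    """n x 5 block: secondary-graph degree plus four presence flags.

    Columns: degree in the secondary graph (backbone + all annotated
    interactions), base-ribose flag, base-phosphate flag, non-canonical
    pair flag, loop membership flag.
    """
    from .graphs import build_secondary_graph      # local import, no cycle at module load

    n = annotation.n
    g = build_secondary_graph(annotation)
    degree = np.zeros(n)
    for i, j in g.edges:
        degree[i] += 1
        degree[j] += 1
    out = np.zeros((n, 5), dtype=float)
    out[:, 0] = degree
    for i, j, kind in annotation.interactions:
        if kind == "base_ribose":
            out[i, 1] = out[j, 1] = 1.0
        elif kind == "base_phosphate":
            out[i, 2] = out[j, 2] = 1.0
        elif kind == "noncanonical_pair":
            out[i, 3] = out[j, 3] = 1.0
    out[:, 4] = annotation.loop_member.astype(float)
    return out


def topological_properties(edges, n: int) -> np.ndarray:
    """n x 5 block of node-level topology descriptors of a simple graph.

    Columns: degree; neighborhood connectivity (mean neighbor degree, 0 for
    isolated nodes); betweenness centrality normalized by (n-1)(n-2)/2;
    local clustering coefficient (0 when degree < 2); eccentricity within
    the node's connected component.
    """
    if n == 0:
        raise ValueError("graph must have at least one node")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((i, j) for i, j in edges if i != j)

    deg = np.array([g.degree(i) for i in range(n)], dtype=float)
    neigh = np.array([
        np.mean([g.degree(j) for j in g.neighbors(i)]) if g.degree(i) > 0 else 0.0
        for i in range(n)])
    btw_map = nx.betweenness_centrality(g, normalized=True)
    btw = np.array([btw_map[i] for i in range(n)])
    clus_map = nx.clustering(g)
    clus = np.array([clus_map[i] for i in range(n)])
    ecc = np.zeros(n)
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for node, e in nx.eccentricity(sub).items():
            ecc[node] = e
    return np.column_stack([deg, neigh, btw, clus, ecc])


def asa_proxy(coords: np.ndarray, radius: float = 8.0) -> np.ndarray:
    """Geometric stand-in for solvent accessibility (non-canonical).

    Counts neighboring residues within `radius` of each representative
    coordinate and negates the count: buried residues have many neighbors
    and hence low values, mimicking the sign of a true accessibility
    scalar.  Intended for use only when no computed ASA table exists; the
    caller's standardization step brings it onto the z-score scale.
    """
    coords = np.asarray(coords, dtype=float)
    from scipy.spatial.distance import cdist
    d = cdist(coords, coords)
    return -(np.count_nonzero(d <= radius, axis=1) - 1).astype(float)


# ---------------------------------------------------------------------------

BLOCK_WIDTHS = {"conservation": 1, "one_hot": 4, "secondary": 5,
                "topological": 5, "asa": 1}


@dataclass
class FeatureStats:
    """Per-column z-score statistics, fitted on the training split only."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, matrices: list[np.ndarray]) -> "FeatureStats":
        x = np.vstack(matrices)
        std = x.std(axis=0)
        std[std < 1e-12] = 1.0
        return cls(x.mean(axis=0), std)


@dataclass
class NodeFeatureMatrix:
    """X_init with its block map (name -> (start, stop) column slice)."""

    X: np.ndarray
    blocks: dict[str, tuple[int, int]]
    continuous: np.ndarray = field(default=None)   # bool mask over columns

    def __post_init__(self):
        if not np.isfinite(self.X).all():
            raise ValueError("X_init contains non-finite entries")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d_init(self) -> int:
        return self.X.shape[1]

    def block(self, name: str) -> np.ndarray:
        a, b = self.blocks[name]
        return self.X[:, a:b]


def standardize(nfm: "NodeFeatureMatrix", stats: FeatureStats) -> "NodeFeatureMatrix":
    """z-score the continuous columns of a raw feature matrix."""
    X = nfm.X.copy()
    m = nfm.continuous
    X[:, m] = (X[:, m] - stats.mean[m]) / stats.std[m]
    return NodeFeatureMatrix(X, dict(nfm.blocks), nfm.continuous.copy())


def assemble_features(n: int, *, conservation=None, embeddings=None,
                      one_hot=None, secondary=None, topological=None,
                      asa=None, d_emb: int = 120,
                      stats: FeatureStats | None = None) -> NodeFeatureMatrix:
    """Concatenate the feature blocks into X_init in the fixed layout.

    Optional blocks (conservation, embeddings, asa) may be None and are
    filled with zeros without changing the layout.  When `stats` is given,
    continuous columns are standardized with it; flag columns (one-hot and
    the four secondary flags) are never touched.  `stats` must be fitted
    on raw (unstandardized) training matrices of the same layout.
    """
    def _check(name, arr, width):
        if arr is None:
            return np.zeros((n, width))
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.shape[0] == 1 and width == 1:
            arr = arr.reshape(-1, 1)
        if arr.shape != (n, width):
            raise ValueError(
                f"block {name!r} has shape {arr.shape}, expected {(n, width)}")
        return arr

    cons = _check("conservation",
                  None if conservation is None else np.asarray(conservation).reshape(-1, 1), 1)
    emb = _check("embedding", embeddings, d_emb)
    oh = _check("one_hot", one_hot, 4)
    sec = _check("secondary", secondary, 5)
    topo = _check("topological", topological, 5)
    asa_b = _check("asa", None if asa is None else np.asarray(asa).reshape(-1, 1), 1)

    parts = [("conservation", cons), ("embedding", emb), ("one_hot", oh),
             ("secondary", sec), ("topological", topo), ("asa", asa_b)]
    blocks, cols, offset = {}, [], 0
    for name, arr in parts:
        blocks[name] = (offset, offset + arr.shape[1])
        cols.append(arr)
        offset += arr.shape[1]
    X = np.concatenate(cols, axis=1)

    d = X.shape[1]
    continuous = np.ones(d, dtype=bool)
    a, b = blocks["one_hot"]
    continuous[a:b] = False
    a, b = blocks["secondary"]
    continuous[a + 1:b] = False        # degree column stays continuous

    if stats is not None:
        X = X.copy()
        X[:, continuous] = ((X[:, continuous] - stats.mean[continuous])
                            / stats.std[continuous])
    return NodeFeatureMatrix(X, blocks, continuous)
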