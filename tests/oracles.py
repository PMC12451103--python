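"""Independent brute-force oracles for the acceptance checks.

Everything here is deliberately slow and literal: direct formulas,
pairwise enumeration, BFS path counting, and a per-nucleotide loop
evaluation of the network equations.  Nothing imports the vectorized
implementation paths it is used to check.
"""

from __future__ import annotations

import math

import numpy as np


# -- classification metrics -------------------------------------------------

def brute_metrics(y_true, p, threshold=0.5):
    y = list(map(int, y_true))
    pred = [1 if pi >= threshold else 0 for pi in p]
    tp = sum(1 for a, b in zip(pred, y) if a == 1 and b == 1)
    fp = sum(1 for a, b in zip(pred, y) if a == 1 and b == 0)
    tn = sum(1 for a, b in zip(pred, y) if a == 0 and b == 0)
    fn = sum(1 for a, b in zip(pred, y) if a == 0 and b == 1)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return tp, fp, tn, fn, precision, recall, mcc


def brute_auc(y_true, scores):
    """Pairwise probability that a positive outscores a negative (ties 1/2)."""
    pos = [s for s, y in zip(scores, y_true) if y == 1]
    neg = [s for s, y in zip(scores, y_true) if y == 0]
    if not pos or not neg:
        return None
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# -- graph topology ---------------------------------------------------------

def _neighbors(edges, n):
    adj = [set() for _ in range(n)]
    for i, j in edges:
        if i != j:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def _bfs_dist(adj, src):
    dist = {src: 0}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def brute_topology(edges, n):
    """degree, neighborhood connectivity, betweenness, clustering, eccentricity."""
    adj = _neighbors(edges, n)
    deg = [len(adj[i]) for i in range(n)]

    neigh = [sum(deg[j] for j in adj[i]) / deg[i] if deg[i] else 0.0
             for i in range(n)]

    clus = []
    for i in range(n):
        if deg[i] < 2:
            clus.append(0.0)
            continue
        links = sum(1 for a in adj[i] for b in adj[i] if a < b and b in adj[a])
        clus.append(2.0 * links / (deg[i] * (deg[i] - 1)))

    ecc = []
    for i in range(n):
        dist = _bfs_dist(adj, i)
        ecc.append(max(dist.values()))

    # betweenness by explicit shortest-path enumeration per (s, t) pair
    btw = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            dist = _bfs_dist(adj, s)
            if t not in dist:
                continue
            paths = _all_shortest_paths(adj, s, t, dist)
            for node in range(n):
                if node in (s, t):
                    continue
                passing = sum(1 for p in paths if node in p)
                btw[node] += passing / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    btw = [b / norm if norm > 0 else 0.0 for b in btw]
    return np.column_stack([deg, neigh, btw, clus, ecc]).astype(float)


def _all_shortest_paths(adj, s, t, dist):
    if t not in dist:
        return []
    out = []

    def walk(path):
        u = path[-1]
        if u == t:
            out.append(set(path))
            return
        for w in adj[u]:
            if w in dist and dist[w] == dist[u] + 1 and dist[u] < dist[t]:
                walk(path + [w])

    # restrict dist to the BFS layers from s toward t
    walk([s])
    return [p for p in out]


# -- contact labeling -------------------------------------------------------

def brute_labels(structure, cutoff=4.0):
    lig_atoms = [(x, y, z) for lig in structure.ligands
                 for _, x, y, z in lig.atoms]
    labels = []
    for res in structure.residues:
        hit = 0
        for _, x, y, z in res.atoms:
            for lx, ly, lz in lig_atoms:
                d = math.sqrt((x - lx) ** 2 + (y - ly) ** 2 + (z - lz) ** 2)
                if d <= cutoff:
                    hit = 1
        labels.append(hit)
    return np.array(labels, dtype=int)


# -- straight-line network evaluation ---------------------------------------

def _ln(x, g, b, eps=1e-5):
    mu = x.mean()
    var = ((x - mu) ** 2).mean()
    return g * (x - mu) / math.sqrt(var + eps) + b


def _softmax_row(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def _mhvf_one(tokens, P, prefix, n_heads):
    """Token-level MHVF for one nucleotide: (v, d) -> (v, d)."""
    v, d = tokens.shape
    dh = d // n_heads
    Q = tokens @ P[f"{prefix}.Wq"]
    K = tokens @ P[f"{prefix}.Wk"]
    V = tokens @ P[f"{prefix}.Wv"]
    ctx = np.zeros((v, d))
    for h in range(n_heads):
        sl = slice(h * dh, (h + 1) * dh)
        scores = (Q[:, sl] @ K[:, sl].T) / math.sqrt(dh)
        for t in range(v):
            ctx[t, sl] = _softmax_row(scores[t]) @ V[:, sl]
    attn = ctx @ P[f"{prefix}.Wo"]
    ffn = np.maximum(attn @ P[f"{prefix}.W1"] + P[f"{prefix}.b1"], 0.0) \
        @ P[f"{prefix}.W2"] + P[f"{prefix}.b2"]
    out = np.zeros_like(tokens)
    for t in range(v):
        h1 = _ln(tokens[t] + attn[t], P[f"{prefix}.ln1_g"], P[f"{prefix}.ln1_b"])
        out[t] = _ln(h1 + ffn[t], P[f"{prefix}.ln2_g"], P[f"{prefix}.ln2_b"])
    return out


def oracle_forward(model, graph):
    """Loop-based evaluation of the whole network; returns probabilities."""
    cfg = model.cfg
    P = {k: t.data for k, t in model.params.items()}
    X = graph.features.X
    n = X.shape[0]
    ahat = {v: graph.normalized_adjacency(v) for v in cfg.views}

    per_view = {v: X for v in cfg.views}
    fused = None
    z_scales = []
    for layer in range(1, cfg.n_layers + 1):
        hs = {}
        for view in cfg.views:
            x_in = fused if (layer > 1 and view == "T") else per_view[view]
            hs[view] = np.maximum(
                ahat[view] @ x_in @ P[f"gcn{layer}.{view}.W"], 0.0)
        out_tokens = np.zeros((n, len(cfg.views), cfg.d_hidden))
        for i in range(n):
            tokens = np.stack([hs[v][i] for v in cfg.views])
            out_tokens[i] = _mhvf_one(tokens, P, f"mhvf{layer}", cfg.n_heads)
        fused = out_tokens.reshape(n, len(cfg.views) * cfg.d_hidden)
        z = np.maximum(fused @ P[f"scale{layer}.W1"]
                       + P[f"scale{layer}.b1"], 0.0) \
            @ P[f"scale{layer}.W2"] + P[f"scale{layer}.b2"]
        per_view = hs
        z_scales.append(z)

    z_node = X @ P["node.W"] + P["node.b"]
    all_scales = [z_node] + z_scales
    if cfg.use_msf:
        z_f = np.zeros((n, cfg.d_scale))
        for i in range(n):
            tokens = np.stack([z[i] for z in all_scales])
            Q = tokens @ P["msf.Wq"]
            K = tokens @ P["msf.Wk"]
            V = tokens @ P["msf.Wv"]
            za = np.zeros_like(tokens)
            for t in range(tokens.shape[0]):
                scores = (Q[t] @ K.T) / math.sqrt(cfg.d_scale)
                za[t] = (_softmax_row(scores) @ V) @ P["msf.Wo"]
            z_f[i] = za.mean(axis=0)
    else:
        z_f = np.concatenate(all_scales, axis=1)

    logits = (np.maximum(z_f @ P["clf.W1"] + P["clf.b1"], 0.0)
              @ P["clf.W2"] + P["clf.b2"]).reshape(-1)
    return 1.0 / (1.0 + np.exp(-logits))
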