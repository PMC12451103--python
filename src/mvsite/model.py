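"""The multi-view GCN with attention-based view and scale fusion.

Per RNA, each of L (default 3) layers runs one GCN propagation per view
and then fuses the per-view node vectors with a Multi-Head View Fusion
(MHVF) block: for every nucleotide the view vectors form a short token
sequence, multi-head self-attention mixes the views, a feed-forward
network refines the attention output, and two residual layer-norms
produce the fused matrix

    X = LN( LN(H + Attention) + FFN(Attention) ),

where H stacks the per-view GCN outputs.  The fused matrix feeds the
*tertiary* branch of the next layer, while the primary and secondary
branches propagate their own (post-ReLU) view outputs — an asymmetric
wiring that keeps the 3D view in the fusion loop.

Each layer's fused matrix is mapped by an MLP to a common width, giving
scale embeddings Z_NA, Z_Loc, Z_Glob; the raw features projected linearly
give Z_Node.  A shared-projection self-attention over the four scale
tokens produces enhanced vectors whose elementwise mean Z_f feeds a small
MLP classifier ending in a sigmoid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .graphs import MultiViewGraph
from .nn import Tensor

__all__ = ["ModelConfig", "MultiViewSiteModel", "ScaleEmbeddings",
           "gcn_propagate", "view_fuse", "multi_scale_fuse", "classify"]


@dataclass
class ModelConfig:
    """Widths and switches of the network; all overridable by config file."""

    d_init: int
    d_hidden: int = 128
    n_heads: int = 4
    d_scale: int = 128
    ffn_mult: int = 4
    clf_hidden: int = 64
    dropout: float = 0.1
    n_layers: int = 3
    views: tuple[str, ...] = ("P", "S", "T")
    use_msf: bool = True
    mhvf_tokens: str = "views"      # "views" (default) or "nodes"
    seed: int = 0

    def __post_init__(self):
        self.views = tuple(self.views)
        if self.mhvf_tokens not in ("views", "nodes"):
            raise ValueError("mhvf_tokens must be 'views' or 'nodes'")
        if self.mhvf_width % self.n_heads:
            raise ValueError("n_heads must divide the MHVF width")
        for v in (self.d_init, self.d_hidden, self.n_heads, self.d_scale,
                  self.ffn_mult, self.clf_hidden, self.n_layers):
            if v <= 0:
                raise ValueError("all dimensions must be positive")
        if not self.views or any(v not in ("P", "S", "T") for v in self.views):
            raise ValueError(f"invalid view set {self.views}")

    @property
    def mhvf_width(self) -> int:
        """Attention model width: per-view in "views" mode, concatenated
        in the alternative "nodes" mode (attention over nucleotides)."""
        if self.mhvf_tokens == "nodes":
            return len(self.views) * self.d_hidden
        return self.d_hidden

    @property
    def d_head(self) -> int:
        return self.mhvf_width // self.n_heads

    @property
    def n_scales(self) -> int:
        return self.n_layers + 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["views"] = list(self.views)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["views"] = tuple(d.get("views", ("P", "S", "T")))
        return cls(**d)


@dataclass
class ScaleEmbeddings:
    """Per-nucleotide representations at every scale plus the fused output."""

    Z_node: np.ndarray
    Z_scales: list[np.ndarray]          # one per GCN layer (NA, Loc, Glob, ...)
    Z_enhanced: list[np.ndarray] | None
    Z_f: np.ndarray
    logits: np.ndarray
    p: np.ndarray
    y_hat: np.ndarray
    attention: dict = field(default_factory=dict)


# -- functional pieces ------------------------------------------------------

def gcn_propagate(a_hat, x, w) -> Tensor:
    """One graph-convolution step: ReLU(A_hat @ X @ W)."""
    a_hat = a_hat if isinstance(a_hat, Tensor) else Tensor(a_hat)
    x = x if isinstance(x, Tensor) else Tensor(x)
    if a_hat.shape[1] != x.shape[0] or x.shape[1] != w.shape[0]:
        raise ValueError(
            f"shape mismatch: A_hat {a_hat.shape}, X {x.shape}, W {w.shape}")
    return (a_hat @ x @ w).relu()


def _attention(tokens: Tensor, wq: Tensor, wk: Tensor, wv: Tensor,
               wo: Tensor, n_heads: int, out: dict | None = None,
               tag: str = "") -> Tensor:
    """Multi-head self-attention over a (n, t, d) token tensor."""
    n, t, d = tokens.shape
    dh = d // n_heads

    def split_heads(x: Tensor) -> Tensor:
        return x.reshape(n, t, n_heads, dh).transpose(0, 2, 1, 3)

    q, k, v = split_heads(tokens @ wq), split_heads(tokens @ wk), split_heads(tokens @ wv)
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
    attn = nn.softmax(scores, axis=-1)                    # (n, h, t, t)
    if out is not None:
        out[tag] = attn.data.copy()
    ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
    return ctx @ wo


def view_fuse(hs: list[Tensor], params: dict[str, Tensor], n_heads: int,
              dropout_masks: tuple | None = None,
              attn_out: dict | None = None, tag: str = "",
              tokens_mode: str = "views") -> Tensor:
    """MHVF: fuse per-view node vectors, returning the (n, v*d) matrix.

    In the default "views" mode the attention tokens of each nucleotide
    are its per-view vectors (attention mixes views).  The alternative
    "nodes" mode attends over nucleotides on the width-v*d concatenation.
    """
    d = hs[0].shape[1]
    for h in hs:
        if h.shape != hs[0].shape:
            raise ValueError("view matrices must share n and d")
    n, v = hs[0].shape[0], len(hs)
    if tokens_mode == "nodes":
        tokens = nn.concat(hs, axis=-1).reshape(1, n, v * d)
    else:
        tokens = nn.stack(hs, axis=1)                     # (n, v, d)
    if params["Wq"].shape[0] != tokens.shape[-1]:
        raise ValueError(f"block width {params['Wq'].shape[0]} != "
                         f"token width {tokens.shape[-1]}")
    attn = _attention(tokens, params["Wq"], params["Wk"], params["Wv"],
                      params["Wo"], n_heads, attn_out, tag)
    if dropout_masks is not None:
        attn = attn * Tensor(dropout_masks[0])
    ffn_h = (attn @ params["W1"] + params["b1"]).relu()
    if dropout_masks is not None:
        ffn_h = ffn_h * Tensor(dropout_masks[1])
    ffn = ffn_h @ params["W2"] + params["b2"]
    h1 = nn.layer_norm(tokens + attn, params["ln1_g"], params["ln1_b"])
    out_tokens = nn.layer_norm(h1 + ffn, params["ln2_g"], params["ln2_b"])
    return out_tokens.reshape(n, v * d)


def multi_scale_fuse(zs: list[Tensor], params: dict[str, Tensor],
                     attn_out: dict | None = None) -> tuple[Tensor, list[Tensor]]:
    """Self-attention over the scale tokens; Z_f is the mean of the outputs."""
    d = zs[0].shape[1]
    for z in zs:
        if z.shape != zs[0].shape:
            raise ValueError("scale embeddings must share n and d_scale")
    n, s = zs[0].shape[0], len(zs)
    tokens = nn.stack(zs, axis=1)                         # (n, s, d)
    za = _attention(tokens, params["Wq"], params["Wk"], params["Wv"],
                    params["Wo"], 1, attn_out, "msf")
    z_f = za.mean(axis=1)
    enhanced = [za[:, k, :] for k in range(s)]
    return z_f, enhanced


def classify(z_f: Tensor, params: dict[str, Tensor]) -> Tensor:
    """MLP head producing one logit per nucleotide."""
    if not np.isfinite(z_f.data).all():
        raise FloatingPointError("non-finite fused embedding")
    h = (z_f @ params["W1"] + params["b1"]).relu()
    return (h @ params["W2"] + params["b2"]).reshape(-1)


# -- the model --------------------------------------------------------------

class MultiViewSiteModel:
    """Holds the parameter tensors and runs the forward pass."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(cfg.seed))

    # parameter construction ------------------------------------------------
    def _add(self, name: str, arr: np.ndarray) -> None:
        self.params[name] = Tensor(arr, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        d, ds = cfg.d_hidden, cfg.d_scale
        mw = cfg.mhvf_width
        v = len(cfg.views)
        for layer in range(1, cfg.n_layers + 1):
            for view in cfg.views:
                d_in = self._gcn_in_dim(layer, view)
                self._add(f"gcn{layer}.{view}.W",
                          nn.glorot_uniform(rng, d_in, d))
            p = f"mhvf{layer}"
            for w in ("Wq", "Wk", "Wv", "Wo"):
                self._add(f"{p}.{w}", nn.glorot_uniform(rng, mw, mw))
            self._add(f"{p}.W1", nn.glorot_uniform(rng, mw, cfg.ffn_mult * mw))
            self._add(f"{p}.b1", np.zeros(cfg.ffn_mult * mw))
            self._add(f"{p}.W2", nn.glorot_uniform(rng, cfg.ffn_mult * mw, mw))
            self._add(f"{p}.b2", np.zeros(mw))
            for ln in ("ln1", "ln2"):
                self._add(f"{p}.{ln}_g", np.ones(mw))
                self._add(f"{p}.{ln}_b", np.zeros(mw))
            self._add(f"scale{layer}.W1", nn.glorot_uniform(rng, v * d, ds))
            self._add(f"scale{layer}.b1", np.zeros(ds))
            self._add(f"scale{layer}.W2", nn.glorot_uniform(rng, ds, ds))
            self._add(f"scale{layer}.b2", np.zeros(ds))
        self._add("node.W", nn.glorot_uniform(rng, cfg.d_init, ds))
        self._add("node.b", np.zeros(ds))
        if cfg.use_msf:
            for w in ("Wq", "Wk", "Wv", "Wo"):
                self._add(f"msf.{w}", nn.glorot_uniform(rng, ds, ds))
        clf_in = ds if cfg.use_msf else cfg.n_scales * ds
        self._add("clf.W1", nn.glorot_uniform(rng, clf_in, cfg.clf_hidden))
        self._add("clf.b1", np.zeros(cfg.clf_hidden))
        self._add("clf.W2", nn.glorot_uniform(rng, cfg.clf_hidden, 1))
        self._add("clf.b2", np.zeros(1))

    def _gcn_in_dim(self, layer: int, view: str) -> int:
        cfg = self.cfg
        if layer == 1:
            return cfg.d_init
        if view == "T":
            return len(cfg.views) * cfg.d_hidden    # consumes the fused matrix
        return cfg.d_hidden

    def _block(self, prefix: str) -> dict[str, Tensor]:
        plen = len(prefix) + 1
        return {k[plen:]: t for k, t in self.params.items()
                if k.startswith(prefix + ".")}

    # forward ---------------------------------------------------------------
    def forward(self, graph: MultiViewGraph, train: bool = False,
                rng: np.random.Generator | None = None,
                collect_attention: bool = False) -> ScaleEmbeddings:
        cfg = self.cfg
        n = graph.n
        attn_maps: dict | None = {} if collect_attention else None
        x_init = Tensor(graph.features.X)
        a_hats = {v: Tensor(graph.normalized_adjacency(v)) for v in cfg.views}

        def dropout_masks(shapes):
            if not train or cfg.dropout <= 0 or rng is None:
                return None
            keep = 1.0 - cfg.dropout
            return tuple((rng.random(s) < keep) / keep for s in shapes)

        per_view: dict[str, Tensor] = {v: x_init for v in cfg.views}
        fused: Tensor | None = None
        z_scales: list[Tensor] = []
        for layer in range(1, cfg.n_layers + 1):
            hs = {}
            for view in cfg.views:
                if layer > 1 and view == "T":
                    x_in = fused
                else:
                    x_in = per_view[view]
                hs[view] = gcn_propagate(a_hats[view], x_in,
                                         self.params[f"gcn{layer}.{view}.W"])
            v = len(cfg.views)
            if cfg.mhvf_tokens == "nodes":
                tok_shape = (1, n, cfg.mhvf_width)
            else:
                tok_shape = (n, v, cfg.mhvf_width)
            masks = dropout_masks([tok_shape,
                                   tok_shape[:-1] + (cfg.ffn_mult * cfg.mhvf_width,)])
            fused = view_fuse([hs[view] for view in cfg.views],
                              self._block(f"mhvf{layer}"), cfg.n_heads,
                              masks, attn_maps, f"mhvf{layer}",
                              tokens_mode=cfg.mhvf_tokens)
            per_view = hs
            sp = self._block(f"scale{layer}")
            z = ((fused @ sp["W1"] + sp["b1"]).relu() @ sp["W2"] + sp["b2"])
            if not np.isfinite(z.data).all():
                raise FloatingPointError(f"non-finite activation at layer {layer}")
            z_scales.append(z)

        z_node = x_init @ self.params["node.W"] + self.params["node.b"]
        all_scales = [z_node] + z_scales
        if cfg.use_msf:
            z_f, enhanced = multi_scale_fuse(all_scales, self._block("msf"),
                                             attn_maps)
        else:
            z_f, enhanced = nn.concat(all_scales, axis=-1), None
        logits = classify(z_f, self._block("clf"))
        p = nn.sigmoid(logits)
        emb = ScaleEmbeddings(
            Z_node=z_node.data, Z_scales=[z.data for z in z_scales],
            Z_enhanced=None if enhanced is None else [z.data for z in enhanced],
            Z_f=z_f.data, logits=logits.data, p=p.data,
            y_hat=(p.data >= 0.5).astype(int),
            attention=attn_maps or {})
        emb._logits_tensor = logits                    # kept for the training loss
        return emb

    def predict_proba(self, graph: MultiViewGraph) -> np.ndarray:
        return self.forward(graph).p

    # persistence -----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path) -> None:
        arrays = {f"param::{k}": v for k, v in self.state_dict().items()}
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.cfg.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MultiViewSiteModel":
        with np.load(path) as data:
            cfg = ModelConfig.from_dict(
                json.loads(bytes(data["config_json"].tobytes()).decode()))
            model = cls(cfg)
            model.load_state_dict(
                {k[len("param::"):]: data[k] for k in data.files
                 if k.startswith("param::")})
        return model
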