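"""Dataset splitting, the optimization loop, metrics, and ablations.

Training minimizes mean per-nucleotide binary cross-entropy with Adam
(default learning rate 6e-5, batch size 30 RNA graphs, 200 epochs).
Batching is per-RNA: each graph is propagated independently, so no
messages cross RNA boundaries, and the batch loss is the mean of the
per-node loss terms pooled over all graphs of the batch.  The returned
checkpoint is the epoch with the best validation AUC.
"""

from __future__ import annotations

import copy
import math

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

from . import nn
from .graphs import MultiViewGraph
from .model import ModelConfig, MultiViewSiteModel

ABLATION_VARIANTS = ("prim_str", "sec_str", "ter_str",
                     "prim_feat", "sec_feat", "ter_feat", "msf")

_VIEW_OF = {"prim_str": "P", "sec_str": "S", "ter_str": "T"}
_FEAT_BLOCKS = {"prim_feat": ("conservation", "embedding", "one_hot"),
                "sec_feat": ("secondary",),
                "ter_feat": ("topological", "asa")}


@dataclass
class TrainConfig:
    """Optimization hyperparameters and ablation switches."""

    learning_rate: float = 6e-5
    batch_size: int = 30
    epochs: int = 200
    val_fraction: float = 0.1
    seed: int = 0
    pos_weight: float | None = None        # optional class weighting, off by default
    ablation: str | None = None            # one of ABLATION_VARIANTS or None
    k_primary: int = 13
    k_tertiary: int = 8
    n_layers: int = 3

    def __post_init__(self):
        for v in (self.learning_rate, self.batch_size, self.epochs,
                  self.k_primary, self.k_tertiary, self.n_layers):
            if v <= 0:
                raise ValueError("hyperparameters must be positive")
        if self.ablation is not None and self.ablation not in ABLATION_VARIANTS:
            raise ValueError(f"unknown ablation variant {self.ablation!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def ablate(cfg: TrainConfig, variant: str) -> TrainConfig:
    """Return a config with the named component disabled."""
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown ablation variant {variant!r}; "
                         f"choose from {ABLATION_VARIANTS}")
    out = copy.deepcopy(cfg)
    out.ablation = variant
    return out


def apply_ablation_to_model_config(mcfg: ModelConfig,
                                   variant: str | None) -> ModelConfig:
    """Translate an ablation flag into the model configuration."""
    if variant is None:
        return mcfg
    d = mcfg.to_dict()
    if variant in _VIEW_OF:
        view = _VIEW_OF[variant]
        d["views"] = [v for v in mcfg.views if v != view]
    elif variant == "msf":
        d["use_msf"] = False
    return ModelConfig.from_dict(d)


def apply_feature_ablation(graphs: list[MultiViewGraph],
                           variant: str | None) -> list[MultiViewGraph]:
    """Zero the ablated view's feature block (graphs untouched)."""
    if variant not in _FEAT_BLOCKS:
        return graphs
    out = []
    for g in graphs:
        feats = copy.deepcopy(g.features)
        for name in _FEAT_BLOCKS[variant]:
            a, b = feats.blocks[name]
            feats.X[:, a:b] = 0.0
        out.append(MultiViewGraph(g.chain_id, feats, g.graphs, g.y, g.meta))
    return out


# -- splitting --------------------------------------------------------------

def split_dataset(chains: list, fraction: float = 0.1,
                  seed: int = 0) -> tuple[list, list]:
    """Deterministic whole-chain split; train gets ceil((1-f) * m) chains."""
    m = len(chains)
    if m < 2:
        raise ValueError("need at least 2 chains to split")
    n_train = math.ceil((1.0 - fraction) * m)
    order = np.random.default_rng(seed).permutation(m)
    train = [chains[i] for i in sorted(order[:n_train])]
    val = [chains[i] for i in sorted(order[n_train:])]
    return train, val


# -- metrics ----------------------------------------------------------------

@dataclass
class MetricsReport:
    TP: int
    FP: int
    TN: int
    FN: int
    precision: float
    recall: float
    mcc: float
    auc: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    """AUC as the Mann-Whitney rank statistic with average ranks for ties.

    Returns None when only one class is present (AUC undefined).
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def compute_metrics(y_true, p, threshold: float = 0.5) -> MetricsReport:
    """Confusion counts plus precision / recall / MCC / AUC.

    Predictions at exactly the threshold count as positive.  MCC is 0 when
    any factor of its denominator vanishes; AUC is None for one-class data.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y_true and p must have equal length")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(tp, fp, tn, fn, precision, recall, mcc, roc_auc(y, p))


# -- training loop ----------------------------------------------------------

def batch_loss(model: MultiViewSiteModel, graphs: list[MultiViewGraph],
               train: bool = False, rng=None,
               pos_weight: float | None = None) -> "nn.Tensor":
    """Mean per-nucleotide BCE over all nodes of all graphs in the batch."""
    losses, total = [], 0
    for g in graphs:
        emb = model.forward(g, train=train, rng=rng)
        per_node = nn.bce_with_logits(emb._logits_tensor, g.y)
        if pos_weight is not None:
            w = np.where(g.y == 1, pos_weight, 1.0)
            per_node = per_node * nn.Tensor(w)
        losses.append(per_node.sum())
        total += g.n
    out = losses[0]
    for term in losses[1:]:
        out = out + term
    return out * (1.0 / total)


@dataclass
class TrainResult:
    model: MultiViewSiteModel
    best_state: dict
    best_epoch: int
    best_val_auc: float
    history: list[dict] = field(default_factory=list)

    def history_text(self) -> str:
        lines = ["epoch\ttrain_loss\tval_loss\tval_auc"]
        for h in self.history:
            auc = "NA" if h["val_auc"] is None else f"{h['val_auc']:.6f}"
            lines.append(f"{h['epoch']}\t{h['train_loss']:.6f}\t"
                         f"{h['val_loss']:.6f}\t{auc}")
        return "\n".join(lines) + "\n"


def _pooled_eval(model, graphs):
    ys = np.concatenate([g.y for g in graphs])
    ps = np.concatenate([model.predict_proba(g) for g in graphs])
    return ys, ps


def train(train_graphs: list[MultiViewGraph],
          val_graphs: list[MultiViewGraph],
          mcfg: ModelConfig, cfg: TrainConfig) -> TrainResult:
    """Adam/BCE optimization; returns best-validation-AUC checkpoint."""
    if not train_graphs:
        raise ValueError("empty training set")
    y_all = np.concatenate([g.y for g in train_graphs])
    if y_all.min() == y_all.max():
        raise ValueError("training labels are all one class; loss is degenerate")

    mcfg = apply_ablation_to_model_config(mcfg, cfg.ablation)
    train_graphs = apply_feature_ablation(train_graphs, cfg.ablation)
    val_graphs = apply_feature_ablation(val_graphs, cfg.ablation)

    model = MultiViewSiteModel(mcfg)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    best_auc, best_state, best_epoch = -np.inf, model.state_dict(), 0
    history = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_graphs))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_graphs[i] for i in order[start:start + cfg.batch_size]]
            opt.zero_grad()
            loss = batch_loss(model, batch, train=True, rng=rng,
                              pos_weight=cfg.pos_weight)
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        if val_graphs:
            val_loss = float(batch_loss(model, val_graphs).data)
            ys, ps = _pooled_eval(model, val_graphs)
            val_auc = roc_auc(ys, ps)
        else:
            val_loss, val_auc = float("nan"), None
        history.append({"epoch": epoch,
                        "train_loss": float(np.mean(epoch_losses)),
                        "val_loss": val_loss, "val_auc": val_auc})
        score = -history[-1]["train_loss"] if val_auc is None else val_auc
        if score > best_auc:
            best_auc, best_state, best_epoch = score, model.state_dict(), epoch

    model.load_state_dict(best_state)
    return TrainResult(model, best_state, best_epoch,
                       best_auc if val_graphs else float("nan"), history)


def evaluate(model: MultiViewSiteModel, graphs: list[MultiViewGraph],
             ablation: str | None = None) -> MetricsReport:
    """Pooled per-nucleotide metrics over a list of RNAs."""
    graphs = apply_feature_ablation(graphs, ablation)
    ys, ps = _pooled_eval(model, graphs)
    return compute_metrics(ys, ps)


# -- sensitivity harness ----------------------------------------------------

def rebuild_tertiary(graphs: list[MultiViewGraph], k: int) -> list[MultiViewGraph]:
    """Re-derive the tertiary k-NN graph from stored coordinates."""
    from .graphs import build_tertiary_graph
    out = []
    for g in graphs:
        coords = g.meta.get("coords")
        if coords is None:
            raise ValueError("graph lacks stored coordinates for the k sweep")
        new = dict(g.graphs)
        new["T"] = build_tertiary_graph(np.asarray(coords), k=k)
        out.append(MultiViewGraph(g.chain_id, g.features, new, g.y, g.meta))
    return out


def sensitivity_sweep(train_graphs, val_graphs, test_graphs,
                      mcfg: ModelConfig, cfg: TrainConfig,
                      k_values=range(2, 16), layer_values=range(1, 7),
                      sweep: str = "k") -> list[dict]:
    """Retrain across k_tertiary (or layer-count) settings; report MCC/AUC."""
    rows = []
    settings = k_values if sweep == "k" else layer_values
    for value in settings:
        m = ModelConfig.from_dict(mcfg.to_dict())
        tr, va, te = train_graphs, val_graphs, test_graphs
        if sweep == "k":
            tr, va, te = (rebuild_tertiary(s, value) for s in (tr, va, te))
        else:
            m = ModelConfig.from_dict({**mcfg.to_dict(), "n_layers": value})
        result = train(tr, va, m, cfg)
        rep = evaluate(result.model, te, cfg.ablation)
        rows.append({"sweep": sweep, "value": value,
                     "mcc": rep.mcc, "auc": rep.auc,
                     "precision": rep.precision, "recall": rep.recall})
    return rows


def sweep_to_tsv(rows: list[dict]) -> str:
    cols = ["sweep", "value", "precision", "recall", "mcc", "auc"]
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join("NA" if r[c] is None else str(r[c])
                               for c in cols))
    return "\n".join(lines) + "\n"
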