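"""Training loop: attention MIL with patch- and nuclei-level penalties.

One training sample is a slide: its patch feature bag and, per patch,
the nucleus graph of that patch.  Each epoch and slide the model
(1) scores patches by gated attention and pools the slide feature,
(2) selects the c highest-attention patches, (3) runs the nuclei GNN on
their graphs, (4) combines slide cross-entropy with patch/nuclei APL
penalties, and takes one Adam step.  The dataset is split 7:1:2 into
stratified train/validation/test parts; the best-validation model is
kept and early stopping uses the validation total loss.

All randomness (splitting, initialization, shuffling) derives from the
config seed, so two runs with the same seed produce identical loss
histories.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph import NucleiGNN, NucleiGraph, fit_degree_normalizer
from .losses import DEFAULT_CLIP_A, DEFAULT_WEIGHTS, apl_loss, one_hot, slide_ce, total_loss
from .mil import AttentionMIL, PatchBag, select_bottom_c, select_top_c, slide_probabilities
from .nn import Adam, Tensor

__all__ = [
    "SlideSample",
    "TrainConfig",
    "TrainResult",
    "split_dataset",
    "train",
    "predict",
    "predict_table",
]


@dataclass
class SlideSample:
    """One slide ready for training: bag plus per-patch nucleus graphs."""

    bag: PatchBag
    graphs: list[NucleiGraph | None]
    label: int

    def __post_init__(self):
        if len(self.graphs) != self.bag.n_patches:
            raise ValueError("one graph (or None) per patch required")


@dataclass
class TrainConfig:
    seed: int = 0
    lr: float = 5e-3
    weight_decay: float = 0.0
    epochs: int = 20
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    clip_a: float = DEFAULT_CLIP_A
    active_term: str = "nce"
    top_c: int = 8
    use_bottom_instances: bool = True
    patience: int = 10
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    feature_dim: int = 1024
    trunk_dim: int = 256
    gate_dim: int = 64
    n_heads: int = 4
    d_k: int = 64
    attention_variant: str = "gated_sa"
    gnn_hidden: int = 64
    gnn_msg_dim: int = 32
    gnn_layers: int = 2
    standardize: bool = True


@dataclass
class ConstrainedMILModel:
    """Attention-MIL plus nuclei-GNN with shared normalization state."""

    mil: AttentionMIL
    gnn: NucleiGNN
    delta: float = 1.0
    patch_mean: np.ndarray | None = None
    patch_std: np.ndarray | None = None
    nuc_mean: np.ndarray | None = None
    nuc_std: np.ndarray | None = None

    def parameters(self):
        return self.mil.parameters() + self.gnn.parameters()

    def normalize_bag(self, bag: PatchBag) -> PatchBag:
        if self.patch_mean is None:
            return bag
        feats = (bag.features - self.patch_mean) / self.patch_std
        return PatchBag(bag.slide_id, feats, bag.coordinates, bag.label)

    def normalize_graph(self, graph: NucleiGraph | None) -> NucleiGraph | None:
        if graph is None or self.nuc_mean is None or graph.n_nodes == 0:
            return graph
        return replace(graph, features=(graph.features - self.nuc_mean) / self.nuc_std)

    def state(self):
        return {
            "mil": self.mil.state(),
            "gnn": self.gnn.state(),
            "delta": self.delta,
            "patch_mean": None if self.patch_mean is None else self.patch_mean.copy(),
            "patch_std": None if self.patch_std is None else self.patch_std.copy(),
            "nuc_mean": None if self.nuc_mean is None else self.nuc_mean.copy(),
            "nuc_std": None if self.nuc_std is None else self.nuc_std.copy(),
        }

    def load_state(self, state):
        self.mil.load_state(state["mil"])
        self.gnn.load_state(state["gnn"])
        self.delta = state["delta"]
        self.patch_mean = state["patch_mean"]
        self.patch_std = state["patch_std"]
        self.nuc_mean = state["nuc_mean"]
        self.nuc_std = state["nuc_std"]


@dataclass
class TrainResult:
    model: ConstrainedMILModel
    config: TrainConfig
    history: pd.DataFrame
    split: dict[str, list[int]]
    best_epoch: int
    best_state: dict = field(repr=False, default=None)


def split_dataset(
    labels: list[int],
    seed: int,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
) -> dict[str, list[int]]:
    """Stratified train/val/test split by slide label (default 7:1:2)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        parts["train"].extend(idx[:n_train].tolist())
        parts["val"].extend(idx[n_train : n_train + n_val].tolist())
        parts["test"].extend(idx[n_train + n_val :].tolist())
    for name, part in parts.items():
        got = set(labels[part].tolist())
        if got != set(np.unique(labels).tolist()):
            raise ValueError(
                f"split '{name}' lost a class (labels present: {sorted(got)}); "
                "add slides per class or change the seed"
            )
    return {k: sorted(v) for k, v in parts.items()}


def _slide_losses(model: ConstrainedMILModel, sample: SlideSample, config: TrainConfig):
    """Forward pass of one slide returning the loss bundle and scores."""
    bag = model.normalize_bag(sample.bag)
    scores, f_slide, slide_logits = model.mil(bag)
    p_slide = slide_logits.reshape(-1).softmax(axis=0)
    l_slide = slide_ce(p_slide, one_hot(sample.label))
    w1, w2, w3 = config.weights
    zero = Tensor(0.0)

    top = select_top_c(scores, config.top_c)
    l_patch = zero
    if w2 > 0:
        sel = [(i, sample.label) for i in top]
        if config.use_bottom_instances:
            bottom = select_bottom_c(scores, config.top_c)
            sel += [(i, 0) for i in bottom if i not in set(top)]
        logits = model.mil.patch_logits(bag, [i for i, _ in sel])
        terms = []
        for row, (_, lbl) in enumerate(sel):
            p = logits.rows([row]).reshape(-1).softmax(axis=0)
            terms.append(apl_loss(p, one_hot(lbl), config.clip_a, config.active_term))
        l_patch = sum(terms[1:], terms[0]) * (1.0 / len(terms))

    l_nuclei = zero
    if w3 > 0:
        terms = []
        for i in top:
            graph = model.normalize_graph(sample.graphs[i])
            if graph is None:
                continue
            _, logits, _ = model.gnn(graph, model.delta)
            p = logits.reshape(-1).softmax(axis=0)
            terms.append(apl_loss(p, one_hot(sample.label), config.clip_a, config.active_term))
        if terms:
            l_nuclei = sum(terms[1:], terms[0]) * (1.0 / len(terms))

    return total_loss(l_slide, l_patch, l_nuclei, config.weights), scores, slide_logits


def _fit_normalizers(model: ConstrainedMILModel, samples: list[SlideSample], train_idx: list[int]):
    feats = np.vstack([samples[i].bag.features for i in train_idx])
    model.patch_mean = feats.mean(axis=0)
    model.patch_std = np.maximum(feats.std(axis=0), 1e-8)
    nuc = [
        samples[i].graphs[j].features
        for i in train_idx
        for j in range(len(samples[i].graphs))
        if samples[i].graphs[j] is not None and samples[i].graphs[j].n_nodes > 0
    ]
    if nuc:
        nuc = np.vstack(nuc)
        model.nuc_mean = nuc.mean(axis=0)
        model.nuc_std = np.maximum(nuc.std(axis=0), 1e-8)


def train(samples: list[SlideSample], config: TrainConfig) -> TrainResult:
    """Train on a stratified 7:1:2 split; returns the best-validation model."""
    if len(samples) < 4:
        raise ValueError("need at least 4 slides")
    labels = [s.label for s in samples]
    split = split_dataset(labels, config.seed, config.split)
    rng = np.random.default_rng([config.seed, 1])
    model = ConstrainedMILModel(
        mil=AttentionMIL(
            feature_dim=config.feature_dim,
            trunk_dim=config.trunk_dim,
            gate_dim=config.gate_dim,
            n_heads=config.n_heads,
            d_k=config.d_k,
            attention_variant=config.attention_variant,
            rng=rng,
        ),
        gnn=NucleiGNN(
            in_dim=16,
            hidden=config.gnn_hidden,
            msg_dim=config.gnn_msg_dim,
            n_layers=config.gnn_layers,
            rng=rng,
        ),
    )
    if config.standardize:
        _fit_normalizers(model, samples, split["train"])
    train_graphs = [
        model.normalize_graph(g) or g
        for i in split["train"]
        for g in samples[i].graphs
        if g is not None and g.n_nodes > 0
    ]
    model.delta = fit_degree_normalizer(train_graphs) if train_graphs else 1.0

    optimizer = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    shuffle_rng = np.random.default_rng([config.seed, 2])
    history_rows = []
    best_state, best_val, best_epoch = model.state(), np.inf, 0
    since_best = 0
    for epoch in range(config.epochs):
        order = np.array(split["train"])
        shuffle_rng.shuffle(order)
        epoch_losses = []
        for i in order:
            bundle, _, _ = _slide_losses(model, samples[i], config)
            optimizer.zero_grad()
            bundle.total.backward()
            optimizer.step()
            epoch_losses.append(bundle.values())
        val_total, val_correct = 0.0, 0
        for i in split["val"]:
            bundle, _, logits = _slide_losses(model, samples[i], config)
            val_total += bundle.total.item()
            _, cls, _ = slide_probabilities(logits)
            val_correct += int(cls == samples[i].label)
        val_total /= max(len(split["val"]), 1)
        row = {k: float(np.mean([e[k] for e in epoch_losses])) for k in epoch_losses[0]}
        row.update(
            epoch=epoch,
            val_l_total=val_total,
            val_accuracy=val_correct / max(len(split["val"]), 1),
        )
        history_rows.append(row)
        if val_total < best_val - 1e-12:
            best_val, best_epoch = val_total, epoch
            best_state = model.state()
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break
    model.load_state(best_state)
    history = pd.DataFrame(history_rows)
    return TrainResult(
        model=model,
        config=config,
        history=history,
        split=split,
        best_epoch=best_epoch,
        best_state=best_state,
    )


def predict(model: ConstrainedMILModel, sample: SlideSample):
    """(PrePro, PreCls, positive-class probability, attention scores)."""
    bag = model.normalize_bag(sample.bag)
    scores, _, logits = model.mil(bag)
    prepro, precls, p = slide_probabilities(logits)
    return prepro, precls, float(p[1]), scores.data


def predict_table(model: ConstrainedMILModel, samples: list[SlideSample], indices=None) -> pd.DataFrame:
    """Per-slide prediction report (slide_id, GT, PrePro, PreCls)."""
    indices = range(len(samples)) if indices is None else indices
    rows = []
    for i in indices:
        prepro, precls, p_pos, _ = predict(model, samples[i])
        rows.append(
            {
                "slide_id": samples[i].bag.slide_id,
                "GT": samples[i].label,
                "PrePro": prepro,
                "PreCls": precls,
                "p_positive": p_pos,
            }
        )
    return pd.DataFrame(rows)
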