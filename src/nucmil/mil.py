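"""Attention-based multiple-instance pooling over patch feature bags.

A slide is a bag of N patch feature vectors (1024-d by default).  Two
multi-head self-attention transforms of the bag feed a sigmoid branch
and a tanh branch; their elementwise product is projected to one
pre-softmax logit per patch and softmax-normalized into attention scores
``s`` (positive, summing to 1).  The slide feature is the attention-
weighted sum of patch features — a convex combination — classified by a
linear slide head.  The ``c`` highest-scoring instances (and optionally
the ``c`` lowest, labeled negative) supervise a linear patch head and
select the patches whose nucleus graphs feed the nuclei branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module, MultiheadSelfAttention, Tensor

__all__ = [
    "PatchBag",
    "AttentionMIL",
    "select_top_c",
    "select_bottom_c",
    "pool_slide",
    "slide_probabilities",
]


@dataclass
class PatchBag:
    """All patch features of one slide plus tile coordinates."""

    slide_id: str
    features: np.ndarray      # N x d
    coordinates: np.ndarray   # N x 2 top-left (x, y) px
    label: int = -1

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.coordinates = np.asarray(self.coordinates)
        if self.features.ndim != 2 or len(self.features) < 1:
            raise ValueError("bag needs at least one patch")
        if len(self.coordinates) != len(self.features):
            raise ValueError("coordinates/features length mismatch")

    @property
    def n_patches(self) -> int:
        return len(self.features)


class AttentionMIL(Module):
    """Gated two-branch attention scoring plus slide and patch heads.

    A shared linear trunk projects raw patch features into a compact
    space consumed by both attention branches and the patch head, so
    the patch-level penalty shapes the same representation that drives
    attention.  The slide feature itself remains the attention-weighted
    sum of the RAW patch features, classified by the slide head.

    The final score projection is zero-initialized: attention starts as
    exact mean pooling and sharpens only as training provides gradient,
    which keeps early pooling unbiased.
    """

    def __init__(
        self,
        feature_dim: int = 1024,
        trunk_dim: int = 256,
        gate_dim: int = 64,
        n_heads: int = 4,
        d_k: int = 64,
        n_classes: int = 2,
        attention_variant: str = "gated_sa",
        rng: np.random.Generator | None = None,
    ):
        if attention_variant not in ("gated_sa", "gated_plain"):
            raise ValueError("unknown attention_variant")
        rng = np.random.default_rng() if rng is None else rng
        self.variant = attention_variant
        self.trunk = Linear(feature_dim, trunk_dim, rng)
        if attention_variant == "gated_sa":
            self.sa_a = MultiheadSelfAttention(trunk_dim, gate_dim, n_heads, d_k, rng)
            self.sa_b = MultiheadSelfAttention(trunk_dim, gate_dim, n_heads, d_k, rng)
        else:  # plain gated attention: linear branch transforms
            self.sa_a = Linear(trunk_dim, gate_dim, rng)
            self.sa_b = Linear(trunk_dim, gate_dim, rng)
        self.score_proj = Linear(gate_dim, 1, rng)
        self.score_proj.weight.data[:] = 0.0
        self.score_proj.bias.data[:] = 0.0
        self.slide_head = Linear(feature_dim, n_classes, rng)
        self.patch_head = Linear(trunk_dim, n_classes, rng)

    def _trunk_features(self, bag: PatchBag) -> Tensor:
        if not np.all(np.isfinite(bag.features)):
            raise ValueError("non-finite patch features")
        return self.trunk(Tensor(bag.features)).relu()

    def attention_scores(self, bag: PatchBag) -> Tensor:
        """Softmax-normalized attention over the bag's patches."""
        h = self._trunk_features(bag)
        gate = self.sa_a(h).sigmoid() * self.sa_b(h).tanh()
        logits = self.score_proj(gate).reshape(-1)
        return logits.softmax(axis=0)

    def forward(self, bag: PatchBag):
        """Returns (scores, slide_feature, slide_logits)."""
        s = self.attention_scores(bag)
        f_slide = pool_slide(Tensor(bag.features), s)
        return s, f_slide, self.slide_head(f_slide.reshape(1, -1))

    __call__ = forward

    def patch_logits(self, bag: PatchBag, indices: np.ndarray) -> Tensor:
        """Per-instance class logits of the selected patches (trunk space)."""
        idx = np.asarray(indices, dtype=np.intp)
        sub = PatchBag(bag.slide_id, bag.features[idx], bag.coordinates[idx], bag.label)
        return self.patch_head(self._trunk_features(sub))


def pool_slide(features: Tensor | np.ndarray, scores: Tensor | np.ndarray) -> Tensor:
    """Attention pooling: the score-weighted sum of patch features."""
    feats = features if isinstance(features, Tensor) else Tensor(features)
    s = scores if isinstance(scores, Tensor) else Tensor(scores)
    if s.shape[0] != feats.shape[0]:
        raise ValueError("scores/features length mismatch")
    return (s.reshape(1, -1) @ feats).reshape(-1)


def select_top_c(scores: np.ndarray | Tensor, c: int = 8) -> np.ndarray:
    """Indices of the c largest scores, ties broken by lower index.

    Returns all indices when the bag holds fewer than c patches.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    s = scores.data if isinstance(scores, Tensor) else np.asarray(scores)
    order = np.lexsort((np.arange(len(s)), -s))
    return np.sort(order[: min(c, len(s))])


def select_bottom_c(scores: np.ndarray | Tensor, c: int = 8) -> np.ndarray:
    """Indices of the c smallest scores, ties broken by lower index."""
    if c < 1:
        raise ValueError("c must be >= 1")
    s = scores.data if isinstance(scores, Tensor) else np.asarray(scores)
    order = np.lexsort((np.arange(len(s)), s))
    return np.sort(order[: min(c, len(s))])


def slide_probabilities(slide_logits: Tensor | np.ndarray) -> tuple[float, int, np.ndarray]:
    """(PrePro, PreCls, class probabilities) from slide logits.

    PreCls is the argmax class; PrePro is the softmax probability of the
    predicted class.
    """
    z = slide_logits.data if isinstance(slide_logits, Tensor) else np.asarray(slide_logits)
    z = z.reshape(-1)
    e = np.exp(z - z.max())
    p = e / e.sum()
    cls = int(np.argmax(p))
    return float(p[cls]), cls, p
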