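"""Noise-robust composite loss: slide cross-entropy plus APL penalties.

Instance labels inherited from the slide label are noisy — a
high-attention patch of a positive slide is not necessarily cancerous —
so the patch- and nuclei-level branches use the Active Passive Loss:

* active term, normalized cross-entropy
  ``NCE = -sum_k q log p / -sum_k log p``, bounded in [0, 1];
* passive term, reverse cross-entropy
  ``RCE = -sum_k p(k) log q(k)`` with ``log 0`` clipped to a constant A
  (default -4), bounded by ``-A``.

The slide level uses plain cross-entropy, and the total is the weighted
sum ``w1 L_slide + w2 L_patch + w3 L_nuclei`` with default weights
(0.7, 0.2, 0.1).  Zeroing a weight removes that branch's loss and its
gradient, which is how the ablations are run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossBundle", "apl_loss", "slide_ce", "total_loss", "one_hot"]

DEFAULT_WEIGHTS = (0.7, 0.2, 0.1)
DEFAULT_CLIP_A = -4.0
_EPS = 1e-7


def one_hot(label: int, n_classes: int = 2) -> np.ndarray:
    q = np.zeros(n_classes)
    q[int(label)] = 1.0
    return q


def _check_q(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    if q.ndim != 1 or np.any(q < 0) or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("q must be a distribution on the simplex")
    return q


def _as_tensor(p) -> Tensor:
    return p if isinstance(p, Tensor) else Tensor(p)


def apl_loss(
    p,
    q,
    clip_a: float = DEFAULT_CLIP_A,
    active: str = "nce",
) -> Tensor:
    """Active Passive Loss of one predicted distribution ``p`` vs truth ``q``.

    ``active`` selects the active term: ``"nce"`` (default) or plain
    ``"ce"``.  ``p`` may be a Tensor for backpropagation; ``q`` is a
    fixed distribution (typically one-hot).
    """
    if active not in ("nce", "ce"):
        raise ValueError("active must be 'nce' or 'ce'")
    if clip_a >= 0:
        raise ValueError("clip_a must be negative")
    q = _check_q(q)
    p = _as_tensor(p).reshape(-1)
    if p.shape[0] != len(q):
        raise ValueError("p/q length mismatch")
    logp = p.clip_min(_EPS).log()
    ce = -(logp * q).sum()
    if active == "nce":
        denom = -logp.sum()
        active_term = ce / denom
    else:
        active_term = ce
    logq = np.where(q > 0, np.log(np.maximum(q, _EPS)), clip_a)
    rce = -(p * logq).sum()
    return active_term + rce


def slide_ce(p, q) -> Tensor:
    """Cross-entropy ``-sum_k q log p`` with ``p`` floored at 1e-7."""
    q = _check_q(q)
    p = _as_tensor(p).reshape(-1)
    if p.shape[0] != len(q):
        raise ValueError("p/q length mismatch")
    return -(p.clip_min(_EPS).log() * q).sum()


@dataclass
class LossBundle:
    slide: Tensor
    patch: Tensor
    nuclei: Tensor
    total: Tensor
    weights: tuple[float, float, float]

    def values(self) -> dict[str, float]:
        return {
            "l_slide": self.slide.item(),
            "l_patch": self.patch.item(),
            "l_nuclei": self.nuclei.item(),
            "l_total": self.total.item(),
        }


def total_loss(
    l_slide,
    l_patch=0.0,
    l_nuclei=0.0,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> LossBundle:
    """Exact weighted sum of the three loss terms."""
    if any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative")
    ls, lp, ln = (_as_tensor(x) for x in (l_slide, l_patch, l_nuclei))
    w1, w2, w3 = weights
    total = ls * w1 + lp * w2 + ln * w3
    return LossBundle(slide=ls, patch=lp, nuclei=ln, total=total, weights=tuple(weights))
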