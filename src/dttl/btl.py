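"""Balanced Target Learning (BTL).

Scores each synthesised minority image with the current classifier's
minority probability, keeps those at or below the confidence ceiling
``p_max`` (very high scores indicate samples far from the decision
boundary, which add little), retains at most ``floor(s * |X_min^t|)`` of
them ranked by descending score, merges them with the pseudo-labeled
target partition into the balanced set T', and fine-tunes F and C on T'
with plain cross-entropy (the domain discriminator is frozen and
unused).  Balance comes from resampling, not loss re-weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _nn as nn
from .cda import CDAState, PartitionedTarget, converged
from .config import BTLConfig, SelectionConfig
from .data import MAJ, MIN
from .models import as_nchw
from .cmt import GeneratedPool

__all__ = ["BalancedTargetSet", "score_minority_prob", "select_samples",
           "assemble_balanced_target", "balanced_ce_loss", "train_btl"]

ORIGIN_PSEUDO_MAJ = "target-pseudo-maj"
ORIGIN_PSEUDO_MIN = "target-pseudo-min"
ORIGIN_SYNTH = "synthesized-min"


@dataclass
class BalancedTargetSet:
    """The reassembled training set T' with per-sample origin tags."""

    images: np.ndarray
    labels: np.ndarray
    origin: np.ndarray  # strings from the ORIGIN_* vocabulary

    def __len__(self) -> int:
        return self.images.shape[0]

    def counts(self) -> dict[str, int]:
        return {"maj": int(np.sum(self.labels == MAJ)),
                "min": int(np.sum(self.labels == MIN))}


def score_minority_prob(state: CDAState, pool: GeneratedPool) -> np.ndarray:
    """Minority-class probability C(F(x))_min for every pool sample."""
    if len(pool) == 0:
        raise ValueError("cannot score an empty pool")
    expected = state.F.layers[0].c_in
    x = as_nchw(pool.samples)
    if x.shape[1] != expected:
        raise ValueError("pool images do not match the trained backbone input")
    return state.minority_score(pool.samples)


def select_samples(pool: GeneratedPool, scores: np.ndarray,
                   cfg: SelectionConfig, n_min: int) -> np.ndarray:
    """Confidence-based retention; returns selected pool indices.

    Keeps samples with p_min <= score <= p_max, ranks them by
    descending score (ties broken by ascending pool index), and
    truncates to floor(s * n_min).
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape[0] != len(pool):
        raise ValueError("scores must align with the pool")
    if n_min < 0:
        raise ValueError("n_min must be >= 0")
    eligible = np.flatnonzero((scores <= cfg.p_max) & (scores >= cfg.p_min))
    # descending score, ascending index on ties
    order = np.lexsort((eligible, -scores[eligible]))
    k = int(np.floor(cfg.s * n_min))
    return eligible[order][:k]


def assemble_balanced_target(part: PartitionedTarget, pool: GeneratedPool,
                             selected: np.ndarray) -> BalancedTargetSet:
    """T' = pseudo-majority U (pseudo-minority U selected synthetic)."""
    selected = np.asarray(selected, dtype=np.int64)
    imgs = [part.maj, part.min, pool.samples[selected]]
    labels = [np.full(len(part.maj), MAJ), np.full(len(part.min), MIN),
              np.full(len(selected), MIN)]
    origin = [np.full(len(part.maj), ORIGIN_PSEUDO_MAJ, dtype=object),
              np.full(len(part.min), ORIGIN_PSEUDO_MIN, dtype=object),
              np.full(len(selected), ORIGIN_SYNTH, dtype=object)]
    return BalancedTargetSet(
        np.concatenate([np.asarray(a, dtype=np.float32).reshape(-1, *part.images.shape[1:])
                        for a in imgs]),
        np.concatenate(labels).astype(np.int64),
        np.concatenate(origin),
    )


def balanced_ce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy -E[log p(true class)] over T'."""
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    y = np.asarray(y, dtype=np.int64)
    if y.size and not np.isin(y, (MAJ, MIN)).all():
        raise ValueError("labels must be in {maj, min}")
    return -float(np.mean(np.log(nn.clamp_prob(p[np.arange(len(y)), y]))))


def train_btl(state: CDAState, t_prime: BalancedTargetSet, cfg: BTLConfig) -> CDAState:
    """Continue training F and C (in place on `state`) on the balanced set."""
    if len(np.unique(t_prime.labels)) < 2:
        raise ValueError("balanced target set is single-class; cannot train")
    if cfg.max_epochs == 0:
        return state
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(6)[5])
    opt = nn.Adam(state.F.params() + state.C.params(), cfg.learning_rate,
                  cfg.weight_decay)
    x = as_nchw(t_prime.images)
    y = t_prime.labels
    n, bs = len(x), cfg.batch_size
    steps = max(1, int(np.ceil(n / bs)))
    history: list[float] = []
    log_rows = []
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        ep_losses = []
        for step in range(steps):
            idx = perm[step * bs:(step + 1) * bs]
            if idx.size == 0:
                continue
            xb, yb = x[idx], y[idx]
            feats = state.F.forward(xb, train=True)
            logits = state.C.forward(feats, train=True)
            pb = nn.softmax(logits)
            loss = balanced_ce_loss(pb, yb)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite entropy loss in balanced training")
            onehot = np.zeros_like(pb)
            onehot[np.arange(len(yb)), yb] = 1.0
            g = ((pb - onehot) / len(yb)).astype(np.float32)
            opt.zero_grad()
            state.F.backward(state.C.backward(g))
            opt.step()
            ep_losses.append(loss)
        mean_loss = float(np.mean(ep_losses))
        log_rows.append({"epoch": epoch, "l_ent": mean_loss})
        history.append(mean_loss)
        if converged(history, cfg.loss_tolerance):
            break
    btl_log = pd.DataFrame(log_rows)
    state.training_log = (pd.concat([state.training_log, btl_log], ignore_index=True)
                          if len(state.training_log) else btl_log)
    return state
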