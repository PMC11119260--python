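"""Cross-domain Discriminability Adaptation (CDA).

Trains the feature generator F, class-prediction layer C and domain
discriminator D by alternating two updates per mini-batch:

* a discriminator step ascending the domain-invariant feature-learning
  (DFL) objective  E_s[log D(F(x))] + E_t[log(1 - D(F(x)))],
* a generator/classifier step descending the same objective in theta_f
  together with the synthetic-discriminability (SD) loss
  -E_s[log C(F(x))_y] + lam * E_t[entropy(C(F(x)))].

Afterwards the trained C(F(.)) pseudo-labels the unlabeled target domain
and partitions it into pseudo-majority and pseudo-minority subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn as nn
from .config import CDAConfig
from .data import MAJ, MIN, LabeledImages
from .models import (as_nchw, build_classifier, build_domain_discriminator,
                     build_feature_generator)

__all__ = ["CDAState", "PartitionedTarget", "dfl_loss", "sd_loss",
           "train_cda", "train_source_only", "pseudo_label"]


# ---------------------------------------------------------------------------
# losses (public, array-in scalar-out; the training loop shares these)


def dfl_loss(d_source: np.ndarray, d_target: np.ndarray) -> float:
    """Domain-invariant feature-learning value: the discriminator ascends
    it, the feature generator descends it.  Always <= 0, approaching 0
    only under perfect domain discrimination."""
    d_source = np.atleast_1d(np.asarray(d_source, dtype=np.float64))
    d_target = np.atleast_1d(np.asarray(d_target, dtype=np.float64))
    if d_source.size == 0 or d_target.size == 0:
        raise ValueError("dfl_loss needs a non-empty batch on each side")
    return float(np.mean(np.log(nn.clamp_prob(d_source)))
                 + np.mean(np.log(1.0 - nn.clamp_prob(d_target))))


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.size and not np.isin(y, (MAJ, MIN)).all():
        raise ValueError("labels must be in {maj, min}")
    return y.astype(np.int64)


def sd_loss(p_source: np.ndarray, y_source: np.ndarray,
            p_target: np.ndarray, lam: float) -> float:
    """Synthetic-discriminability loss: source cross-entropy plus
    lam x mean prediction entropy of the target (sharpening term)."""
    p_source = np.atleast_2d(np.asarray(p_source, dtype=np.float64))
    p_target = np.atleast_2d(np.asarray(p_target, dtype=np.float64))
    y = _check_labels(y_source)
    ce = 0.0
    if p_source.size:
        ce = -float(np.mean(np.log(nn.clamp_prob(p_source[np.arange(len(y)), y]))))
    ent = 0.0
    if p_target.size:
        pt = nn.clamp_prob(p_target)
        ent = -float(np.mean(np.sum(pt * np.log(pt), axis=1)))
    return ce + lam * ent


# ---------------------------------------------------------------------------
# state


@dataclass
class CDAState:
    """Trained (or initialised) F/C/D triple with its training log."""

    F: nn.Sequential
    C: nn.Sequential
    D: nn.Sequential
    cfg: CDAConfig
    training_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def features(self, images: np.ndarray) -> np.ndarray:
        return self.F.forward(as_nchw(images), train=False)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """(N, 2) class probabilities of C(F(x)); columns (maj, min)."""
        return nn.softmax(self.C.forward(self.features(images), train=False))

    def minority_score(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images)[:, MIN]

    def domain_prob(self, images: np.ndarray) -> np.ndarray:
        z = self.D.forward(self.features(images), train=False)
        return nn.sigmoid(z[:, 0])


@dataclass
class PartitionedTarget:
    """Pseudo-labeled partition of the target domain."""

    images: np.ndarray          # all target images, original order
    pseudo_labels: np.ndarray   # (N,) in {MAJ, MIN}

    @property
    def maj(self) -> np.ndarray:
        return self.images[self.pseudo_labels == MAJ]

    @property
    def min(self) -> np.ndarray:
        return self.images[self.pseudo_labels == MIN]

    @property
    def maj_indices(self) -> np.ndarray:
        return np.flatnonzero(self.pseudo_labels == MAJ)

    @property
    def min_indices(self) -> np.ndarray:
        return np.flatnonzero(self.pseudo_labels == MIN)


def init_state(cfg: CDAConfig) -> CDAState:
    root = np.random.SeedSequence(cfg.seed)
    r_f, r_c, r_d = (np.random.default_rng(s) for s in root.spawn(3))
    return CDAState(
        F=build_feature_generator(r_f, cfg.feature_dim),
        C=build_classifier(r_c, cfg.feature_dim),
        D=build_domain_discriminator(r_d, cfg.feature_dim),
        cfg=cfg,
    )


def converged(history: list[float], tol: float, window: int = 3) -> bool:
    """Moving-average loss-variation stopping rule."""
    if len(history) < window + 1:
        return False
    diffs = np.abs(np.diff(np.asarray(history[-(window + 1):])))
    return bool(diffs.mean() < tol)


def _entropy_grad(p: np.ndarray) -> np.ndarray:
    """d/dlogits of mean prediction entropy H(p) for softmax p, per row."""
    logp = np.log(nn.clamp_prob(p))
    return p * ((p * logp).sum(axis=1, keepdims=True) - logp)


def _check_finite(value: float, term: str) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite loss in term '{term}'")


def train_cda(source: LabeledImages, target_images: np.ndarray,
              cfg: CDAConfig, adversarial: bool = True) -> CDAState:
    """Alternating adversarial optimisation of F, C, D.

    ``adversarial=False`` trains F and C on the source cross-entropy
    alone (the no-adaptation ablation / source-only baseline path).
    """
    if len(source) == 0 or len(target_images) == 0:
        raise ValueError("both domains must be non-empty")
    if len(np.unique(source.labels)) < 2:
        raise ValueError("source must contain both classes")
    state = init_state(cfg)
    if cfg.max_epochs == 0:
        return state
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
    opt_fc = nn.Adam(state.F.params() + state.C.params(), cfg.learning_rate,
                     cfg.weight_decay)
    opt_d = nn.Adam(state.D.params(), cfg.learning_rate, cfg.weight_decay)

    x_src = as_nchw(source.images)
    y_src = source.labels
    x_tgt = as_nchw(target_images)
    ns, nt = len(x_src), len(x_tgt)
    bs = cfg.batch_size
    steps = max(1, int(np.ceil(max(ns, nt) / bs)))
    history: list[float] = []
    log_rows = []
    for epoch in range(cfg.max_epochs):
        if cfg.adv_ramp_epochs > 0:
            adv_w = cfg.adv_weight * min(1.0, (epoch + 1) / cfg.adv_ramp_epochs)
        else:
            adv_w = cfg.adv_weight
        perm_s = rng.permutation(ns)
        perm_t = rng.permutation(nt)
        ep_dfl, ep_sd = [], []
        for step in range(steps):
            bi_s = perm_s[(step * bs) % ns:(step * bs) % ns + bs]
            bi_t = perm_t[(step * bs) % nt:(step * bs) % nt + bs]
            if bi_s.size == 0 or bi_t.size == 0:
                continue
            xb_s, yb = x_src[bi_s], y_src[bi_s]
            xb_t = x_tgt[bi_t]
            nb_s, nb_t = len(xb_s), len(xb_t)
            x_all = np.concatenate([xb_s, xb_t])

            # one F forward per step: the D update treats the features
            # as fixed inputs, the F/C update backpropagates through them
            feats = state.F.forward(x_all, train=True)
            if adversarial:
                # --- discriminator ascent on the DFL objective (F frozen)
                z = state.D.forward(feats, train=True)[:, 0]
                p_dom = nn.sigmoid(z)
                ldfl = dfl_loss(p_dom[:nb_s], p_dom[nb_s:])
                _check_finite(ldfl, "dfl")
                gz = np.empty_like(z)
                gz[:nb_s] = -(1.0 - p_dom[:nb_s]) / nb_s   # ascend log D
                gz[nb_s:] = p_dom[nb_s:] / nb_t            # ascend log(1-D)
                opt_d.zero_grad()
                state.D.backward(gz[:, None].astype(np.float32))
                opt_d.step()
            else:
                ldfl = 0.0

            # --- generator/classifier descent on DFL + SD
            logits = state.C.forward(feats, train=True)
            p = nn.softmax(logits)
            lsd = sd_loss(p[:nb_s], yb, p[nb_s:], cfg.lam)
            _check_finite(lsd, "sd")
            g_logits = np.zeros_like(logits)
            onehot = np.zeros((nb_s, 2), dtype=np.float64)
            onehot[np.arange(nb_s), yb] = 1.0
            g_logits[:nb_s] = (p[:nb_s] - onehot) / nb_s
            if cfg.lam > 0:
                g_logits[nb_s:] = cfg.lam * _entropy_grad(p[nb_s:]) / nb_t
            if cfg.marginal_diversity > 0:
                # bonus: ascend the entropy of the mean target prediction
                pbar = p[nb_s:].mean(axis=0, keepdims=True)
                dl_dp = (np.log(nn.clamp_prob(pbar)) + 1.0) / nb_t
                jac = p[nb_s:] * (dl_dp - (p[nb_s:] * dl_dp).sum(axis=1, keepdims=True))
                g_logits[nb_s:] += cfg.marginal_diversity * jac
            opt_fc.zero_grad()
            d_feat = state.C.backward(g_logits.astype(np.float32))
            if adversarial:
                z = state.D.forward(feats, train=True)[:, 0]
                p_dom = nn.sigmoid(z)
                gz = np.empty_like(z)
                if cfg.adversarial_mode == "literal":
                    # descend the DFL value itself; gradients vanish once D wins
                    gz[:nb_s] = (1.0 - p_dom[:nb_s]) / nb_s
                    gz[nb_s:] = -p_dom[nb_s:] / nb_t
                else:
                    # non-saturating confusion surrogate (same fixed points):
                    # descend -E_s[log(1-D)] - E_t[log D]
                    gz[:nb_s] = p_dom[:nb_s] / nb_s
                    gz[nb_s:] = -(1.0 - p_dom[nb_s:]) / nb_t
                d_feat = d_feat + adv_w * state.D.backward(gz[:, None].astype(np.float32))
            state.F.backward(d_feat.astype(np.float32))
            opt_fc.step()
            ep_dfl.append(ldfl)
            ep_sd.append(lsd)
        row = {"epoch": epoch, "l_dfl": float(np.mean(ep_dfl)),
               "l_sd": float(np.mean(ep_sd))}
        row["total"] = abs(row["l_dfl"]) + row["l_sd"] if adversarial else row["l_sd"]
        log_rows.append(row)
        history.append(row["total"])
        if converged(history, cfg.loss_tolerance):
            break
    state.training_log = pd.DataFrame(log_rows)
    return state


def train_source_only(source: LabeledImages, target_images: np.ndarray,
                      cfg: CDAConfig) -> CDAState:
    """Supervised source training of F and C only (no adaptation)."""
    return train_cda(source, target_images, cfg, adversarial=False)


def pseudo_label(state: CDAState, target_images: np.ndarray) -> PartitionedTarget:
    """Argmax pseudo-labels; exact ties go to the majority class."""
    if len(target_images) == 0:
        raise ValueError("target set must be non-empty")
    p = state.predict_proba(target_images)
    labels = np.where(p[:, MIN] > p[:, MAJ], MIN, MAJ)
    return PartitionedTarget(np.asarray(target_images, dtype=np.float32), labels)
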