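"""Cross-domain Minority Translation (CMT).

A dual-generator, dual-discriminator translation GAN in the cycle-
consistency family: G maps source-majority images toward the target-
minority distribution, G' maps target-majority images toward the
source-minority distribution, and patch discriminators D_t / D_s judge
realism on the target and source sides.  The objective combines

* an adversarial term (discriminators maximise, generators minimise),
* a direct-translation (DT) penalty  E||G(x) - x||_1,
* a minority cycle-consistency (MCC) penalty
  E||G'(G(x_s)) - x_s||_1 + E||G(G'(x_t)) - x_t||_1,
* an identity (IDE) penalty  E||G'(x_s) - x_s||_1 + E||G(x_t) - x_t||_1,

weighted (lambda_DT, lambda_MCC, lambda_IDE).  After training,
``synthesize_minority`` applies G to the full source-majority set to
produce the synthetic target-minority pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import _nn as nn
from .cda import converged
from .config import CMTConfig, CMTWeights
from .data import MAJ, MIN, LabeledImages
from .models import ResidualGenerator, as_nchw, build_patch_discriminator

__all__ = ["CMTState", "GeneratedPool", "dt_loss", "mcc_loss", "identity_loss",
           "gan_losses", "cmt_objective", "train_cmt", "synthesize_minority"]

Translator = Callable[[np.ndarray], np.ndarray]


def _batch(images) -> np.ndarray:
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    return x


def _l1(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(np.abs(a - b)))


def dt_loss(G: Translator, batch: np.ndarray) -> float:
    """Mean per-pixel L1 deviation of the translation from its input."""
    batch = _batch(batch)
    if batch.size == 0:
        raise ValueError("dt_loss needs a non-empty batch")
    return _l1(_batch(G(batch)), batch)


def mcc_loss(G: Translator, G_prime: Translator,
             batch_s: np.ndarray, batch_t: np.ndarray) -> float:
    """Minority cycle-consistency: both round trips should reconstruct."""
    batch_s, batch_t = _batch(batch_s), _batch(batch_t)
    if batch_s.size == 0 and batch_t.size == 0:
        raise ValueError("mcc_loss needs at least one non-empty batch")
    total = 0.0
    if batch_s.size:
        total += _l1(_batch(G_prime(_batch(G(batch_s)))), batch_s)
    if batch_t.size:
        total += _l1(_batch(G(_batch(G_prime(batch_t)))), batch_t)
    return total


def identity_loss(G: Translator, G_prime: Translator,
                  batch_s: np.ndarray, batch_t: np.ndarray) -> float:
    """Generators should leave inputs already in their output domain alone."""
    batch_s, batch_t = _batch(batch_s), _batch(batch_t)
    if batch_s.size == 0 and batch_t.size == 0:
        raise ValueError("identity_loss needs at least one non-empty batch")
    total = 0.0
    if batch_s.size:
        total += _l1(_batch(G_prime(batch_s)), batch_s)
    if batch_t.size:
        total += _l1(_batch(G(batch_t)), batch_t)
    return total


@dataclass
class CMTState:
    G: ResidualGenerator
    G_prime: ResidualGenerator
    D_s: nn.Sequential
    D_t: nn.Sequential
    cfg: CMTConfig
    training_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def disc_prob(self, disc: nn.Sequential, images: np.ndarray) -> np.ndarray:
        return nn.sigmoid(disc.forward(as_nchw(images), train=False))


def gan_losses(state: CMTState, batch_s_maj, batch_t_maj,
               batch_s_all, batch_t_all) -> tuple[float, float]:
    """Adversarial objective value from each side's perspective.

    Returns ``(generator_loss, discriminator_objective)`` where the
    discriminator objective is
    E[log D_t(x_t)] + E[log(1-D_t(G(x_s_maj)))] + E[log D_s(x_s)] +
    E[log(1-D_s(G'(x_t_maj)))]; discriminators maximise it and the
    generators minimise the same quantity, so the generator loss equals
    the fake-sample terms of the objective.
    """
    for name, b in (("batch_s_maj", batch_s_maj), ("batch_t_maj", batch_t_maj),
                    ("batch_s_all", batch_s_all), ("batch_t_all", batch_t_all)):
        if _batch(b).size == 0:
            raise ValueError(f"gan_losses: empty required batch {name}")
    fake_t = state.G(_batch(batch_s_maj))
    fake_s = state.G_prime(_batch(batch_t_maj))
    p_real_t = nn.clamp_prob(state.disc_prob(state.D_t, batch_t_all))
    p_fake_t = nn.clamp_prob(state.disc_prob(state.D_t, fake_t))
    p_real_s = nn.clamp_prob(state.disc_prob(state.D_s, batch_s_all))
    p_fake_s = nn.clamp_prob(state.disc_prob(state.D_s, fake_s))
    disc_obj = (float(np.mean(np.log(p_real_t))) + float(np.mean(np.log(1 - p_fake_t)))
                + float(np.mean(np.log(p_real_s))) + float(np.mean(np.log(1 - p_fake_s))))
    gen_loss = float(np.mean(np.log(1 - p_fake_t))) + float(np.mean(np.log(1 - p_fake_s)))
    if not (np.isfinite(disc_obj) and np.isfinite(gen_loss)):
        raise FloatingPointError("non-finite adversarial loss")
    return gen_loss, disc_obj


def cmt_objective(gan: float, dt: float, mcc: float, ide: float,
                  w: CMTWeights) -> float:
    """Weighted translation objective L_GAN + w_DT*L_DT + w_MCC*L_MCC + w_IDE*L_IDE."""
    return gan + w.lambda_dt * dt + w.lambda_mcc * mcc + w.lambda_ide * ide


@dataclass
class GeneratedPool:
    """Synthetic target-minority images plus the index of the
    source-majority image each was translated from."""

    samples: np.ndarray
    provenance: np.ndarray

    def __len__(self) -> int:
        return self.samples.shape[0]


def init_state(cfg: CMTConfig) -> CMTState:
    root = np.random.SeedSequence(cfg.seed)
    r_g, r_gp, r_ds, r_dt = (np.random.default_rng(s) for s in root.spawn(4))
    return CMTState(G=ResidualGenerator(r_g), G_prime=ResidualGenerator(r_gp),
                    D_s=build_patch_discriminator(r_ds),
                    D_t=build_patch_discriminator(r_dt), cfg=cfg)


def _l1_grad(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    return (np.sign(pred - ref) / pred.size).astype(np.float32)


def train_cmt(source: LabeledImages, target_partition, cfg: CMTConfig) -> CMTState:
    """Alternating Adam optimisation of the translation objective.

    ``target_partition`` is a :class:`~dttl.cda.PartitionedTarget`; its
    pseudo-majority and pseudo-minority sides are both required.
    """
    s_maj = source.images[source.labels == MAJ]
    s_min = source.images[source.labels == MIN]
    t_maj = np.asarray(target_partition.maj)
    t_min = np.asarray(target_partition.min)
    for name, arr in (("source majority", s_maj), ("source minority", s_min),
                      ("target pseudo-majority", t_maj), ("target pseudo-minority", t_min)):
        if arr.shape[0] == 0:
            raise ValueError(f"train_cmt: empty required subset: {name}")
    state = init_state(cfg)
    if cfg.max_epochs == 0:
        return state
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[4])
    w = cfg.weights
    opt_g = nn.Adam(state.G.params() + state.G_prime.params(),
                    cfg.learning_rate, cfg.weight_decay)
    opt_d = nn.Adam(state.D_s.params() + state.D_t.params(),
                    cfg.learning_rate, cfg.weight_decay)
    x_s_all = as_nchw(source.images)
    x_t_all = as_nchw(target_partition.images)
    x_s_maj, x_s_min = as_nchw(s_maj), as_nchw(s_min)
    x_t_maj, x_t_min = as_nchw(t_maj), as_nchw(t_min)
    bs = cfg.batch_size
    steps = max(1, int(np.ceil(len(x_s_maj) / bs)))
    history: list[float] = []
    log_rows = []

    def draw(x: np.ndarray) -> np.ndarray:
        idx = rng.integers(0, len(x), size=min(bs, len(x)))
        return x[idx]

    for epoch in range(cfg.max_epochs):
        ep = {"l_gan": [], "l_dt": [], "l_mcc": [], "l_ide": [], "l_cmt": []}
        for _ in range(steps):
            b_s_maj, b_t_maj = draw(x_s_maj), draw(x_t_maj)
            b_s_min, b_t_min = draw(x_s_min), draw(x_t_min)
            if cfg.real_pool == "minority":
                b_s_all, b_t_all = draw(x_s_min), draw(x_t_min)
            else:
                b_s_all, b_t_all = draw(x_s_all), draw(x_t_all)

            # ---- generator forwards (shared with the discriminator step)
            # G sees one batch [s_maj | dt_in | s_min | t_min]; G' sees
            # [t_maj | s_min | t_min]; cycle second hops are separate
            # passes, and backwards run in reverse forward order so the
            # per-layer cache stacks unwind correctly.
            dt_in = b_s_maj if cfg.dt_on_source_majority else b_t_maj
            n1, n2, n3, n4 = len(b_s_maj), len(dt_in), len(b_s_min), len(b_t_min)
            sl_adv_t = slice(0, n1)
            sl_dt = slice(n1, n1 + n2)
            sl_cyc_s = slice(n1 + n2, n1 + n2 + n3)
            sl_ide_t = slice(n1 + n2 + n3, n1 + n2 + n3 + n4)
            out_a = state.G.forward(
                np.concatenate([b_s_maj, dt_in, b_s_min, b_t_min]), train=True)
            m1, m2, m3 = len(b_t_maj), len(b_s_min), len(b_t_min)
            sl_adv_s = slice(0, m1)
            sl_ide_s = slice(m1, m1 + m2)
            sl_cyc_t = slice(m1 + m2, m1 + m2 + m3)
            out_b = state.G_prime.forward(
                np.concatenate([b_t_maj, b_s_min, b_t_min]), train=True)

            # ---- discriminator step (maximise; fakes treated as fixed)
            opt_d.zero_grad()
            disc_obj = 0.0
            for disc, real, fake in ((state.D_t, b_t_all, out_a[sl_adv_t]),
                                     (state.D_s, b_s_all, out_b[sl_adv_s])):
                xb = np.concatenate([real, fake])
                z = disc.forward(xb, train=True)
                pr = nn.sigmoid(z)
                n_r, n_f = len(real), len(fake)
                disc_obj += (np.log(nn.clamp_prob(pr[:n_r])).mean()
                             + np.log(1 - nn.clamp_prob(pr[n_r:])).mean())
                gz = np.empty_like(z)
                gz[:n_r] = -(1 - pr[:n_r]) / n_r    # ascend log D(real)
                gz[n_r:] = pr[n_r:] / n_f           # ascend log(1 - D(fake))
                disc.backward(gz.astype(np.float32))
            opt_d.step()

            # ---- generator step (minimise the full objective)
            opt_g.zero_grad()
            rec_s = state.G_prime.forward(out_a[sl_cyc_s], train=True)
            rec_t = state.G.forward(out_b[sl_cyc_t], train=True)
            z_t = state.D_t.forward(out_a[sl_adv_t], train=True)
            z_s = state.D_s.forward(out_b[sl_adv_s], train=True)

            g_a = np.zeros_like(out_a)
            g_b = np.zeros_like(out_b)
            pf_t, pf_s = nn.sigmoid(z_t), nn.sigmoid(z_s)
            l_gan = (float(np.log(1 - nn.clamp_prob(pf_t)).mean())
                     + float(np.log(1 - nn.clamp_prob(pf_s)).mean()))
            if cfg.generator_mode == "literal":
                # descend log(1 - D(fake)); vanishes once D wins
                gz_t = (-pf_t / n1).astype(np.float32)
                gz_s = (-pf_s / m1).astype(np.float32)
            else:
                # non-saturating surrogate: descend -log D(fake)
                gz_t = (-(1.0 - pf_t) / n1).astype(np.float32)
                gz_s = (-(1.0 - pf_s) / m1).astype(np.float32)
            g_a[sl_adv_t] += state.D_t.backward(gz_t)
            g_b[sl_adv_s] += state.D_s.backward(gz_s)
            l_mcc = _l1(rec_t, b_t_min) + _l1(rec_s, b_s_min)
            g_b[sl_cyc_t] += state.G.backward(w.lambda_mcc * _l1_grad(rec_t, b_t_min))
            g_a[sl_cyc_s] += state.G_prime.backward(w.lambda_mcc * _l1_grad(rec_s, b_s_min))
            l_dt = _l1(out_a[sl_dt], dt_in)
            g_a[sl_dt] += w.lambda_dt * _l1_grad(out_a[sl_dt], dt_in)
            l_ide = _l1(out_a[sl_ide_t], b_t_min) + _l1(out_b[sl_ide_s], b_s_min)
            g_a[sl_ide_t] += w.lambda_ide * _l1_grad(out_a[sl_ide_t], b_t_min)
            g_b[sl_ide_s] += w.lambda_ide * _l1_grad(out_b[sl_ide_s], b_s_min)
            state.G_prime.backward(g_b)
            state.G.backward(g_a)
            opt_g.step()

            l_cmt = cmt_objective(l_gan, l_dt, l_mcc, l_ide, w)
            if not np.isfinite(l_cmt):
                raise FloatingPointError("non-finite translation objective")
            for k, v in (("l_gan", l_gan), ("l_dt", l_dt), ("l_mcc", l_mcc),
                         ("l_ide", l_ide), ("l_cmt", l_cmt)):
                ep[k].append(v)
        row = {"epoch": epoch, **{k: float(np.mean(v)) for k, v in ep.items()},
               "l_disc": float(disc_obj)}
        log_rows.append(row)
        history.append(abs(row["l_cmt"]))
        if converged(history, cfg.loss_tolerance):
            break
    state.training_log = pd.DataFrame(log_rows)
    return state


def synthesize_minority(state: CMTState, majority: np.ndarray) -> GeneratedPool:
    """Translate every source-majority image into a synthetic
    target-minority sample; provenance is the identity index map."""
    majority = np.asarray(majority, dtype=np.float32)
    if majority.shape[0] == 0:
        return GeneratedPool(majority.reshape(0, *majority.shape[1:]),
                             np.zeros(0, dtype=np.int64))
    samples = state.G(majority).astype(np.float32)
    return GeneratedPool(samples, np.arange(len(majority), dtype=np.int64))
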