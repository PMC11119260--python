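"""Synthetic two-domain imbalanced image cohorts.

Emulates the structure of cross-site chest-radiograph transfer tasks:
two binary-class domains whose class imbalance is on the order of
0.25 : 1 and whose domain gap is a *global intensity change* — a
multiplicative contrast factor plus an additive brightness offset, the
shift family that histogram-level adaptation work hypothesises accounts
for most cross-device radiograph variation.

Each image is a smoothed-noise textured background; minority ("lesion
present") images superimpose a bright disc of configurable amplitude and
radius at a random interior location.  Target images reuse the source
renderer with seed streams paired by (class, index), so with the shift
at identity the two domains coincide exactly and the configured shift is
the *only* systematic domain difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .config import SyntheticConfig
from .data import CLASS_IDS, CLASS_NAMES, MAJ, MIN, CohortPair, LabeledImages

BACKGROUND_MEAN = 0.35     # base gray level of the tissue-like texture
TEXTURE_AMPLITUDE = 0.10   # peak-scaled amplitude of the smoothed noise field
TEXTURE_SIGMA = 3.0        # Gaussian smoothing scale, pixels


def _coerce_label(label) -> int:
    if label in CLASS_IDS:
        return CLASS_IDS[label]
    if label in (MAJ, MIN):
        return int(label)
    raise ValueError(f"label must be 'maj' or 'min', got {label!r}")


def render_components(label, cfg: SyntheticConfig, rng: np.random.Generator) -> dict:
    """Render one image and return its parts (background, lesion mask, image).

    Draw order is fixed — background field, then lesion geometry (minority
    only), then pixel noise — so a given generator state yields a
    bit-reproducible image.
    """
    cls = _coerce_label(label)
    s = cfg.image_size
    field = gaussian_filter(rng.normal(0.0, 1.0, size=(s, s)), TEXTURE_SIGMA, mode="wrap")
    peak = np.abs(field).max()
    if peak > 0:
        field = field / peak * TEXTURE_AMPLITUDE
    background = BACKGROUND_MEAN + field
    mask = np.zeros((s, s), dtype=bool)
    if cls == MIN:
        lo, hi = cfg.lesion_radius_range
        r = int(rng.integers(lo, hi + 1))
        cy = int(rng.integers(r + 1, s - r - 1))
        cx = int(rng.integers(r + 1, s - r - 1))
        yy, xx = np.ogrid[:s, :s]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    img = background + cfg.lesion_intensity * mask
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=(s, s))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return {"background": background.astype(np.float32), "lesion_mask": mask, "image": img}


def render_image(label, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Render a single (H, W) float32 image in [0, 1]."""
    return render_components(label, cfg, rng)["image"]


def apply_domain_shift(img: np.ndarray, cfg: SyntheticConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Global intensity shift: clip(contrast * img + brightness + noise, 0, 1)."""
    if not (np.isfinite(cfg.shift_contrast) and np.isfinite(cfg.shift_brightness)):
        raise ValueError("shift parameters must be finite")
    out = cfg.shift_contrast * np.asarray(img, dtype=np.float64) + cfg.shift_brightness
    if cfg.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        out = out + rng.normal(0.0, cfg.noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _identity_shift(cfg: SyntheticConfig) -> SyntheticConfig:
    import dataclasses
    return dataclasses.replace(cfg, shift_contrast=1.0, shift_brightness=0.0)


def make_cohort(cfg: SyntheticConfig) -> CohortPair:
    """Generate the paired source/target cohort.

    Source images are rendered as-is; target images are rendered from
    seed streams paired by (class, sample index) and then passed through
    :func:`apply_domain_shift`.  Target labels are retained only in the
    evaluation-only ``target_hidden_labels`` field.
    """
    counts = (cfg.n_source_majority + cfg.n_source_minority,
              cfg.n_target_majority + cfg.n_target_minority)
    if min(counts) == 0:
        raise ValueError("each domain needs at least one sample")
    root = np.random.SeedSequence(cfg.seed)
    # children: [0] unused namespace marker, [1] shift noise, [2] interleave
    _, shift_child, perm_child = root.spawn(3)
    shift_rng = np.random.default_rng(shift_child)

    def render_class(cls: int, n: int) -> np.ndarray:
        imgs = np.empty((n, cfg.image_size, cfg.image_size), dtype=np.float32)
        for i in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0, cls, i)))
            imgs[i] = render_image(cls, cfg, rng)
        return imgs

    src_maj = render_class(MAJ, cfg.n_source_majority)
    src_min = render_class(MIN, cfg.n_source_minority)
    source = LabeledImages(
        np.concatenate([src_maj, src_min]),
        np.concatenate([np.full(len(src_maj), MAJ), np.full(len(src_min), MIN)]),
    )
    tgt_maj = render_class(MAJ, cfg.n_target_majority)
    tgt_min = render_class(MIN, cfg.n_target_minority)
    tgt = np.concatenate([tgt_maj, tgt_min])
    hidden = np.concatenate([np.full(len(tgt_maj), MAJ), np.full(len(tgt_min), MIN)])
    tgt = apply_domain_shift(tgt, cfg, rng=shift_rng)
    # deterministic interleave so class blocks are not positional giveaways
    order = np.random.default_rng(perm_child).permutation(len(tgt))
    return CohortPair(source, tgt[order], hidden[order])


def cohort_summary(cohort: CohortPair) -> pd.DataFrame:
    """Per-domain class counts and minority/majority imbalance ratio."""
    rows = []
    for domain, labels in (("source", cohort.source.labels),
                           ("target", cohort.target_hidden_labels)):
        n_maj = int(np.sum(labels == MAJ))
        n_min = int(np.sum(labels == MIN))
        rows.append({"domain": domain, "n_majority": n_maj, "n_minority": n_min,
                     "imbalance_ratio": (n_min / n_maj) if n_maj else float("nan")})
    return pd.DataFrame(rows)


def imbalance_ratio(n_majority: int, n_minority: int) -> float:
    """Minority/majority count ratio; 0 when the minority is empty."""
    if n_majority <= 0:
        return float("nan")
    return n_minority / n_majority


def disc_template_response(images: np.ndarray, radius: int) -> np.ndarray:
    """Matched-filter lesion score: max over locations of (mean inside a
    disc of ``radius``) minus (mean in the surrounding annulus).

    Serves as a fixed, training-free separability oracle for synthetic
    cohorts and as an independent check that translated images acquire
    lesion structure.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    size = 2 * (radius + 3) + 1
    c = size // 2
    yy, xx = np.ogrid[:size, :size]
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    disc = (d2 <= radius**2).astype(np.float64)
    ring = ((d2 > radius**2) & (d2 <= (radius + 3) ** 2)).astype(np.float64)
    kernel = disc / disc.sum() - ring / ring.sum()
    kernel = kernel[::-1, ::-1]
    out = np.empty(images.shape[0])
    for i, img in enumerate(images):
        out[i] = fftconvolve(img, kernel, mode="valid").max()
    return out


def template_scores(cohort_images: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    r = int(round(sum(cfg.lesion_radius_range) / 2))
    return disc_template_response(cohort_images, r)
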