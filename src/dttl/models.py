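"""Desk-scale network architectures.

These are small CPU-friendly realisations of the framework's four
network roles: feature generator F, class-prediction layer C, domain
discriminator D, and the translation generators/discriminators.  Named
large backbones can be slotted in by registering a builder under the
same interface; the bundled ones are sized for 32x32 grayscale images.
"""

from __future__ import annotations

import numpy as np

from . import _nn as nn


def as_nchw(images: np.ndarray) -> np.ndarray:
    """(N, H, W) or (H, W) -> float32 (N, 1, H, W)."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[:, None]
    return x


def build_feature_generator(rng: np.random.Generator, feature_dim: int = 64) -> nn.Sequential:
    """3 stride-2 conv blocks (16/32/64) + global average pooling."""
    return nn.Sequential(
        nn.Conv2d(1, 16, 3, 2, 1, rng), nn.ReLU(),
        nn.Conv2d(16, 32, 3, 2, 1, rng), nn.ReLU(),
        nn.Conv2d(32, feature_dim, 3, 2, 1, rng), nn.ReLU(),
        nn.GlobalAvgPool(),
    )


def build_classifier(rng: np.random.Generator, feature_dim: int = 64) -> nn.Sequential:
    """Two-layer class-prediction head; outputs 2 logits."""
    return nn.Sequential(
        nn.Dense(feature_dim, 32, rng), nn.ReLU(),
        nn.Dense(32, 2, rng),
    )


def build_domain_discriminator(rng: np.random.Generator, feature_dim: int = 64) -> nn.Sequential:
    """Two layers with ReLU and Dropout(0.5); outputs 1 logit."""
    return nn.Sequential(
        nn.Dense(feature_dim, 32, rng), nn.ReLU(), nn.Dropout(0.5, rng),
        nn.Dense(32, 1, rng),
    )


class ResidualGenerator:
    """Encoder-decoder image translator computing x + delta(x), clipped.

    Two stride-2 downsampling blocks, a residual block, two sub-pixel
    upsampling blocks (all convolutions run at or below half
    resolution); the final convolution is zero-initialised so an
    untrained generator is exactly the identity on [0, 1] images.
    Widths and depth are kept small: the translations this stage learns
    are global intensity changes plus small local structures.
    """

    def __init__(self, rng: np.random.Generator):
        self.net = nn.Sequential(
            nn.Conv2d(1, 8, 3, 2, 1, rng), nn.ReLU(),
            nn.Conv2d(8, 16, 3, 2, 1, rng), nn.ReLU(),
            nn.Residual(nn.Conv2d(16, 16, 3, 1, 1, rng), nn.ReLU(),
                        nn.Conv2d(16, 16, 3, 1, 1, rng)),
            nn.Conv2d(16, 32, 3, 1, 1, rng), nn.PixelShuffle2x(), nn.ReLU(),
            nn.Conv2d(8, 4, 3, 1, 1, rng, zero_init=True), nn.PixelShuffle2x(),
        )
        self._pre_stack: list[np.ndarray] = []

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        delta = self.net.forward(x, train=train)
        pre = x + delta
        if train:
            self._pre_stack.append(pre)
        return np.clip(pre, 0.0, 1.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # clip passes gradient only where the pre-activation is interior
        pre = self._pre_stack.pop()
        mask = (pre > 0.0) & (pre < 1.0)
        d = dout * mask
        return d + self.net.backward(d)

    def __call__(self, images: np.ndarray) -> np.ndarray:
        """Eval-mode translation of (N, H, W) images in [0, 1]."""
        x = as_nchw(images)
        out = self.forward(x, train=False)
        return out[:, 0]


def build_patch_discriminator(rng: np.random.Generator) -> nn.Sequential:
    """Patch-style conv discriminator; spatial-mean logit."""
    return nn.Sequential(
        nn.Conv2d(1, 8, 3, 2, 1, rng), nn.ReLU(),
        nn.Conv2d(8, 16, 3, 2, 1, rng), nn.ReLU(),
        nn.Conv2d(16, 1, 3, 1, 1, rng),
        nn.SpatialMean(),
    )
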