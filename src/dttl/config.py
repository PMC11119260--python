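"""Configuration dataclasses, YAML loading and config hashing.

Every stage of the pipeline is driven by a small frozen-ish dataclass with
validated fields; :class:`RunConfig` nests them all and is what the CLI and
``run_dttl`` consume.  Defaults are the desk-scale study conditions: 32x32
grayscale cohorts with a 0.25:1 imbalance ratio and a global
brightness/contrast domain shift.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic two-domain imbalanced cohort.

    The target domain is the source rendering passed through a global
    affine intensity shift (``contrast * x + brightness``) plus pixel
    noise — the kind of acquisition-level shift that separates X-ray
    datasets collected on different devices.
    """

    image_size: int = 32
    n_source_majority: int = 400
    n_source_minority: int = 100
    n_target_majority: int = 400
    n_target_minority: int = 100
    shift_brightness: float = 0.15
    shift_contrast: float = 1.4
    noise_sd: float = 0.05
    lesion_intensity: float = 0.35
    lesion_radius_range: tuple[int, int] = (3, 6)
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        for name in ("n_source_majority", "n_source_minority",
                     "n_target_majority", "n_target_minority"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (-0.5 <= self.shift_brightness <= 0.5):
            raise ValueError("shift_brightness must lie in [-0.5, 0.5]")
        if not (self.shift_contrast > 0 and np.isfinite(self.shift_contrast)):
            raise ValueError("shift_contrast must be a finite positive factor")
        if not (self.noise_sd >= 0 and np.isfinite(self.noise_sd)):
            raise ValueError("noise_sd must be finite and >= 0")
        if not (0 < self.lesion_intensity <= 1):
            raise ValueError("lesion_intensity must lie in (0, 1]")
        lo, hi = self.lesion_radius_range
        self.lesion_radius_range = (int(lo), int(hi))
        if lo < 1 or hi < lo or 2 * hi + 2 > self.image_size:
            raise ValueError("lesion_radius_range must fit inside the image")


@dataclass
class CDAConfig:
    """Adversarial feature-alignment stage (generator F, classifier C,
    domain discriminator D)."""

    lam: float = 0.1               # weight of the target prediction-entropy term
    learning_rate: float = 2e-4
    weight_decay: float = 5e-4
    batch_size: int = 16
    max_epochs: int = 60
    loss_tolerance: float = 5e-4
    feature_dim: int = 64
    arch: str = "conv16-32-64"
    marginal_diversity: float = 0.0  # optional marginal-entropy bonus, off by default
    adversarial_mode: str = "nonsaturating"  # or "literal"
    adv_weight: float = 0.3   # weight of the confusion term in the F update
    adv_ramp_epochs: int = 10  # linear ramp of adv_weight from 0
    seed: int = 0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.adversarial_mode not in ("nonsaturating", "literal"):
            raise ValueError("adversarial_mode must be 'nonsaturating' or 'literal'")


@dataclass
class CMTWeights:
    """Weights of the translation objective's regularisers."""

    lambda_dt: float = 1.0
    lambda_mcc: float = 10.0
    lambda_ide: float = 5.0

    def __post_init__(self):
        if min(self.lambda_dt, self.lambda_mcc, self.lambda_ide) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class CMTConfig:
    weights: CMTWeights = field(default_factory=CMTWeights)
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    batch_size: int = 16
    max_epochs: int = 25
    loss_tolerance: float = 5e-4
    dt_on_source_majority: bool = False
    real_pool: str = "minority"  # discriminator real samples: "minority" subsets or whole "domain"
    generator_mode: str = "nonsaturating"  # or "literal"
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.weights, dict):
            self.weights = CMTWeights(**self.weights)
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.real_pool not in ("domain", "minority"):
            raise ValueError("real_pool must be 'domain' or 'minority'")
        if self.generator_mode not in ("nonsaturating", "literal"):
            raise ValueError("generator_mode must be 'nonsaturating' or 'literal'")


@dataclass
class SelectionConfig:
    """Confidence-based retention of synthesised minority samples.

    Candidates scoring above ``p_max`` are discarded as too far from the
    decision boundary on the minority side.  Candidates scoring below
    ``p_min`` are discarded as too far on the *majority* side: with the
    default ``p_min = 0.5`` a candidate is eligible for the minority
    label only when the classifier's argmax already is minority, which
    keeps the selection consistent with the pseudo-labeling rule.
    ``p_min = 0`` disables the floor, leaving the pure upper-threshold
    rule.
    """

    p_max: float = 0.95
    p_min: float = 0.5
    s: float = 1.0

    def __post_init__(self):
        if not (0 < self.p_max <= 1):
            raise ValueError("p_max must lie in (0, 1]")
        if not (0 <= self.p_min < self.p_max):
            raise ValueError("p_min must lie in [0, p_max)")
        if self.s <= 0:
            raise ValueError("s must be > 0")


@dataclass
class BTLConfig:
    learning_rate: float = 2e-4
    weight_decay: float = 5e-4
    batch_size: int = 16
    max_epochs: int = 15
    loss_tolerance: float = 5e-4
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    data_dir: str | None = None
    cda: CDAConfig = field(default_factory=CDAConfig)
    cmt: CMTConfig = field(default_factory=CMTConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    btl: BTLConfig = field(default_factory=BTLConfig)
    outer_iterations: int = 1
    eval_split: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name, cls in (("synthetic", SyntheticConfig), ("cda", CDAConfig),
                          ("cmt", CMTConfig), ("selection", SelectionConfig),
                          ("btl", BTLConfig)):
            val = getattr(self, name)
            if isinstance(val, dict):
                setattr(self, name, cls(**val))
        if self.synthetic is None and self.data_dir is None:
            raise ValueError("either synthetic cohort parameters or data_dir required")
        if self.outer_iterations < 1:
            raise ValueError("outer_iterations must be >= 1")
        if not (0 < self.eval_split < 1):
            raise ValueError("eval_split must lie in (0, 1)")


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def config_hash(cfg: Any) -> str:
    """Stable short hash of any config dataclass, embedded in artifacts."""
    payload = json.dumps(_to_jsonable(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str) -> RunConfig:
    """Read a YAML run configuration (nested keys mirror RunConfig)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
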