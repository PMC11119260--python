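"""In-memory containers and image-directory IO.

Class encoding is global: 0 = majority ("maj", lesion absent), 1 = minority
("min", lesion present, the positive class).  Images are float32 arrays in
[0, 1]; batches are stacked as (N, H, W).

Target-domain labels are *evaluation-only*: they live in a separate field
(:attr:`CohortPair.target_hidden_labels`) and in the sidecar
``target_manifest.csv`` on disk, and no training operation accepts them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

MAJ, MIN = 0, 1
CLASS_NAMES = {MAJ: "maj", MIN: "min"}
CLASS_IDS = {"maj": MAJ, "min": MIN}


@dataclass
class LabeledImages:
    """A stack of images with per-sample class labels."""

    images: np.ndarray  # (N, H, W) float32 in [0, 1]
    labels: np.ndarray  # (N,) int, values in {MAJ, MIN}

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.shape[0] != self.labels.shape[0]:
            raise ValueError("images and labels must align")

    def __len__(self) -> int:
        return self.images.shape[0]

    def subset(self, idx: np.ndarray) -> "LabeledImages":
        return LabeledImages(self.images[idx], self.labels[idx])


@dataclass
class CohortPair:
    """Labeled source domain plus unlabeled target domain.

    ``target_hidden_labels`` is retained solely for splitting and final
    evaluation; training code receives ``target_images`` only.
    """

    source: LabeledImages
    target_images: np.ndarray
    target_hidden_labels: np.ndarray

    def __post_init__(self):
        self.target_images = np.asarray(self.target_images, dtype=np.float32)
        self.target_hidden_labels = np.asarray(self.target_hidden_labels, dtype=np.int64)


def _to_float01(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:  # RGB(A) -> luminance by channel mean
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype == np.uint8:
        return (arr / 255.0).astype(np.float32)
    if arr.dtype == np.uint16:
        return (arr / 65535.0).astype(np.float32)
    return np.clip(arr.astype(np.float32), 0.0, 1.0)


def _read_dir(path: Path, image_size: int | None) -> tuple[np.ndarray, list[str]]:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
    imgs, names = [], []
    for p in files:
        try:
            arr = _to_float01(iio.imread(p))
        except Exception as exc:  # unreadable file: skip, keep going
            warnings.warn(f"skipping unreadable image {p}: {exc}")
            continue
        if image_size is not None and arr.shape != (image_size, image_size):
            arr = resize(arr, (image_size, image_size), anti_aliasing=True).astype(np.float32)
        imgs.append(arr)
        names.append(p.name)
    if not imgs:
        raise ValueError(f"no readable images in {path}")
    return np.stack(imgs), names


def load_image_dataset(root: str | Path, image_size: int | None = None,
                       require_manifest: bool = False) -> CohortPair:
    """Load the documented layout: ``source/maj``, ``source/min``,
    ``target/unlabeled`` plus optional ``target_manifest.csv``."""
    root = Path(root)
    imgs_maj, _ = _read_dir(root / "source" / "maj", image_size)
    imgs_min, _ = _read_dir(root / "source" / "min", image_size)
    source = LabeledImages(
        np.concatenate([imgs_maj, imgs_min]),
        np.concatenate([np.full(len(imgs_maj), MAJ), np.full(len(imgs_min), MIN)]),
    )
    t_imgs, t_names = _read_dir(root / "target" / "unlabeled", image_size)
    manifest = root / "target_manifest.csv"
    if manifest.exists():
        df = pd.read_csv(manifest).set_index("filename")
        hidden = np.array([CLASS_IDS[df.loc[n, "hidden_label"]] for n in t_names])
    elif require_manifest:
        raise FileNotFoundError(f"evaluation requested but {manifest} is missing")
    else:
        hidden = np.full(len(t_imgs), -1)
    return CohortPair(source, t_imgs, hidden)


def write_cohort(cohort: CohortPair, outdir: str | Path) -> None:
    """Write the directory layout consumed by :func:`load_image_dataset`."""
    outdir = Path(outdir)
    for cls in (MAJ, MIN):
        d = outdir / "source" / CLASS_NAMES[cls]
        d.mkdir(parents=True, exist_ok=True)
        for i in np.flatnonzero(cohort.source.labels == cls):
            _write_png(d / f"{i:05d}.png", cohort.source.images[i])
    td = outdir / "target" / "unlabeled"
    td.mkdir(parents=True, exist_ok=True)
    rows = []
    for j in range(cohort.target_images.shape[0]):
        name = f"{j:05d}.png"
        _write_png(td / name, cohort.target_images[j])
        rows.append({"filename": name,
                     "hidden_label": CLASS_NAMES.get(int(cohort.target_hidden_labels[j]), "na")})
    pd.DataFrame(rows).to_csv(outdir / "target_manifest.csv", index=False)


def _write_png(path: Path, img: np.ndarray) -> None:
    iio.imwrite(path, np.clip(np.rint(img * 255), 0, 255).astype(np.uint8))
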