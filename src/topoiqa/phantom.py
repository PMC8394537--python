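"""Synthetic fundus-like phantoms for offline testing of the pipeline.

A "good" phantom mimics the gross topology of a usable fundus photograph
in grayscale: a bright circular retina disc on a dark camera surround,
containing a dark macula blob, a brighter optic-disc region, branching
dark vessel curves, a scattering of small dark spots (texture detail) and
mild pixel noise.  Under the sublevel filtration this guarantees the
signature features the method keys on — a long-lived hole (the bright
retina enclosed by the dark surround, filled only when the optic-disc
peak enters) and several persistent dark components (macula, vessels,
spots).

A "bad" phantom is a good phantom passed through quality degradations
(Gaussian blur, multiplicative uneven illumination, opaque occluding
patches, contrast compression), with magnitudes drawn so that the two
classes are separable but overlapping rather than trivially distinct.
Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .cubical import GrayImage, ValidationError

__all__ = [
    "PhantomSpec",
    "PhantomStudy",
    "DEGRADATIONS",
    "generate_phantom",
    "generate_study",
    "toy_ring_image",
    "write_study",
]

#: Recognized degradation kinds and the (low, high) default magnitude range
#: each magnitude is drawn from for a "bad" phantom.
DEGRADATIONS: dict[str, tuple[float, float]] = {
    "blur": (1.5, 3.5),  # Gaussian sigma, px
    "uneven_illumination": (0.35, 0.65),  # darkest multiplicative factor
    "occlusion": (1, 3),  # number of opaque patches
    "low_contrast": (0.35, 0.60),  # compression factor toward the mean
}


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one synthetic fundus phantom."""

    size: int = 64
    seed: int = 0
    label: str = "good"
    degradations: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValidationError(f"phantom size must be >= 32, got {self.size}")
        if self.label not in ("good", "bad"):
            raise ValidationError(f"label must be good or bad, got {self.label!r}")
        if self.degradations:
            unknown = set(self.degradations) - set(DEGRADATIONS)
            if unknown:
                raise ValidationError(f"unknown degradations: {sorted(unknown)}")
            if self.label == "good":
                raise ValidationError("good phantoms take no degradations")


@dataclass(frozen=True)
class PhantomStudy:
    """A balanced labeled phantom set with a stratified train/val split."""

    images: tuple[GrayImage, ...]
    labels: tuple[str, ...]
    specs: tuple[PhantomSpec, ...]
    train_idx: np.ndarray
    val_idx: np.ndarray


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float):
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _draw_vessels(canvas: np.ndarray, origin, retina_mask, rng) -> None:
    s = canvas.shape[0]
    n_vessels = rng.integers(4, 7)
    for _ in range(n_vessels):
        angle = rng.uniform(0, 2 * math.pi)
        r, c = float(origin[0]), float(origin[1])
        for _ in range(int(0.6 * s)):
            angle += rng.normal(0.0, 0.25)
            r += math.sin(angle)
            c += math.cos(angle)
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < s and 0 <= ci < s) or not retina_mask[ri, ci]:
                break
            canvas[ri, ci] = 75
            if rng.random() < 0.5 and ci + 1 < s and retina_mask[ri, ci + 1]:
                canvas[ri, ci + 1] = 78


def _good_phantom(size: int, rng: np.random.Generator) -> np.ndarray:
    canvas = np.full((size, size), 12.0)
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    retina_r = 0.44 * size
    retina = _disc_mask((size, size), center, retina_r)
    rr, cc = np.indices((size, size))
    radial = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / retina_r
    canvas[retina] = (170.0 - 25.0 * radial**2)[retina]

    off = 0.16 * size
    side = rng.choice([-1.0, 1.0])
    optic_center = (center[0] + rng.normal(0, 1), center[1] + side * off)
    macula_center = (center[0] + rng.normal(0, 1), center[1] - side * off)
    canvas[_disc_mask((size, size), macula_center, 0.08 * size)] = 55.0
    _draw_vessels(canvas, optic_center, retina, rng)
    # small dark spots: texture detail that survives in sharp images only
    inner = _disc_mask((size, size), center, 0.80 * retina_r)
    free = inner & (canvas > 100)
    choices = np.flatnonzero(free)
    n_spots = rng.integers(10, 15)
    for flat in rng.choice(choices, size=min(n_spots, choices.size), replace=False):
        canvas[np.unravel_index(flat, canvas.shape)] = 60.0
    canvas[_disc_mask((size, size), optic_center, 0.09 * size)] = 235.0
    canvas += rng.normal(0.0, 4.0, canvas.shape)
    return canvas


def _apply_degradations(
    canvas: np.ndarray, degradations: dict[str, float], rng: np.random.Generator
) -> np.ndarray:
    s = canvas.shape[0]
    out = canvas.astype(float)
    if "blur" in degradations:
        out = gaussian_filter(out, sigma=float(degradations["blur"]))
    if "uneven_illumination" in degradations:
        g0 = float(degradations["uneven_illumination"])
        theta = rng.uniform(0, 2 * math.pi)
        rr, cc = np.indices(out.shape)
        proj = (rr * math.sin(theta) + cc * math.cos(theta)) / s
        proj = (proj - proj.min()) / (proj.max() - proj.min())
        out = out * (g0 + (1.0 - g0) * proj)
    if "occlusion" in degradations:
        for _ in range(int(degradations["occlusion"])):
            ctr = (rng.uniform(0.2 * s, 0.8 * s), rng.uniform(0.2 * s, 0.8 * s))
            radius = rng.uniform(0.10 * s, 0.20 * s)
            value = float(rng.choice([10.0, 230.0]))
            out[_disc_mask(out.shape, ctr, radius)] = value
    if "low_contrast" in degradations:
        gamma = float(degradations["low_contrast"])
        mean = out.mean()
        out = (out - mean) * gamma + mean
    return out


def _sample_degradations(rng: np.random.Generator) -> dict[str, float]:
    kinds = list(DEGRADATIONS)
    chosen = rng.choice(kinds, size=rng.integers(1, 4), replace=False)
    out: dict[str, float] = {}
    for kind in chosen:
        lo, hi = DEGRADATIONS[kind]
        if kind == "occlusion":
            out[kind] = int(rng.integers(int(lo), int(hi) + 1))
        else:
            out[kind] = float(rng.uniform(lo, hi))
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, str]:
    """Generate one labeled phantom image, deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    canvas = _good_phantom(spec.size, rng)
    if spec.label == "bad":
        degradations = (
            dict(spec.degradations) if spec.degradations else _sample_degradations(rng)
        )
        canvas = _apply_degradations(canvas, degradations, rng)
    values = np.clip(np.rint(canvas), 0, 255).astype(np.int64)
    return GrayImage(values, depth=256), spec.label


def generate_study(
    n_per_class: int, seed: int = 0, size: int = 64
) -> PhantomStudy:
    """Balanced good/bad phantom set with a stratified 85/15 split.

    The validation subset takes ``ceil(0.15 * n_per_class)`` images per
    class (so 50 per class gives an 84/16 split); membership is a
    deterministic function of ``seed``.
    """
    if n_per_class < 10:
        raise ValidationError("need at least 10 phantoms per class")
    root = np.random.SeedSequence(seed)
    image_seeds = root.generate_state(2 * n_per_class + 1) % (2**31)
    specs, images, labels = [], [], []
    for i in range(2 * n_per_class):
        label = "good" if i < n_per_class else "bad"
        spec = PhantomSpec(size=size, seed=int(image_seeds[i]), label=label)
        img, lab = generate_phantom(spec)
        specs.append(spec)
        images.append(img)
        labels.append(lab)
    n_val = math.ceil(0.15 * n_per_class)
    rng = np.random.default_rng(image_seeds[-1])
    train, val = [], []
    for cls in range(2):
        idx = rng.permutation(n_per_class) + cls * n_per_class
        val.extend(idx[:n_val])
        train.extend(idx[n_val:])
    return PhantomStudy(
        images=tuple(images),
        labels=tuple(labels),
        specs=tuple(specs),
        train_idx=np.sort(np.asarray(train)),
        val_idx=np.sort(np.asarray(val)),
    )


def toy_ring_image() -> GrayImage:
    """The 3x3 toy image whose filtration has one component and one hole.

    A reconstruction (not a published matrix): the minimal 3x3 grid over
    four luminescence levels {1, 2, 3, 4} whose sublevel filtration shows
    a single connected component appearing at level 1 and surviving to
    the end, and a single hole born at level 2 and filled at level 4 —
    the outer ring holds 1, 2, 2, 2, 2, 2, 2, 2 (clockwise from the
    top-left) and the center holds 4.  Stored with depth 5 so that the
    value 4 is representable on the 0-based intensity scale.
    """
    return GrayImage(
        np.array([[1, 2, 2], [2, 4, 2], [2, 2, 2]], dtype=np.int64), depth=5
    )


def write_study(study: PhantomStudy, out_dir: str | os.PathLike) -> Path:
    """Write a study as PNG images plus ``labels.csv`` and ``split.csv``."""
    import pandas as pd
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = []
    for i, (img, lab) in enumerate(zip(study.images, study.labels)):
        image_id = f"phantom_{i:04d}"
        Image.fromarray(img.values.astype(np.uint8), mode="L").save(
            out / f"{image_id}.png"
        )
        ids.append(image_id)
    pd.DataFrame({"image_id": ids, "label": study.labels}).to_csv(
        out / "labels.csv", index=False
    )
    split = np.full(len(ids), "train", dtype=object)
    split[study.val_idx] = "val"
    pd.DataFrame({"image_id": ids, "subset": split}).to_csv(
        out / "split.csv", index=False
    )
    return out
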