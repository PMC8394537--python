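"""Vectorization of persistence diagrams into topological feature vectors.

Seven descriptor families — persistent entropy, bottleneck amplitude,
p-Wasserstein amplitudes (p = 1, 2), persistence landscapes (layers
k = 1, 2 under L1/L2 norms), Betti curves (L1/L2), Gaussian heat surfaces
(sigma = 1.6, 3.2 under L1/L2) and point counts — are evaluated per
homology dimension (H0, H1), giving a fixed 30-element vector per image.

Conventions
-----------
* Bottleneck / Wasserstein features are *amplitudes*: the distance from
  the diagram to the empty diagram, i.e. every point matched to the
  diagonal at L-infinity cost ``(death - birth) / 2``.
* Functional descriptors are sampled on a fixed uniform grid over
  ``[0, depth - 1]`` (``n_bins`` points; the 2-D heat surface uses the
  corresponding square grid) so that features are comparable across
  images; norms are rectangle-rule approximations of the continuous
  Lp norm.
* Persistent entropy uses the natural logarithm and the standard
  negative-sum Shannon form; an empty diagram scores 0 on every
  descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cubical import GrayImage, ValidationError, build_complex
from .homology import PersistenceDiagram, compute_persistence

__all__ = [
    "SampledFunction",
    "SampledSurface",
    "TopoFeatureVector",
    "FEATURE_NAMES",
    "persistent_entropy",
    "bottleneck_amplitude",
    "wasserstein_amplitude",
    "landscape",
    "betti_curve",
    "heat_surface",
    "function_norm",
    "n_points",
    "featurize",
]

#: Default number of sample points for functional descriptors.
DEFAULT_N_BINS = 100

#: Gaussian heat-kernel bandwidths.
DEFAULT_SIGMAS = (1.6, 3.2)

#: Canonical 30 feature names, ordered as the descriptor table reads down
#: its columns.
FEATURE_NAMES: tuple[str, ...] = (
    "pe_h0",
    "pe_h1",
    "bottleneck_h0",
    "bottleneck_h1",
    "wasserstein_p1_h0",
    "wasserstein_p1_h1",
    "wasserstein_p2_h0",
    "wasserstein_p2_h1",
    "landscape_l1_k1_h0",
    "landscape_l1_k1_h1",
    "landscape_l1_k2_h0",
    "landscape_l1_k2_h1",
    "landscape_l2_k1_h0",
    "landscape_l2_k1_h1",
    "landscape_l2_k2_h0",
    "landscape_l2_k2_h1",
    "betticurve_l1_h0",
    "betticurve_l1_h1",
    "betticurve_l2_h0",
    "betticurve_l2_h1",
    "heat_l1_s1.6_h0",
    "heat_l1_s1.6_h1",
    "heat_l1_s3.2_h0",
    "heat_l1_s3.2_h1",
    "heat_l2_s1.6_h0",
    "heat_l2_s1.6_h1",
    "heat_l2_s3.2_h0",
    "heat_l2_s3.2_h1",
    "npoints_h0",
    "npoints_h1",
)


@dataclass(frozen=True)
class SampledFunction:
    """A real function sampled on a uniform, strictly increasing grid."""

    grid: np.ndarray
    values: np.ndarray

    @property
    def spacing(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size > 1 else 1.0


@dataclass(frozen=True)
class SampledSurface:
    """A real function on the plane sampled on a uniform square grid."""

    grid: np.ndarray  # shared x/y sample locations
    values: np.ndarray  # (n, n)

    @property
    def spacing(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size > 1 else 1.0


@dataclass(frozen=True)
class TopoFeatureVector:
    """Ordered 30-element topological descriptor vector for one image."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(FEATURE_NAMES),):
            raise ValidationError(
                f"feature vector must have length {len(FEATURE_NAMES)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("feature vector contains non-finite entries")
        object.__setattr__(self, "values", arr)

    def to_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


def _grid(depth: int, n_bins: int) -> np.ndarray:
    return np.linspace(0.0, depth - 1, n_bins)


def persistent_entropy(dg: PersistenceDiagram) -> float:
    """Shannon entropy (natural log) of normalized bar lifetimes."""
    life = dg.lifetimes()
    life = life[life > 0]
    total = life.sum()
    if life.size == 0 or total == 0:
        return 0.0
    p = life / total
    return float(-np.sum(p * np.log(p))) + 0.0  # avoid -0.0 for one bar


def bottleneck_amplitude(dg: PersistenceDiagram) -> float:
    """L-infinity distance to the empty diagram: max (death - birth) / 2."""
    life = dg.lifetimes()
    return float(life.max() / 2.0) if life.size else 0.0


def wasserstein_amplitude(dg: PersistenceDiagram, p: int) -> float:
    """p-Wasserstein distance to the empty diagram, p in {1, 2}."""
    if p not in (1, 2):
        raise ValidationError(f"p must be 1 or 2, got {p}")
    life = dg.lifetimes() / 2.0
    if life.size == 0:
        return 0.0
    return float(np.sum(life**p) ** (1.0 / p))


def landscape(
    dg: PersistenceDiagram, k: int, n_bins: int = DEFAULT_N_BINS
) -> SampledFunction:
    """k-th persistence landscape sampled on the standard grid.

    Each bar (b, d) contributes the tent function rising from b to the
    apex (d - b)/2 at the midpoint and falling back to 0 at d; the
    landscape is the k-th largest tent value pointwise (0 where fewer
    than k bars cover x).
    """
    if k < 1:
        raise ValidationError(f"layer k must be >= 1, got {k}")
    x = _grid(dg.depth, n_bins)
    b, d = dg.births_deaths()
    if b.size < k:
        return SampledFunction(x, np.zeros_like(x))
    tents = np.minimum(x[None, :] - b[:, None], d[:, None] - x[None, :])
    np.clip(tents, 0.0, None, out=tents)
    if k == 1:
        vals = tents.max(axis=0)
    else:
        part = np.partition(tents, b.size - k, axis=0)
        vals = part[b.size - k, :]
    return SampledFunction(x, vals)


def betti_curve(
    dg: PersistenceDiagram, n_bins: int = DEFAULT_N_BINS
) -> SampledFunction:
    """Number of bars covering each grid point (half-open [b, d);
    essential bars count through the top level inclusive)."""
    x = _grid(dg.depth, n_bins)
    counts = np.zeros_like(x)
    for bar in dg.bars:
        if bar.essential:
            counts += (x >= bar.birth) & (x <= bar.death)
        else:
            counts += (x >= bar.birth) & (x < bar.death)
    return SampledFunction(x, counts)


def heat_surface(
    dg: PersistenceDiagram, sigma: float, n_bins: int = DEFAULT_N_BINS
) -> SampledSurface:
    """Gaussian heat surface of the diagram on the standard square grid.

    A positive Gaussian bump of bandwidth ``sigma`` is placed at each
    (birth, death) point and a negative one at its mirror image (death,
    birth), making the surface antisymmetric across the diagonal.
    """
    if sigma <= 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    x = _grid(dg.depth, n_bins)
    b, d = dg.births_deaths()
    if b.size == 0:
        return SampledSurface(x, np.zeros((n_bins, n_bins)))
    inv = 1.0 / (2.0 * sigma**2)
    # separable: exp(-((x-b)^2+(y-d)^2)/2s^2) = exp(-(x-b)^2/2s^2) * exp(-(y-d)^2/2s^2)
    gx_b = np.exp(-inv * (x[None, :] - b[:, None]) ** 2)
    gx_d = np.exp(-inv * (x[None, :] - d[:, None]) ** 2)
    surface = gx_b.T @ gx_d - gx_d.T @ gx_b  # rows: x(birth axis), cols: y(death axis)
    return SampledSurface(x, surface)


def function_norm(f: "SampledFunction | SampledSurface", p: int) -> float:
    """Rectangle-rule approximation of the continuous Lp norm, p in {1, 2}."""
    if p not in (1, 2):
        raise ValidationError(f"p must be 1 or 2, got {p}")
    vals = np.abs(np.asarray(f.values, dtype=float))
    measure = f.spacing ** vals.ndim
    return float((np.sum(vals**p) * measure) ** (1.0 / p))


def n_points(dg: PersistenceDiagram) -> int:
    """Number of off-diagonal points (stored bars) in the diagram."""
    return len(dg)


def featurize(
    img: GrayImage,
    n_bins: int = DEFAULT_N_BINS,
    sigmas: tuple[float, float] = DEFAULT_SIGMAS,
    method: str = "union_find",
) -> TopoFeatureVector:
    """Run the full topological pipeline on one image.

    Image -> filtered cubical complex -> persistence diagram -> 30-element
    descriptor vector, with every functional descriptor evaluated per
    homology dimension.  Deterministic.
    """
    dg = compute_persistence(build_complex(img), method=method)
    return featurize_diagram(dg, n_bins=n_bins, sigmas=sigmas)


def featurize_diagram(
    dg: PersistenceDiagram,
    n_bins: int = DEFAULT_N_BINS,
    sigmas: tuple[float, float] = DEFAULT_SIGMAS,
) -> TopoFeatureVector:
    """Assemble the 30-feature vector from a (mixed-dimension) diagram."""
    subs = [dg.in_dimension(0), dg.in_dimension(1)]
    feats: list[float] = []
    feats += [persistent_entropy(s) for s in subs]
    feats += [bottleneck_amplitude(s) for s in subs]
    for p in (1, 2):
        feats += [wasserstein_amplitude(s, p) for s in subs]
    for norm_p in (1, 2):
        for k in (1, 2):
            feats += [
                function_norm(landscape(s, k, n_bins), norm_p) for s in subs
            ]
    for norm_p in (1, 2):
        feats += [function_norm(betti_curve(s, n_bins), norm_p) for s in subs]
    for norm_p in (1, 2):
        for sigma in sigmas:
            feats += [
                function_norm(heat_surface(s, sigma, n_bins), norm_p) for s in subs
            ]
    feats += [float(n_points(s)) for s in subs]
    return TopoFeatureVector(np.asarray(feats))
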