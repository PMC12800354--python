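"""Tissue detection, tessellation and the three ROI protocols.

A slide is reduced to its tissue pixels by Otsu thresholding on the grey
channel mean (background is assumed bright), then exhaustively split into
non-overlapping ``patch_size`` x ``patch_size`` windows on the regular grid
anchored at pixel (0, 0); clipped margins are discarded, never padded.

Three region-of-interest protocols decide which tissue tiles feed the
models:

* ``none``   -- every tissue tile is kept;
* ``mask``   -- only tiles overlapping a tumour annotation mask (the
  stand-in for an expert pathologist's exhaustive annotation);
* ``learned`` -- tiles kept by a logistic tumour/non-tumour tile classifier
  trained on a small labelled tile sample (3,000 tiles by default).

Both filters are restrictions of the tissue grid: keep[mask] and
keep[learned] are always subsets of keep[none].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

PROTOCOLS = ("none", "mask", "learned")


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two occupied grey levels; no threshold exists."""


class PreprocError(ValueError):
    """Invalid input to a preprocessing operation."""


@dataclass
class TissueMask:
    mask: np.ndarray  # H x W bool
    threshold: int  # grey level; tissue = grey < threshold
    method: str = "otsu"


@dataclass
class PatchGrid:
    """Exhaustive regular tessellation of one slide.

    ``coords`` lists every full grid cell (x, y upper-left corners, windows
    half-open); ``tissue_fraction`` is recorded for all cells; ``keep`` holds
    one boolean vector per ROI protocol.
    """

    patch_size: int
    image_shape: tuple[int, int]  # (H, W)
    coords: np.ndarray  # n x 2 of (x, y)
    tissue_fraction: np.ndarray  # n floats in [0, 1]
    keep: dict[str, np.ndarray] = field(default_factory=dict)

    def kept_coords(self, protocol: str = "none") -> np.ndarray:
        if protocol not in self.keep:
            raise PreprocError(f"protocol {protocol!r} not computed on this grid")
        return self.coords[self.keep[protocol]]

    def n_kept(self, protocol: str = "none") -> int:
        return int(self.keep[protocol].sum())


@dataclass
class TileFilterModel:
    """Logistic tumour/non-tumour tile classifier (the learned ROI filter)."""

    weights: np.ndarray
    bias: float
    threshold: float = 0.5
    training_size: int = 3000

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        z = features @ self.weights + self.bias
        return 1.0 / (1.0 + np.exp(-z))


def otsu_threshold(histogram: np.ndarray) -> int:
    """Grey level maximizing between-class variance; lowest level on ties.

    A threshold ``t`` splits levels into [0, t) and [t, 256); tissue is the
    darker class, so pixels strictly below ``t`` are tissue.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.shape != (256,) or np.any(hist < 0):
        raise PreprocError("histogram must be 256 non-negative counts")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("histogram occupies fewer than two levels")
    p = hist / hist.sum()
    levels = np.arange(256)
    omega = np.cumsum(p)  # P(level < t) evaluated at t-1
    mu = np.cumsum(p * levels)
    mu_total = mu[-1]
    w0 = omega[:-1]  # class weight for t = 1..255
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(255)
    num = (mu_total * w0 - mu[:-1]) ** 2
    sigma_b[valid] = num[valid] / (w0[valid] * w1[valid])
    # lowest maximizing level; plateaus are flat in exact arithmetic, so
    # ties are resolved within a relative float tolerance
    best = sigma_b.max()
    tol = 1e-9 * max(best, 1.0)
    return int(np.flatnonzero(sigma_b >= best - tol)[0]) + 1


def tissue_mask(image: np.ndarray) -> TissueMask:
    """Otsu tissue detection on the unweighted channel-mean grey image."""
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise PreprocError("expected a non-empty H x W x 3 image")
    grey = np.clip(np.rint(image.astype(float).mean(axis=2)), 0, 255).astype(np.uint8)
    hist = np.bincount(grey.ravel(), minlength=256)
    t = otsu_threshold(hist)
    return TissueMask(mask=grey < t, threshold=t)


def tessellate(
    tissue: TissueMask | np.ndarray,
    patch_size: int = 224,
    min_tissue_fraction: float = 0.5,
) -> PatchGrid:
    """Enumerate the non-overlapping grid; keep cells with enough tissue.

    Grid origin is pixel (0, 0), row-major; partial cells at the right and
    bottom margins are clipped (no padding).  ``keep['none']`` marks cells
    with tissue_fraction >= ``min_tissue_fraction``.
    """
    mask = tissue.mask if isinstance(tissue, TissueMask) else np.asarray(tissue)
    h, w = mask.shape
    if patch_size > h or patch_size > w:
        raise PreprocError(
            f"patch_size {patch_size} exceeds image dimensions {(h, w)}"
        )
    coords = []
    fractions = []
    for y in range(0, h - patch_size + 1, patch_size):
        for x in range(0, w - patch_size + 1, patch_size):
            coords.append((x, y))
            fractions.append(
                mask[y : y + patch_size, x : x + patch_size].mean()
            )
    coords_arr = np.asarray(coords, dtype=int)
    frac_arr = np.asarray(fractions, dtype=float)
    return PatchGrid(
        patch_size=patch_size,
        image_shape=(h, w),
        coords=coords_arr,
        tissue_fraction=frac_arr,
        keep={"none": frac_arr >= min_tissue_fraction},
    )


def apply_mask_filter(
    grid: PatchGrid,
    tumour_mask: np.ndarray,
    min_tumour_fraction: float = 0.5,
) -> PatchGrid:
    """Mark ``keep['mask']``: tissue tiles with enough annotated tumour."""
    tumour_mask = np.asarray(tumour_mask).astype(bool)
    if tumour_mask.shape != grid.image_shape:
        raise PreprocError(
            f"tumour mask shape {tumour_mask.shape} != image shape {grid.image_shape}"
        )
    ps = grid.patch_size
    frac = np.array(
        [tumour_mask[y : y + ps, x : x + ps].mean() for x, y in grid.coords]
    )
    grid.keep["mask"] = grid.keep["none"] & (frac >= min_tumour_fraction)
    return grid


def train_tile_filter(
    features: np.ndarray,
    labels: np.ndarray,
    training_size: int = 3000,
    threshold: float = 0.5,
    C: float = 1.0,
    seed: int = 0,
) -> TileFilterModel:
    """Fit the learned ROI filter on labelled tile features.

    If more than ``training_size`` labelled tiles are supplied, a random
    subset of that size is used, mirroring a fixed annotation budget.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    if features.shape[0] != labels.shape[0]:
        raise PreprocError("features and labels are misaligned")
    if len(np.unique(labels)) < 2:
        raise PreprocError("tile filter training needs both classes")
    if not 0.0 < threshold < 1.0:
        raise PreprocError("threshold must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if features.shape[0] > training_size:
        idx = rng.choice(features.shape[0], training_size, replace=False)
        features, labels = features[idx], labels[idx]
        if len(np.unique(labels)) < 2:
            raise PreprocError("subsampled training set lost a class")
    clf = LogisticRegression(C=C, max_iter=10_000)  # default penalty: L2
    clf.fit(features, labels)
    return TileFilterModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        threshold=threshold,
        training_size=min(training_size, features.shape[0]),
    )


def apply_learned_filter(
    grid: PatchGrid,
    model: TileFilterModel,
    features: np.ndarray,
) -> PatchGrid:
    """Mark ``keep['learned']`` from per-tile tumour probabilities.

    ``features`` must align row-for-row with the tissue-kept tiles
    (``grid.kept_coords('none')``).
    """
    features = np.asarray(features, dtype=float)
    n_tissue = grid.n_kept("none")
    if features.shape[0] != n_tissue:
        raise PreprocError(
            f"got {features.shape[0]} feature rows for {n_tissue} tissue tiles"
        )
    keep = np.zeros(len(grid.coords), dtype=bool)
    if n_tissue:
        proba = model.predict_proba(features)
        keep[np.flatnonzero(grid.keep["none"])] = proba >= model.threshold
    grid.keep["learned"] = keep
    return grid


def extract_patches(
    image: np.ndarray, grid: PatchGrid, protocol: str = "none"
) -> np.ndarray:
    """Stack the kept patches of one protocol into an (n, ps, ps, 3) array."""
    ps = grid.patch_size
    coords = grid.kept_coords(protocol)
    if len(coords) == 0:
        raise PreprocError(f"no patches kept under protocol {protocol!r}")
    return np.stack([image[y : y + ps, x : x + ps] for x, y in coords])
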