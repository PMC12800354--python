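"""Deterministic tile featurization and view-ensembled slide embeddings.

Each tile is summarized by a fixed 64-dimensional handcrafted descriptor:

* per-channel mean and standard deviation (6),
* 8-bin per-channel intensity histograms (24),
* 8-bin gradient-magnitude histogram (8),
* 26 grey-level co-occurrence summaries (6 Haralick-style properties at 4
  offsets, plus co-occurrence entropy and grey-level entropy).

The descriptor is deterministic and independent of the tile's position on
the slide.  A slide is represented the way view-ensembled self-supervised
slide encoders expose theirs: many randomized *views* (random tile subsets
with per-tile dihedral augmentation) are each mean-pooled, the view
embeddings are averaged, and the result is L2-normalized to unit norm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix, graycoprops

FEATURE_DIM = 64
_GLCM_LEVELS = 32
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
_GLCM_PROPS = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "ASM",
    "energy",
    "correlation",
)
N_DIHEDRAL = 8


class EmptySlideError(ValueError):
    """No tiles available to embed."""


class NormalizationError(ValueError):
    """Slide vector vanished; cannot be normalized to unit norm."""


@dataclass
class SlideEmbedding:
    """Unit-norm vector summarizing one slide."""

    vector: np.ndarray
    n_views: int


def apply_dihedral(patch: np.ndarray, index: int) -> np.ndarray:
    """One of the 8 square symmetries: rotations 0-3, then mirrored rotations."""
    if not 0 <= index < N_DIHEDRAL:
        raise ValueError(f"dihedral index must be in [0, 8), got {index}")
    out = patch if index < 4 else patch[:, ::-1]
    return np.rot90(out, k=index % 4)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def featurize_tile(patch: np.ndarray) -> np.ndarray:
    """64-dimensional deterministic descriptor of one square RGB tile."""
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"expected a square H x H x 3 patch, got {patch.shape}")
    x = patch.astype(float) / 255.0

    moments = np.concatenate([x.mean(axis=(0, 1)), x.std(axis=(0, 1))])

    chan_hists = [
        np.histogram(x[..., c], bins=8, range=(0.0, 1.0))[0] for c in range(3)
    ]
    chan_hists = np.concatenate([h / h.sum() for h in chan_hists])

    grey = x.mean(axis=2)
    gy, gx = np.gradient(grey)
    gmag = np.hypot(gx, gy)
    ghist = np.histogram(gmag, bins=8, range=(0.0, 0.5))[0].astype(float)
    ghist /= ghist.sum()

    q = (grey * (_GLCM_LEVELS - 1)).round().astype(np.uint8)
    glcm = graycomatrix(
        q,
        distances=[1],
        angles=list(_GLCM_ANGLES),
        levels=_GLCM_LEVELS,
        symmetric=True,
        normed=True,
    )
    cooc = []
    for prop in _GLCM_PROPS:
        vals = graycoprops(glcm, prop)[0]
        if prop == "contrast":
            vals = vals / (_GLCM_LEVELS - 1) ** 2
        elif prop == "dissimilarity":
            vals = vals / (_GLCM_LEVELS - 1)
        cooc.extend(vals)
    cooc.append(_entropy(glcm[:, :, 0, :].mean(axis=2).ravel()))
    level_hist = np.bincount(q.ravel(), minlength=_GLCM_LEVELS).astype(float)
    cooc.append(_entropy(level_hist / level_hist.sum()))

    vec = np.concatenate([moments, chan_hists, ghist, np.asarray(cooc)])
    vec = np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0)
    assert vec.shape == (FEATURE_DIM,)
    return vec


def sample_view(
    n_tiles: int,
    fraction: float,
    rng: np.random.Generator,
    augment: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one view: ceil(fraction * n) tiles without replacement, plus a
    random dihedral transform per tile (identity when ``augment`` is off)."""
    if n_tiles < 1:
        raise EmptySlideError("cannot sample a view from an empty tile set")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("view fraction must lie in (0, 1]")
    m = math.ceil(fraction * n_tiles)
    indices = rng.choice(n_tiles, size=m, replace=False)
    transforms = (
        rng.integers(0, N_DIHEDRAL, size=m) if augment else np.zeros(m, dtype=int)
    )
    return indices, transforms


def slide_embedding(views: list[np.ndarray]) -> SlideEmbedding:
    """Ensemble view embeddings into one unit-norm slide vector.

    Each view is an (n_i, D) array of tile features; a view's embedding is
    the mean of its tile features, the slide vector is the mean over views,
    L2-normalized.
    """
    if len(views) == 0:
        raise EmptySlideError("need at least one view")
    means = []
    for v in views:
        v = np.asarray(v, dtype=float)
        if v.ndim != 2 or v.shape[0] == 0:
            raise EmptySlideError("each view must be a non-empty (n, D) array")
        means.append(v.mean(axis=0))
    vec = np.mean(means, axis=0)
    norm = np.linalg.norm(vec)
    if norm == 0:
        raise NormalizationError("slide vector has zero norm")
    return SlideEmbedding(vector=vec / norm, n_views=len(views))


class TileFeaturizer:
    """Caches dihedral-transformed tile features for one slide.

    Views only ever request (tile, transform) pairs, so at most
    ``8 * n_tiles`` featurizations happen per slide regardless of the
    number of views.
    """

    def __init__(self, patches: np.ndarray):
        self.patches = np.asarray(patches)
        if self.patches.ndim != 4 or self.patches.shape[0] == 0:
            raise EmptySlideError("need a non-empty (n, ps, ps, 3) patch stack")
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    @property
    def n_tiles(self) -> int:
        return self.patches.shape[0]

    def feature(self, index: int, transform: int = 0) -> np.ndarray:
        key = (int(index), int(transform))
        if key not in self._cache:
            self._cache[key] = featurize_tile(
                apply_dihedral(self.patches[index], transform)
            )
        return self._cache[key]

    def view_features(
        self, indices: np.ndarray, transforms: np.ndarray
    ) -> np.ndarray:
        return np.stack(
            [self.feature(i, t) for i, t in zip(indices, transforms)]
        )


def embed_slide(
    patches: np.ndarray,
    n_views: int = 100,
    view_fraction: float = 0.25,
    rng: np.random.Generator | int | None = 0,
    augment: bool = True,
) -> SlideEmbedding:
    """Full slide representation: sample views, pool, ensemble, normalize."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    feat = TileFeaturizer(patches)
    views = []
    for _ in range(n_views):
        idx, tr = sample_view(feat.n_tiles, view_fraction, rng, augment=augment)
        views.append(feat.view_features(idx, tr))
    return slide_embedding(views)
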