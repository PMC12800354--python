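"""Synthetic multi-modal iCCA cohort generator.

Emulates the statistical structure the downstream pipeline assumes, so every
module is testable without any external download:

* multi-slide patients drawn from the five transcriptomic classes, with
  class-conditional tumour texture and a shared, class-independent non-tumour
  tissue motif painted on a near-white background;
* class-structured expression counts (log-normal, rounded) with dropout and
  five disjoint class signatures;
* class-dependent exponential survival with independent censoring;
* a clinical covariate table.

The texture vocabulary mirrors the histological correlates of the classes
qualitatively: dense basophilic dots for immune infiltration, elongated
streaks for fibrotic stroma, and a pale cell-poor hue for the desert-like
class.  ``texture_effect`` scales every class-specific deviation from the
shared base texture, so 0 means the tumour texture carries no class signal
at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import line as draw_line

from histotx.rna import CLASSES, ExpressionMatrix, GeneSignatureSet


class ConfigError(ValueError):
    """Raised for invalid cohort configurations."""


#: A slide whose tissue covers at least this fraction of the canvas is
#: plausibly surgical; biopsy strips are painted strictly smaller.
SURGICAL_MIN_TISSUE_FRACTION = 0.30

# Shared base texture (all classes at texture_effect = 0).
_BACKGROUND_LEVEL = 246
_NONTUMOUR_RGB = np.array([205.0, 170.0, 190.0])
_TUMOUR_RGB = np.array([185.0, 150.0, 175.0])
_BASE_DOT_DENSITY = 0.004
_BASE_STREAK_DENSITY = 0.004
# Tumour tissue carries a fine-grained, class-independent micro-texture
# (higher pixel variance) that statistically distinguishes tumour from
# stroma at the tile level.  The per-slide noise scales are drawn from
# *overlapping* ranges, so tile-level tumour-ness is an imperfect cue:
# learnable well from a few thousand labelled tiles, but only partially
# recoverable from bag-level labels alone.
_TUMOUR_PIXEL_NOISE_RANGE = (8.0, 14.0)
_NT_PIXEL_NOISE_RANGE = (6.0, 13.0)
_SLIDE_JITTER = 10.0  # slide-level staining variation, uniform per channel
# Within-class biological heterogeneity: each slide's tumour deviates from
# its class's canonical texture (hue and motif densities), so the class
# signal-to-noise at slide level is bounded even with many tiles -- the
# regime in which ROI filtering visibly matters.
_TUMOUR_SLIDE_JITTER = 12.0
_TUMOUR_DOT_JITTER = 0.005
_TUMOUR_STREAK_JITTER = 0.005
# The non-tumour compartment is class-independent but heterogeneous across
# slides: its hue and motif densities are drawn per slide, and on a fraction
# of slides it mimics the tumour palette of a *random* class (normal
# parenchyma resembling hepatic stem-like tumour, stroma resembling the
# fibrotic classes).  This confounds weakly-supervised models unless
# non-tumour tiles are filtered out.
_NT_SLIDE_JITTER = 18.0
_NT_MIMIC_PROB = 0.6
_NT_MIMIC_JITTER = 6.0
_NT_MAX_DOT_DENSITY = 0.015
_NT_MAX_STREAK_DENSITY = 0.015

# Class-specific texture offsets, scaled by texture_effect.
_COLOUR_OFFSET = {
    "hepatic_stem_like": np.array([12.0, -8.0, -6.0]),
    "tumour_classical": np.array([-14.0, 6.0, 4.0]),
    "inflammatory_stroma": np.array([-4.0, -14.0, 8.0]),
    "immune_classical": np.array([-10.0, -4.0, -12.0]),
    "desert_like": np.array([16.0, 12.0, 10.0]),
}
_DOT_OFFSET = {
    "hepatic_stem_like": -0.003,
    "tumour_classical": 0.0,
    "inflammatory_stroma": 0.008,
    "immune_classical": 0.016,
    "desert_like": -0.003,
}
_STREAK_OFFSET = {
    "hepatic_stem_like": 0.0,
    "tumour_classical": 0.004,
    "inflammatory_stroma": 0.012,
    "immune_classical": 0.0,
    "desert_like": -0.004,
}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    Default class prevalences follow the discovery-cohort structure (37%
    hepatic stem-like, 4% desert-like, remaining mass split across the other
    three classes); slides per surgical patient are uniform on [1, 5];
    survival medians (months) decrease from hepatic stem-like to the
    tumour-classical class, matching the direction of the reported contrasts.
    """

    n_patients: int = 60
    class_prevalences: tuple[float, ...] = (0.37, 0.13, 0.21, 0.25, 0.04)
    slides_per_patient_range: tuple[int, int] = (1, 5)
    biopsy_fraction: float = 0.3
    image_size: int = 448
    tumour_fraction_range: tuple[float, float] = (0.3, 0.6)
    texture_effect: float = 1.0
    n_genes: int = 2000
    signature_size: int = 50
    expression_effect: float = 1.0
    dropout_rate: float = 0.2
    # per-class exponential hazards (1/month); medians ~ (49, 21, 31, 43, 43)
    hazard_by_class: tuple[float, ...] = (
        math.log(2) / 49,
        math.log(2) / 21,
        math.log(2) / 31,
        math.log(2) / 43,
        math.log(2) / 43,
    )
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p = np.asarray(self.class_prevalences, dtype=float)
        if p.size != len(CLASSES):
            raise ConfigError(f"need {len(CLASSES)} class prevalences, got {p.size}")
        if np.any(p < 0) or np.any(p > 1):
            raise ConfigError("class prevalences must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError(f"class prevalences sum to {p.sum()}, expected 1")
        lo, hi = self.slides_per_patient_range
        if lo < 1 or hi < lo:
            raise ConfigError("slides_per_patient_range lower bound must be >= 1")
        h = np.asarray(self.hazard_by_class, dtype=float)
        if h.size != len(CLASSES) or np.any(h <= 0):
            raise ConfigError("all class hazards must be positive")
        for name in ("biopsy_fraction", "dropout_rate", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")
        if self.texture_effect < 0 or self.expression_effect < 0:
            raise ConfigError("effect sizes must be non-negative")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.image_size < 32:
            raise ConfigError("image_size too small to paint tissue")


@dataclass
class SlideRecord:
    """One synthetic slide with its ground-truth tumour mask."""

    slide_id: str
    patient_id: str
    image: np.ndarray  # H x W x 3, uint8
    tumour_mask: np.ndarray | None  # H x W, bool
    sample_type: str  # "biopsy" | "surgical"
    rna_linked: str  # "RNA+" | "RNA-"
    true_class: str


@dataclass
class SyntheticCohort:
    slides: list[SlideRecord]
    expression: ExpressionMatrix
    signatures: GeneSignatureSet
    survival: pd.DataFrame  # patient_id, time_months, event
    clinical: pd.DataFrame  # patient_id, true_class, sample_type, age, sex

    def patient_classes(self) -> pd.Series:
        return self.clinical.set_index("patient_id")["true_class"]


def _tissue_region(rng: np.random.Generator, size: int, biopsy: bool) -> np.ndarray:
    """Boolean tissue mask: large ellipse for surgical, narrow strip for biopsy."""
    yy, xx = np.mgrid[0:size, 0:size]
    if biopsy:
        # wide enough that a strip split across two grid columns still
        # leaves at least one tile majority-tissue at patch sizes <= size/4
        width = 0.30 * size
        cx = rng.uniform(0.3, 0.7) * size
        top, bot = 0.12 * size, 0.88 * size
        mask = (np.abs(xx - cx) < width / 2) & (yy > top) & (yy < bot)
    else:
        a = rng.uniform(0.40, 0.46) * size
        b = rng.uniform(0.40, 0.46) * size
        cy = size / 2 + rng.uniform(-0.03, 0.03) * size
        cx = size / 2 + rng.uniform(-0.03, 0.03) * size
        mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    return mask


def _tumour_region(
    rng: np.random.Generator, tissue: np.ndarray, fraction: float
) -> np.ndarray:
    """Disc inside the tissue covering ~``fraction`` of the tissue area."""
    size = tissue.shape[0]
    ys, xs = np.nonzero(tissue)
    cy, cx = ys.mean(), xs.mean()
    cy += rng.uniform(-0.05, 0.05) * size
    cx += rng.uniform(-0.05, 0.05) * size
    yy, xx = np.mgrid[0 : tissue.shape[0], 0 : tissue.shape[1]]
    dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
    target = fraction * tissue.sum()
    lo, hi = 1.0, float(size)
    for _ in range(40):  # bisection on the radius
        mid = 0.5 * (lo + hi)
        area = np.count_nonzero(tissue & (dist2 <= mid**2))
        if area < target:
            lo = mid
        else:
            hi = mid
    return tissue & (dist2 <= hi**2)


def _scatter_dots(
    rng: np.random.Generator,
    image: np.ndarray,
    region: np.ndarray,
    density: float,
    colour: np.ndarray,
) -> None:
    seeds = (rng.random(region.shape) < density) & region
    dots = seeds.copy()
    dots[1:, :] |= seeds[:-1, :]
    dots[:, 1:] |= seeds[:, :-1]
    dots[1:, 1:] |= seeds[:-1, :-1]
    dots &= region
    image[dots] = colour


def _draw_streaks(
    rng: np.random.Generator,
    image: np.ndarray,
    region: np.ndarray,
    density: float,
    colour: np.ndarray,
) -> None:
    n = int(round(density * region.sum() / 40.0))
    if n <= 0:
        return
    ys, xs = np.nonzero(region)
    size = region.shape[0]
    for _ in range(n):
        k = rng.integers(len(ys))
        y0, x0 = int(ys[k]), int(xs[k])
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(25, 50)
        y1 = int(np.clip(y0 + length * np.sin(ang), 0, size - 1))
        x1 = int(np.clip(x0 + length * np.cos(ang), 0, size - 1))
        rr, cc = draw_line(y0, x0, y1, x1)
        for dy in (0, 1):
            r = np.clip(rr + dy, 0, size - 1)
            inside = region[r, cc]
            image[r[inside], cc[inside]] = colour


def paint_slide(
    rng: np.random.Generator,
    config: CohortConfig,
    true_class: str,
    biopsy: bool,
    tumour_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint one slide; returns (uint8 image, boolean tumour mask).

    The tumour mask records the painted tumour region pixel-for-pixel.
    """
    size = config.image_size
    e = config.texture_effect
    img = np.empty((size, size, 3), dtype=float)
    img[:] = _BACKGROUND_LEVEL + rng.normal(0, 2.0, (size, size, 1))

    tissue = _tissue_region(rng, size, biopsy)
    tumour = _tumour_region(rng, tissue, tumour_fraction)
    nontumour = tissue & ~tumour

    jitter = rng.uniform(-_SLIDE_JITTER, _SLIDE_JITTER, 3)

    # Per-slide non-tumour appearance: either a neutral stromal hue with its
    # own slide-level jitter, or (mimic mode) the full tumour palette -- hue
    # and motif densities -- of a *random* class, drawn independently of
    # this slide's true class.  Only the micro-texture scale (pixel noise)
    # statistically separates mimicking stroma from tumour.
    mimic_cls: str | None = None
    if rng.random() < _NT_MIMIC_PROB:
        mimic_cls = CLASSES[int(rng.integers(len(CLASSES)))]
        nt_col = (
            _TUMOUR_RGB
            + jitter
            + e * _COLOUR_OFFSET[mimic_cls]
            + rng.uniform(-_NT_MIMIC_JITTER, _NT_MIMIC_JITTER, 3)
        )
    else:
        nt_col = (
            _NONTUMOUR_RGB
            + jitter
            + rng.uniform(-_NT_SLIDE_JITTER, _NT_SLIDE_JITTER, 3)
        )
    nt_sd = rng.uniform(*_NT_PIXEL_NOISE_RANGE)
    img[nontumour] = nt_col + rng.normal(0, nt_sd, (nontumour.sum(), 3))

    tum_col = (
        _TUMOUR_RGB
        + jitter
        + e * _COLOUR_OFFSET[true_class]
        + rng.uniform(-_TUMOUR_SLIDE_JITTER, _TUMOUR_SLIDE_JITTER, 3)
    )
    tum_sd = rng.uniform(*_TUMOUR_PIXEL_NOISE_RANGE)
    img[tumour] = tum_col + rng.normal(0, tum_sd, (tumour.sum(), 3))

    if mimic_cls is not None:
        nt_dots = max(0.0, _BASE_DOT_DENSITY + e * _DOT_OFFSET[mimic_cls])
        nt_streaks = max(0.0, _BASE_STREAK_DENSITY + e * _STREAK_OFFSET[mimic_cls])
    else:
        nt_dots = rng.uniform(0.0, _NT_MAX_DOT_DENSITY)
        nt_streaks = rng.uniform(0.0, _NT_MAX_STREAK_DENSITY)
    _scatter_dots(rng, img, nontumour, nt_dots, np.array([70.0, 50.0, 100.0]))
    _draw_streaks(rng, img, nontumour, nt_streaks, np.array([150.0, 120.0, 160.0]))

    dot_density = max(
        0.0,
        _BASE_DOT_DENSITY
        + e * _DOT_OFFSET[true_class]
        + rng.uniform(-_TUMOUR_DOT_JITTER, _TUMOUR_DOT_JITTER),
    )
    streak_density = max(
        0.0,
        _BASE_STREAK_DENSITY
        + e * _STREAK_OFFSET[true_class]
        + rng.uniform(-_TUMOUR_STREAK_JITTER, _TUMOUR_STREAK_JITTER),
    )
    _scatter_dots(rng, img, tumour, dot_density, np.array([70.0, 50.0, 100.0]))
    _draw_streaks(rng, img, tumour, streak_density, np.array([150.0, 120.0, 160.0]))

    return np.clip(img, 0, 255).astype(np.uint8), tumour


def simulate_expression(
    config: CohortConfig,
    classes: pd.Series,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, GeneSignatureSet]:
    """Class-structured log-normal-rounded counts with dropout.

    ``classes`` maps patient id -> class name; each patient contributes one
    RNA+ sample.  Five disjoint signatures of ``signature_size`` genes are
    planted; a class-k sample has its class-k signature genes shifted upward
    by ``expression_effect`` on the log scale.
    """
    if config.n_genes < 5 * config.signature_size:
        raise ConfigError(
            "n_genes must be >= 5 * signature_size for disjoint signatures"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    classes = pd.Series(classes)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    s = config.signature_size
    sig_sets = {
        cls: gene_ids[k * s : (k + 1) * s] for k, cls in enumerate(CLASSES)
    }
    signatures = GeneSignatureSet(
        sig_sets, {cls: "synthetic class signature" for cls in CLASSES}
    )

    mu = rng.uniform(1.0, 4.0, config.n_genes)
    log_vals = rng.normal(
        mu[:, None], 1.0, (config.n_genes, len(classes))
    )
    for j, cls in enumerate(classes.to_numpy()):
        k = CLASSES.index(cls)
        log_vals[k * s : (k + 1) * s, j] += config.expression_effect
    counts = np.rint(np.exp(log_vals))
    if config.dropout_rate > 0:
        counts[rng.random(counts.shape) < config.dropout_rate] = 0.0
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=list(classes.index))
    )
    return expr, signatures


def simulate_survival(
    classes: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential event times with class hazards and independent censoring.

    Censoring is exponential with the rate chosen so that the marginal
    probability of censoring before the event equals ``censor_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    classes = pd.Series(classes)
    hazards = dict(zip(CLASSES, config.hazard_by_class))
    times = np.empty(len(classes))
    events = np.empty(len(classes), dtype=int)
    for j, cls in enumerate(classes.to_numpy()):
        lam = hazards[cls]
        t_event = rng.exponential(1.0 / lam)
        if config.censor_rate >= 1.0:
            times[j], events[j] = t_event, 0
        elif config.censor_rate <= 0.0:
            times[j], events[j] = t_event, 1
        else:
            lam_c = lam * config.censor_rate / (1.0 - config.censor_rate)
            t_cens = rng.exponential(1.0 / lam_c)
            times[j] = min(t_event, t_cens)
            events[j] = int(t_event <= t_cens)
    return pd.DataFrame(
        {
            "patient_id": list(classes.index),
            "time_months": times,
            "event": events,
        }
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    prev = np.asarray(config.class_prevalences, dtype=float)

    patient_ids = [f"P{i:04d}" for i in range(config.n_patients)]
    classes = rng.choice(len(CLASSES), size=config.n_patients, p=prev)
    class_names = [CLASSES[k] for k in classes]

    lo, hi = config.slides_per_patient_range
    slides: list[SlideRecord] = []
    sample_types = []
    for pid, cls in zip(patient_ids, class_names):
        biopsy = rng.random() < config.biopsy_fraction
        n_slides = 1 if biopsy else int(rng.integers(lo, hi + 1))
        sample_types.append("biopsy" if biopsy else "surgical")
        for s in range(n_slides):
            frac = rng.uniform(*config.tumour_fraction_range)
            img, mask = paint_slide(rng, config, cls, biopsy, frac)
            slides.append(
                SlideRecord(
                    slide_id=f"{pid}_S{s}",
                    patient_id=pid,
                    image=img,
                    tumour_mask=mask,
                    sample_type="biopsy" if biopsy else "surgical",
                    rna_linked="RNA+" if s == 0 else "RNA-",
                    true_class=cls,
                )
            )

    class_series = pd.Series(class_names, index=patient_ids)
    expr, signatures = simulate_expression(config, class_series, rng)
    survival = simulate_survival(class_series, config, rng)

    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "true_class": class_names,
            "sample_type": sample_types,
            "age": np.clip(rng.normal(63, 10, config.n_patients), 27, 88).round(0),
            "sex": rng.choice(["M", "F"], config.n_patients, p=[0.57, 0.43]),
        }
    )
    return SyntheticCohort(slides, expr, signatures, survival, clinical)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write a cohort to disk in plain formats (PNG/TSV/GMT/CSV)."""
    out = Path(outdir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for rec in cohort.slides:
        Image.fromarray(rec.image).save(out / "slides" / f"{rec.slide_id}.png")
        if rec.tumour_mask is not None:
            Image.fromarray(rec.tumour_mask.astype(np.uint8) * 255).save(
                out / "masks" / f"{rec.slide_id}_mask.png"
            )
    cohort.expression.to_tsv(out / "expression.tsv")
    cohort.signatures.to_gmt(out / "signatures.gmt")
    cohort.survival.to_csv(out / "survival.csv", index=False)
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    pd.DataFrame(
        [
            {
                "slide_id": r.slide_id,
                "patient_id": r.patient_id,
                "sample_type": r.sample_type,
                "rna_linked": r.rna_linked,
                "true_class": r.true_class,
            }
            for r in cohort.slides
        ]
    ).to_csv(out / "slides.csv", index=False)
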