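"""End-to-end experiment plumbing: cohort -> grids -> embeddings -> CV report.

This module glues the pipeline stages together for a whole cohort so that
experiments (and the command-line interface) stay one-liners:

1. tissue detection + tessellation per slide, with all three ROI protocols;
2. one cached tile featurizer per slide (dihedral features are computed at
   most once per tile/transform pair, shared across protocols and views);
3. view-ensembled slide embeddings, or MIL bags, per protocol;
4. patient-stratified 5-fold cross-validation of the chosen model, with the
   fold plan shared across protocols and model types.

Slides whose tumour annotation overlaps no tile at the configured tumour
fraction keep their single highest-tumour-fraction tile instead (a guard
for small tumours at coarse grids); a slide with no annotated tumour at all
raises an empty-slide error under the mask protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from histotx.features import EmptySlideError, TileFeaturizer, sample_view, slide_embedding
from histotx.heads import EvalReport, FoldPlan, HeadConfig, cross_validate, stratified_patient_folds, train_head
from histotx.mil import Bag, MILTrainConfig, predict_bags, train_mil
from histotx.preproc import (
    apply_mask_filter,
    extract_patches,
    tessellate,
    tissue_mask,
    train_tile_filter,
)
from histotx.synthetic import SyntheticCohort


@dataclass
class PipelineConfig:
    """Desk-scale defaults: 112-px tiles on 448-px synthetic slides give a
    4x4 grid, and 100 views of 25% of the tiles per slide embedding."""

    patch_size: int = 112
    min_tissue_fraction: float = 0.5
    min_tumour_fraction: float = 0.5
    n_views: int = 100
    view_fraction: float = 0.25
    filter_training_size: int = 3000
    head: HeadConfig = field(default_factory=HeadConfig)
    mil: MILTrainConfig = field(default_factory=MILTrainConfig)
    k_folds: int = 5
    seed: int = 0


@dataclass
class SlidePrep:
    """Per-slide preprocessing products shared by every downstream model."""

    slide_id: str
    patient_id: str
    true_class: str
    featurizer: TileFeaturizer  # over tissue tiles (protocol 'none')
    tissue_features: np.ndarray  # n_tissue x 64, identity transform
    tumour_fraction: np.ndarray  # per tissue tile
    keep_indices: dict[str, np.ndarray]  # protocol -> indices into tissue tiles


def preprocess_cohort(
    cohort: SyntheticCohort,
    config: PipelineConfig | None = None,
    protocols: tuple[str, ...] = ("none", "mask", "learned"),
) -> dict[str, SlidePrep]:
    """Tessellate and featurize every slide; resolve all requested protocols."""
    cfg = config or PipelineConfig()
    preps: dict[str, SlidePrep] = {}
    for rec in cohort.slides:
        tm = tissue_mask(rec.image)
        grid = tessellate(tm, cfg.patch_size, cfg.min_tissue_fraction)
        patches = extract_patches(rec.image, grid, "none")
        featurizer = TileFeaturizer(patches)
        feats = np.stack(
            [featurizer.feature(i, 0) for i in range(featurizer.n_tiles)]
        )
        if rec.tumour_mask is not None:
            apply_mask_filter(grid, rec.tumour_mask, cfg.min_tumour_fraction)
            tissue_idx = np.flatnonzero(grid.keep["none"])
            ps = cfg.patch_size
            tfrac = np.array(
                [
                    rec.tumour_mask[y : y + ps, x : x + ps].mean()
                    for x, y in grid.coords[tissue_idx]
                ]
            )
            mask_local = np.flatnonzero(grid.keep["mask"][tissue_idx])
        else:
            tfrac = np.zeros(featurizer.n_tiles)
            mask_local = np.array([], dtype=int)
        keep = {"none": np.arange(featurizer.n_tiles)}
        if "mask" in protocols:
            if len(mask_local) == 0:
                if tfrac.max(initial=0.0) <= 0.0:
                    raise EmptySlideError(
                        f"slide {rec.slide_id}: no annotated tumour tile"
                    )
                mask_local = np.array([int(np.argmax(tfrac))])
            keep["mask"] = mask_local
        preps[rec.slide_id] = SlidePrep(
            slide_id=rec.slide_id,
            patient_id=rec.patient_id,
            true_class=rec.true_class,
            featurizer=featurizer,
            tissue_features=feats,
            tumour_fraction=tfrac,
            keep_indices=keep,
        )

    if "learned" in protocols:
        _resolve_learned_protocol(preps, cfg)
    return preps


def _resolve_learned_protocol(
    preps: dict[str, SlidePrep], cfg: PipelineConfig
) -> None:
    """Train the tile filter on mask-derived tile labels, then apply it."""
    feats = np.concatenate([p.tissue_features for p in preps.values()])
    labels = np.concatenate(
        [
            (p.tumour_fraction >= cfg.min_tumour_fraction).astype(int)
            for p in preps.values()
        ]
    )
    model = train_tile_filter(
        feats, labels, training_size=cfg.filter_training_size, seed=cfg.seed
    )
    for p in preps.values():
        proba = model.predict_proba(p.tissue_features)
        idx = np.flatnonzero(proba >= model.threshold)
        if len(idx) == 0:
            idx = np.array([int(np.argmax(proba))])
        p.keep_indices["learned"] = idx


def embed_cohort(
    preps: dict[str, SlidePrep],
    protocol: str = "none",
    n_views: int = 100,
    view_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """View-ensembled slide embeddings for every slide under one protocol.

    Returns (X, meta): X is slide_id x 64 features, meta carries patient_id
    and true_class aligned with X's rows.
    """
    rows, meta = [], []
    for j, sid in enumerate(sorted(preps)):
        p = preps[sid]
        subset = p.keep_indices[protocol]
        if len(subset) == 0:
            raise EmptySlideError(f"slide {sid}: protocol {protocol!r} keeps no tile")
        rng = np.random.default_rng([seed, j])
        views = []
        for _ in range(n_views):
            local, transforms = sample_view(len(subset), view_fraction, rng)
            views.append(
                np.stack(
                    [
                        p.featurizer.feature(subset[i], t)
                        for i, t in zip(local, transforms)
                    ]
                )
            )
        rows.append(slide_embedding(views).vector)
        meta.append(
            {"slide_id": sid, "patient_id": p.patient_id, "true_class": p.true_class}
        )
    meta_df = pd.DataFrame(meta).set_index("slide_id")
    X = pd.DataFrame(
        np.stack(rows), index=meta_df.index, columns=[f"f{i}" for i in range(64)]
    )
    return X, meta_df


def build_bags(
    preps: dict[str, SlidePrep], protocol: str, target_class: str
) -> tuple[list[Bag], np.ndarray, np.ndarray]:
    """One MIL bag per slide from the protocol's kept tiles."""
    bags, ys, pids = [], [], []
    for sid in sorted(preps):
        p = preps[sid]
        subset = p.keep_indices[protocol]
        if len(subset) == 0:
            raise EmptySlideError(f"slide {sid}: protocol {protocol!r} keeps no tile")
        label = int(p.true_class == target_class)
        bags.append(
            Bag(
                instances=p.tissue_features[subset],
                label=label,
                slide_id=sid,
                patient_id=p.patient_id,
            )
        )
        ys.append(label)
        pids.append(p.patient_id)
    return bags, np.array(ys), np.array(pids)


def _scale_bags(bags: list[Bag], mu: np.ndarray, sd: np.ndarray) -> list[Bag]:
    return [
        Bag(
            instances=(b.instances - mu) / sd,
            label=b.label,
            slide_id=b.slide_id,
            patient_id=b.patient_id,
        )
        for b in bags
    ]


def _fit_mil(bags: list[Bag], y: np.ndarray, cfg: MILTrainConfig):
    X = np.concatenate([b.instances for b in bags])
    mu, sd = X.mean(axis=0), np.maximum(X.std(axis=0), 1e-8)
    model = train_mil(_scale_bags(bags, mu, sd), cfg)
    return model, mu, sd


def _predict_mil(fitted, bags: list[Bag]) -> np.ndarray:
    model, mu, sd = fitted
    return predict_bags(model, _scale_bags(bags, mu, sd))


def shared_fold_plan(
    cohort: SyntheticCohort, target_class: str, k: int = 5, seed: int = 0
) -> FoldPlan:
    """The one patient-level stratified plan reused by every training."""
    labels = (cohort.patient_classes() == target_class).astype(int)
    return stratified_patient_folds(labels, k=k, seed=seed)


def evaluate_protocol(
    preps: dict[str, SlidePrep],
    plan: FoldPlan,
    target_class: str,
    protocol: str = "none",
    model: str = "head",
    config: PipelineConfig | None = None,
    labels_override: np.ndarray | None = None,
) -> tuple[EvalReport, np.ndarray, list]:
    """Cross-validate one model under one ROI protocol on the shared folds.

    ``labels_override`` replaces the slide labels (used for permutation
    nulls); it must be patient-consistent.
    """
    cfg = config or PipelineConfig()
    if model == "head":
        X, meta = embed_cohort(
            preps, protocol, cfg.n_views, cfg.view_fraction, cfg.seed
        )
        y = (meta["true_class"] == target_class).to_numpy(int)
        if labels_override is not None:
            y = np.asarray(labels_override)
        return cross_validate(
            X.to_numpy(),
            y,
            meta["patient_id"].to_numpy(),
            plan,
            fit=lambda Xt, yt: train_head(Xt, yt, cfg.head),
            predict=lambda m, Xt: m.predict_proba(Xt)[:, 1],
        )
    if model == "mil":
        bags, y, pids = build_bags(preps, protocol, target_class)
        if labels_override is not None:
            y = np.asarray(labels_override)
            bags = [
                Bag(b.instances, int(lbl), b.slide_id, b.patient_id)
                for b, lbl in zip(bags, y)
            ]
        return cross_validate(
            bags,
            y,
            pids,
            plan,
            fit=lambda bt, yt: _fit_mil(bt, yt, cfg.mil),
            predict=_predict_mil,
        )
    raise ValueError(f"unknown model {model!r}")
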