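"""Transcriptomic class assignment from bulk expression.

The five iCCA transcriptomic classes are defined on the RNA side by a
nearest-class signature rule: genes quantified in at least half of the
samples are retained, profiles are quantile-normalized, every gene is
centred across samples (variance untouched), the mean centred expression
of each class signature is computed per sample, and the class with the
highest signature mean is assigned.

The pipeline order is fixed: filter -> quantile normalize -> centre ->
score -> argmax.  :func:`classify_expression` runs the whole chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical order of the five iCCA transcriptomic classes.  Exact score
#: ties are broken in favour of the earliest class in this order.
CLASSES: tuple[str, ...] = (
    "hepatic_stem_like",
    "tumour_classical",
    "inflammatory_stroma",
    "immune_classical",
    "desert_like",
)


class ExpressionError(ValueError):
    """Raised for invalid expression matrices or signature sets."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ExpressionError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ExpressionError("duplicate sample ids")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ExpressionError("non-finite expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class GeneSignatureSet:
    """Named gene sets, one per transcriptomic class."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ExpressionError(f"empty gene set: {name}")

    @property
    def class_names(self) -> list[str]:
        return list(self.sets)

    def to_gmt(self, path) -> None:
        # GMT: one set per line -- name, description, then member genes,
        # tab-separated.
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *genes]) + "\n")

    @classmethod
    def from_gmt(cls, path) -> "GeneSignatureSet":
        sets: dict[str, list[str]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ExpressionError(f"malformed GMT line: {line[:60]!r}")
                sets[parts[0]] = [g for g in parts[2:] if g]
                descriptions[parts[0]] = parts[1]
        return cls(sets, descriptions)


@dataclass
class ClassAssignment:
    """Per-sample signature scores, the argmax class, and a tie flag."""

    scores: pd.DataFrame  # samples x classes
    assigned: pd.Series  # sample -> class name
    tie_flag: pd.Series  # sample -> bool

    def to_csv(self, path) -> None:
        out = self.scores.copy()
        out["assigned_class"] = self.assigned
        out["tie_flag"] = self.tie_flag
        out.to_csv(path, index_label="sample_id")


def filter_genes(expr: ExpressionMatrix, min_fraction: float = 0.5) -> ExpressionMatrix:
    """Keep genes quantified (value > 0) in at least ``min_fraction`` of samples."""
    if expr.n_samples < 1:
        raise ExpressionError("expression matrix has no samples")
    frac = (expr.values.to_numpy() > 0).mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        raise ExpressionError("all genes removed by the quantification filter")
    return ExpressionMatrix(expr.values.loc[keep])


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share the mean-of-sorted-values distribution.

    Each column's sorted values are replaced by the across-sample mean of
    sorted values; tied values within a column receive the mean of the target
    values at the ranks they jointly occupy, so the map is well defined.
    """
    if expr.n_samples < 2:
        raise ExpressionError("quantile normalization needs >= 2 samples")
    arr = expr.values.to_numpy(dtype=float)
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = target
        # average target values over tied entries
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=assigned, minlength=uniq.size)
        counts = np.bincount(inv, minlength=uniq.size)
        out[:, j] = (sums / counts)[inv]
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    )


def genewise_center(expr: ExpressionMatrix) -> pd.DataFrame:
    """Subtract each gene's across-sample mean; variances are untouched.

    Returns a plain DataFrame since centred values are signed and no longer
    satisfy the non-negativity contract of :class:`ExpressionMatrix`.
    """
    vals = expr.values
    return vals.sub(vals.mean(axis=1), axis=0)


def signature_scores(
    centered: pd.DataFrame, signatures: GeneSignatureSet
) -> pd.DataFrame:
    """Per-sample mean centred expression of each class signature.

    Genes absent from the (filtered) matrix are ignored; a signature with no
    present genes is an error naming the class.
    """
    cols = {}
    for name, genes in signatures.sets.items():
        present = centered.index.intersection(genes)
        if len(present) == 0:
            raise ExpressionError(
                f"signature {name!r} has no genes present after filtering"
            )
        cols[name] = centered.loc[present].mean(axis=0)
    return pd.DataFrame(cols)


def assign_class(scores: pd.DataFrame) -> ClassAssignment:
    """Argmax over class scores; exact ties flagged, broken by canonical order."""
    arr = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ExpressionError("non-finite signature score")
    order = [c for c in CLASSES if c in scores.columns]
    order += [c for c in scores.columns if c not in order]
    ordered = scores[order].to_numpy()
    idx = np.argmax(ordered, axis=1)
    maxval = ordered[np.arange(len(idx)), idx]
    ties = (ordered == maxval[:, None]).sum(axis=1) > 1
    assigned = pd.Series([order[i] for i in idx], index=scores.index)
    return ClassAssignment(
        scores=scores,
        assigned=assigned,
        tie_flag=pd.Series(ties, index=scores.index),
    )


def classify_expression(
    expr: ExpressionMatrix,
    signatures: GeneSignatureSet,
    min_fraction: float = 0.5,
) -> ClassAssignment:
    """Full RNA-side pipeline: filter, quantile normalize, centre, score, argmax."""
    kept = filter_genes(expr, min_fraction=min_fraction)
    normed = quantile_normalize(kept)
    centered = genewise_center(normed)
    scores = signature_scores(centered, signatures)
    return assign_class(scores)
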