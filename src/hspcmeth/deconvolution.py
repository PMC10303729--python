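"""Reference-based cell-type deconvolution by non-negative least squares.

A reference atlas A holds the mean β per marker CpG (rows) per cell type
(columns). For a sample with panel β vector b, the cell-type composition
estimate is

    x* = argmin_{x ≥ 0} ‖A x − b‖₂

solved with the Lawson–Hanson active-set algorithm. No sum-to-one
constraint is imposed; normalization of x* to proportions is a reporting
option and the raw coefficients are always retained. Here the atlas columns
are hematopoietic stem cells (HSC), lymphoid-primed multipotent progenitors
(LMPP), common myeloid progenitors (CMP), and a pooled mature-leukocyte
pseudo-type.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.base import BaseEstimator, TransformerMixin

from .beta_io import (
    BetaMatrix,
    MarkerPanel,
    SampleAnnotation,
    ValidationError,
    _detect_sep,
)

__all__ = [
    "ReferenceAtlas",
    "DeconvolutionResult",
    "build_reference",
    "read_atlas",
    "write_atlas",
    "nnls_solve",
    "deconvolve_sample",
    "sum_progenitor_fractions",
    "NNLSDeconvolver",
]


@dataclass
class ReferenceAtlas:
    """Mean β per cell type at each panel CpG — the NNLS design matrix.

    ``means`` is CpG × cell-type (serialized the same way: CpGs as rows,
    cell types as columns).
    """

    means: pd.DataFrame

    def __post_init__(self) -> None:
        if self.means.isna().any().any():
            raise ValidationError("reference atlas must have no missing entries")
        vals = self.means.to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError("reference atlas means must lie in [0, 1]")
        if len(set(self.means.columns)) != self.means.shape[1]:
            raise ValidationError("duplicate cell-type labels in atlas")
        if len(set(self.means.index)) != self.means.shape[0]:
            raise ValidationError("duplicate CpG ids in atlas")
        self.means = self.means.astype(float)
        self.means.index = self.means.index.astype(str).rename("cpg_id")
        self.means.columns = self.means.columns.astype(str).rename(None)

    @property
    def cell_types(self) -> list[str]:
        return list(self.means.columns)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.means.index)

    @property
    def matrix(self) -> np.ndarray:
        return self.means.to_numpy()


@dataclass
class DeconvolutionResult:
    """Per-sample nonnegative cell-type composition estimate."""

    sample_id: str
    fractions: pd.Series  # reported fractions (normalized if requested)
    raw_fractions: pd.Series  # NNLS coefficients before normalization
    residual_norm: float  # ‖Ax − b‖₂ at the raw solution
    normalized: bool
    degenerate: bool = False  # all-zero fit; normalization impossible


def build_reference(
    beta: BetaMatrix,
    ann: SampleAnnotation,
    cell_types: Sequence[str],
    panel: MarkerPanel | Sequence[str],
    leukocyte_label: str = "leukocytes",
    leukocyte_groups: Sequence[str] | None = None,
) -> ReferenceAtlas:
    """Average reference profiles into an atlas over the panel CpGs.

    Each requested cell type's column is the per-CpG mean over its annotated
    samples. If ``leukocyte_label`` is among ``cell_types``, that column
    pools the mature-leukocyte groups (``leukocyte_groups``, default: every
    annotated group not named as a cell type) as the mean of per-group
    means — equal weight per leukocyte group regardless of group size, so
    arbitrary reference-cohort composition does not bias the pseudo-type.
    """
    cpg_ids = panel.cpg_ids if isinstance(panel, MarkerPanel) else list(panel)
    sub = beta.subset_cpgs(cpg_ids)
    cols: dict[str, pd.Series] = {}
    for ct in cell_types:
        if ct == leukocyte_label and ct not in ann.groups:
            groups = leukocyte_groups
            if groups is None:
                groups = [g for g in ann.groups if g not in cell_types]
            if not groups:
                raise ValidationError(
                    f"no groups available to build the {leukocyte_label!r} pseudo-type"
                )
            per_group = []
            for g in groups:
                samples = ann.samples_in(g)
                if not samples:
                    raise ValidationError(f"leukocyte group {g!r} has no samples")
                per_group.append(sub.data[samples].mean(axis=1))
            cols[ct] = pd.concat(per_group, axis=1).mean(axis=1)
        else:
            samples = [s for s in ann.samples_in(ct) if s in sub.data.columns]
            if not samples:
                raise ValidationError(f"cell type {ct!r} has no annotated samples")
            cols[ct] = sub.data[samples].mean(axis=1)
    means = pd.DataFrame(cols, index=cpg_ids)
    if means.isna().any().any():
        bad = means.index[means.isna().any(axis=1)]
        raise ValidationError(
            f"missing values prevent reference means at CpG(s): {', '.join(bad)}"
        )
    return ReferenceAtlas(means)


def read_atlas(path: str | Path, sep: str | None = None) -> ReferenceAtlas:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), comment="#", index_col=0)
    df.index = df.index.astype(str)
    return ReferenceAtlas(df)


def write_atlas(
    atlas: ReferenceAtlas,
    path: str | Path,
    sep: str | None = None,
    header_comment: str | None = None,
) -> None:
    path = Path(path)
    use_sep = sep or ("," if path.suffix.lower() == ".csv" else "\t")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        atlas.means.to_csv(fh, sep=use_sep, index_label="cpg_id")


def nnls_solve(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve min ‖Ax − b‖₂ s.t. x ≥ 0 (Lawson–Hanson active set).

    Returns the nonnegative solution and the residual norm; deterministic.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.ndim != 2 or A.shape[1] < 1:
        raise ValidationError(f"A must be 2-D with ≥1 column, got shape {A.shape}")
    if b.shape != (A.shape[0],):
        raise ValidationError(
            f"b has shape {b.shape}, expected ({A.shape[0]},) to match A"
        )
    if not (np.isfinite(A).all() and np.isfinite(b).all()):
        raise ValidationError("A and b must be finite")
    x, rnorm = scipy.optimize.nnls(A, b)
    return x, float(rnorm)


def deconvolve_sample(
    atlas: ReferenceAtlas,
    beta_by_cpg: Mapping[str, float] | pd.Series,
    normalize: bool = False,
    sample_id: str = "",
) -> DeconvolutionResult:
    """Estimate one sample's cell-type composition against the atlas."""
    missing = [c for c in atlas.cpg_ids if c not in beta_by_cpg]
    if missing:
        raise ValidationError(f"sample lacks atlas CpG(s): {', '.join(missing)}")
    b = np.array([float(beta_by_cpg[c]) for c in atlas.cpg_ids])
    x, rnorm = nnls_solve(atlas.matrix, b)
    raw = pd.Series(x, index=atlas.cell_types, name=sample_id)
    total = float(x.sum())
    degenerate = False
    if normalize:
        if total > 0:
            fractions = raw / total
        else:
            fractions = raw.copy()
            degenerate = True
    else:
        fractions = raw.copy()
    return DeconvolutionResult(
        sample_id=sample_id,
        fractions=fractions,
        raw_fractions=raw,
        residual_norm=rnorm,
        normalized=normalize,
        degenerate=degenerate,
    )


def sum_progenitor_fractions(
    result: DeconvolutionResult, progenitor_types: Sequence[str]
) -> float:
    """Sum the named cell-type fractions (e.g. HSC + LMPP + CMP)."""
    unknown = [t for t in progenitor_types if t not in result.fractions.index]
    if unknown:
        raise ValidationError(f"unknown cell type(s): {', '.join(unknown)}")
    return float(result.fractions[list(progenitor_types)].sum())


class NNLSDeconvolver(TransformerMixin, BaseEstimator):
    """Reference-based NNLS composition estimator (sklearn transformer).

    Fit on reference profiles (samples × CpGs frame ``X``, per-sample cell
    type labels ``y``) to build the mean-β atlas, then :meth:`transform`
    maps any samples × CpGs frame to per-sample cell-type fractions.

    Parameters
    ----------
    normalize
        If True, report proportions x/Σx (raw coefficients are kept in
        :attr:`raw_fractions_` of the last transform).

    Attributes
    ----------
    atlas_ : ReferenceAtlas
    cell_types_ : list of str
    """

    def __init__(self, normalize: bool = False):
        self.normalize = normalize

    def fit(self, X, y) -> "NNLSDeconvolver":
        X = pd.DataFrame(X)
        labels = list(y)
        if len(labels) != len(X):
            raise ValidationError("one cell-type label per reference sample required")
        beta = BetaMatrix(X.T)
        ann = SampleAnnotation.from_labels(list(X.index), labels)
        self.atlas_ = build_reference(beta, ann, ann.groups, list(X.columns))
        self.cell_types_ = self.atlas_.cell_types
        self.n_features_in_ = X.shape[1]
        return self

    @classmethod
    def from_atlas(cls, atlas: ReferenceAtlas, normalize: bool = False) -> "NNLSDeconvolver":
        est = cls(normalize=normalize)
        est.atlas_ = atlas
        est.cell_types_ = atlas.cell_types
        est.n_features_in_ = len(atlas.cpg_ids)
        return est

    def transform(self, X) -> pd.DataFrame:
        """Per-sample fractions (rows: samples, columns: cell types)."""
        results = self.deconvolve(X)
        if not results:
            return pd.DataFrame(columns=self.cell_types_)
        return pd.DataFrame(
            [r.fractions.to_numpy() for r in results],
            index=[r.sample_id for r in results],
            columns=self.cell_types_,
        )

    def deconvolve(self, X) -> list[DeconvolutionResult]:
        if not hasattr(self, "atlas_"):
            raise ValidationError("NNLSDeconvolver is not fitted")
        X = pd.DataFrame(X)
        return [
            deconvolve_sample(
                self.atlas_, X.loc[s], normalize=self.normalize, sample_id=str(s)
            )
            for s in X.index
        ]
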