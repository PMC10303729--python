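"""Cell-type-specific CpG marker selection.

Candidate markers discriminate a target cell population from everything else
along two axes: a large difference of group-mean β and low within-group
variation. Selection is made reproducible by scalarizing the two axes into

    score = |Δmean| − w · max(sd_target, sd_rest)

with weight ``w`` exposed (default 1). The worst-case group sd is used
because a marker is unusable if *either* group is noisy. A Pareto-front
report over (|Δmean| ↑, max sd ↓) is available for inspection alongside the
scalarized ranking.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .beta_io import HYPER, HYPO, BetaMatrix, SampleAnnotation, ValidationError

__all__ = [
    "group_stats",
    "rank_candidates",
    "pareto_front",
    "select_subset_markers",
    "MarkerSelector",
]

STAT_COLUMNS = [
    "mean_target",
    "mean_rest",
    "delta",
    "sd_target",
    "sd_rest",
    "n_target",
    "n_rest",
]


def group_stats(
    beta: BetaMatrix,
    ann: SampleAnnotation,
    target_group: str,
    rest_groups: Sequence[str] | None = None,
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """Per-CpG group means, sds and their difference, target vs rest.

    Returns a DataFrame indexed by CpG with columns ``mean_target``,
    ``mean_rest``, ``delta`` (= mean_target − mean_rest), ``sd_target``,
    ``sd_rest`` (sample sd, n−1 denominator), ``n_target``, ``n_rest``.
    CpGs missing in more than ``max_missing_frac`` of either group's samples
    are dropped; remaining statistics are complete-case per CpG.
    """
    if rest_groups is None:
        rest_groups = [g for g in ann.groups if g != target_group]
    rest_groups = list(rest_groups)
    if target_group in rest_groups:
        raise ValidationError(
            f"target group {target_group!r} overlaps the comparison groups"
        )
    in_matrix = set(beta.sample_ids)
    target_samples = [s for s in ann.samples_in(target_group) if s in in_matrix]
    rest_samples = [s for s in ann.samples_in(*rest_groups) if s in in_matrix]
    if len(target_samples) < 2:
        raise ValidationError(
            f"target group {target_group!r} has {len(target_samples)} sample(s) "
            "in the matrix; need at least 2"
        )
    if len(rest_samples) < 2:
        raise ValidationError(
            f"comparison groups {rest_groups} have {len(rest_samples)} sample(s) "
            "in the matrix; need at least 2"
        )
    overlap = set(target_samples) & set(rest_samples)
    if overlap:
        raise ValidationError(
            f"samples in both target and comparison sets: {sorted(overlap)}"
        )

    tgt = beta.data[target_samples]
    rst = beta.data[rest_samples]
    keep = (tgt.isna().mean(axis=1) <= max_missing_frac) & (
        rst.isna().mean(axis=1) <= max_missing_frac
    )
    tgt, rst = tgt.loc[keep], rst.loc[keep]

    stats = pd.DataFrame(
        {
            "mean_target": tgt.mean(axis=1),
            "mean_rest": rst.mean(axis=1),
            "sd_target": tgt.std(axis=1, ddof=1),
            "sd_rest": rst.std(axis=1, ddof=1),
            "n_target": tgt.notna().sum(axis=1),
            "n_rest": rst.notna().sum(axis=1),
        }
    )
    stats["delta"] = stats["mean_target"] - stats["mean_rest"]
    stats.index.name = "cpg_id"
    return stats[STAT_COLUMNS]


def _score(stats: pd.DataFrame, weight: float) -> pd.Series:
    return stats["delta"].abs() - weight * stats[["sd_target", "sd_rest"]].max(axis=1)


def rank_candidates(
    stats: pd.DataFrame,
    direction: str = "both",
    n_top: int | None = None,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Rank CpGs by score, filter by direction, keep the top ``n_top``.

    Direction of a candidate is ``hyper`` iff its delta is positive (target
    more methylated than rest). Ties are broken by larger |delta|, then
    lexicographic CpG identifier.
    """
    if stats.empty:
        raise ValidationError("no CpG statistics to rank")
    if direction not in (HYPER, HYPO, "both"):
        raise ValidationError(
            f"direction must be 'hyper', 'hypo' or 'both', got {direction!r}"
        )
    if weight < 0:
        raise ValidationError("weight must be nonnegative")
    out = stats.copy()
    out["direction"] = np.where(out["delta"] > 0, HYPER, HYPO)
    out["score"] = _score(out, weight)
    if direction != "both":
        out = out[out["direction"] == direction]
    out = out.assign(_absdelta=out["delta"].abs())
    out = out.sort_values(
        by=["score", "_absdelta", "cpg_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_absdelta")
    if n_top is not None:
        if n_top < 1:
            raise ValidationError("n_top must be >= 1")
        if n_top > len(out):
            warnings.warn(
                f"requested {n_top} candidates but only {len(out)} available "
                f"for direction {direction!r}; returning all",
                stacklevel=2,
            )
        out = out.head(n_top)
    return out[["direction", "score"] + STAT_COLUMNS]


def pareto_front(stats: pd.DataFrame) -> pd.Series:
    """Boolean mask of CpGs not dominated in (|delta| larger, max sd smaller).

    A CpG is dominated if another has |delta| ≥ it and max-group-sd ≤ it with
    at least one strict inequality.
    """
    absdelta = stats["delta"].abs().to_numpy()[:, None]
    maxsd = stats[["sd_target", "sd_rest"]].max(axis=1).to_numpy()[:, None]
    ge_delta = absdelta.T >= absdelta
    le_sd = maxsd.T <= maxsd
    strict = (absdelta.T > absdelta) | (maxsd.T < maxsd)
    dominated = (ge_delta & le_sd & strict).any(axis=1)
    return pd.Series(~dominated, index=stats.index, name="pareto_front")


def select_subset_markers(
    beta: BetaMatrix,
    ann: SampleAnnotation,
    subsets: Sequence[str],
    n_hypo: int = 3,
    n_hyper: int = 3,
    weight: float = 1.0,
    max_missing_frac: float = 0.2,
) -> dict[str, pd.DataFrame]:
    """Per-subset marker selection against all other subsets plus leukocytes.

    For each subset the comparison group is the union of every other
    annotated group. Each CpG may serve at most one subset: it is claimed by
    the subset where its score is highest (greedy, deterministic). The
    default of three hypo- and three hypermethylated markers per subset
    yields an 18-CpG design over three subsets.
    """
    subsets = list(subsets)
    stats_by_subset = {
        s: group_stats(beta, ann, s, max_missing_frac=max_missing_frac)
        for s in subsets
    }
    scored = {
        s: rank_candidates(st, direction="both", weight=weight)
        for s, st in stats_by_subset.items()
    }
    # claim each CpG for the subset where its score is maximal (ties: first
    # subset in the given order)
    score_table = pd.DataFrame({s: scored[s]["score"] for s in subsets})
    claimed_by = score_table.idxmax(axis=1)

    out: dict[str, pd.DataFrame] = {}
    for s in subsets:
        mine = scored[s].loc[claimed_by.loc[scored[s].index] == s]
        parts = []
        for direction, want in ((HYPO, n_hypo), (HYPER, n_hyper)):
            cands = mine[mine["direction"] == direction]
            if len(cands) < want:
                warnings.warn(
                    f"subset {s!r}: only {len(cands)} {direction}methylated "
                    f"candidate(s) available of {want} requested",
                    stacklevel=2,
                )
            parts.append(cands.head(want))
        out[s] = pd.concat(parts)
    return out


class MarkerSelector(TransformerMixin, BaseEstimator):
    """Supervised selection of cell-type-specific CpGs (sklearn transformer).

    Fit on a samples × CpGs β DataFrame ``X`` and per-sample group labels
    ``y``; the transformer keeps the top-scoring candidate CpGs for the
    target group and :meth:`transform` restricts any matrix to them.

    Parameters
    ----------
    target_group
        Group label whose specific markers are sought.
    rest_groups
        Comparison groups; default all other labels seen in ``y``.
    direction
        'hyper', 'hypo' or 'both'.
    n_top
        Number of candidates to keep.
    weight
        Penalty weight on the worst-case within-group sd in the score.
    max_missing_frac
        Drop CpGs missing in more than this fraction of either group.

    Attributes
    ----------
    stats_ : DataFrame
        Per-CpG group statistics (means, sds, delta).
    candidates_ : DataFrame
        Ranked selected candidates with direction and score.
    selected_ids_ : list of str
        CpG identifiers kept, in rank order.
    """

    def __init__(
        self,
        target_group: str = "",
        rest_groups: Sequence[str] | None = None,
        direction: str = "both",
        n_top: int = 3,
        weight: float = 1.0,
        max_missing_frac: float = 0.2,
    ):
        self.target_group = target_group
        self.rest_groups = rest_groups
        self.direction = direction
        self.n_top = n_top
        self.weight = weight
        self.max_missing_frac = max_missing_frac

    def fit(self, X: pd.DataFrame, y: Sequence[str]) -> "MarkerSelector":
        X = pd.DataFrame(X)
        beta = BetaMatrix(X.T)
        ann = SampleAnnotation.from_labels(list(X.index), list(y))
        self.stats_ = group_stats(
            beta,
            ann,
            self.target_group,
            self.rest_groups,
            max_missing_frac=self.max_missing_frac,
        )
        self.candidates_ = rank_candidates(
            self.stats_, self.direction, self.n_top, self.weight
        )
        self.selected_ids_ = list(self.candidates_.index)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "selected_ids_"):
            raise ValidationError("MarkerSelector is not fitted")
        X = pd.DataFrame(X)
        missing = [c for c in self.selected_ids_ if c not in X.columns]
        if missing:
            raise ValidationError(f"input lacks selected CpG(s): {', '.join(missing)}")
        return X[self.selected_ids_]

    def get_support(self) -> np.ndarray:
        return np.isin(self.feature_names_in_, self.selected_ids_)
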