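"""Validation statistics: Pearson correlation, recovery metrics, and the
total-vs-summed-subsets consistency check.

Pearson's r is the single correlation measure used throughout. Correlations
on degenerate input (zero variance in either vector) are reported as an
explicit *undefined* result — never a silent NaN and never an exception —
so degenerate cohorts remain visible in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .beta_io import MeasurementTable, ValidationError
from .deconvolution import DeconvolutionResult

__all__ = [
    "CorrelationResult",
    "RecoveryReport",
    "pearson_r",
    "recovery_report",
    "consistency_check",
    "correlate_with_covariate",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with sample size; ``r is None`` marks an undefined result."""

    r: float | None
    n: int
    loo_range: tuple[float, float] | None = None  # leave-one-out min/max r

    @property
    def defined(self) -> bool:
        return self.r is not None


def _as_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(
            f"paired 1-D vectors required, got shapes {x.shape} and {y.shape}"
        )
    if x.size < 2:
        raise ValidationError(f"need at least 2 paired observations, got {x.size}")
    return x, y


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Sample Pearson correlation; None when either vector has zero variance."""
    x, y = _as_pair(x, y)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None
    return float(scipy.stats.pearsonr(x, y).statistic)


@dataclass
class RecoveryReport:
    """Truth-vs-estimate summary for fraction recovery (percent scale)."""

    n: int
    rmse: float
    bias: float  # mean signed error (estimate − truth)
    pearson_r: float | None
    table: pd.DataFrame  # per-sample truth, estimate, error


def recovery_report(
    truth: Sequence[float],
    estimates: Sequence[float],
    sample_ids: Sequence[str] | None = None,
) -> RecoveryReport:
    """RMSE, bias, and Pearson r of estimated vs true fractions."""
    t, e = _as_pair(truth, estimates)
    err = e - t
    table = pd.DataFrame(
        {
            "truth": t,
            "estimate": e,
            "error": err,
        },
        index=list(sample_ids) if sample_ids is not None else range(len(t)),
    )
    return RecoveryReport(
        n=len(t),
        rmse=float(np.sqrt(np.mean(err**2))),
        bias=float(np.mean(err)),
        pearson_r=pearson_r(t, e),
        table=table,
    )


def consistency_check(
    total_estimates: Mapping[str, float] | pd.Series,
    subset_results: Sequence[DeconvolutionResult],
    progenitor_types: Sequence[str],
    subset_scale: str = "unit",
) -> tuple[pd.DataFrame, dict]:
    """Compare calibration-model totals with summed deconvolution subsets.

    ``total_estimates`` maps sample id → total HSPC estimate in percent;
    each deconvolution result contributes Σ fractions over
    ``progenitor_types`` (converted ×100 when ``subset_scale="unit"``).
    Returns the per-sample table (total, summed, difference) and a summary
    with the maximum absolute difference and Pearson r.
    """
    totals = pd.Series(total_estimates, dtype=float)
    summed = {}
    for res in subset_results:
        unknown = [t for t in progenitor_types if t not in res.fractions.index]
        if unknown:
            raise ValidationError(f"unknown cell type(s): {', '.join(unknown)}")
        s = float(res.fractions[list(progenitor_types)].sum())
        summed[res.sample_id] = s * 100.0 if subset_scale == "unit" else s
    summed = pd.Series(summed, dtype=float)
    only_total = set(totals.index) - set(summed.index)
    only_subset = set(summed.index) - set(totals.index)
    if only_total or only_subset:
        raise ValidationError(
            "sample sets differ; only in totals: "
            f"{sorted(only_total)}, only in subsets: {sorted(only_subset)}"
        )
    summed = summed.loc[totals.index]
    table = pd.DataFrame(
        {
            "total_percent": totals,
            "summed_subsets_percent": summed,
            "difference": summed - totals,
        }
    )
    summary = {
        "n": int(len(table)),
        "max_abs_difference": float(table["difference"].abs().max()),
        "mean_difference": float(table["difference"].mean()),
        "pearson_r": pearson_r(totals.to_numpy(), summed.to_numpy())
        if len(table) >= 2
        else None,
    }
    return table, summary


def correlate_with_covariate(
    measurements: MeasurementTable,
    cpg_id: str,
    covariate_name: str,
    loo: bool = False,
) -> CorrelationResult:
    """Pearson r between a CpG's percent methylation and a sample covariate.

    Pairing is complete-case: only samples carrying both the CpG measurement
    and the covariate enter. With ``loo=True`` the result also carries the
    min/max r over all leave-one-out subsets, a leverage-point diagnostic.
    """
    sub = measurements.table[measurements.table["cpg_id"] == cpg_id]
    if sub.empty:
        raise ValidationError(f"no measurements for CpG {cpg_id!r}")
    if covariate_name not in measurements.table.columns:
        raise ValidationError(
            f"covariate {covariate_name!r} not present; available: "
            f"{', '.join(measurements.covariate_columns) or '(none)'}"
        )
    cov = measurements.covariate(covariate_name)
    merged = sub.set_index("sample_id")["percent_methylation"].to_frame("meth")
    merged["cov"] = cov.reindex(merged.index)
    merged = merged.dropna()
    if len(merged) < 2:
        raise ValidationError(
            f"need ≥2 complete (CpG, covariate) pairs, got {len(merged)}"
        )
    x = merged["meth"].to_numpy(dtype=float)
    y = merged["cov"].to_numpy(dtype=float)
    r = pearson_r(x, y)
    loo_range = None
    if loo and len(merged) >= 3 and r is not None:
        rs = []
        for i in range(len(merged)):
            mask = np.arange(len(merged)) != i
            ri = pearson_r(x[mask], y[mask])
            if ri is not None:
                rs.append(ri)
        if rs:
            loo_range = (min(rs), max(rs))
    return CorrelationResult(r=r, n=len(merged), loo_range=loo_range)
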