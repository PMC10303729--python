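"""Synthetic methylation data with the structure the pipeline assumes.

Generators for (i) per-cell-type reference β profiles with planted marker
CpGs, (ii) linear mixtures of reference profiles with additive technical
noise, (iii) CD34+/CD34− dilution series with known mixture fractions, and
(iv) a leukemia-like cohort whose panel methylation tracks a blast-count
covariate. Everything is driven by a single integer seed and is
bit-reproducible.

Background CpGs follow a bimodal β distribution (modes near 0.1 and 0.9,
equal weight), mimicking the genome-wide β landscape; a planted marker sits
at the opposite mode for its target type, offset by ``marker_delta``.
Technical noise is additive Gaussian on β, clamped to [0, 1]; assay-specific
overdispersion is deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .beta_io import (
    HYPER,
    HYPO,
    BetaMatrix,
    MeasurementTable,
    SampleAnnotation,
    ValidationError,
)
from .calibration import DilutionSeries
from .deconvolution import ReferenceAtlas

__all__ = [
    "SyntheticSpec",
    "make_reference_profiles",
    "simulate_mixture",
    "simulate_dilution_series",
    "make_leukemia_cohort",
]

DEFAULT_DILUTION_GRID = (0.0, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the targeted-marker setting: a handful of cell types,
    three hyper- and three hypomethylated markers planted per type with a
    large methylation difference (|Δβ| = 0.6) and tight within-type
    replication (sd 0.02 on β), measured with additive technical noise
    (sd 0.02 on β).
    """

    n_cell_types: int = 4
    cell_type_names: Sequence[str] | None = None
    n_background_cpgs: int = 200
    markers_per_type: tuple[int, int] = (3, 3)  # (n_hyper, n_hypo)
    marker_delta: float = 0.6
    within_type_sd: float = 0.02
    noise_sd: float = 0.02
    samples_per_type: int = 5
    dilution_grid: Sequence[float] = DEFAULT_DILUTION_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.marker_delta <= 1.0):
            raise ValidationError("marker_delta must lie in (0, 1]")
        if min(self.within_type_sd, self.noise_sd) < 0:
            raise ValidationError("standard deviations must be nonnegative")
        if any(f < 0 or f > 100 for f in self.dilution_grid):
            raise ValidationError("dilution_grid fractions must lie in [0, 100]")
        if self.cell_type_names is not None:
            if len(self.cell_type_names) != self.n_cell_types:
                raise ValidationError(
                    "cell_type_names length must equal n_cell_types"
                )

    @property
    def type_names(self) -> list[str]:
        if self.cell_type_names is not None:
            return list(self.cell_type_names)
        return [f"type{i + 1:02d}" for i in range(self.n_cell_types)]


def _clamp01(a: np.ndarray) -> np.ndarray:
    return np.clip(a, 0.0, 1.0)


def _bimodal_background(rng: np.random.Generator, n: int) -> np.ndarray:
    high = rng.random(n) < 0.5
    lo = rng.normal(0.1, 0.04, n)
    hi = rng.normal(0.9, 0.04, n)
    return _clamp01(np.where(high, hi, lo))


def make_reference_profiles(
    spec: SyntheticSpec,
) -> tuple[BetaMatrix, SampleAnnotation, dict[str, dict]]:
    """Generate replicate reference profiles with planted marker CpGs.

    Returns the β matrix (CpG × sample), per-sample annotations, and a truth
    map ``cpg_id → {cell_type, direction, planted_delta, shrunk}``. Marker
    offsets that would leave [0, 1] are shrunk to fit and flagged.
    """
    rng = np.random.default_rng(spec.seed)
    types = spec.type_names
    n_hyper, n_hypo = spec.markers_per_type

    cpg_ids: list[str] = []
    type_means: dict[str, list[float]] = {t: [] for t in types}
    truth: dict[str, dict] = {}

    # background: one shared baseline per CpG, identical expectation across
    # types so inter-group deltas come from sampling noise alone
    bg = _bimodal_background(rng, spec.n_background_cpgs)
    for i, base in enumerate(bg):
        cpg_ids.append(f"bg{i + 1:05d}")
        for t in types:
            type_means[t].append(float(base))

    # planted markers: target type offset from the off-target baseline
    m = 0
    for t in types:
        for direction, count in ((HYPER, n_hyper), (HYPO, n_hypo)):
            for _ in range(count):
                m += 1
                cpg = f"mk{m:04d}_{t}_{direction}"
                cpg_ids.append(cpg)
                if direction == HYPER:
                    base = float(_clamp01(rng.normal(0.1, 0.03, 1))[0])
                    target = base + spec.marker_delta
                else:
                    base = float(_clamp01(rng.normal(0.9, 0.03, 1))[0])
                    target = base - spec.marker_delta
                shrunk = target < 0.0 or target > 1.0
                target = float(np.clip(target, 0.0, 1.0))
                for u in types:
                    type_means[u].append(target if u == t else base)
                truth[cpg] = {
                    "cell_type": t,
                    "direction": direction,
                    "planted_delta": abs(target - base),
                    "shrunk": bool(shrunk),
                }

    sample_ids: list[str] = []
    groups: list[str] = []
    cols: dict[str, np.ndarray] = {}
    n_cpgs = len(cpg_ids)
    for t in types:
        mu = np.asarray(type_means[t])
        for r in range(spec.samples_per_type):
            sid = f"{t}_r{r + 1:02d}"
            sample_ids.append(sid)
            groups.append(t)
            jitter = rng.normal(0.0, spec.within_type_sd, n_cpgs)
            cols[sid] = _clamp01(mu + jitter)

    beta = BetaMatrix(pd.DataFrame(cols, index=cpg_ids))
    ann = SampleAnnotation.from_labels(sample_ids, groups, source="synthetic")
    return beta, ann, truth


def simulate_mixture(
    atlas: ReferenceAtlas,
    proportions: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Mix atlas columns by known proportions, add technical noise, clamp.

    ``b = A·p + ε`` with ε i.i.d. Gaussian(0, noise_sd), clamped to [0, 1].
    """
    p = np.asarray(proportions, dtype=float)
    if p.shape != (len(atlas.cell_types),):
        raise ValidationError(
            f"need {len(atlas.cell_types)} proportions, got shape {p.shape}"
        )
    if (p < 0).any():
        raise ValidationError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"proportions must sum to 1, got {p.sum()!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    b = atlas.matrix @ p
    if noise_sd > 0:
        b = b + rng.normal(0.0, noise_sd, b.shape)
    return pd.Series(_clamp01(b), index=atlas.cpg_ids)


def simulate_dilution_series(
    atlas: ReferenceAtlas,
    grid: Sequence[float] = DEFAULT_DILUTION_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
    source: str = "synthetic",
    positive_type: str | None = None,
) -> tuple[DilutionSeries, MeasurementTable]:
    """Dilution series over a two-type (CD34+, CD34−) atlas.

    Each grid value f (percent) yields one sample mixed at proportions
    (f/100, 1 − f/100) of the positive and negative type, with measurement
    noise; the known fraction f is carried alongside.
    """
    if len(atlas.cell_types) != 2:
        raise ValidationError(
            f"dilution atlas needs exactly 2 cell types, got {atlas.cell_types}"
        )
    if any(f < 0 or f > 100 for f in grid):
        raise ValidationError("dilution grid fractions must lie in [0, 100]")
    pos = positive_type or atlas.cell_types[0]
    if pos not in atlas.cell_types:
        raise ValidationError(f"positive type {pos!r} not in atlas")
    neg = [t for t in atlas.cell_types if t != pos][0]
    rng = np.random.default_rng(seed)
    rows = []
    long_rows = []
    index = []
    for i, f in enumerate(grid):
        props = {pos: f / 100.0, neg: 1.0 - f / 100.0}
        b = simulate_mixture(
            atlas, [props[t] for t in atlas.cell_types], noise_sd, rng
        )
        sid = f"dil{i + 1:02d}_{source}"
        index.append(sid)
        rows.append({**b.to_dict(), "known_fraction": float(f)})
        for cpg in atlas.cpg_ids:
            long_rows.append(
                {
                    "sample_id": sid,
                    "cpg_id": cpg,
                    "percent_methylation": 100.0 * b[cpg],
                    "known_fraction": float(f),
                }
            )
    series = DilutionSeries(pd.DataFrame(rows, index=index), source=source)
    table = MeasurementTable(pd.DataFrame(long_rows))
    return series, table


def make_leukemia_cohort(
    atlas: ReferenceAtlas,
    n_samples: int = 39,
    blast_range: tuple[float, float] = (0.0, 100.0),
    noise_sd: float = 0.03,
    seed: int = 0,
    hspc_type: str | None = None,
) -> MeasurementTable:
    """Leukemia-like cohort: panel β interpolates HSPC-like vs leukocyte
    reference with the blast fraction, plus technical noise.

    The blast fraction (percent) is drawn uniformly in ``blast_range`` and
    stored as the ``blast_count_percent`` covariate.
    """
    lo, hi = blast_range
    if not (0 <= lo <= 100 and 0 <= hi <= 100 and lo <= hi):
        raise ValidationError("blast_range must satisfy 0 ≤ lo ≤ hi ≤ 100")
    if n_samples < 2:
        raise ValidationError("need at least 2 samples for a cohort")
    if len(atlas.cell_types) != 2:
        raise ValidationError(
            f"leukemia-cohort atlas needs exactly 2 cell types, got {atlas.cell_types}"
        )
    pos = hspc_type or atlas.cell_types[0]
    neg = [t for t in atlas.cell_types if t != pos][0]
    rng = np.random.default_rng(seed)
    blasts = rng.uniform(lo, hi, n_samples)
    long_rows = []
    for i, blast in enumerate(blasts):
        props = {pos: blast / 100.0, neg: 1.0 - blast / 100.0}
        b = simulate_mixture(
            atlas, [props[t] for t in atlas.cell_types], noise_sd, rng
        )
        sid = f"leuk{i + 1:03d}"
        for cpg in atlas.cpg_ids:
            long_rows.append(
                {
                    "sample_id": sid,
                    "cpg_id": cpg,
                    "percent_methylation": 100.0 * b[cpg],
                    "blast_count_percent": float(blast),
                }
            )
    return MeasurementTable(pd.DataFrame(long_rows))
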