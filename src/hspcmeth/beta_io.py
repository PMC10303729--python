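"""Tabular I/O for methylation data and the packaged marker panels.

The canonical in-memory representation of array-style methylation data is a
:class:`BetaMatrix` — CpG sites as rows, samples as columns, values as
methylation fractions (β) in [0, 1]. Targeted assays (pyrosequencing) report
the same quantity as a percentage in long format; those are held in a
:class:`MeasurementTable` and converted to the β scale on demand, so that one
algebra serves both data sources.

CpG identifiers are opaque strings (Illumina "cg…" probe IDs in practice); no
genomic coordinates are needed anywhere in the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "BetaMatrix",
    "SampleAnnotation",
    "Marker",
    "MarkerPanel",
    "MeasurementTable",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_annotations",
    "read_measurements",
    "write_measurements",
    "builtin_panel",
    "read_panel",
    "write_panel",
]

DEFAULT_MISSING_TOKEN = "NA"

HYPER = "hyper"
HYPO = "hypo"


class ValidationError(ValueError):
    """Input violates a structural invariant (bounds, uniqueness, coverage)."""


class ParseError(ValueError):
    """Input cell could not be interpreted as a number or missing token."""


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in {".tsv", ".tab"}:
        return "\t"
    with open(path, "r", newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if line.count("\t") >= line.count(",") else ","
    return "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class BetaMatrix:
    """CpG-by-sample matrix of methylation β values.

    Parameters
    ----------
    data
        DataFrame indexed by CpG identifier with sample identifiers as
        columns. Values are β in [0, 1]; NaN marks a missing measurement.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str).rename("cpg_id")
        self.data.columns = self.data.columns.astype(str).rename(None)
        _check_unique(list(self.data.index), "CpG identifier")
        _check_unique(list(self.data.columns), "sample identifier")
        vals = self.data.to_numpy()
        bad = np.where(~np.isnan(vals) & ((vals < 0.0) | (vals > 1.0)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value {vals[i, j]} out of [0, 1] at CpG "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> "BetaMatrix":
        missing = [c for c in cpg_ids if c not in self.data.index]
        if missing:
            raise ValidationError(f"CpG(s) not in matrix: {', '.join(missing)}")
        return BetaMatrix(self.data.loc[list(cpg_ids)])

    def samples_frame(self) -> pd.DataFrame:
        """Samples-as-rows view (sample × CpG), the estimator orientation."""
        return self.data.T


@dataclass
class SampleAnnotation:
    """Per-sample group labels (cell type / tissue) and optional source.

    Each annotated sample maps to exactly one group; ``source`` is free text
    (mPB, CB, PB, BM, apheresis, …).
    """

    table: pd.DataFrame  # columns: sample_id, group[, source]

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        if not required.issubset(self.table.columns):
            raise ValidationError(
                f"annotation needs columns {sorted(required)}, "
                f"got {list(self.table.columns)}"
            )
        _check_unique(list(self.table["sample_id"]), "annotated sample")
        if "source" not in self.table.columns:
            self.table = self.table.assign(source="")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_labels(
        cls, sample_ids: Sequence[str], groups: Sequence[str], source: str = ""
    ) -> "SampleAnnotation":
        return cls(
            pd.DataFrame(
                {"sample_id": list(sample_ids), "group": list(groups), "source": source}
            )
        )

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.table["group"]:
            if g not in seen:
                seen.append(g)
        return seen

    def group_of(self, sample_id: str) -> str:
        hit = self.table.loc[self.table["sample_id"] == sample_id, "group"]
        if hit.empty:
            raise ValidationError(f"sample {sample_id!r} has no annotation")
        return str(hit.iloc[0])

    def samples_in(self, *groups: str) -> list[str]:
        mask = self.table["group"].isin(groups)
        return list(self.table.loc[mask, "sample_id"])


@dataclass(frozen=True)
class Marker:
    cpg_id: str
    gene: str
    direction: str  # "hyper" or "hypo" in the target cell type

    def __post_init__(self) -> None:
        if self.direction not in (HYPER, HYPO):
            raise ValidationError(
                f"marker {self.cpg_id}: direction must be 'hyper' or 'hypo', "
                f"got {self.direction!r}"
            )


@dataclass
class MarkerPanel:
    """A named set of marker CpGs with gene symbols and methylation direction."""

    name: str
    markers: list[Marker]

    def __post_init__(self) -> None:
        _check_unique([m.cpg_id for m in self.markers], f"CpG in panel {self.name!r}")

    @property
    def cpg_ids(self) -> list[str]:
        return [m.cpg_id for m in self.markers]

    def __len__(self) -> int:
        return len(self.markers)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "markers": [
                {"cpg_id": m.cpg_id, "gene": m.gene, "direction": m.direction}
                for m in self.markers
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MarkerPanel":
        return cls(
            name=d["name"],
            markers=[
                Marker(m["cpg_id"], m.get("gene", ""), m["direction"])
                for m in d["markers"]
            ],
        )


# The packaged panels. The 3-CpG panel quantifies total HSPCs (all three
# CpGs are methylated in HSPCs and unmethylated in mature leukocytes); the
# 6-CpG panel carries one hypo- and one hypermethylated CpG per HSPC subtype
# (HSC, LMPP, CMP) and is the reference-deconvolution panel.
_BUILTIN_PANELS: dict[str, MarkerPanel] = {
    "hspc3": MarkerPanel(
        "hspc3",
        [
            Marker("cg17707057", "STK17A", HYPER),
            Marker("cg00164282", "MYO1D", HYPER),
            Marker("cg17607231", "SP140", HYPER),
        ],
    ),
    "subset6": MarkerPanel(
        "subset6",
        [
            Marker("cg08865625", "HLF", HYPO),
            Marker("cg17707057", "STK17A", HYPER),
            Marker("cg09749364", "BMF", HYPO),
            Marker("cg01986630", "FTO", HYPER),
            Marker("cg06768361", "TESC", HYPO),
            Marker("cg00164282", "MYO1D", HYPER),
        ],
    ),
}


def builtin_panel(name: str) -> MarkerPanel:
    """Return a packaged marker panel (``hspc3`` or ``subset6``)."""
    try:
        panel = _BUILTIN_PANELS[name]
    except KeyError:
        raise ValidationError(
            f"unknown panel {name!r}; available: {', '.join(sorted(_BUILTIN_PANELS))}"
        ) from None
    return MarkerPanel.from_dict(panel.to_dict())  # defensive copy


def read_panel(path: str | Path) -> MarkerPanel:
    with open(path) as fh:
        return MarkerPanel.from_dict(json.load(fh))


def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(panel.to_dict(), fh, indent=2)
        fh.write("\n")


@dataclass
class MeasurementTable:
    """Long-format targeted-assay measurements (percent methylation, 0–100).

    One row per (sample, CpG); ``known_fraction`` and further covariate
    columns (e.g. ``blast_count_percent``) are carried through by name.
    """

    table: pd.DataFrame  # columns: sample_id, cpg_id, percent_methylation, ...

    def __post_init__(self) -> None:
        required = {"sample_id", "cpg_id", "percent_methylation"}
        if not required.issubset(self.table.columns):
            raise ValidationError(
                f"measurement table needs columns {sorted(required)}, "
                f"got {list(self.table.columns)}"
            )
        dup = self.table.duplicated(subset=["sample_id", "cpg_id"])
        if dup.any():
            row = self.table.loc[dup].iloc[0]
            raise ValidationError(
                f"duplicate measurement for (sample {row['sample_id']!r}, "
                f"CpG {row['cpg_id']!r})"
            )
        pm = pd.to_numeric(self.table["percent_methylation"], errors="raise")
        out = pm.notna() & ((pm < 0.0) | (pm > 100.0))
        if out.any():
            row = self.table.loc[out].iloc[0]
            raise ValidationError(
                f"percent_methylation {row['percent_methylation']} out of [0, 100] "
                f"at (sample {row['sample_id']!r}, CpG {row['cpg_id']!r})"
            )
        if "known_fraction" in self.table.columns:
            kf = pd.to_numeric(self.table["known_fraction"], errors="raise")
            bad = kf.notna() & ((kf < 0.0) | (kf > 100.0))
            if bad.any():
                row = self.table.loc[bad].iloc[0]
                raise ValidationError(
                    f"known_fraction {row['known_fraction']} out of [0, 100] "
                    f"at sample {row['sample_id']!r}"
                )
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.table["sample_id"]:
            if s not in seen:
                seen.append(s)
        return seen

    @property
    def covariate_columns(self) -> list[str]:
        core = {"sample_id", "cpg_id", "percent_methylation"}
        return [c for c in self.table.columns if c not in core]

    def beta_frame(self, cpg_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Pivot to sample × CpG β values (percent ÷ 100)."""
        wide = self.table.pivot(
            index="sample_id", columns="cpg_id", values="percent_methylation"
        )
        wide = wide.loc[self.sample_ids]
        if cpg_ids is not None:
            missing = [c for c in cpg_ids if c not in wide.columns]
            if missing:
                raise ValidationError(
                    f"measurements lack panel CpG(s): {', '.join(missing)}"
                )
            wide = wide[list(cpg_ids)]
        return wide / 100.0

    def covariate(self, name: str) -> pd.Series:
        """Per-sample value of a covariate column (first non-null per sample)."""
        if name not in self.table.columns:
            raise ValidationError(
                f"covariate {name!r} not present; available: "
                f"{', '.join(self.covariate_columns) or '(none)'}"
            )
        per_sample = self.table.groupby("sample_id", sort=False)[name].first()
        return per_sample.loc[self.sample_ids]


def read_beta_matrix(
    path: str | Path,
    scale: str = "unit",
    sep: str | None = None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> BetaMatrix:
    """Read a CpG-by-sample β matrix from a delimited text file.

    The first column holds CpG identifiers, the header row sample
    identifiers. ``scale="percent"`` divides values by 100 on ingest so the
    in-memory matrix is always on the β ∈ [0, 1] scale.
    """
    path = Path(path)
    if scale not in ("unit", "percent"):
        raise ValidationError(f"scale must be 'unit' or 'percent', got {scale!r}")
    use_sep = _detect_sep(path, sep)
    df = pd.read_csv(
        path,
        sep=use_sep,
        comment="#",
        index_col=0,
        na_values=[missing_token],
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            cpg = df.index[bad][0]
            raise ParseError(
                f"non-numeric cell {df.loc[cpg, col]!r} at CpG {cpg!r}, "
                f"sample {col!r} (missing token is {missing_token!r})"
            )
        numeric[col] = converted
    if scale == "percent":
        vals = numeric.to_numpy()
        bad = np.where(~np.isnan(vals) & ((vals < 0.0) | (vals > 100.0)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"percent value {vals[i, j]} out of [0, 100] at CpG "
                f"{numeric.index[i]!r}, sample {numeric.columns[j]!r}"
            )
        numeric = numeric / 100.0
    return BetaMatrix(numeric)


def write_beta_matrix(
    beta: BetaMatrix,
    path: str | Path,
    scale: str = "unit",
    sep: str | None = None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    header_comment: str | None = None,
) -> None:
    path = Path(path)
    use_sep = sep or ("," if path.suffix.lower() == ".csv" else "\t")
    df = beta.data if scale == "unit" else beta.data * 100.0
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=use_sep, index_label="cpg_id", na_rep=missing_token)


def read_annotations(path: str | Path, sep: str | None = None) -> SampleAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), comment="#", dtype=str)
    return SampleAnnotation(df)


def read_measurements(path: str | Path, sep: str | None = None) -> MeasurementTable:
    """Read a long-format targeted measurement table (percent scale)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), comment="#")
    df["sample_id"] = df["sample_id"].astype(str)
    df["cpg_id"] = df["cpg_id"].astype(str)
    return MeasurementTable(df)


def write_measurements(
    table: MeasurementTable,
    path: str | Path,
    sep: str | None = None,
    header_comment: str | None = None,
) -> None:
    path = Path(path)
    use_sep = sep or ("," if path.suffix.lower() == ".csv" else "\t")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.table.to_csv(fh, sep=use_sep, index=False)
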