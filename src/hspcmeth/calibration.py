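"""Dilution-series calibration of cell-fraction prediction.

Graded mixtures of sorted CD34+ and CD34− cells with flow-cytometry-verified
CD34+ fractions serve as training data: the known fraction (percent) is
regressed on the β values of a small marker panel by ordinary least squares
with intercept. The fitted model maps targeted methylation measurements of a
new sample to an HSPC-fraction estimate. Because CD34+ cells from mobilized
peripheral blood and cord blood differ in methylation at the panel CpGs,
models are trained per source and never mixed.

Predictions are clamped to [0, 100] for reporting, but the unclamped value
is always retained so that systematic over- or underestimation stays
visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .beta_io import MarkerPanel, MeasurementTable, ValidationError

__all__ = [
    "DilutionSeries",
    "DilutionCalibrator",
    "Prediction",
    "fit_dilution_model",
    "predict_fraction",
    "batch_predict",
    "model_to_json",
    "model_from_json",
]


@dataclass
class DilutionSeries:
    """Paired (known CD34+ fraction %, panel β) records from a dilution run.

    ``data`` has one row per dilution sample: a ``known_fraction`` column in
    [0, 100] plus one β column per panel CpG; the index holds sample ids.
    """

    data: pd.DataFrame
    source: str = ""  # mPB or CB

    def __post_init__(self) -> None:
        if "known_fraction" not in self.data.columns:
            raise ValidationError("dilution series needs a 'known_fraction' column")
        kf = self.data["known_fraction"]
        if ((kf < 0) | (kf > 100)).any():
            raise ValidationError("known_fraction values must lie in [0, 100]")
        if self.data.drop(columns="known_fraction").isna().any().any():
            raise ValidationError("dilution series has missing panel β values")

    @property
    def cpg_ids(self) -> list[str]:
        return [c for c in self.data.columns if c != "known_fraction"]

    @classmethod
    def from_measurements(
        cls, table: MeasurementTable, panel: MarkerPanel, source: str = ""
    ) -> "DilutionSeries":
        beta = table.beta_frame(panel.cpg_ids)
        kf = table.covariate("known_fraction")
        if kf.isna().any():
            bad = list(kf.index[kf.isna()])
            raise ValidationError(f"samples without known_fraction: {bad}")
        return cls(beta.assign(known_fraction=kf.astype(float)), source=source)


def _constant_or_collinear(X: pd.DataFrame) -> list[str]:
    """Name columns responsible for a rank-deficient design."""
    culprits = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0.0]
    if culprits:
        return culprits
    corr = X.corr().to_numpy()
    cols = list(X.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if np.isclose(abs(corr[i, j]), 1.0):
                culprits.extend([cols[i], cols[j]])
    return sorted(set(culprits))


class Prediction(NamedTuple):
    percent: float  # clamped to [0, 100]
    unclamped_percent: float


class DilutionCalibrator(RegressorMixin, BaseEstimator):
    """OLS model of known cell fraction (%) on panel β values.

    Parameters
    ----------
    panel
        MarkerPanel or list of CpG ids defining predictor order. ``None``
        uses all columns of the training frame.
    source
        Label of the training material (e.g. ``"mPB"`` or ``"CB"``);
        informational, carried into serialized models.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray
        One coefficient per panel CpG (fraction-% per unit β), in
        ``cpg_ids_`` order.
    cpg_ids_ : list of str
    r_squared_ : float
    residual_sd_ : float
        Residual standard deviation, n − p − 1 denominator (NaN when the
        fit is saturated).
    n_samples_ : int
    """

    def __init__(
        self,
        panel: MarkerPanel | Sequence[str] | None = None,
        source: str = "",
        allow_rank_deficient: bool = False,
    ):
        self.panel = panel
        self.source = source
        # noise-free two-type mixtures make every panel CpG an affine
        # function of the mixing fraction, so the multi-CpG design is
        # exactly collinear; opting in uses the minimum-norm OLS solution
        # (fitted values are still the LS optimum) instead of erroring
        self.allow_rank_deficient = allow_rank_deficient

    def _panel_ids(self, X: pd.DataFrame) -> list[str]:
        if self.panel is None:
            return list(X.columns)
        if isinstance(self.panel, MarkerPanel):
            return self.panel.cpg_ids
        return list(self.panel)

    def fit(self, X, y) -> "DilutionCalibrator":
        X = pd.DataFrame(X)
        ids = self._panel_ids(X)
        missing = [c for c in ids if c not in X.columns]
        if missing:
            raise ValidationError(
                f"training data lacks panel CpG(s): {', '.join(missing)}"
            )
        Xp = X[ids].astype(float)
        y = np.asarray(y, dtype=float)
        n, p = Xp.shape
        if y.shape != (n,):
            raise ValidationError(f"y has shape {y.shape}, expected ({n},)")
        if n < p + 1:
            raise ValidationError(
                f"need at least {p + 1} dilution records for a {p}-CpG panel, got {n}"
            )
        design = np.column_stack([np.ones(n), Xp.to_numpy()])
        if np.linalg.matrix_rank(design) < p + 1 and not self.allow_rank_deficient:
            culprits = _constant_or_collinear(Xp)
            raise ValidationError(
                "design matrix is rank deficient; constant or collinear CpG(s): "
                + (", ".join(culprits) if culprits else "(multi-way collinearity)")
            )
        coeffs, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        self.cpg_ids_ = ids
        self.intercept_ = float(coeffs[0])
        self.coef_ = coeffs[1:].copy()
        fitted = design @ coeffs
        resid = y - fitted
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        self.r_squared_ = 1.0 if tss == 0.0 and rss <= 1e-24 else (
            float("nan") if tss == 0.0 else 1.0 - rss / tss
        )
        dof = n - p - 1
        self.residual_sd_ = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")
        self.n_samples_ = n
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise ValidationError("DilutionCalibrator is not fitted")

    def _design(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        missing = [c for c in self.cpg_ids_ if c not in X.columns]
        if missing:
            raise ValidationError(f"input lacks panel CpG(s): {', '.join(missing)}")
        return X[self.cpg_ids_].to_numpy(dtype=float)

    def predict(self, X) -> np.ndarray:
        """Predicted fraction (%), clamped to [0, 100]."""
        return np.clip(self.predict_unclamped(X), 0.0, 100.0)

    def predict_unclamped(self, X) -> np.ndarray:
        self._check_fitted()
        return self.intercept_ + self._design(X) @ self.coef_

    def coefficients(self) -> dict[str, float]:
        self._check_fitted()
        return dict(zip(self.cpg_ids_, map(float, self.coef_)))


def fit_dilution_model(
    series: DilutionSeries,
    panel: MarkerPanel | Sequence[str] | None = None,
    allow_rank_deficient: bool = False,
) -> DilutionCalibrator:
    """Fit the multivariable dilution model; returns the fitted calibrator."""
    X = series.data.drop(columns="known_fraction")
    model = DilutionCalibrator(
        panel=panel, source=series.source, allow_rank_deficient=allow_rank_deficient
    )
    return model.fit(X, series.data["known_fraction"].to_numpy())


def predict_fraction(
    model: DilutionCalibrator, beta_by_cpg: Mapping[str, float]
) -> Prediction:
    """Predict the cell fraction (%) for one sample's panel β values."""
    model._check_fitted()
    missing = [c for c in model.cpg_ids_ if c not in beta_by_cpg]
    if missing:
        raise ValidationError(f"sample lacks panel CpG(s): {', '.join(missing)}")
    X = pd.DataFrame([{c: beta_by_cpg[c] for c in model.cpg_ids_}])
    raw = float(model.predict_unclamped(X)[0])
    return Prediction(percent=float(np.clip(raw, 0.0, 100.0)), unclamped_percent=raw)


def batch_predict(
    model: DilutionCalibrator, measurements: MeasurementTable
) -> pd.DataFrame:
    """Predict for every sample of a measurement table.

    Returns one row per sample with ``predicted_percent`` and
    ``unclamped_percent``; a sample missing a panel CpG yields a row whose
    ``error`` column names the gap instead of failing the whole batch.
    """
    model._check_fitted()
    wide = measurements.beta_frame()
    rows = []
    for sample_id in measurements.sample_ids:
        betas = wide.loc[sample_id]
        missing = [
            c for c in model.cpg_ids_ if c not in betas.index or pd.isna(betas.get(c))
        ]
        if missing:
            rows.append(
                {
                    "sample_id": sample_id,
                    "predicted_percent": np.nan,
                    "unclamped_percent": np.nan,
                    "error": f"missing panel CpG(s): {', '.join(missing)}",
                }
            )
            continue
        pred = predict_fraction(model, betas.to_dict())
        rows.append(
            {
                "sample_id": sample_id,
                "predicted_percent": pred.percent,
                "unclamped_percent": pred.unclamped_percent,
                "error": "",
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "predicted_percent", "unclamped_percent", "error"]
    )


def model_to_json(model: DilutionCalibrator, path: str | Path | None = None) -> dict:
    """Serialize a fitted calibrator (panel, intercept, coefficients, fit stats)."""
    model._check_fitted()
    panel = model.panel
    doc = {
        "panel": panel.to_dict() if isinstance(panel, MarkerPanel) else list(model.cpg_ids_),
        "source": model.source,
        "intercept": model.intercept_,
        "coefficients": model.coefficients(),
        "diagnostics": {
            "r_squared": model.r_squared_,
            "residual_sd": model.residual_sd_,
            "n": model.n_samples_,
        },
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
    return doc


def model_from_json(source: str | Path | Mapping) -> DilutionCalibrator:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = dict(source)
    panel = (
        MarkerPanel.from_dict(doc["panel"])
        if isinstance(doc["panel"], Mapping)
        else list(doc["panel"])
    )
    model = DilutionCalibrator(panel=panel, source=doc.get("source", ""))
    model.cpg_ids_ = list(doc["coefficients"])
    model.intercept_ = float(doc["intercept"])
    model.coef_ = np.array([doc["coefficients"][c] for c in model.cpg_ids_], dtype=float)
    diag = doc.get("diagnostics", {})
    model.r_squared_ = float(diag.get("r_squared", float("nan")))
    model.residual_sd_ = float(diag.get("residual_sd", float("nan")))
    model.n_samples_ = int(diag.get("n", 0))
    return model
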