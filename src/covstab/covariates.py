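"""Covariate removal from regional measures by controls-fitted linear regression.

Regional thickness values are regressed on age and sex (plus intracranial
volume for volumetric measures) using ordinary least squares fitted on the
control subjects only, and the fitted model is then applied to every subject.
Fitting on controls detrends healthy ageing without absorbing disease-related
differences, so the AD group's departure from the healthy trend survives into
the residuals that the structural covariance networks are built from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SubjectTable
from .exceptions import ParameterError, RankDeficiencyError

__all__ = [
    "CovariateModel",
    "ResidualTable",
    "covariates_for",
    "fit_covariate_model",
    "apply_residualization",
]


def covariates_for(measure_kind: str) -> list[str]:
    """Covariate list: age and sex; intracranial volume added for volumes."""
    if measure_kind == "thickness":
        return ["age", "sex"]
    if measure_kind == "volume":
        return ["age", "sex", "icv"]
    raise ParameterError("measure_kind must be 'thickness' or 'volume'")


@dataclass
class CovariateModel:
    """Per-region OLS coefficients for the covariate regression.

    ``coefficients`` is indexed by region with an ``intercept`` column followed
    by one column per covariate.
    """

    coefficients: pd.DataFrame
    covariates: list[str]
    fit_group: str
    measure_kind: str

    @property
    def region_labels(self) -> list[str]:
        return list(self.coefficients.index)

    def to_csv(self, path) -> None:
        self.coefficients.rename_axis("region").to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, fit_group: str = "control", measure_kind: str = "thickness"):
        coef = pd.read_csv(path, index_col="region")
        covs = [c for c in coef.columns if c != "intercept"]
        return cls(coef, covariates=covs, fit_group=fit_group, measure_kind=measure_kind)


@dataclass
class ResidualTable:
    """Subjects x regions residuals after covariate removal.

    Carries the subject ids and group labels of the source table plus the
    provenance (measure kind and covariate list) of the correction.
    """

    data: pd.DataFrame  # subject_id, group, then one column per region
    measure_kind: str
    covariates: list[str]

    @property
    def region_labels(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("subject_id", "group")]

    def values(self, group: str | None = None) -> np.ndarray:
        df = self.data if group is None else self.data[self.data["group"] == group]
        return df[self.region_labels].to_numpy(dtype=float)

    def ids(self, group: str | None = None) -> np.ndarray:
        df = self.data if group is None else self.data[self.data["group"] == group]
        return df["subject_id"].to_numpy()

    def subset(self, subject_ids) -> np.ndarray:
        """Residual rows for the given subject ids, in the given order."""
        indexed = self.data.set_index("subject_id")
        missing = [s for s in subject_ids if s not in indexed.index]
        if missing:
            raise ParameterError(f"unknown subject ids {missing[:5]}")
        return indexed.loc[list(subject_ids), self.region_labels].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _design_matrix(table: SubjectTable, covariates: list[str], rows) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(rows))] + [rows[c].to_numpy(dtype=float) for c in covariates]
    )
    return X


def fit_covariate_model(
    table: SubjectTable,
    measure_kind: str | None = None,
    fit_group: str = "control",
) -> CovariateModel:
    """Fit per-region OLS of measure on covariates, on ``fit_group`` only."""
    kind = measure_kind or table.measure_kind
    covs = covariates_for(kind)
    rows = table.data[table.data["group"] == fit_group]
    if len(rows) <= len(covs) + 1:
        raise ParameterError(
            f"fit group {fit_group!r} has {len(rows)} subjects; "
            f"need more than {len(covs) + 1}"
        )
    for c in covs:
        if np.ptp(rows[c].to_numpy(dtype=float)) == 0:
            raise RankDeficiencyError(f"covariate {c!r} is constant in the fit group")
    X = _design_matrix(table, covs, rows)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("covariate design matrix is rank deficient")
    Y = rows[table.region_labels].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    coef = pd.DataFrame(
        beta.T, index=table.region_labels, columns=["intercept", *covs]
    )
    return CovariateModel(coef, covariates=covs, fit_group=fit_group, measure_kind=kind)


def apply_residualization(model: CovariateModel, table: SubjectTable) -> ResidualTable:
    """Subtract the model's predictions from every subject's measures.

    Applied to all subjects (both groups) with the controls-fitted model, so
    group differences relative to the healthy trend are retained.
    """
    if model.region_labels != table.region_labels:
        raise ParameterError("region labels of model and table do not match")
    missing = [c for c in model.covariates if c not in table.data.columns]
    if missing:
        raise ParameterError(f"table lacks covariates {missing}")
    X = _design_matrix(table, model.covariates, table.data)
    pred = X @ model.coefficients[["intercept", *model.covariates]].to_numpy().T
    resid = table.data[table.region_labels].to_numpy(dtype=float) - pred
    data = table.data[["subject_id", "group"]].reset_index(drop=True)
    data = pd.concat(
        [data, pd.DataFrame(resid, columns=table.region_labels)], axis=1
    )
    return ResidualTable(data, measure_kind=model.measure_kind, covariates=model.covariates)
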