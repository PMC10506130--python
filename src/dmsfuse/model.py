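"""Weighted ordinary-least-squares model over the variant features.

The predictor is a plain linear model (no regularization) minimizing
sum_i w_i (y_i - yhat_i)^2 with an intercept.  Rows are inversely weighted
by the number of measurements available for the identical variant, so each
distinct variant contributes total weight 1 regardless of how many DMS
datasets or AS sources cover it — compensating for regions with denser
assay coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LinearRegression

from .features import FeatureError, FeatureRow, design_matrix


class ModelError(ValueError):
    pass


@dataclass
class LinearModel:
    intercept: float
    coefficients: dict[str, float]
    training_meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.coefficients)

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"intercept": self.intercept,
                 "coefficients": self.coefficients,
                 "training_meta": self.training_meta},
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "LinearModel":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def compute_row_weights(rows: list[FeatureRow]) -> list[FeatureRow]:
    """Set each row's weight to 1 / (rows sharing its variant key).

    The key includes the protein, so identical substitutions on different
    proteins are counted separately.  Weights are set in place; the list is
    returned for chaining.
    """
    counts: dict = {}
    for row in rows:
        counts[row.key] = counts.get(row.key, 0) + 1
    for row in rows:
        row.weight = 1.0 / counts[row.key]
    return rows


def fit(rows: list[FeatureRow], as_enabled: bool,
        training_meta: dict | None = None) -> LinearModel:
    """Fit the weighted OLS model; deterministic closed-form solution."""
    X, columns, y, w = design_matrix(rows, as_enabled)
    if np.isnan(y).any():
        raise ModelError("training rows must carry target scores")
    if len(rows) < len(columns) + 1:
        raise ModelError(
            f"{len(rows)} rows cannot identify {len(columns)} features + intercept"
        )
    if not np.isfinite(X).all():
        raise ModelError("non-finite feature values")
    # Flag collinear designs before delegating to least squares.  Two kinds
    # of rank drop are expected and resolved deterministically by the
    # minimum-norm lstsq solution: the AS encoding is structurally redundant
    # by one dimension (each 20-block sums to the AS value per row), and an
    # amino acid absent from the training rows leaves its encoding column
    # identically zero (its coefficient comes back 0).
    Xc = np.column_stack([np.ones(len(rows)), X]) * np.sqrt(w)[:, None]
    rank = np.linalg.matrix_rank(Xc)
    n_zero_cols = int((~Xc.any(axis=0)).sum())
    expected = Xc.shape[1] - n_zero_cols - (1 if as_enabled else 0)
    if rank < expected:
        singular = _singular_columns(Xc, ["intercept"] + columns)
        raise ModelError(f"rank-deficient design; singular columns: {singular}")
    reg = LinearRegression().fit(X, y, sample_weight=w)
    return LinearModel(
        intercept=float(reg.intercept_),
        coefficients={c: float(b) for c, b in zip(columns, reg.coef_)},
        training_meta=dict(training_meta or {}, n_rows=len(rows),
                           as_enabled=as_enabled),
    )


def _singular_columns(Xc: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (greedy scan)."""
    singular = []
    for j in range(Xc.shape[1]):
        reduced = np.delete(Xc, j, axis=1)
        if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(Xc):
            singular.append(names[j])
    return singular


def predict(model: LinearModel, rows: list[FeatureRow]) -> np.ndarray:
    """Apply the affine model: intercept + sum(coef * feature) per row."""
    as_enabled = model.training_meta.get("as_enabled", model.n_features > 3)
    try:
        X, columns, _, _ = design_matrix(rows, as_enabled)
    except FeatureError as exc:
        raise ModelError(f"feature schema mismatch: {exc}") from exc
    if columns != model.feature_names:
        missing = set(model.feature_names) - set(columns)
        extra = set(columns) - set(model.feature_names)
        raise ModelError(
            f"feature schema mismatch; missing={sorted(missing)}, "
            f"extra={sorted(extra)}"
        )
    beta = np.array([model.coefficients[c] for c in columns])
    return model.intercept + X @ beta
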