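"""Pretreatment chain for peak-area tables: normalise, centre, scale.

The fixed order is (1) normalisation of each sample to its total intensity
(compensating overall variability in extraction, injection, detection and
urine volume), (2) mean centring, (3) unit-variance scaling. Centring and
scaling statistics are always estimated on the training partition and reused
on held-out data, so cross-validation never leaks test-fold information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline

from .errors import ValidationError
from .tables import FeatureTable

__all__ = [
    "TotalIntensityNormalizer",
    "Autoscaler",
    "PreprocessConfig",
    "PreprocessState",
    "normalize_total_intensity",
    "autoscale",
    "make_preprocessor",
    "preprocess_table",
]


class TotalIntensityNormalizer(TransformerMixin, BaseEstimator):
    """Divide every sample row by its own total intensity (stateless)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        sums = X.sum(axis=1)
        bad = np.flatnonzero(sums <= 0)
        if bad.size:
            raise ValidationError(
                f"sample row(s) {bad.tolist()} have non-positive total intensity"
            )
        return X / sums[:, None]


class Autoscaler(TransformerMixin, BaseEstimator):
    """Mean centring and/or unit-variance scaling with sample (n-1) SDs.

    Zero-variance columns are mapped to all-zeros with a warning rather than
    erroring: label permutation and subsampling can legitimately create them.
    """

    def __init__(self, center: bool = True, scale: bool = True):
        self.center = center
        self.scale = scale

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.means_ = X.mean(axis=0)
        if X.shape[0] < 2:
            self.sds_ = np.zeros(X.shape[1])
        else:
            self.sds_ = X.std(axis=0, ddof=1)
        if self.scale and np.any(self.sds_ == 0):
            warnings.warn(
                f"{int((self.sds_ == 0).sum())} constant column(s) scaled to zero",
                stacklevel=2,
            )
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.means_.shape[0]:
            raise ValidationError(
                f"expected {self.means_.shape[0]} columns, got {X.shape[1]}"
            )
        out = X - self.means_ if self.center else X.copy()
        if self.scale:
            nonzero = self.sds_ > 0
            out[:, nonzero] /= self.sds_[nonzero]
            out[:, ~nonzero] = 0.0
        return out


@dataclass(frozen=True)
class PreprocessConfig:
    """Which pretreatment steps to apply (all on by default)."""

    normalize: bool = True
    center: bool = True
    scale: bool = True

    @classmethod
    def from_dict(cls, d: dict | None) -> "PreprocessConfig":
        return cls(**(d or {}))


@dataclass(frozen=True)
class PreprocessState:
    """Fit-time statistics, reusable on held-out partitions."""

    column_means: np.ndarray
    column_sds: np.ndarray
    applied_steps: tuple[str, ...] = field(default_factory=tuple)


def make_preprocessor(config: PreprocessConfig | None = None) -> Pipeline:
    """Sklearn pipeline applying the configured steps in the fixed order."""
    cfg = config or PreprocessConfig()
    steps: list[tuple[str, object]] = []
    if cfg.normalize:
        steps.append(("normalize", TotalIntensityNormalizer()))
    if cfg.center or cfg.scale:
        steps.append(("autoscale", Autoscaler(center=cfg.center, scale=cfg.scale)))
    if not steps:
        steps.append(("identity", "passthrough"))
    return Pipeline(steps)


def normalize_total_intensity(table: FeatureTable) -> FeatureTable:
    """Row-sum normalisation of a feature table; row sums become exactly 1."""
    sums = table.values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        names = [str(s) for s in table.sample_ids[bad]]
        raise ValidationError(f"sample(s) {names} have non-positive total intensity")
    return table.with_values(table.values / sums[:, None])


def autoscale(
    train: FeatureTable,
    apply_to: FeatureTable | None = None,
    state: PreprocessState | None = None,
) -> tuple[FeatureTable, PreprocessState]:
    """Centre and scale ``apply_to`` using statistics from ``train`` (or ``state``).

    When ``state`` is given it is reused verbatim (no refit); otherwise
    means and (n-1)-denominator SDs are estimated on ``train``. By default
    the transform is applied to ``train`` itself.
    """
    target = train if apply_to is None else apply_to
    scaler = Autoscaler()
    if state is not None:
        if len(state.column_means) != target.n_variables:
            raise ValidationError(
                f"state covers {len(state.column_means)} variables, "
                f"table has {target.n_variables}"
            )
        scaler.means_ = np.asarray(state.column_means, dtype=float)
        scaler.sds_ = np.asarray(state.column_sds, dtype=float)
    else:
        scaler.fit(train.values)
    out = target.with_values(scaler.transform(target.values))
    new_state = PreprocessState(
        column_means=scaler.means_.copy(),
        column_sds=scaler.sds_.copy(),
        applied_steps=("center", "scale"),
    )
    return out, new_state


def preprocess_table(
    table: FeatureTable, config: PreprocessConfig | None = None
) -> FeatureTable:
    """Apply the full configured chain to one table (fit == apply)."""
    prep = make_preprocessor(config)
    return table.with_values(prep.fit_transform(table.values))
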