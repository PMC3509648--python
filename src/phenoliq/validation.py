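"""Model validation: PRESS and Q² statistics, leave-one-out cross
validation, external-set validation, and y-scrambling.

PRESS is the sum of squared prediction errors, ``sum (yhat_i - y_i)^2``.
Q² compares PRESS with the spread of the observations around a reference
mean, ``Q² = 1 - PRESS / sum (y_i - ybar_ref)^2``; by default the reference
is the mean of the *training* responses for both internal and external
validation, so the two statistics share a common yardstick.  A flag on the
external validator switches to the validation-set mean, which for the
retention fixture moves Q²_ext only in the third decimal.

y-scrambling refits the model on permuted responses to bound chance
correlation: a sound model collapses to near-zero R² once the response is
shuffled, and the intercept of the R²-versus-|correlation| line stays small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .modeling import fit_ols

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationReport",
    "ScramblingReport",
    "ExternalSplit",
    "press",
    "q2",
    "loo_cv",
    "y_scramble",
    "external_validate",
    "ols_fitter",
]


class Fitter(Protocol):
    def __call__(self, X: pd.DataFrame, y: np.ndarray) -> object: ...


def ols_fitter(X: pd.DataFrame, y: np.ndarray):
    """Default fitter: standardized OLS (refit per fold / permutation)."""
    return fit_ols(X, y, standardize=True)


@dataclass
class ValidationReport:
    """PRESS/Q² summary plus the per-compound residual table."""

    press_value: float
    q2_value: float
    reference_mean: float
    reference_kind: str  # "train-mean" | "validation-mean" | "full-mean"
    table: pd.DataFrame  # columns: observed, predicted, residual
    label: str = ""

    def summary(self) -> dict:
        return {
            "label": self.label,
            "PRESS": self.press_value,
            "Q2": self.q2_value,
            "reference_mean": self.reference_mean,
            "reference_kind": self.reference_kind,
            "n": int(len(self.table)),
        }


@dataclass
class ExternalSplit:
    """Row labels for the train / test / validation partition.

    ``train`` holds every compound used to fit (for the neural networks it
    is further divided: ``test`` is the early-stopping subset and is a
    subset of ``train``); ``validation`` is the held-out external set.
    """

    train: list[str]
    test: list[str]
    validation: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.train) & set(self.validation)
        if overlap:
            raise ValueError(f"compounds in both train and validation: {sorted(overlap)}")
        if not set(self.test) <= set(self.train):
            raise ValueError("test subset must be contained in the training set")

    @classmethod
    def from_labels(cls, labels: pd.Series) -> "ExternalSplit":
        train = list(labels.index[labels.isin(["train", "test"])])
        test = list(labels.index[labels == "test"])
        validation = list(labels.index[labels == "validation"])
        return cls(train=train, test=test, validation=validation)


def press(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Predictive residual sum of squares."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1 or observed.size < 1:
        raise ValueError("observed and predicted must be equal-length 1-D arrays")
    return float(np.sum((predicted - observed) ** 2))


def q2(
    observed: Sequence[float],
    predicted: Sequence[float],
    reference_mean: float,
) -> float:
    """Q² = 1 - PRESS / sum (y_i - reference_mean)^2."""
    observed = np.asarray(observed, dtype=float)
    denom = float(np.sum((observed - reference_mean) ** 2))
    if denom == 0.0:
        raise ValueError("zero denominator: observations equal the reference mean")
    return 1.0 - press(observed, predicted) / denom


def loo_cv(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    fitter: Fitter = ols_fitter,
) -> ValidationReport:
    """Leave-one-out cross validation by explicit per-fold refitting.

    Each row is predicted by a model fitted on the remaining n-1 rows;
    PRESS_int and Q²_int use the full-sample mean as reference.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 rows")
    predictions = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            model = fitter(X.iloc[keep], y[keep])
        except Exception as exc:
            raise RuntimeError(f"fold {i} (left out {X.index[i]!r}) failed: {exc}") from exc
        predictions[i] = np.asarray(model.predict(X.iloc[[i]]))[0]
    reference = float(y.mean())
    table = pd.DataFrame(
        {"observed": y, "predicted": predictions, "residual": predictions - y},
        index=X.index,
    )
    return ValidationReport(
        press_value=press(y, predictions),
        q2_value=q2(y, predictions, reference),
        reference_mean=reference,
        reference_kind="full-mean",
        table=table,
        label="leave-one-out",
    )


def external_validate(
    predictions: pd.Series | np.ndarray,
    split: ExternalSplit,
    observed: pd.Series,
    reference: str = "train-mean",
    label: str = "",
) -> ValidationReport:
    """External validation: PRESS_ext and Q²_ext on the validation rows.

    ``predictions`` and ``observed`` are indexed by compound; the reference
    mean is the mean observed response of the training rows (default) or of
    the validation rows (``reference="validation-mean"``).
    """
    if not isinstance(predictions, pd.Series):
        predictions = pd.Series(np.asarray(predictions, dtype=float), index=observed.index)
    missing = [c for c in split.validation if c not in predictions.index]
    if missing:
        raise ValueError(f"predictions missing validation compounds: {missing}")
    obs_val = observed.loc[split.validation].to_numpy(dtype=float)
    pred_val = predictions.loc[split.validation].to_numpy(dtype=float)
    if reference == "train-mean":
        ref_mean = float(observed.loc[split.train].mean())
    elif reference == "validation-mean":
        ref_mean = float(obs_val.mean())
    else:
        raise ValueError("reference must be 'train-mean' or 'validation-mean'")
    table = pd.DataFrame(
        {"observed": obs_val, "predicted": pred_val, "residual": pred_val - obs_val},
        index=split.validation,
    )
    return ValidationReport(
        press_value=press(obs_val, pred_val),
        q2_value=q2(obs_val, pred_val, ref_mean),
        reference_mean=ref_mean,
        reference_kind=reference,
        table=table,
        label=label,
    )


@dataclass
class ScramblingReport:
    """Per-permutation scrambled-model quality and the diagnostic line fit."""

    n_permutations: int
    table: pd.DataFrame  # columns: r2_scrambled, abs_correlation
    slope: float
    intercept: float
    original_r2: float
    seed: int
    mean_scrambled_r2: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_scrambled_r2 = float(self.table["r2_scrambled"].mean())

    def summary(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "mean_scrambled_r2": self.mean_scrambled_r2,
            "slope": self.slope,
            "intercept": self.intercept,
            "original_r2": self.original_r2,
            "seed": self.seed,
        }


def y_scramble(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    fitter: Fitter = ols_fitter,
    n_permutations: int = 500,
    seed: int = 0,
) -> ScramblingReport:
    """Refit on permuted responses to quantify chance correlation.

    The descriptor subset is fixed (coefficients are refit per permutation;
    selection is *not* rerun).  For each permutation the scrambled model's
    R² and the absolute Pearson correlation between permuted and observed
    responses are recorded; a least-squares line of R² on |correlation| is
    fitted and its intercept reported — a small intercept means models built
    on noise carry no explanatory power.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations for a meaningful diagnostic")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)

    def model_r2(y_fit: np.ndarray) -> float:
        model = fitter(X, y_fit)
        pred = np.asarray(model.predict(X))
        sst = float(np.sum((y_fit - y_fit.mean()) ** 2))
        return 1.0 - float(np.sum((pred - y_fit) ** 2)) / sst

    original_r2 = model_r2(y)
    rows = []
    for _ in range(n_permutations):
        y_perm = rng.permutation(y)
        r = np.corrcoef(y_perm, y)[0, 1]
        rows.append({"r2_scrambled": model_r2(y_perm), "abs_correlation": abs(r)})
    table = pd.DataFrame(rows)
    slope, intercept = np.polyfit(table["abs_correlation"], table["r2_scrambled"], deg=1)
    return ScramblingReport(
        n_permutations=n_permutations,
        table=table,
        slope=float(slope),
        intercept=float(intercept),
        original_r2=original_r2,
        seed=seed,
    )
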