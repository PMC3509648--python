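"""Unsupervised forward selection (UFS) and stepwise multiple linear
regression (SMLR).

UFS builds a maximal subset of descriptor columns whose mutual squared
multiple correlation never exceeds ``r2max``: it seeds with the least
correlated column pair and then repeatedly admits the candidate with the
smallest squared multiple correlation against the span of the columns
already selected, permanently rejecting candidates above the threshold.
This removes redundancy and multicollinearity without looking at the
response.

SMLR is the classical forward-stepwise procedure with backward checks,
driven by partial-F thresholds (F-to-enter, F-to-remove).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .modeling import LinearModel, fit_ols

logger = logging.getLogger(__name__)

__all__ = ["UfsResult", "StepwiseStep", "StepwiseTrace", "ufs", "smlr"]

_RANK_TOL = 1e-10  # residual norm below which a column counts as dependent


@dataclass
class UfsResult:
    """Outcome of unsupervised forward selection."""

    selected: list[str]
    rejected: dict[str, float]  # name -> R^2 against selected span at rejection
    r2max: float
    dropped_constant: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class StepwiseStep:
    action: str  # "enter" | "remove"
    descriptor: str
    partial_f: float
    model_r2: float


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep]
    f_enter: float
    f_remove: float

    @property
    def selected(self) -> list[str]:
        current: list[str] = []
        for step in self.steps:
            if step.action == "enter":
                current.append(step.descriptor)
            else:
                current.remove(step.descriptor)
        return current


def _as_frame(matrix: DescriptorMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, DescriptorMatrix) else matrix


def ufs(matrix: DescriptorMatrix | pd.DataFrame, r2max: float = 0.90) -> UfsResult:
    """Unsupervised forward selection with threshold ``r2max``.

    Columns are centred and scaled to unit norm internally, so the squared
    multiple correlation of a candidate against the selected span is simply
    the squared norm of its projection onto an orthonormal basis of that
    span.  The basis is grown by modified Gram-Schmidt with
    re-orthogonalization; a candidate whose residual norm falls below 1e-10
    is treated as exactly dependent (R^2 = 1).  Ties are broken toward the
    lower original column index.
    """
    df = _as_frame(matrix)
    names = list(df.columns)
    X = df.to_numpy(dtype=float)
    n = X.shape[0]

    centred = X - X.mean(axis=0)
    norms = np.linalg.norm(centred, axis=0)
    scale = np.linalg.norm(X, axis=0) / np.sqrt(n)
    near_constant = norms < 1e-8 * np.maximum(scale * np.sqrt(n), 1.0)
    dropped = [names[j] for j in np.flatnonzero(near_constant)]
    usable = [j for j in range(len(names)) if not near_constant[j]]
    if len(usable) < 2:
        raise ValueError("UFS needs at least 2 non-constant columns")

    U = centred[:, usable] / norms[usable]
    usable_names = [names[j] for j in usable]

    # seed: the pair with the smallest absolute pairwise correlation
    corr = np.abs(U.T @ U)
    iu = np.triu_indices(len(usable), k=1)
    seed_flat = np.argmin(corr[iu])
    first, second = iu[0][seed_flat], iu[1][seed_flat]

    selected_idx: list[int] = []
    rejected: dict[str, float] = {}
    basis: list[np.ndarray] = []

    def admit(j: int) -> None:
        v = U[:, j].copy()
        for q in basis:
            v -= q @ v * q
        for q in basis:  # re-orthogonalization pass
            v -= q @ v * q
        basis.append(v / np.linalg.norm(v))
        selected_idx.append(j)

    admit(first)
    remaining = [j for j in range(len(usable)) if j != first]
    # the seed partner competes first but passes through the normal check
    remaining.remove(second)
    remaining.insert(0, second)

    while remaining:
        r2_values = np.empty(len(remaining))
        for k, j in enumerate(remaining):
            v = U[:, j].copy()
            for q in basis:
                v -= q @ v * q
            residual = np.linalg.norm(v)
            r2_values[k] = 1.0 if residual < _RANK_TOL else min(1.0, 1.0 - residual**2)
        over = r2_values > r2max
        for k in np.flatnonzero(over):
            rejected[usable_names[remaining[k]]] = float(r2_values[k])
        remaining = [j for k, j in enumerate(remaining) if not over[k]]
        r2_values = r2_values[~over]
        if not remaining:
            break
        # smallest R^2 wins; ties go to the lower original index
        best = min(range(len(remaining)), key=lambda k: (r2_values[k], remaining[k]))
        logger.debug("ufs: admit %s (R2=%.4f)", usable_names[remaining[best]], r2_values[best])
        admit(remaining.pop(best))

    return UfsResult(
        selected=[usable_names[j] for j in selected_idx],
        rejected=rejected,
        r2max=r2max,
        dropped_constant=dropped,
    )


# ---------------------------------------------------------------------------
# stepwise multiple linear regression
# ---------------------------------------------------------------------------

def _sse(X: np.ndarray, y: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def smlr(
    X: DescriptorMatrix | pd.DataFrame,
    y: np.ndarray | pd.Series,
    f_enter: float = 6.0,
    f_remove: float = 3.0,
) -> tuple[StepwiseTrace, LinearModel | None]:
    """Forward-stepwise regression with backward elimination.

    At each step the candidate with the largest partial F enters if its F is
    at least ``f_enter``; after every entry, included descriptors whose
    partial F has dropped below ``f_remove`` are removed (smallest first).
    Candidates that would make the design rank-deficient, or for which
    n <= p + 2, are refused.  Descriptors are standardized to zero mean and
    unit variance before fitting; the returned model retains the
    standardization parameters.  Returns ``(trace, model)``; the model is
    None when nothing entered.
    """
    df = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if len(df) != len(y):
        raise ValueError("X and y have different numbers of rows")
    n = len(y)
    names = list(df.columns)
    sd = df.std(ddof=1).replace(0.0, 1.0)
    Z = ((df - df.mean()) / sd).to_numpy(dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))

    steps: list[StepwiseStep] = []
    included: list[int] = []
    if sst == 0.0:
        return StepwiseTrace(steps=steps, f_enter=f_enter, f_remove=f_remove), None

    def model_sse(idx: list[int]) -> float:
        return _sse(Z[:, idx], y) if idx else sst

    max_passes = 4 * len(names) + 10  # guards against enter/remove cycling
    passes = 0
    while passes < max_passes:
        passes += 1
        changed = False
        # --- forward step
        sse_current = model_sse(included)
        if sse_current < 1e-10 * sst:
            break  # perfect fit up to roundoff; nothing left to explain
        best_f, best_j, best_sse = -np.inf, None, None
        for j in range(len(names)):
            if j in included:
                continue
            p_new = len(included) + 1
            if n <= p_new + 2:
                logger.info("smlr: refusing %s (n <= p+2)", names[j])
                continue
            candidate = included + [j]
            design = np.column_stack([np.ones(n), Z[:, candidate]])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                logger.info("smlr: refusing %s (rank-deficient design)", names[j])
                continue
            sse_new = model_sse(candidate)
            dof = n - p_new - 1
            improvement = sse_current - sse_new
            if sse_new < 1e-12 * sst:
                f_stat = np.inf if improvement > 1e-12 * sst else 0.0
            else:
                f_stat = improvement / (sse_new / dof)
            if f_stat > best_f:
                best_f, best_j, best_sse = f_stat, j, sse_new
        if best_j is not None and best_f >= f_enter:
            included.append(best_j)
            steps.append(
                StepwiseStep("enter", names[best_j], float(best_f), 1.0 - best_sse / sst)
            )
            changed = True

            # --- backward checks after each entry
            while len(included) > 1:
                sse_full = model_sse(included)
                dof = n - len(included) - 1
                partial = []
                for j in included:
                    reduced = [k for k in included if k != j]
                    sse_red = model_sse(reduced)
                    f_stat = (
                        np.inf
                        if sse_full <= 0
                        else (sse_red - sse_full) / (sse_full / dof)
                    )
                    partial.append((f_stat, j))
                f_min, j_min = min(partial)
                if f_min < f_remove:
                    included.remove(j_min)
                    sse_after = model_sse(included)
                    steps.append(
                        StepwiseStep("remove", names[j_min], float(f_min), 1.0 - sse_after / sst)
                    )
                else:
                    break
        if not changed:
            break

    trace = StepwiseTrace(steps=steps, f_enter=f_enter, f_remove=f_remove)
    if not included:
        return trace, None
    model = fit_ols(df.iloc[:, included], y, standardize=True)
    return trace, model
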