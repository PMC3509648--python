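"""End-to-end pipeline: pretreatment, selection, modelling, validation.

``run_pipeline`` chains the stages the retention study applies —
pretreat -> (UFS) -> SMLR -> OLS/ANN -> leave-one-out + external validation
+ y-scrambling — and writes CSV/JSON reports plus a run manifest into an
output directory.  Every numeric default equals the study's printed
setting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .descriptors import DescriptorMatrix, pretreat
from .modeling import AnnSearchSpace, sensitivity_ranking, train_ann_ensemble
from .selection import smlr, ufs
from .validation import (
    ExternalSplit,
    external_validate,
    loo_cv,
    y_scramble,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for a full run; defaults are the study's printed values."""

    min_variance: float = 0.0005
    constant_fraction: float = 0.5
    use_ufs: bool = True
    r2max: float = 0.90
    f_enter: float = 6.0
    f_remove: float = 3.0
    train_ann: bool = True
    n_networks: int = 500
    ann_hidden_range: tuple[int, int] = (3, 8)
    ann_decay: float = 0.01
    ann_max_iter: int = 300
    ann_select_on: str = "test"
    n_scrambles: int = 500
    seed: int = 0
    output_dir: str = "phenoliq_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ann_hidden_range"] = list(self.ann_hidden_range)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    selected_descriptors: list[str]
    summary: dict
    output_dir: Path
    stages: list[str] = field(default_factory=list)


def run_pipeline(
    matrix: DescriptorMatrix,
    response: pd.Series,
    split: pd.Series,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full workflow and write reports under ``config.output_dir``.

    ``split`` labels each compound "train", "test", or "validation"; models
    are fitted on the 'train'+'test' rows (the test rows only steer neural-
    network early stopping) and externally validated on the rest.
    """
    config = config or PipelineConfig()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    summary: dict = {"config": config.to_dict(), "versions": _versions()}

    ext_split = ExternalSplit.from_labels(split)
    fit_rows = split != "validation"
    X_all = matrix.data
    y_all = response

    # 1. pretreatment
    treated = pretreat(matrix, config.constant_fraction, config.min_variance)
    pd.Series(treated.pretreatment_flags, name="reason").rename_axis("descriptor").to_csv(
        out / "pretreatment.csv"
    )
    stages.append("pretreat")
    summary["pretreatment"] = {
        "kept": len(treated.descriptors),
        "removed": len(treated.pretreatment_flags),
    }

    # 2. optional UFS (unsupervised: uses fitting rows only)
    pool = treated.data.loc[fit_rows]
    if config.use_ufs:
        ufs_result = ufs(pool, r2max=config.r2max)
        pool = pool[ufs_result.selected]
        (out / "ufs_selected.txt").write_text("\n".join(ufs_result.selected) + "\n")
        stages.append("ufs")
        summary["ufs"] = {
            "selected": ufs_result.selected,
            "rejected": len(ufs_result.rejected),
            "r2max": config.r2max,
        }

    # 3. stepwise regression on the fitting rows
    y_fit = y_all.loc[fit_rows.index[fit_rows]].to_numpy(dtype=float)
    trace, linear_model = smlr(pool, y_fit, config.f_enter, config.f_remove)
    trace_frame = pd.DataFrame(
        [
            {"action": s.action, "descriptor": s.descriptor, "partial_F": s.partial_f, "model_R2": s.model_r2}
            for s in trace.steps
        ]
    )
    trace_frame.to_csv(out / "smlr_trace.csv", index=False)
    stages.append("smlr")
    if linear_model is None:
        raise RuntimeError("smlr: no descriptor met the F-to-enter threshold")
    selected = linear_model.descriptors
    summary["smlr"] = {
        "selected": selected,
        "R2": linear_model.r2,
        "coefficients": dict(zip(selected, linear_model.coef.tolist())),
        "intercept": linear_model.intercept,
    }

    X_sel_fit = treated.data.loc[fit_rows, selected]
    X_sel_all = treated.data[selected]

    # 4. validation of the linear model
    loo = loo_cv(X_sel_fit, y_fit)
    pred_all = pd.Series(linear_model.predict(X_sel_all), index=X_sel_all.index)
    ext = external_validate(pred_all, ext_split, y_all, label="linear")
    ext_val_mean = external_validate(
        pred_all, ext_split, y_all, reference="validation-mean", label="linear"
    )
    scramble = y_scramble(
        X_sel_fit, y_fit, n_permutations=config.n_scrambles, seed=config.seed
    )
    scramble.table.to_csv(out / "scrambling.csv", index=False)
    stages.extend(["loo", "external", "scramble"])
    summary["validation"] = {
        "PRESS_int": loo.press_value,
        "Q2_int": loo.q2_value,
        "PRESS_ext": ext.press_value,
        "Q2_ext_train_mean": ext.q2_value,
        "Q2_ext_validation_mean": ext_val_mean.q2_value,
        "scrambling": scramble.summary(),
    }
    residuals = pd.concat(
        [loo.table.assign(stage="loo"), ext.table.assign(stage="external")]
    )
    residuals.to_csv(out / "residuals.csv")

    # 5. neural-network ensemble on the selected descriptors
    if config.train_ann:
        space = AnnSearchSpace(
            hidden_range=config.ann_hidden_range,
            hidden_decay=config.ann_decay,
            output_decay=config.ann_decay,
            max_iter=config.ann_max_iter,
        )
        best, leaderboard = train_ann_ensemble(
            X_sel_all,
            y_all.to_numpy(dtype=float),
            split.to_numpy(),
            config=space,
            n_networks=config.n_networks,
            seed=config.seed,
            select_on=config.ann_select_on,
        )
        leaderboard.to_csv(out / "ann_leaderboard.csv", index=False)
        best.to_json(out / "ann_best.json")
        ann_pred = pd.Series(best.predict(X_sel_all), index=X_sel_all.index)
        ann_ext = external_validate(ann_pred, ext_split, y_all, label="ann")
        ranking = sensitivity_ranking(best, X_sel_fit, y_fit)
        ranking.to_csv(out / "ann_sensitivity.csv", index=False)
        stages.append("ann")
        summary["ann"] = {
            "n_hidden": best.n_hidden,
            "hidden_activation": best.hidden_activation,
            "output_activation": best.output_activation,
            "PRESS_ext": ann_ext.press_value,
            "Q2_ext": ann_ext.q2_value,
            "sensitivity_ranking": ranking["descriptor"].tolist(),
        }

    summary["stages"] = stages
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest = {
        "stages": stages,
        "seed": config.seed,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        config=config,
        selected_descriptors=selected,
        summary=summary,
        output_dir=out,
        stages=stages,
    )


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "phenoliq": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
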