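"""Embedded retention-time dataset and published model summaries.

The package ships the 39-compound phenolics table (experimental retention
times, the four models' predicted retention times, and the
train/test/validation membership) together with the published regression
equations, neural-network architectures, the UFS-selected descriptor list,
and the printed mean-polarizability values.  Compound structures are
curated SMILES assembled from the standard nomenclature of the 39 named
compounds — the original source prints names only — and are used for
descriptor demonstrations, never for re-deriving the published regression
coefficients.

``reproduce_paper_statistics`` recomputes training R², external PRESS, and
external Q² for each prediction column of the table and compares them with
the published numbers.  The comparison tolerances (±0.01 on PRESS, ±0.005
on R²/Q²) reflect that the stored predictions are rounded to 2 decimals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .chem import Molecule, embed_3d, molecule_from_smiles
from .validation import ExternalSplit, external_validate

__all__ = [
    "PhenolicsDataset",
    "PublishedModels",
    "load_fixture",
    "reproduce_paper_statistics",
    "PREDICTION_COLUMNS",
]

#: prediction column -> workflow label
PREDICTION_COLUMNS = {
    "pred_smlr": "SMLR",
    "pred_ufs_smlr": "UFS-SMLR",
    "pred_smlr_ann": "SMLR-ANN",
    "pred_ufs_smlr_ann": "UFS-SMLR-ANN",
}

# sha256 of the shipped data files; load_fixture refuses silently altered data
_CHECKSUMS = {
    "retention_dataset.csv": "e79a36542db9a32de8292ab29a861f838eef60c45eb6c706c682a1a1304af2c7",
    "structures.csv": "066c296a3bab5e1dcb4cf62815a2689391d6ffa8cd3ec004f45a5f5e04e670a8",
    "published_models.json": "117b89b7d9ba2187162ab13518d7060e1efc4d639734430b9dd376c19568d1d9",
}

# tolerances implied by 2-d.p. rounding of the stored predictions
TOLERANCES = {"R2": 0.005, "PRESS_ext": 0.01, "Q2_ext": 0.005}


@dataclass
class PhenolicsDataset:
    """The 39-compound retention table with split labels and structures."""

    table: pd.DataFrame  # indexed by compound name
    smiles: dict[str, str]
    structure_provenance: str = "curated"

    def __post_init__(self) -> None:
        if len(self.table) != 39:
            raise ValueError(f"expected 39 compounds, got {len(self.table)}")
        counts = self.table["split"].value_counts()
        if (counts.get("train", 0), counts.get("test", 0), counts.get("validation", 0)) != (25, 5, 9):
            raise ValueError(f"split sizes must be 25/5/9, got {counts.to_dict()}")
        rt = self.table["rt_exp"]
        if not ((rt > 1.0) & (rt < 7.0)).all():
            raise ValueError("experimental retention times outside (1, 7) minutes")

    @property
    def split(self) -> ExternalSplit:
        return ExternalSplit.from_labels(self.table["split"])

    @property
    def training_mean_rt(self) -> float:
        """Mean experimental RT over the 30 training compounds (minutes)."""
        labels = self.table["split"]
        return float(self.table.loc[labels != "validation", "rt_exp"].mean())

    def molecule(self, compound: str, embed: bool = False, seed: int = 2012) -> Molecule:
        """Build the curated structure of a compound (optionally embedded in 3D)."""
        mol = molecule_from_smiles(self.smiles[compound], name=compound)
        return embed_3d(mol, seed=seed) if embed else mol


@dataclass
class PublishedModels:
    """Published coefficient sets, ANN architectures, and printed statistics."""

    equations: dict[str, dict]
    ann: dict[str, dict]
    ufs_selected_descriptors: list[str]
    ufs_r2max: float
    mp_values: dict[str, float]
    scrambling_intercepts: dict[str, float]
    settings: dict[str, object] = field(default_factory=dict)

    def statistic(self, model: str, name: str) -> float:
        """Look up a printed statistic by (model key, statistic name)."""
        if model in self.equations:
            return float(self.equations[model]["stats"][name])
        if model in self.ann:
            return float(self.ann[model][name])
        raise KeyError(f"unknown model {model!r}")


def _read_bytes(filename: str) -> bytes:
    return resources.files("phenoliq.data").joinpath(filename).read_bytes()


def _verified_bytes(filename: str) -> bytes:
    raw = _read_bytes(filename)
    digest = hashlib.sha256(raw).hexdigest()
    expected = _CHECKSUMS[filename]
    if digest != expected:
        raise ValueError(
            f"checksum mismatch for {filename}: {digest} != {expected}; "
            "the shipped data file has been altered"
        )
    return raw


def load_fixture(verify_checksum: bool = True) -> tuple[PhenolicsDataset, PublishedModels]:
    """Load the embedded dataset and published-model summaries."""
    import io

    read = _verified_bytes if verify_checksum else _read_bytes
    table = pd.read_csv(io.BytesIO(read("retention_dataset.csv")), index_col="compound")
    structures = pd.read_csv(io.BytesIO(read("structures.csv")), index_col="compound")
    models_raw = json.loads(read("published_models.json").decode())
    dataset = PhenolicsDataset(
        table=table,
        smiles=structures["smiles"].to_dict(),
        structure_provenance=structures["provenance"].iloc[0],
    )
    published = PublishedModels(
        equations=models_raw["equations"],
        ann=models_raw["ann"],
        ufs_selected_descriptors=models_raw["ufs_selected_descriptors"],
        ufs_r2max=float(models_raw["ufs_r2max"]),
        mp_values=models_raw["mp_values"],
        scrambling_intercepts=models_raw["scrambling_intercepts"],
        settings=models_raw["settings"],
    )
    return dataset, published


#: (prediction column, statistic) -> published value lookup key
_PRINTED = {
    ("pred_smlr", "R2"): ("smlr_4", "R2"),
    ("pred_smlr", "PRESS_ext"): ("smlr_4", "PRESS_ext"),
    ("pred_smlr", "Q2_ext"): ("smlr_4", "Q2_ext"),
    ("pred_ufs_smlr", "R2"): ("ufs_smlr_5", "R2"),
    ("pred_ufs_smlr", "PRESS_ext"): ("ufs_smlr_5", "PRESS_ext"),
    ("pred_ufs_smlr", "Q2_ext"): ("ufs_smlr_5", "Q2_ext"),
    ("pred_smlr_ann", "PRESS_ext"): ("SMLR-ANN", "PRESS_ext"),
    ("pred_smlr_ann", "Q2_ext"): ("SMLR-ANN", "Q2_ext"),
    ("pred_ufs_smlr_ann", "PRESS_ext"): ("UFS-SMLR-ANN", "PRESS_ext"),
    ("pred_ufs_smlr_ann", "Q2_ext"): ("UFS-SMLR-ANN", "Q2_ext"),
}


def reproduce_paper_statistics(
    dataset: PhenolicsDataset | None = None,
    published: PublishedModels | None = None,
) -> pd.DataFrame:
    """Recompute every published statistic derivable from the stored table.

    For each prediction column: R² (1 - SSE/SST) over the 30 training rows,
    and PRESS_ext / Q²_ext over the 9 validation rows with the training-mean
    reference.  Returns a DataFrame with recomputed and printed values and a
    ``within_tolerance`` flag.
    """
    if dataset is None or published is None:
        dataset, published = load_fixture()
    table = dataset.table
    split = dataset.split
    observed = table["rt_exp"]
    train_rows = table["split"] != "validation"
    rows = []
    for column, workflow in PREDICTION_COLUMNS.items():
        pred = table[column]
        obs_tr = observed[train_rows].to_numpy()
        pred_tr = pred[train_rows].to_numpy()
        sse = float(np.sum((obs_tr - pred_tr) ** 2))
        sst = float(np.sum((obs_tr - obs_tr.mean()) ** 2))
        recomputed = {"R2": 1.0 - sse / sst}
        report = external_validate(pred, split, observed, label=workflow)
        recomputed["PRESS_ext"] = report.press_value
        recomputed["Q2_ext"] = report.q2_value
        for stat, value in recomputed.items():
            key = (column, stat)
            if key not in _PRINTED:
                continue
            model_key, stat_name = _PRINTED[key]
            printed = published.statistic(model_key, stat_name)
            rows.append(
                {
                    "model": workflow,
                    "statistic": stat,
                    "recomputed": value,
                    "printed": printed,
                    "within_tolerance": bool(abs(value - printed) <= TOLERANCES[stat]),
                }
            )
    return pd.DataFrame(rows)
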