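"""Molecular descriptors used in the retention models, plus matrix assembly
and pretreatment.

Implemented families
--------------------
HNar
    Narumi harmonic topological index: the harmonic mean of heavy-atom
    vertex degrees, ``A / sum_i(1/delta_i)``.  Sensitive to branching.
IDM
    Mean information content on the distance magnitude: the Shannon entropy
    (bits) of the upper-triangle topological distances, each distance
    weighted by its share of the Wiener index.
Mp
    Mean atomic polarizability scaled on carbon, averaged over *all* atoms
    including hydrogens.
GATS (Geary autocorrelation)
    Geary spatial autocorrelation of an atomic property on the
    hydrogen-suppressed graph at a fixed topological lag.
DISP (COMMA2 displacement)
    Euclidean distance (Angstrom) between the geometric centroid and the
    property-weighted centroid; all atoms including hydrogens.
3D-MoRSE
    Property-weighted sum of sinc terms of interatomic distances,
    ``sum_{i<j} w_i w_j sin(s r_ij)/(s r_ij)``.  Signal number k corresponds
    to scattering parameter s = k - 1 (1/Angstrom), 32 signals in total;
    ``sin(0)/0`` is taken as 1.

Descriptor columns are named with the conventional codes (``GATS2v``,
``Mor32e``, ``DISPm``...), so selected subsets map directly onto the
published model equations.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import (
    Molecule,
    WeightScheme,
    get_weight_scheme,
    heavy_atom_graph,
    weight_vector,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorMatrix",
    "hnar",
    "idm",
    "mp",
    "gats",
    "geary_autocorrelation",
    "disp",
    "morse",
    "compute_matrix",
    "pretreat",
    "parse_descriptor_name",
    "PAPER_DESCRIPTORS",
    "MODEL_DESCRIPTORS",
]

#: descriptors appearing in the published equations
MODEL_DESCRIPTORS = [
    "HNar", "IDM", "Mp", "GATS2v", "DISPe", "DISPm", "Mor22v", "Mor28e", "Mor32e",
]
PAPER_DESCRIPTORS = MODEL_DESCRIPTORS


@dataclass
class DescriptorMatrix:
    """Compounds x named descriptors, with per-column pretreatment flags."""

    data: pd.DataFrame
    pretreatment_flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor columns: {dupes}")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValueError("descriptor matrix contains non-finite values")

    @property
    def compounds(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptors(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# individual descriptors
# ---------------------------------------------------------------------------

def hnar(mol: Molecule) -> float:
    """Narumi harmonic topological index over the heavy-atom graph."""
    _, degrees = heavy_atom_graph(mol)
    if np.any(degrees == 0):
        raise ValueError("HNar undefined: isolated heavy atom (zero degree)")
    return len(degrees) / float(np.sum(1.0 / degrees))


def idm(mol: Molecule) -> float:
    """Mean information content on the distance magnitude (bits).

    With W the Wiener index (sum of upper-triangle topological distances),
    each distance d contributes -(d/W) log2(d/W).
    """
    dm, _ = heavy_atom_graph(mol)
    a = dm.heavy_atom_count
    if a < 2:
        raise ValueError("IDM requires at least two heavy atoms")
    iu = np.triu_indices(a, k=1)
    d = dm.entries[iu].astype(float)
    w = d.sum()
    p = d / w
    return float(-(p * np.log2(p)).sum())


def mp(mol: Molecule) -> float:
    """Mean carbon-scaled atomic polarizability over all atoms (H included)."""
    weights = weight_vector(mol, "p", include_h=True)
    return float(weights.mean())


def geary_autocorrelation(
    distances: np.ndarray, weights: np.ndarray, lag: int
) -> float | None:
    """Geary coefficient of ``weights`` on a graph with the given topological
    distance matrix, at ``lag``.  Returns None when no vertex pair sits at
    the lag or the weights have zero variance (the statistic is undefined).
    """
    w = np.asarray(weights, dtype=float)
    a = len(w)
    mask = np.asarray(distances) == lag
    np.fill_diagonal(mask, False)
    n_pairs = int(mask.sum()) // 2  # unordered pairs at this lag
    variance = float(np.sum((w - w.mean()) ** 2)) / (a - 1)
    if n_pairs == 0 or variance == 0.0:
        return None
    diff2 = (w[:, None] - w[None, :]) ** 2
    # ordered sum over pairs at the lag, normalized by 2 * (unordered pair count)
    numerator = float(diff2[mask].sum()) / (2.0 * n_pairs)
    return numerator / variance


def gats(mol: Molecule, lag: int, scheme: WeightScheme | str) -> float:
    """Geary autocorrelation at a topological lag on the heavy-atom graph.

    Degenerate cases (no atom pair at the lag, or zero weight variance)
    return 0 with a warning rather than NaN, so descriptor matrices remain
    finite for downstream selection.
    """
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    dm, _ = heavy_atom_graph(mol)
    w = weight_vector(mol, scheme, include_h=False)
    value = geary_autocorrelation(dm.entries, w, lag)
    if value is None:
        warnings.warn(f"GATS{lag} degenerate for {mol.name!r}; returning 0")
        return 0.0
    return value


def disp(mol: Molecule, scheme: WeightScheme | str) -> float:
    """Displacement between geometric and property-weighted centers (Angstrom)."""
    coords = mol.coordinates()
    w = weight_vector(mol, scheme, include_h=True)
    weighted_center = (w[:, None] * coords).sum(axis=0) / w.sum()
    centroid = coords.mean(axis=0)
    return float(np.linalg.norm(weighted_center - centroid))


def morse(mol: Molecule, signal: int, scheme: WeightScheme | str) -> float:
    """3D-MoRSE signal: sum over atom pairs of w_i w_j sinc(s r_ij).

    ``signal`` runs 1..32; the scattering parameter is s = signal - 1 in
    1/Angstrom (signal 1 is the s = 0 limit, where every sinc term is 1).
    """
    if not 1 <= signal <= 32:
        raise ValueError(f"MoRSE signal must be in 1..32, got {signal}")
    s = float(signal - 1)
    coords = mol.coordinates()
    w = weight_vector(mol, scheme, include_h=True)
    iu = np.triu_indices(len(w), k=1)
    rij = np.linalg.norm(coords[iu[0]] - coords[iu[1]], axis=1)
    if s == 0.0:
        sinc = np.ones_like(rij)
    else:
        sinc = np.sin(s * rij) / (s * rij)
    return float((w[iu[0]] * w[iu[1]] * sinc).sum())


# ---------------------------------------------------------------------------
# descriptor-name registry
# ---------------------------------------------------------------------------

_GATS_RE = re.compile(r"^GATS(\d+)([umvep])$")
_MORSE_RE = re.compile(r"^Mor(\d+)([umvep])$")
_DISP_RE = re.compile(r"^DISP([mvep])$")


def parse_descriptor_name(name: str) -> Callable[[Molecule], float]:
    """Map a descriptor code (e.g. ``GATS2v``) to its computing function."""
    if name == "HNar":
        return hnar
    if name == "IDM":
        return idm
    if name == "Mp":
        return mp
    m = _GATS_RE.match(name)
    if m:
        lag, code = int(m.group(1)), m.group(2)
        return lambda mol: gats(mol, lag, code)
    m = _MORSE_RE.match(name)
    if m:
        signal, code = int(m.group(1)), m.group(2)
        return lambda mol: morse(mol, signal, code)
    m = _DISP_RE.match(name)
    if m:
        code = m.group(1)
        return lambda mol: disp(mol, code)
    raise ValueError(f"unknown descriptor name {name!r}")


def compute_matrix(
    mols: Sequence[Molecule], spec: Iterable[str]
) -> DescriptorMatrix:
    """Compute a compounds x descriptors matrix in request order.

    Duplicate requests collapse to a single column (with a warning); a
    failure in any cell raises an error naming the compound and descriptor.
    """
    mols = list(mols)
    if not mols:
        raise ValueError("empty molecule list")
    names: list[str] = []
    for name in spec:
        if name in names:
            warnings.warn(f"duplicate descriptor request {name!r}; keeping one column")
            continue
        names.append(name)
    if not names:
        raise ValueError("empty descriptor request")
    funcs = {name: parse_descriptor_name(name) for name in names}
    rows = []
    labels = []
    for k, mol in enumerate(mols):
        label = mol.name or f"mol{k}"
        row = []
        for name in names:
            try:
                value = funcs[name](mol)
            except Exception as exc:
                raise RuntimeError(
                    f"descriptor {name!r} failed for compound {label!r}: {exc}"
                ) from exc
            row.append(value)
            logger.debug("descriptor %s(%s) = %.6g", name, label, value)
        rows.append(row)
        labels.append(label)
    frame = pd.DataFrame(rows, index=labels, columns=names, dtype=float)
    return DescriptorMatrix(data=frame)


# ---------------------------------------------------------------------------
# pretreatment
# ---------------------------------------------------------------------------

def pretreat(
    matrix: DescriptorMatrix,
    constant_fraction: float = 0.5,
    min_variance: float = 0.0005,
) -> DescriptorMatrix:
    """Remove uninformative columns before selection.

    A column is dropped when (a) it is identically zero, (b) a single value
    occupies at least ``constant_fraction`` of the rows, or (c) its sample
    variance (n-1 denominator, raw values) is below ``min_variance``.
    Removal reasons are recorded in ``pretreatment_flags``.
    """
    df = matrix.data
    if df.empty:
        raise ValueError("empty descriptor matrix")
    n = len(df)
    flags: dict[str, str] = {}
    for col in df.columns:
        values = df[col].to_numpy(dtype=float)
        if np.all(values == 0.0):
            flags[col] = "zero"
        elif pd.Series(values).value_counts().iloc[0] / n >= constant_fraction:
            flags[col] = f"constant-{constant_fraction:.0%}"
        elif n > 1 and float(np.var(values, ddof=1)) < min_variance:
            flags[col] = f"variance<{min_variance}"
    kept = [c for c in df.columns if c not in flags]
    if not kept:
        raise ValueError("pretreatment removed every column")
    for col, reason in flags.items():
        logger.info("pretreat: dropping %s (%s)", col, reason)
    return DescriptorMatrix(data=df[kept].copy(), pretreatment_flags=flags)
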