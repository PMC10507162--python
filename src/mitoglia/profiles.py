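"""Six-metric per-cell profiles and their principal component analysis.

The profile holds, per cell: Sholl index, % CD68 volume, median mitochondrial
volume, number of mitochondria, % mitochondrial volume, and % perinuclear
mitochondria.  Sphericity is excluded because it is derived from volume, and
the largest-organelle volume is reported separately.  Features are z-scored
before the eigendecomposition — the six metrics mix μm³, counts and
percentages, so covariance PCA would be dominated by scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core_io import DomainError, is_undefined

logger = logging.getLogger("mitoglia")

#: Feature order of the profile matrix (fixed, used everywhere downstream).
METRIC_NAMES = [
    "sholl_index",
    "pct_cd68_volume",
    "median_mito_volume",
    "n_mito",
    "pct_mito_volume",
    "perinuclear_pct",
]

LABEL_NAMES = ["genotype", "condition", "sex", "group"]


@dataclass
class PcaResult:
    scores: np.ndarray                  # cells × k
    loadings: np.ndarray                # features × k, unit-norm columns
    explained_variance_ratio: np.ndarray
    metric_names: list[str]


def assemble_profiles(cells: list[dict]) -> pd.DataFrame:
    """Build the labeled cells × 6 profile matrix.

    Each entry needs the six METRIC_NAMES keys plus ``cell_id`` and any group
    labels.  Cells with an undefined (NaN/None) metric are excluded and the
    reason logged — typically cells with zero mitochondria.
    """
    rows = []
    for cell in cells:
        missing = [m for m in METRIC_NAMES if is_undefined(cell.get(m))]
        if missing:
            logger.info(
                "excluding cell %s from PCA: undefined %s",
                cell.get("cell_id", "?"), ", ".join(missing),
            )
            continue
        row = {"cell_id": cell.get("cell_id", "")}
        for m in METRIC_NAMES:
            row[m] = float(cell[m])
        for lab in LABEL_NAMES:
            if lab in cell:
                row[lab] = cell[lab]
        rows.append(row)
    if not rows:
        raise DomainError("no cells with complete profiles")
    df = pd.DataFrame(rows)
    n_excluded = len(cells) - len(rows)
    if n_excluded:
        logger.info("excluded %d of %d cells with incomplete profiles", n_excluded, len(cells))
    return df


def collect_cell_features(cells, radius: float = 10.0, bin_width: float = 10.0) -> pd.DataFrame:
    """One tidy row per cell: all metrics plus the Sholl index and labels.

    Cells without a filament tracing get an undefined (NaN) Sholl index; the
    sphericity and largest-volume columns are carried for group statistics
    but are not part of the PCA feature set.
    """
    from .morphometrics import compute_cell_metrics
    from .sholl import sholl_curve, sholl_index

    rows = []
    for cell in cells:
        m = compute_cell_metrics(cell, radius=radius, bin_width=bin_width)
        if cell.filament is not None:
            curve = sholl_curve(cell.filament, center=cell.soma_center)
            s_index = sholl_index(curve)
        else:
            s_index = float("nan")
        rows.append({
            "cell_id": cell.cell_id,
            "genotype": cell.genotype,
            "condition": cell.condition,
            "sex": cell.sex,
            "group": cell.group or cell.condition,
            "sholl_index": s_index,
            "pct_cd68_volume": m.pct_cd68_volume,
            "median_mito_volume": m.median_mito_volume,
            "n_mito": m.n_mito,
            "pct_mito_volume": m.pct_mito_volume,
            "perinuclear_pct": m.perinuclear_pct,
            "mean_sphericity": m.mean_sphericity,
            "largest_mito_volume": m.largest_mito_volume,
        })
    return pd.DataFrame(rows)


def standardize(X: np.ndarray, metric_names: list[str] | None = None) -> np.ndarray:
    """Z-score columns; a zero-variance column is an error naming the metric."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = (
            ", ".join(metric_names[i] for i in zero) if metric_names
            else ", ".join(str(i) for i in zero)
        )
        raise DomainError(f"zero-variance metric(s): {names}")
    return (X - mu) / sd


def run_pca(
    profiles: np.ndarray | pd.DataFrame,
    k: int = 2,
    metric_names: list[str] | None = None,
) -> PcaResult:
    """PCA of the standardized profile matrix.

    Columns are z-scored, then decomposed; scores are the standardized data
    projected on the unit-norm loading vectors.  Signs are fixed so that each
    loading column's largest-magnitude entry is positive.
    """
    if isinstance(profiles, pd.DataFrame):
        metric_names = [c for c in profiles.columns if c in METRIC_NAMES] or list(profiles.columns)
        X = profiles[metric_names].to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        if metric_names is None:
            metric_names = [f"m{i}" for i in range(X.shape[1])]
    if X.shape[0] < k + 1:
        raise DomainError(f"need at least {k + 1} cells for k={k} components")
    Xs = standardize(X, metric_names)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Xs)
    loadings = pca.components_.T.copy()  # features × k
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        metric_names=list(metric_names),
    )
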