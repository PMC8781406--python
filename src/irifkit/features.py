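"""Per-focus and per-nucleus morphometry of segmented repair foci.

Feature definitions:

* focus volume = voxel count x physical voxel volume (µm³),
* normalized focus intensity = mean over the focus voxels of
  ``channel value / 99th percentile of the channel over the whole nucleus``
  (scale-free: invariant to multiplying a channel by a positive constant),
* occupied fraction = total focus volume / nucleus volume x 100 (%),
* colocalization = Pearson correlation between the two channel values over
  the union of a nucleus's segmented focus voxels ("inner pixels"); it is
  undefined (reported missing, never 0) when fewer than two focus voxels
  exist or either channel is constant over them.

The per-nucleus feature matrix feeds a PCA biplot; features are
standardized to unit variance by default because they mix counts, volumes,
percentages and correlations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.decomposition import PCA

from irifkit.stack_io import LabelMap, VolumeStack

logger = logging.getLogger(__name__)

FOCUS_COLUMNS = [
    "nucleus_id", "focus_id", "volume_um3",
    "mean_norm_intensity_A", "mean_norm_intensity_B",
    "centroid_z_um", "centroid_y_um", "centroid_x_um",
]
NUCLEUS_COLUMNS = [
    "nucleus_id", "n_foci", "nucleus_volume_um3", "occupied_fraction_pct",
    "coloc_pearson",
]


def _percentile99(values: np.ndarray) -> float:
    # linear-interpolation definition, fixed for determinism
    return float(np.percentile(values, 99, method="linear"))


def extract_features(
    stack: VolumeStack,
    nuclei: LabelMap,
    foci: LabelMap,
    channels: tuple[str, str] = ("chA", "chB"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the focus-level and nucleus-level feature tables.

    Every focus label must lie entirely inside a single nucleus label
    (a focus spanning two nuclei violates the nesting invariant and is an
    error). Returns ``(focus_table, nucleus_table)``.
    """
    chA = np.asarray(stack.channel(channels[0]), dtype=float)
    chB = np.asarray(stack.channel(channels[1]), dtype=float)
    nuc = nuclei.labels
    foc = foci.labels
    if nuc.shape != foc.shape:
        raise ValueError("nucleus and focus label maps must share a shape")
    voxel_volume = nuclei.voxel_volume
    dz, dy, dx = nuclei.voxel_size

    n_nuclei = int(nuc.max())
    p99 = {}
    nucleus_voxels = {}
    for nid in range(1, n_nuclei + 1):
        m = nuc == nid
        nucleus_voxels[nid] = int(m.sum())
        if nucleus_voxels[nid]:
            p99[nid] = (
                max(_percentile99(chA[m]), np.finfo(float).eps),
                max(_percentile99(chB[m]), np.finfo(float).eps),
            )

    focus_rows = []
    for fid in range(1, int(foc.max()) + 1):
        m = foc == fid
        n_vox = int(m.sum())
        if n_vox == 0:
            continue
        owners = np.unique(nuc[m])
        owners = owners[owners > 0]
        if len(owners) != 1 or (nuc[m] == 0).any():
            raise ValueError(
                f"focus {fid} is not nested in a single nucleus (touches {sorted(owners)})"
            )
        nid = int(owners[0])
        zz, yy, xx = np.nonzero(m)
        focus_rows.append(
            {
                "nucleus_id": nid,
                "focus_id": fid,
                "volume_um3": n_vox * voxel_volume,
                "mean_norm_intensity_A": float(np.mean(chA[m] / p99[nid][0])),
                "mean_norm_intensity_B": float(np.mean(chB[m] / p99[nid][1])),
                "centroid_z_um": float((zz.mean() + 0.5) * dz),
                "centroid_y_um": float((yy.mean() + 0.5) * dy),
                "centroid_x_um": float((xx.mean() + 0.5) * dx),
            }
        )
    focus_table = pd.DataFrame(focus_rows, columns=FOCUS_COLUMNS)

    coloc = coloc_pearson(stack, nuclei, foci, channels=channels)
    nucleus_rows = []
    for nid in range(1, n_nuclei + 1):
        if nucleus_voxels[nid] == 0:
            continue
        sub = focus_table[focus_table["nucleus_id"] == nid]
        nucleus_volume = nucleus_voxels[nid] * voxel_volume
        nucleus_rows.append(
            {
                "nucleus_id": nid,
                "n_foci": int(len(sub)),
                "nucleus_volume_um3": nucleus_volume,
                "occupied_fraction_pct": float(sub["volume_um3"].sum() / nucleus_volume * 100.0),
                "coloc_pearson": coloc.get(nid, np.nan),
            }
        )
    nucleus_table = pd.DataFrame(nucleus_rows, columns=NUCLEUS_COLUMNS)
    return focus_table, nucleus_table


def coloc_pearson(
    stack: VolumeStack,
    nuclei: LabelMap,
    foci: LabelMap,
    channels: tuple[str, str] = ("chA", "chB"),
) -> dict[int, float]:
    """Per-nucleus Pearson correlation of the two channels over focus voxels.

    Undefined correlations (fewer than 2 focus voxels, or zero variance in
    either channel) are reported as NaN, not 0.
    """
    chA = np.asarray(stack.channel(channels[0]), dtype=float)
    chB = np.asarray(stack.channel(channels[1]), dtype=float)
    nuc = nuclei.labels
    inner = foci.labels > 0
    out: dict[int, float] = {}
    for nid in range(1, int(nuc.max()) + 1):
        m = inner & (nuc == nid)
        if m.sum() < 2:
            out[nid] = np.nan
            continue
        a, b = chA[m], chB[m]
        if np.std(a) == 0 or np.std(b) == 0:
            out[nid] = np.nan
            continue
        out[nid] = float(np.corrcoef(a, b)[0, 1])
    return out


def pca_biplot(
    records: pd.DataFrame,
    feature_columns: list[str] | None = None,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the per-nucleus feature matrix for biplot display.

    Rows with any missing value are dropped (listwise deletion, logged).
    Returns ``(scores, loadings, explained_variance_fractions)`` where
    ``loadings`` has one orthonormal column per component and the fractions
    are non-increasing and sum to 1 over all components.
    """
    if feature_columns is None:
        feature_columns = [c for c in records.columns if c != "nucleus_id"]
    X = records[feature_columns].to_numpy(dtype=float)
    keep = np.isfinite(X).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("PCA: dropped %d row(s) with missing values", n_dropped)
    X = X[keep]
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 complete rows and 2 features")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [feature_columns[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant feature(s) cannot be standardized: {bad}")
        X = (X - X.mean(axis=0)) / sd
    n_components = min(X.shape)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # (n_features, n_components), orthonormal columns
    fractions = pca.explained_variance_ratio_
    return scores, loadings, fractions
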