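"""PCA of gene-usage vectors and distance summaries on the PC1-PC2 plane.

PCA is column-centered and unscaled (frequencies already share a scale),
matching the R ``prcomp`` default; component signs follow a deterministic
convention (the largest-magnitude loading of each component is positive).
Two distance summaries describe repertoire structure: each sample's
Euclidean distance to its nearest neighbor of the same tissue, and the
distance between a patient's paired samples from two tissues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["PCAResult", "pca_usage", "tissue_distances"]


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # genes x components
    explained_variance_ratio: np.ndarray


def pca_usage(usage: pd.DataFrame, n_components: int | None = None,
              scale: bool = False) -> PCAResult:
    """Principal components of a samples x genes usage matrix."""
    if usage.shape[0] < 2 or usage.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 genes")
    x = usage.to_numpy(dtype=float)
    if np.allclose(x.var(axis=0), 0.0):
        raise ValueError("constant matrix has no variance to decompose")
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    k = min(n_components or min(x.shape) - 0, usage.shape[0] - 1, usage.shape[1])
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T  # genes x components
    # sign convention: largest-|loading| entry of each component positive
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=usage.index, columns=cols),
        loadings=pd.DataFrame(loadings, index=usage.columns, columns=cols),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def tissue_distances(scores: pd.DataFrame, tissues: pd.Series,
                     patients: pd.Series,
                     pair: tuple[str, str] = ("PBMC", "tumor"),
                     components: tuple[str, str] = ("PC1", "PC2"),
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nearest-neighbor-within-tissue and paired between-tissue distances.

    ``scores`` rows, ``tissues`` and ``patients`` are aligned by position.
    Returns ``(nn_within, paired_between)``; samples from a singleton tissue
    get a flagged NaN nearest-neighbor distance.
    """
    pts = scores[list(components)].to_numpy(dtype=float)
    tissues = np.asarray(tissues)
    patients = np.asarray(patients)

    nn_rows = []
    for i in range(len(pts)):
        same = np.flatnonzero((tissues == tissues[i]))
        same = same[same != i]
        if same.size == 0:
            nn_rows.append({"sample": scores.index[i], "tissue": tissues[i],
                            "patient_id": patients[i], "nn_distance": np.nan,
                            "flagged": True})
            continue
        d = np.linalg.norm(pts[same] - pts[i], axis=1)
        nn_rows.append({"sample": scores.index[i], "tissue": tissues[i],
                        "patient_id": patients[i], "nn_distance": float(d.min()),
                        "flagged": False})
    nn_within = pd.DataFrame(nn_rows)

    a, b = pair
    paired_rows = []
    for patient in np.unique(patients):
        ia = np.flatnonzero((patients == patient) & (tissues == a))
        ib = np.flatnonzero((patients == patient) & (tissues == b))
        if ia.size == 1 and ib.size == 1:
            d = float(np.linalg.norm(pts[ia[0]] - pts[ib[0]]))
            paired_rows.append({"patient_id": patient, "tissue_a": a,
                                "tissue_b": b, "distance": d})
    paired_between = pd.DataFrame(paired_rows)
    return nn_within, paired_between
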