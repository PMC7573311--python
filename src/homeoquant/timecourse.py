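"""Time-course statistics: expression gating, PCA, and variably expressed
homeolog (VEH) detection.

A homeolog counts as expressed when its FPKM strictly exceeds 1.0 at one or
more time points. All downstream statistics work on log10(FPKM + 1). PCA is
run on the sample x homeolog matrix (samples = sample set x time point),
column-centered only, via singular value decomposition with a fixed sign
convention. A VEH is a homeolog whose log-scale time series has mean > 1.0
and coefficient of variation (sd/mean) > 0.20 — the CV criterion picks up
variability over the course without assuming any particular trajectory
shape, which pairwise differential tests on autocorrelated time points
cannot do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

EXPRESSED_FPKM = 1.0
VEH_MEAN_MIN = 1.0
VEH_CV_MIN = 0.20


def gate_expressed(fpkm_matrix: pd.DataFrame,
                   threshold: float = EXPRESSED_FPKM) -> pd.Index:
    """Homeologs with max FPKM strictly above ``threshold`` at >= 1 time
    point (exactly 1.0 does not pass)."""
    if fpkm_matrix.empty:
        raise ValueError("empty FPKM matrix")
    mx = fpkm_matrix.max(axis=1)
    return fpkm_matrix.index[mx > threshold]


def log_transform(fpkm):
    """Elementwise log10(FPKM + 1); rejects negative input."""
    arr = np.asarray(fpkm, dtype=float)
    if (arr < 0).any():
        raise ValueError("FPKM values must be non-negative")
    if isinstance(fpkm, (pd.DataFrame, pd.Series)):
        return np.log10(fpkm + 1.0)
    return np.log10(arr + 1.0)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # features x components
    explained_variance_ratio: np.ndarray


def stack_sample_sets(log_matrices: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-sample-set log matrices (gene x time) into one
    sample x gene matrix with rows like ``I_A:t24``, restricted to the genes
    shared by all sets so homeolog pairs stay matched."""
    shared = None
    for df in log_matrices.values():
        idx = set(df.index)
        shared = idx if shared is None else shared & idx
    shared = sorted(shared or ())
    rows, names = [], []
    for label in log_matrices:
        df = log_matrices[label].loc[shared]
        for t in df.columns:
            rows.append(df[t].values)
            names.append(f"{label}:t{t:g}" if not isinstance(t, str)
                         else f"{label}:{t}")
    return pd.DataFrame(rows, index=names, columns=shared)


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of a sample x feature matrix by SVD of the column-centered data.

    No variance scaling is applied. The sign of each component is fixed by
    making its largest-magnitude loading positive, so scores reproduce
    exactly across reruns.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.values.astype(float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = n_components or min(x.shape)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u * s
    var = s**2
    total_var = (x**2).sum()
    ratio = var / total_var if total_var > 0 else np.zeros_like(var)
    comps = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=matrix.columns, columns=comps),
        explained_variance_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# VEH detection
# ---------------------------------------------------------------------------

def detect_veh(fpkm_matrix: pd.DataFrame, mean_min: float = VEH_MEAN_MIN,
               cv_min: float = VEH_CV_MIN, ddof: int = 1,
               expressed_threshold: float = EXPRESSED_FPKM) -> pd.DataFrame:
    """Per-homeolog VEH table from a gene x time FPKM matrix.

    Mean and CV are taken over log10(FPKM+1) across time points; both
    thresholds are strict inequalities and order-free, so the call does not
    depend on time-point ordering. The sample standard deviation (ddof=1) is
    used by default. Homeologs with zero mean have no defined CV and are
    flagged, never called.
    """
    logm = log_transform(fpkm_matrix)
    mean = logm.mean(axis=1)
    sd = logm.std(axis=1, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = pd.Series(np.where(mean > 0, sd / mean.replace(0, np.nan), np.nan),
                       index=mean.index)
    cv_undefined = ~(mean > 0)
    is_expressed = fpkm_matrix.max(axis=1) > expressed_threshold
    is_veh = is_expressed & (mean > mean_min) & (cv > cv_min) & ~cv_undefined
    return pd.DataFrame({
        "mean_log": mean, "cv": cv, "is_expressed": is_expressed,
        "cv_undefined": cv_undefined, "is_veh": is_veh,
    })
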