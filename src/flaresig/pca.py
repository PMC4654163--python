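"""PCA of normalised expression with factor-loading gene ranking.

Assays are the observations and genes the variables. The decomposition is an
SVD of the gene-centred (optionally unit-scaled) assay-by-gene matrix, with a
deterministic sign convention: the largest-magnitude loading of every
component is made positive, because factor-loading plots are sign-sensitive.
``top_loading_genes`` reproduces the top-k (default 20) genes by absolute PC1
loading; ``cluster_separation`` turns qualitative score-plot clustering into
a mean silhouette number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .io import SampleTable, ValidationError
from .normalization import ExpressionMatrix

__all__ = ["PCAResult", "run_pca", "top_loading_genes", "cluster_separation"]


@dataclass
class PCAResult:
    scores: pd.DataFrame           # assays x components
    loadings: pd.DataFrame         # genes x components
    variance_fraction: np.ndarray  # per component
    centered: bool = True
    scaled: bool = False

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(expr: ExpressionMatrix, center: bool = True,
            scale: bool = False) -> PCAResult:
    """Principal components of the assay-by-gene expression matrix."""
    values = expr.values
    if values.shape[1] < 2 or values.shape[0] < 2:
        raise ValidationError("PCA needs >=2 assays and >=2 genes")
    X = values.to_numpy(dtype=float).T  # assays x genes
    if np.isnan(X).any():
        raise ValidationError("PCA input contains missing values")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            gene = values.index[np.flatnonzero(sd == 0)[0]]
            raise ValidationError(
                f"gene {gene!r} is constant; cannot unit-scale")
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # drop numerically null components (e.g. the one lost to centering)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    k = int((s > tol).sum())
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    total = float((s ** 2).sum())
    var_frac = (s ** 2) / total if total > 0 else np.zeros(k)
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=values.columns, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=values.index, columns=comp_names),
        variance_fraction=var_frac,
        centered=center,
        scaled=scale,
    )


def top_loading_genes(pca: PCAResult, component: int = 1,
                      k: int = 20) -> pd.DataFrame:
    """Top-k genes by absolute loading on one component (1-based).

    Ordered by |loading| descending, ties broken by gene id; returns
    min(k, n_genes) rows with the signed loadings.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not 1 <= component <= pca.n_components:
        raise ValidationError(
            f"component {component} out of range 1..{pca.n_components}")
    col = pca.loadings.iloc[:, component - 1]
    order = sorted(col.index, key=lambda g: (-abs(col[g]), g))
    top = order[:min(k, len(order))]
    return pd.DataFrame({
        "gene": top,
        "loading": [float(col[g]) for g in top],
        "abs_loading": [abs(float(col[g])) for g in top],
    })


def cluster_separation(pca: PCAResult, meta: SampleTable,
                       labels: str = "group",
                       components: tuple[int, ...] = (1, 2)) -> float:
    """Mean silhouette of assays in the selected PC score subspace."""
    if labels not in ("group", "batch"):
        raise ValidationError("labels must be 'group' or 'batch'")
    comp_cols = []
    for c in components:
        if not 1 <= c <= pca.n_components:
            raise ValidationError(f"component {c} out of range")
        comp_cols.append(f"PC{c}")
    lab = meta.frame.set_index("assay_id")[labels].astype(str)
    missing = [a for a in pca.scores.index if a not in lab.index]
    if missing:
        raise ValidationError(f"assays missing from metadata: {missing[:5]}")
    y = lab.loc[pca.scores.index].to_numpy()
    if len(set(y)) < 2:
        raise ValidationError("silhouette needs >=2 label classes")
    X = pca.scores[comp_cols].to_numpy()
    return float(silhouette_score(X, y, metric="euclidean"))
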