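"""Principal-component signature projection of expression matrices.

An expression matrix (genes x samples) is restricted to a gene signature,
gene-centered (no variance scaling by default), and decomposed by SVD.
Samples are scored by the standard correlation between each sample's gene
vector and each principal-component loading vector, and group separation
in the top-3 score space is quantified by the silhouette coefficient plus
a 2-means partition agreement score -- a testable surrogate for visual
clustering of sample groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)


@dataclass
class PCScores:
    """Per-sample correlation scores on the leading principal components."""

    scores: pd.DataFrame                 # samples x components, in [-1, 1]
    explained_variance_ratio: np.ndarray


class SignaturePCA(TransformerMixin, BaseEstimator):
    """PCA with correlation-based sample scores, sklearn-style.

    ``fit`` expects X of shape (n_samples, n_genes); genes are mean-centered
    and decomposed by SVD.  Component signs are fixed by making the
    largest-magnitude loading positive, so results are deterministic across
    runs and platforms.  ``transform`` returns, for each sample, the Pearson
    correlation between its gene vector and each loading vector.

    Parameters
    ----------
    n_components : int
        Number of leading components kept (default 3).
    scale : bool
        Optionally z-score genes after centering (off by default).
    """

    def __init__(self, n_components: int = 3, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n_samples, n_genes = X.shape
        if self.n_components > min(n_samples, n_genes):
            raise ValueError("n_components exceeds min(n_samples, n_genes)")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if self.scale:
            sd = Xc.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ValueError("zero-variance gene cannot be scaled")
            Xc = Xc / sd
            self.scale_ = sd
        total_var = float(np.sum(Xc**2))
        if total_var == 0:
            raise ValueError("matrix has zero variance after centering")
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        # sign convention: largest-|loading| entry positive per component
        for i in range(Vt.shape[0]):
            j = np.argmax(np.abs(Vt[i]))
            if Vt[i, j] < 0:
                Vt[i] = -Vt[i]
                U[:, i] = -U[:, i]
        self.components_ = Vt[: self.n_components]
        self.singular_values_ = S[: self.n_components]
        self.explained_variance_ratio_ = (S[: self.n_components] ** 2) / (S**2).sum()
        return self

    def transform(self, X):
        """Correlation of each sample's gene vector with each loading."""
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        scores = np.empty((X.shape[0], self.components_.shape[0]))
        for i, sample in enumerate(X):
            if np.std(sample) == 0:
                raise ValueError(f"sample {i} has a constant gene vector")
            for j, pc in enumerate(self.components_):
                scores[i, j] = np.corrcoef(sample, pc)[0, 1]
        return scores


def pca_fit(matrix: pd.DataFrame, n_components: int = 3) -> SignaturePCA:
    """Fit the decomposition on a genes x samples frame."""
    return SignaturePCA(n_components=n_components).fit(matrix.to_numpy().T)


def pc_scores(matrix: pd.DataFrame, model: SignaturePCA) -> PCScores:
    """Correlation scores of each sample against the fitted components."""
    scores = model.transform(matrix.to_numpy().T)
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return PCScores(
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        model.explained_variance_ratio_,
    )


def project_signature(
    matrix: pd.DataFrame,
    signature: set[str] | list[str],
    groups: pd.Series | None = None,
    n_components: int = 3,
    random_state: int | None = 0,
) -> tuple[PCScores, dict]:
    """Restrict an expression matrix to a gene signature and project.

    ``matrix`` is genes x samples.  Signature genes missing from the matrix
    are logged and skipped (at least 2 must be present).  When sample group
    labels are supplied the separation report carries the silhouette
    coefficient over the top-component score space and the adjusted Rand
    agreement between a 2-means partition of the scores and the labels.
    """
    signature = set(signature)
    present = [g for g in matrix.index if g in signature]
    missing = signature - set(present)
    if missing:
        logger.info("%d signature genes absent from matrix", len(missing))
    if len(present) < 2:
        raise ValueError("fewer than 2 signature genes found in matrix")
    sub = matrix.loc[present]
    n_components = min(n_components, sub.shape[1], sub.shape[0])
    model = pca_fit(sub, n_components=n_components)
    scores = pc_scores(sub, model)
    report: dict = {
        "n_signature_genes_used": len(present),
        "n_signature_genes_missing": len(missing),
        "explained_variance_ratio": model.explained_variance_ratio_.tolist(),
    }
    if groups is not None:
        labels = groups.loc[scores.scores.index]
        pts = scores.scores.to_numpy()
        if labels.nunique() >= 2:
            report["silhouette"] = float(silhouette_score(pts, labels))
            km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit(pts)
            report["two_means_ari"] = float(adjusted_rand_score(labels, km.labels_))
    return scores, report
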