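"""QC-aware exploratory outputs: PCA of samples and heatmap clustering orders.

Both operations work on a :class:`~panelqc.normalize.NormalizedMatrix` and
can exclude samples the QC flagged (FAIL, or FAIL and ALERT) so the effect
of removing bad samples on the run's structure is visible.  The tested
surface is numeric (scores, explained variance, leaf orders, z-values);
rendered figures are optional CLI artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .matrix import AnnotationTable, PanelQCError
from .normalize import NormalizedMatrix
from .qc import QCRunResult

logger = logging.getLogger(__name__)

EXCLUSION_POLICIES = ("none", "fail", "fail+alert")
DISTANCES = ("euclidean", "correlation")
LINKAGES = ("average", "complete", "ward")


@dataclass(frozen=True)
class PCAResult:
    """Sample scores in principal-component space."""

    sample_ids: tuple[str, ...]
    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    n_genes_used: int
    annotations: pd.DataFrame | None = None

    def scores_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.scores,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"PC{i + 1}" for i in range(self.scores.shape[1])],
        )
        if self.annotations is not None:
            frame = frame.join(self.annotations)
        return frame


@dataclass(frozen=True)
class HeatmapExport:
    """Row/column dendrogram leaf orders plus the z-scored value matrix."""

    row_order: tuple[str, ...]
    col_order: tuple[str, ...]
    values: pd.DataFrame  # z-scored, original row/col order
    row_linkage: list  # scipy linkage merge rows, as nested lists
    col_linkage: list
    constant_rows: tuple[str, ...] = ()
    annotations: pd.DataFrame | None = None


def _excluded_ids(qc: QCRunResult | None, policy: str) -> set[str]:
    if policy not in EXCLUSION_POLICIES:
        raise PanelQCError(f"unknown exclusion policy {policy!r}; choose from {EXCLUSION_POLICIES}")
    if policy == "none" or qc is None:
        return set()
    return set(qc.failed_sample_ids(include_alert=(policy == "fail+alert")))


class SamplePCA(BaseEstimator):
    """PCA of samples over the most variable genes, sklearn-style.

    Genes are centered across samples but not scaled; scores come from a
    full singular value decomposition with a deterministic sign convention
    (the largest-magnitude loading of each component is positive).

    Parameters
    ----------
    top_k_genes : int
        Number of most-variable genes retained (all genes if fewer).

    Attributes
    ----------
    scores_ : ndarray, samples x components
    explained_variance_ratio_ : ndarray
    n_genes_used_ : int
    """

    def __init__(self, top_k_genes: int = 500):
        self.top_k_genes = top_k_genes

    def fit(self, X, y=None):
        """X: samples x genes real matrix (ndarray or DataFrame)."""
        X = np.asarray(X, dtype=float)
        n_samples, n_genes = X.shape
        if n_samples < 2:
            raise PanelQCError("PCA needs at least 2 samples")
        if self.top_k_genes < 2:
            raise PanelQCError("top_k_genes must be >= 2")
        variances = X.var(axis=0, ddof=1)
        k = min(self.top_k_genes, n_genes)
        # stable selection: ties broken by input order
        keep = np.sort(np.argsort(-variances, kind="stable")[:k])
        sub = X[:, keep]
        pca = PCA(n_components=min(n_samples - 1, sub.shape[1]), svd_solver="full")
        scores = pca.fit_transform(sub)
        # deterministic sign: largest-|loading| entry of each component positive
        for c in range(pca.components_.shape[0]):
            load = pca.components_[c]
            imax = int(np.argmax(np.abs(load)))
            if load[imax] < 0:
                pca.components_[c] *= -1.0
                scores[:, c] *= -1.0
        self.scores_ = scores
        self.components_ = pca.components_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.explained_variance_ = pca.explained_variance_
        self.n_genes_used_ = int(k)
        self.gene_indices_ = keep
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_


def pca_samples(
    norm: NormalizedMatrix,
    qc: QCRunResult | None = None,
    exclude_flagged: str = "none",
    top_k_genes: int = 500,
) -> PCAResult:
    """PCA of samples from a normalized matrix, optionally excluding flagged ones.

    Control probes should have been removed at normalization time
    (``normalize(..., remove_controls=True)``); in a failed run they would
    otherwise dominate the leading components.
    """
    excluded = _excluded_ids(qc, exclude_flagged)
    keep = [s for s in norm.sample_ids if s not in excluded]
    if len(keep) < 2:
        raise PanelQCError(
            f"fewer than 2 samples remain after exclusion ({len(keep)} of {len(norm.sample_ids)})"
        )
    if excluded:
        logger.info("PCA excludes %d flagged sample(s)", len(norm.sample_ids) - len(keep))
    cols = [norm.sample_ids.index(s) for s in keep]
    X = norm.values[:, cols].T  # samples x genes
    est = SamplePCA(top_k_genes=top_k_genes).fit(X)
    return PCAResult(
        sample_ids=tuple(keep),
        scores=est.scores_,
        explained_variance_ratio=est.explained_variance_ratio_,
        n_genes_used=est.n_genes_used_,
    )


def _zscore_rows(values: np.ndarray, probe_ids) -> tuple[np.ndarray, tuple[str, ...]]:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[constant, :] = 1.0
    z = (values - mean) / sd
    z[constant, :] = 0.0  # constant rows carry no signal; zeroed and flagged
    return z, tuple(probe_ids[i] for i in np.flatnonzero(constant))


def hclust_orders(
    norm: NormalizedMatrix,
    qc: QCRunResult | None = None,
    exclude_flagged: str = "none",
    distance: str = "euclidean",
    linkage: str = "average",
) -> HeatmapExport:
    """Hierarchical-clustering leaf orders for a genes x samples heatmap.

    Rows (genes) are z-scored; rows and columns are clustered with the
    requested distance and linkage.  Deterministic: scipy's linkage breaks
    ties by input order, so re-running is bit-identical.
    """
    if distance not in DISTANCES:
        raise PanelQCError(f"unknown distance {distance!r}; choose from {DISTANCES}")
    if linkage not in LINKAGES:
        raise PanelQCError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    excluded = _excluded_ids(qc, exclude_flagged)
    keep = [s for s in norm.sample_ids if s not in excluded]
    if len(keep) < 2:
        raise PanelQCError("heatmap needs at least 2 samples after exclusion")
    if len(norm.probe_ids) < 2:
        raise PanelQCError("heatmap needs at least 2 probes")
    cols = [norm.sample_ids.index(s) for s in keep]
    values = norm.values[:, cols]

    z, constant_rows = _zscore_rows(values, norm.probe_ids)
    if len(constant_rows) == len(norm.probe_ids):
        raise PanelQCError("all rows are constant: nothing to cluster")

    def _linkage(data: np.ndarray) -> np.ndarray:
        if linkage == "ward":
            return sch.linkage(data, method="ward", metric="euclidean")
        return sch.linkage(pdist(data, metric=distance), method=linkage)

    row_link = _linkage(z)
    col_link = _linkage(z.T)
    row_order = tuple(norm.probe_ids[i] for i in sch.leaves_list(row_link))
    col_order = tuple(keep[i] for i in sch.leaves_list(col_link))

    return HeatmapExport(
        row_order=row_order,
        col_order=col_order,
        values=pd.DataFrame(
            z, index=pd.Index(norm.probe_ids, name="probe_id"), columns=keep
        ),
        row_linkage=row_link.tolist(),
        col_linkage=col_link.tolist(),
        constant_rows=constant_rows,
    )


def join_annotation(result, ann: AnnotationTable):
    """Attach annotation labels to a PCAResult or HeatmapExport.

    Labels align by sample id; samples without a label get ``"unannotated"``
    (reported via logging, never fatal).
    """
    if isinstance(result, PCAResult):
        labels, _ = ann.labels_for(result.sample_ids)
        return replace(result, annotations=labels)
    if isinstance(result, HeatmapExport):
        labels, _ = ann.labels_for(result.col_order)
        return replace(result, annotations=labels)
    raise PanelQCError(f"cannot annotate object of type {type(result).__name__}")
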