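"""Count normalization: CPM (default), log2-CPM and a closed-form NB VST.

The variance-stabilizing transform assumes counts are negative-binomial
with variance mu + alpha * mu^2 for a single common dispersion alpha.  The
stabilizer for that variance function is the closed form

    g(x) = (2 / sqrt(alpha)) * asinh(sqrt(alpha * x))        alpha > 0
    g(x) = 2 * sqrt(x)                                        alpha = 0

which is strictly increasing and has g(0) = 0; for an NB variable with the
assumed variance, Var g(X) is approximately constant across means.  This is
"vst (NB closed form)" — it is not intended to agree numerically with any
other package's vst.  The common dispersion is a per-gene method-of-moments
excess, medianed over genes, computed on counts rescaled to the median
library size; the transform is applied to counts rescaled the same way so
that sequencing depth is normalised out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import ControlSpec, ExpressionMatrix, PanelQCError
from .qc import compute_cpm

logger = logging.getLogger(__name__)

METHODS = ("cpm", "log2cpm", "vst")


@dataclass(frozen=True)
class NormalizedMatrix:
    """A normalized probe x sample real-valued matrix."""

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    method: str
    controls_removed: bool
    alpha: float | None = None  # common dispersion, vst only

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise PanelQCError(
                f"values shape {values.shape} does not match ids "
                f"({len(self.probe_ids)} x {len(self.sample_ids)})"
            )
        if not np.isfinite(values).all():
            raise PanelQCError("normalized values contain non-finite entries")
        if self.method == "cpm" and (values < 0).any():
            raise PanelQCError("cpm values must be non-negative")
        object.__setattr__(self, "values", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.probe_ids, name="probe_id"),
            columns=list(self.sample_ids),
        )

    def sidecar(self) -> dict:
        """Metadata for the JSON sidecar written next to the CSV export."""
        meta = {"method": self.method, "controls_removed": self.controls_removed}
        if self.method == "vst":
            meta["alpha"] = self.alpha
        return meta


def vst_transform(x, alpha: float):
    """Apply the NB variance stabilizer g(x) elementwise.

    Strictly increasing in x; g(0) = 0; reduces to 2*sqrt(x) as alpha -> 0.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise PanelQCError("vst input must be non-negative")
    if alpha < 0:
        raise PanelQCError(f"dispersion alpha must be >= 0, got {alpha}")
    if alpha == 0:
        return 2.0 * np.sqrt(x)
    return (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * x))


def _depth_scaled_counts(matrix: ExpressionMatrix) -> np.ndarray:
    """Counts rescaled per sample to the median library size."""
    lib = matrix.library_sizes()
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        names = ", ".join(matrix.sample_ids[i] for i in zero)
        raise PanelQCError(f"zero library size for sample(s): {names}")
    return matrix.counts * (np.median(lib) / lib)[np.newaxis, :]


def estimate_common_dispersion(matrix: ExpressionMatrix) -> float:
    """Method-of-moments common NB dispersion alpha.

    On counts rescaled to the median library size, each gene with mean
    m > 0 and non-zero variance s^2 contributes max(0, (s^2 - m) / m^2);
    alpha is the median contribution.  Constant genes are excluded.
    """
    if matrix.n_samples < 2:
        raise PanelQCError("dispersion estimation needs at least 2 samples")
    scaled = _depth_scaled_counts(matrix)
    m = scaled.mean(axis=1)
    s2 = scaled.var(axis=1, ddof=1)
    eligible = (m > 0) & (s2 > 0)
    if not eligible.any():
        logger.warning("no gene with positive mean and variance; alpha set to 0")
        return 0.0
    alpha_g = np.maximum(0.0, (s2[eligible] - m[eligible]) / m[eligible] ** 2)
    return float(np.median(alpha_g))


def normalize(
    matrix: ExpressionMatrix,
    method: str = "cpm",
    remove_controls: bool = False,
    controls: ControlSpec | None = None,
    alpha: float | None = None,
) -> NormalizedMatrix:
    """Normalize a count matrix for visualisation.

    Parameters
    ----------
    method : {"cpm", "log2cpm", "vst"}
        ``cpm`` is the default.  ``log2cpm`` is log2(cpm + 1).  ``vst`` is
        the closed-form NB stabilizer on depth-rescaled counts.
    remove_controls : bool
        Drop control probes *before* normalization (recommended for PCA and
        heatmaps: in a failed run controls would dominate).  Requires
        ``controls``.  The QC filters themselves always use the full matrix.
    alpha : float, optional
        Common dispersion for vst; estimated from the data when omitted.
    """
    if method not in METHODS:
        raise PanelQCError(f"unknown normalization method {method!r}; choose from {METHODS}")
    if remove_controls:
        if controls is None:
            raise PanelQCError("remove_controls=True requires a ControlSpec")
        matrix = matrix.drop_probes(controls.all_ids)

    used_alpha: float | None = None
    if method == "cpm":
        values = compute_cpm(matrix)
    elif method == "log2cpm":
        values = np.log2(compute_cpm(matrix) + 1.0)
    else:  # vst
        used_alpha = float(alpha) if alpha is not None else estimate_common_dispersion(matrix)
        values = vst_transform(_depth_scaled_counts(matrix), used_alpha)

    return NormalizedMatrix(
        probe_ids=matrix.probe_ids,
        sample_ids=matrix.sample_ids,
        values=values,
        method=method,
        controls_removed=remove_controls,
        alpha=used_alpha,
    )


class CountNormalizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer over samples x genes count arrays.

    ``fit`` estimates the common dispersion when ``method="vst"``;
    ``transform`` maps raw counts to the normalized scale.  For the
    probe x sample workflow use :func:`normalize`, which wraps this.

    Parameters
    ----------
    method : {"cpm", "log2cpm", "vst"}
    alpha : float, optional
        Fixed dispersion; skips estimation.

    Attributes
    ----------
    alpha_ : float or None
        Dispersion used (vst only).
    median_library_size_ : float
        Depth anchor for the vst rescaling, from the fitted data.
    """

    def __init__(self, method: str = "cpm", alpha: float | None = None):
        self.method = method
        self.alpha = alpha

    def _to_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, pd.DataFrame):
            frame = X.T
        else:
            X = np.asarray(X)
            frame = pd.DataFrame(
                X.T,
                index=[f"g{i}" for i in range(X.shape[1])],
                columns=[f"s{j}" for j in range(X.shape[0])],
            )
        return ExpressionMatrix.from_frame(frame)

    def fit(self, X, y=None):
        if self.method not in METHODS:
            raise PanelQCError(f"unknown normalization method {self.method!r}")
        matrix = self._to_matrix(X)
        self.median_library_size_ = float(np.median(matrix.library_sizes()))
        if self.method == "vst":
            self.alpha_ = (
                float(self.alpha) if self.alpha is not None else estimate_common_dispersion(matrix)
            )
        else:
            self.alpha_ = None
        return self

    def transform(self, X) -> np.ndarray:
        matrix = self._to_matrix(X)
        if self.method == "cpm":
            return compute_cpm(matrix).T
        if self.method == "log2cpm":
            return np.log2(compute_cpm(matrix) + 1.0).T
        lib = matrix.library_sizes()
        scaled = matrix.counts * (self.median_library_size_ / lib)[np.newaxis, :]
        return vst_transform(scaled, self.alpha_).T
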