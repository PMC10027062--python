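"""Sample quality control from positive (spike-in) and negative control probes.

The method applies two per-sample filters to a targeted-panel run of N
samples and combines their three-level flags:

*Positive-control filter.*  The percentage of reads allocated to the
spike-in probes over the total library size is expected in the 0–5% range
for good samples; a sample is flagged ALERT when it exceeds 10% and FAIL
when it exceeds 40%.

*Negative-control filter.*  Counts are normalised to counts per million
(CPM) and each sample's mean CPM over the M negative probes, CPM_i, is
reduced to a deviance

    delta_i = CPM_i - mean_over_samples(CPM)

A sample whose |delta_i| exceeds ``sd_multiplier`` times the standard
deviation of the deviances is a background outlier (ALERT).  Because a run
in which *every* sample is contaminated leaves all deviances inside the
band, a second rule makes a sample FAIL outright when the percentage of
reads on the negative probes exceeds 10% of its library size.

The overall flag is FAIL if either filter FAILs, else ALERT if either
ALERTs, else PASS.  All threshold comparisons are strict ("exceeds"): a
sample at exactly 40.0% is ALERT, not FAIL.

The run-level entry points are :func:`run_qc` and the sklearn-style
estimator :class:`PanelQC`.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import (
    DEFAULT_NEGATIVE_PREFIX,
    DEFAULT_POSITIVE_PREFIX,
    detect_controls,
)
from .matrix import ControlSpec, ExpressionMatrix, PanelQCError

logger = logging.getLogger(__name__)

#: minimum number of samples for the deviance band to be meaningful
MIN_SAMPLES_FOR_BAND = 3

RECORD_COLUMNS = [
    "sample_id",
    "library_size",
    "pos_pct",
    "neg_pct",
    "neg_mean_cpm",
    "delta",
    "pos_flag",
    "neg_flag",
    "overall_flag",
]


class Flag(str, enum.Enum):
    """Three-level QC flag; severity order PASS < ALERT < FAIL."""

    PASS = "PASS"
    ALERT = "ALERT"
    FAIL = "FAIL"

    @property
    def severity(self) -> int:
        return {"PASS": 0, "ALERT": 1, "FAIL": 2}[self.value]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class QCThresholds:
    """The four tunable constants of the method.

    Defaults are the published values: positive-control FAIL above 40% of
    the library, positive-control ALERT above 10%, negative-control FAIL
    above 10%, deviance band at +/- 2 standard deviations.
    """

    pos_fail_pct: float = 40.0
    pos_alert_pct: float = 10.0
    neg_fail_pct: float = 10.0
    sd_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.pos_alert_pct < self.pos_fail_pct <= 100):
            raise PanelQCError(
                "need 0 < pos_alert_pct < pos_fail_pct <= 100, got "
                f"alert={self.pos_alert_pct}, fail={self.pos_fail_pct}"
            )
        if not (0 < self.neg_fail_pct <= 100):
            raise PanelQCError(f"need 0 < neg_fail_pct <= 100, got {self.neg_fail_pct}")
        if not self.sd_multiplier > 0:
            raise PanelQCError(f"need sd_multiplier > 0, got {self.sd_multiplier}")

    def as_dict(self) -> dict[str, float]:
        return {
            "pos_fail_pct": self.pos_fail_pct,
            "pos_alert_pct": self.pos_alert_pct,
            "neg_fail_pct": self.neg_fail_pct,
            "sd_multiplier": self.sd_multiplier,
        }


@dataclass(frozen=True)
class SampleQCRecord:
    """All per-sample QC quantities."""

    sample_id: str
    library_size: int
    pos_pct: float
    neg_pct: float
    neg_mean_cpm: float
    delta: float
    pos_flag: Flag
    neg_flag: Flag
    overall_flag: Flag


@dataclass(frozen=True)
class QCRunResult:
    """Per-sample records plus run-level deviance statistics."""

    records: tuple[SampleQCRecord, ...]
    delta_sd: float
    thresholds: QCThresholds
    deviance_filter_applied: bool
    one_sided_band: bool = False

    @property
    def band_high(self) -> float:
        return self.thresholds.sd_multiplier * self.delta_sd

    @property
    def band_low(self) -> float:
        return -self.band_high

    @property
    def n_samples(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": r.sample_id,
                "library_size": r.library_size,
                "pos_pct": r.pos_pct,
                "neg_pct": r.neg_pct,
                "neg_mean_cpm": r.neg_mean_cpm,
                "delta": r.delta,
                "pos_flag": r.pos_flag.value,
                "neg_flag": r.neg_flag.value,
                "overall_flag": r.overall_flag.value,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=RECORD_COLUMNS)

    def pass_table(self) -> pd.DataFrame:
        """Samples passing both filters."""
        frame = self.to_frame()
        return frame[frame["overall_flag"] == Flag.PASS.value].reset_index(drop=True)

    def fail_table(self) -> pd.DataFrame:
        """Samples not passing QC: any ALERT or FAIL."""
        frame = self.to_frame()
        return frame[frame["overall_flag"] != Flag.PASS.value].reset_index(drop=True)

    def flag_counts(self) -> dict[str, int]:
        frame = self.to_frame()
        return {f.value: int((frame["overall_flag"] == f.value).sum()) for f in Flag}

    def flags(self) -> dict[str, Flag]:
        return {r.sample_id: r.overall_flag for r in self.records}

    def failed_sample_ids(self, include_alert: bool = False) -> list[str]:
        worst = {Flag.FAIL} if not include_alert else {Flag.FAIL, Flag.ALERT}
        return [r.sample_id for r in self.records if r.overall_flag in worst]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def compute_cpm(matrix: ExpressionMatrix) -> np.ndarray:
    """Counts per million: X[i, j] / library_size_j * 1e6, per sample column.

    Every column of the result sums to 1e6.  Raises if any sample has a
    zero library size, naming the sample.
    """
    lib = matrix.library_sizes()
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        names = ", ".join(matrix.sample_ids[i] for i in zero)
        raise PanelQCError(f"zero library size for sample(s): {names}")
    return matrix.counts / lib[np.newaxis, :] * 1e6


def control_fraction(matrix: ExpressionMatrix, control_ids, sample_id: str) -> float:
    """Percent of the sample's total library allocated to ``control_ids``."""
    j = matrix.sample_index(sample_id)
    rows = [matrix.probe_index(p) for p in control_ids]
    lib = int(matrix.counts[:, j].sum())
    if lib == 0:
        raise PanelQCError(f"zero library size for sample(s): {sample_id}")
    return 100.0 * matrix.counts[rows, j].sum() / lib


def negative_mean_cpm(cpm: np.ndarray, matrix: ExpressionMatrix, negative_ids, sample_id: str) -> float:
    """Mean CPM over the negative-control probes for one sample (CPM_i)."""
    if not negative_ids:
        raise PanelQCError("negative control set is empty")
    j = matrix.sample_index(sample_id)
    rows = [matrix.probe_index(p) for p in negative_ids]
    return float(np.mean(cpm[rows, j]))


def negative_deviance(neg_mean_cpms) -> np.ndarray:
    """Deviance delta_i = CPM_i minus the across-sample mean of CPM.

    The deviances sum to zero by construction.
    """
    values = np.asarray(neg_mean_cpms, dtype=float)
    if values.size == 0:
        raise PanelQCError("no samples: cannot compute deviances")
    return values - values.mean()


def flag_positive(pos_pct: float, thresholds: QCThresholds = QCThresholds()) -> Flag:
    """FAIL above the fail threshold, ALERT above the alert threshold (strict)."""
    if pos_pct > thresholds.pos_fail_pct:
        return Flag.FAIL
    if pos_pct > thresholds.pos_alert_pct:
        return Flag.ALERT
    return Flag.PASS


def flag_negative(
    neg_pct: float,
    delta: float,
    delta_sd: float,
    thresholds: QCThresholds = QCThresholds(),
    deviance_filter_applied: bool = True,
    one_sided_band: bool = False,
) -> Flag:
    """Negative-control flag from the fraction rule and the deviance band.

    FAIL when the negative-control read percentage exceeds the fraction
    threshold; otherwise ALERT when the deviance lies outside the
    ``sd_multiplier`` x SD band (two-sided on |delta| by default; the
    one-sided mode only flags elevated background, delta > band).
    """
    if delta_sd < 0:
        raise PanelQCError(f"delta_sd must be >= 0, got {delta_sd}")
    if neg_pct > thresholds.neg_fail_pct:
        return Flag.FAIL
    if deviance_filter_applied:
        band = thresholds.sd_multiplier * delta_sd
        outside = delta > band if one_sided_band else abs(delta) > band
        if outside:
            return Flag.ALERT
    return Flag.PASS


def combine_flags(pos_flag: Flag, neg_flag: Flag) -> Flag:
    """Overall flag: FAIL dominates ALERT dominates PASS."""
    return pos_flag if pos_flag.severity >= neg_flag.severity else neg_flag


# ---------------------------------------------------------------------------
# run-level QC
# ---------------------------------------------------------------------------


def run_qc(
    matrix: ExpressionMatrix,
    controls: ControlSpec,
    thresholds: QCThresholds = QCThresholds(),
    one_sided_band: bool = False,
) -> QCRunResult:
    """Run both control filters on every sample of a run.

    ``delta_sd`` is the sample (N-1 denominator) standard deviation of the
    deviances.  With fewer than three samples the band is statistically
    meaningless, so the deviance sub-filter is skipped (with a warning) and
    ``deviance_filter_applied`` is False.
    """
    controls.validate_against(matrix)
    cpm = compute_cpm(matrix)
    lib = matrix.library_sizes()
    pos_rows = [matrix.probe_index(p) for p in sorted(controls.positive_ids)]
    neg_rows = [matrix.probe_index(p) for p in sorted(controls.negative_ids)]

    pos_pct = 100.0 * matrix.counts[pos_rows, :].sum(axis=0) / lib
    neg_pct = 100.0 * matrix.counts[neg_rows, :].sum(axis=0) / lib
    neg_mean = cpm[neg_rows, :].mean(axis=0)
    delta = negative_deviance(neg_mean)

    n = matrix.n_samples
    applied = n >= MIN_SAMPLES_FOR_BAND
    if not applied:
        logger.warning(
            "only %d sample(s): deviance band skipped (needs >= %d)", n, MIN_SAMPLES_FOR_BAND
        )
    delta_sd = float(np.std(delta, ddof=1)) if n >= 2 else 0.0

    records = []
    for j, sample in enumerate(matrix.sample_ids):
        pflag = flag_positive(float(pos_pct[j]), thresholds)
        nflag = flag_negative(
            float(neg_pct[j]),
            float(delta[j]),
            delta_sd,
            thresholds,
            deviance_filter_applied=applied,
            one_sided_band=one_sided_band,
        )
        records.append(
            SampleQCRecord(
                sample_id=sample,
                library_size=int(lib[j]),
                pos_pct=float(pos_pct[j]),
                neg_pct=float(neg_pct[j]),
                neg_mean_cpm=float(neg_mean[j]),
                delta=float(delta[j]),
                pos_flag=pflag,
                neg_flag=nflag,
                overall_flag=combine_flags(pflag, nflag),
            )
        )
    return QCRunResult(
        records=tuple(records),
        delta_sd=delta_sd,
        thresholds=thresholds,
        deviance_filter_applied=applied,
        one_sided_band=one_sided_band,
    )


class PanelQC(BaseEstimator):
    """Run-level sample QC as an sklearn-style estimator.

    Fit on one run; the flags are run-level quantities (the deviance band is
    estimated from the run itself), so there is no out-of-run ``predict`` —
    use :meth:`fit_predict`.

    Parameters
    ----------
    positive_prefix, negative_prefix : str
        Case-insensitive probe-id prefixes identifying the control sets.
    positive_ids, negative_ids : sequence of str, optional
        Explicit control id lists; take precedence over the prefixes.
    pos_fail_pct, pos_alert_pct, neg_fail_pct, sd_multiplier : float
        The four QC thresholds (defaults 40, 10, 10, 2).
    one_sided_band : bool
        If True, only elevated negative-control background (delta above the
        band) raises a deviance ALERT.

    Attributes
    ----------
    result_ : QCRunResult
    controls_ : ControlSpec
    flags_ : ndarray of str, overall flag per sample in input order
    delta_sd_ : float
    band_low_, band_high_ : float
    """

    def __init__(
        self,
        positive_prefix: str = DEFAULT_POSITIVE_PREFIX,
        negative_prefix: str = DEFAULT_NEGATIVE_PREFIX,
        positive_ids=None,
        negative_ids=None,
        pos_fail_pct: float = 40.0,
        pos_alert_pct: float = 10.0,
        neg_fail_pct: float = 10.0,
        sd_multiplier: float = 2.0,
        one_sided_band: bool = False,
    ):
        self.positive_prefix = positive_prefix
        self.negative_prefix = negative_prefix
        self.positive_ids = positive_ids
        self.negative_ids = negative_ids
        self.pos_fail_pct = pos_fail_pct
        self.pos_alert_pct = pos_alert_pct
        self.neg_fail_pct = neg_fail_pct
        self.sd_multiplier = sd_multiplier
        self.one_sided_band = one_sided_band

    def _as_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            # sklearn orientation: rows samples, columns probes
            return ExpressionMatrix.from_frame(X.T)
        raise PanelQCError(
            "X must be an ExpressionMatrix or a samples x probes DataFrame "
            "with probe ids as columns"
        )

    def fit(self, X, y=None):
        matrix = self._as_matrix(X)
        self.thresholds_ = QCThresholds(
            pos_fail_pct=self.pos_fail_pct,
            pos_alert_pct=self.pos_alert_pct,
            neg_fail_pct=self.neg_fail_pct,
            sd_multiplier=self.sd_multiplier,
        )
        self.controls_ = detect_controls(
            matrix,
            positive_prefix=self.positive_prefix,
            negative_prefix=self.negative_prefix,
            positive_ids=self.positive_ids,
            negative_ids=self.negative_ids,
        )
        self.result_ = run_qc(
            matrix, self.controls_, self.thresholds_, one_sided_band=self.one_sided_band
        )
        self.sample_ids_ = np.asarray(matrix.sample_ids)
        self.flags_ = np.asarray([r.overall_flag.value for r in self.result_.records])
        self.delta_sd_ = self.result_.delta_sd
        self.band_low_ = self.result_.band_low
        self.band_high_ = self.result_.band_high
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit on the run and return the overall flag per sample."""
        return self.fit(X).flags_
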