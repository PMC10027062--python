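"""Core containers for probe-by-sample count data.

Targeted expression panels (HTG EdgeSeq-style) export a read-count matrix
with probes on rows and samples on columns.  A handful of those probes are
controls: positive spike-ins added at known input, and negative probes
against non-human sequences that measure background.  The containers here
carry the counts, the control-probe sets and optional sample annotations,
and enforce the invariants everything downstream relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance for accepting near-integer counts from spreadsheet exports
_INT_TOL = 1e-9


class PanelQCError(ValueError):
    """Raised for invalid inputs anywhere in the package."""


def _find_duplicates(values) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for v in values:
        if v in seen and v not in dups:
            dups.append(v)
        seen.add(v)
    return dups


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated probe x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    probe_ids : sequence of str
        Unique probe identifiers, one per row, order preserved.
    sample_ids : sequence of str
        Unique sample identifiers, one per column, order preserved.
    counts : ndarray of shape (n_probes, n_samples)
        Non-negative integer read counts.
    """

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", tuple(str(p) for p in self.probe_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise PanelQCError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise PanelQCError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(self.probe_ids) == 0 or len(self.sample_ids) == 0:
            raise PanelQCError("matrix must have at least one probe and one sample")
        dup_p = _find_duplicates(self.probe_ids)
        if dup_p:
            raise PanelQCError(f"duplicate probe id(s): {', '.join(dup_p)}")
        dup_s = _find_duplicates(self.sample_ids)
        if dup_s:
            raise PanelQCError(f"duplicate sample id(s): {', '.join(dup_s)}")
        if not np.issubdtype(counts.dtype, np.number):
            raise PanelQCError(f"counts are not numeric (dtype {counts.dtype})")
        if np.isnan(counts.astype(float)).any():
            r, c = np.argwhere(np.isnan(counts.astype(float)))[0]
            raise PanelQCError(
                f"missing/NaN count at probe {self.probe_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts.astype(float))
            off = np.abs(counts.astype(float) - rounded) > _INT_TOL
            if off.any():
                r, c = np.argwhere(off)[0]
                raise PanelQCError(
                    f"non-integer count {counts[r, c]!r} at probe "
                    f"{self.probe_ids[r]!r}, sample {self.sample_ids[c]!r}"
                )
            counts = rounded
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            r, c = np.argwhere(counts < 0)[0]
            raise PanelQCError(
                f"negative count {counts[r, c]} at probe {self.probe_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    # -- basic introspection ------------------------------------------------

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Total reads per sample over all probes, controls included."""
        return self.counts.sum(axis=0)

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise PanelQCError(f"unknown probe id {probe_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise PanelQCError(f"unknown sample id {sample_id!r}") from None

    # -- conversion ---------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame with probe ids as index, sample ids as columns."""
        return cls(
            probe_ids=tuple(str(i) for i in frame.index),
            sample_ids=tuple(str(c) for c in frame.columns),
            counts=frame.to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(),
            index=pd.Index(self.probe_ids, name="probe_id"),
            columns=list(self.sample_ids),
        )

    # -- subsetting (order-preserving) --------------------------------------

    def drop_probes(self, probe_ids) -> "ExpressionMatrix":
        drop = set(probe_ids)
        keep = [i for i, p in enumerate(self.probe_ids) if p not in drop]
        if not keep:
            raise PanelQCError("dropping these probes would leave an empty matrix")
        return ExpressionMatrix(
            probe_ids=tuple(self.probe_ids[i] for i in keep),
            sample_ids=self.sample_ids,
            counts=self.counts[keep, :],
        )

    def select_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return ExpressionMatrix(
            probe_ids=self.probe_ids,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            counts=self.counts[:, idx],
        )


@dataclass(frozen=True)
class ControlSpec:
    """The positive (spike-in) and negative (non-human) control probe sets."""

    positive_ids: frozenset[str]
    negative_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive_ids", frozenset(self.positive_ids))
        object.__setattr__(self, "negative_ids", frozenset(self.negative_ids))
        overlap = self.positive_ids & self.negative_ids
        if overlap:
            raise PanelQCError(
                f"probe(s) listed as both positive and negative control: "
                f"{', '.join(sorted(overlap))}"
            )

    @property
    def all_ids(self) -> frozenset[str]:
        return self.positive_ids | self.negative_ids

    @property
    def n_negative(self) -> int:
        """M, the number of negative-control probes."""
        return len(self.negative_ids)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Check both sets are non-empty and all ids exist in the matrix."""
        if not self.positive_ids or not self.negative_ids:
            raise PanelQCError(
                "both positive and negative control sets must be non-empty to run QC"
            )
        missing = self.all_ids - set(matrix.probe_ids)
        if missing:
            raise PanelQCError(
                f"control probe id(s) not in matrix: {', '.join(sorted(missing))}"
            )


@dataclass(frozen=True)
class AnnotationTable:
    """Sample annotations: one row per sample, one or more categorical label columns."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        frame = self.frame
        if frame.index.name is None:
            frame = frame.rename_axis("sample_id")
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        if dups:
            raise PanelQCError(f"duplicate sample id(s) in annotation: {', '.join(map(str, dups))}")
        if frame.shape[1] == 0:
            raise PanelQCError("annotation table has no label columns")
        frame = frame.astype(str)
        object.__setattr__(self, "frame", frame)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.frame.index)

    @property
    def label_columns(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def labels_for(self, sample_ids) -> tuple[pd.DataFrame, list[str]]:
        """Align labels to ``sample_ids``.

        Unmatched samples get the explicit label ``"unannotated"`` in every
        column and are returned (and logged), never silently dropped.
        """
        sample_ids = [str(s) for s in sample_ids]
        aligned = self.frame.reindex(sample_ids)
        unmatched = [s for s in sample_ids if s not in self.frame.index]
        if unmatched:
            logger.warning(
                "%d sample(s) without annotation: %s", len(unmatched), ", ".join(unmatched)
            )
            aligned.loc[unmatched, :] = "unannotated"
        aligned.index.name = "sample_id"
        return aligned.astype(str), unmatched
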