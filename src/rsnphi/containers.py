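"""Core data containers shared across the package.

The substrate of every metric in this package is a small multivariate
*binary* time-series: ``T`` time points by ``N`` regions, each entry 0
(below-baseline activity) or 1 (above-baseline activity).  Because series
from several subjects are routinely concatenated to obtain longer signals,
binary series carry *provenance*: the list of contiguous segments, one per
source subject, so that downstream transition counting can refuse to count
a "transition" that spans two different subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class Segment:
    """One contiguous block of a (possibly concatenated) time-series."""

    subject: str
    start: int
    length: int

    @property
    def stop(self) -> int:
        return self.start + self.length


@dataclass
class RegionTimeSeries:
    """Continuous region-level signals, time x region.

    Parameters
    ----------
    values : ndarray, shape (T, N)
        Real-valued signals, no missing values.
    region_labels : list of str
    tr_seconds : float
        Sampling interval (repetition time); 2.0 s for the emulated study.
    """

    values: np.ndarray
    region_labels: list[str]
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D time x region array")
        t, n = self.values.shape
        if t < 2 or n < 2:
            raise ValueError(
                f"need >= 2 time points and >= 2 regions, got {t} x {n}"
            )
        if len(self.region_labels) != n:
            raise ValueError("region_labels length must match number of columns")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain NaN or infinities")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryTimeSeries:
    """Binary region-level series, time x region, values in {0, 1}.

    ``provenance`` partitions the time axis into per-subject segments; a
    single-subject series has one segment covering everything.
    """

    values: np.ndarray
    region_labels: list[str]
    provenance: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D time x region array")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise ValueError(
                f"non-binary value at row {bad[0]}, column {bad[1]}"
            )
        self.values = self.values.astype(np.int8)
        if len(self.region_labels) != self.values.shape[1]:
            raise ValueError("region_labels length must match number of columns")
        if not self.provenance:
            self.provenance = [Segment("s0", 0, self.values.shape[0])]
        self._check_provenance()

    def _check_provenance(self) -> None:
        pos = 0
        for seg in self.provenance:
            if seg.start != pos or seg.length <= 0:
                raise ValueError("provenance segments must partition the time axis")
            pos += seg.length
        if pos != self.values.shape[0]:
            raise ValueError("provenance segments must partition the time axis")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def segment_boundaries(self) -> list[int]:
        """Start positions of each provenance segment."""
        return [seg.start for seg in self.provenance]

    def with_values(self, values: np.ndarray) -> "BinaryTimeSeries":
        return replace(self, values=values)
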