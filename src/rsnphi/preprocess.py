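"""Continuous-to-binary preprocessing of region time-series.

The pipeline mirrors standard resting-state practice: per-region linear
detrending, band-pass filtering (0.01-0.1 Hz Butterworth by default,
applied zero-phase), z-scoring of each region against its own mean and
standard deviation, and binarization at the region's own baseline --
positive z-scores map to 1 (above-baseline activity), the rest to 0.
Concatenation utilities assemble multi-subject series while recording
per-subject provenance segments.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .containers import BinaryTimeSeries, RegionTimeSeries, Segment


def detrend_and_filter(x: RegionTimeSeries, low_hz: float = 0.01,
                       high_hz: float = 0.1, order: int = 2) -> RegionTimeSeries:
    """Linear detrend then zero-phase Butterworth band-pass, per region.

    A second-order filter applied forward-backward (``filtfilt``) keeps the
    timing of state changes undistorted.  Cutoffs must lie strictly inside
    (0, Nyquist) where Nyquist = 1 / (2 * tr_seconds).
    """
    nyq = 1.0 / (2.0 * x.tr_seconds)
    if not 0.0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"cutoffs must satisfy 0 < low ({low_hz}) < high ({high_hz}) "
            f"< Nyquist ({nyq})"
        )
    detrended = sps.detrend(x.values, axis=0, type="linear")
    sos = sps.butter(order, [low_hz / nyq, high_hz / nyq],
                     btype="bandpass", output="sos")
    filtered = sps.sosfiltfilt(sos, detrended, axis=0)
    return RegionTimeSeries(filtered, x.region_labels, x.tr_seconds)


def standardize(x: RegionTimeSeries, ddof: int = 1) -> RegionTimeSeries:
    """Z-score each region against its own mean and (sample) SD."""
    sd = x.values.std(axis=0, ddof=ddof)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [x.region_labels[i] for i in flat]
        raise ValueError(f"zero-variance region(s): {names}")
    z = (x.values - x.values.mean(axis=0)) / sd
    return RegionTimeSeries(z, x.region_labels, x.tr_seconds)


def binarize(z: RegionTimeSeries, zero_to: int = 0) -> BinaryTimeSeries:
    """Threshold standardized signals at zero: z > 0 -> 1, z < 0 -> 0.

    An exact zero is a measure-zero boundary case; it maps to ``zero_to``
    (0 by default) so the rule is deterministic.
    """
    if zero_to not in (0, 1):
        raise ValueError("zero_to must be 0 or 1")
    if zero_to:
        values = (z.values >= 0).astype(np.int8)
    else:
        values = (z.values > 0).astype(np.int8)
    return BinaryTimeSeries(values, z.region_labels)


def preprocess(x: RegionTimeSeries, low_hz: float = 0.01, high_hz: float = 0.1,
               filter_signal: bool = True) -> BinaryTimeSeries:
    """Full continuous-to-binary chain: detrend/filter, z-score, binarize."""
    if filter_signal:
        x = detrend_and_filter(x, low_hz, high_hz)
    return binarize(standardize(x))


def concatenate_subjects(series: list[BinaryTimeSeries],
                         subject_ids: list[str] | None = None
                         ) -> BinaryTimeSeries:
    """Join per-subject binary series along the time axis.

    The output's provenance records each subject's segment so transition
    counting can exclude the artificial cross-subject jumps.
    """
    if not series:
        raise ValueError("cannot concatenate an empty list of series")
    labels = series[0].region_labels
    for s in series[1:]:
        if s.n_regions != series[0].n_regions or s.region_labels != labels:
            raise ValueError("all series must share region labels and width")
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(len(series))]
    segments, pos = [], 0
    for sid, s in zip(subject_ids, series):
        segments.append(Segment(sid, pos, s.n_timepoints))
        pos += s.n_timepoints
    values = np.concatenate([s.values for s in series], axis=0)
    return BinaryTimeSeries(values, labels, segments)


def leave_one_out_concat(series: list[BinaryTimeSeries],
                         subject_ids: list[str] | None = None
                         ) -> list[BinaryTimeSeries]:
    """All leave-one-subject-out concatenations, in left-out order.

    With ``n`` input subjects, returns ``n`` concatenated series; the
    ``i``-th omits subject ``i`` and preserves the order of the rest.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 subjects for leave-one-out")
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(len(series))]
    out = []
    for i in range(len(series)):
        rest = [s for j, s in enumerate(series) if j != i]
        ids = [sid for j, sid in enumerate(subject_ids) if j != i]
        out.append(concatenate_subjects(rest, ids))
    return out
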