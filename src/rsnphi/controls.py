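"""Spatial and temporal permutation controls.

Two null models probe what a metric actually measures:

* **Spatial controls** regroup regions across networks: each control
  network draws its regions from distinct source networks, destroying
  within-network composition while preserving every region's own series.
* **Temporal controls** shuffle whole time points of a series: the
  multiset of system states (hence all state frequencies, and any
  order-insensitive metric such as mean correlation) is exactly
  preserved, while the sequence of transitions is destroyed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import BinaryTimeSeries


@dataclass
class ControlSpec:
    """Counts and seed for the two control procedures."""

    n_spatial: int = 100
    n_temporal_per_network: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spatial < 1 or self.n_temporal_per_network < 1:
            raise ValueError("control counts must be >= 1")


def spatial_controls(region_pool: dict[str, BinaryTimeSeries],
                     spec: ControlSpec,
                     nodes_per_control: int = 5) -> list[BinaryTimeSeries]:
    """Random control networks with all regions from distinct source networks.

    ``region_pool`` maps network label -> its (time-aligned) binary
    series; each control draws ``nodes_per_control`` source networks
    without replacement and takes one randomly chosen region from each.
    """
    labels = sorted(region_pool)
    if len(labels) < nodes_per_control:
        raise ValueError(
            f"need >= {nodes_per_control} source networks, got {len(labels)}")
    lengths = {region_pool[l].n_timepoints for l in labels}
    if len(lengths) != 1:
        raise ValueError("all source series must be aligned in time")
    rng = np.random.default_rng(spec.seed)
    out = []
    for c in range(spec.n_spatial):
        chosen = rng.choice(len(labels), size=nodes_per_control, replace=False)
        cols, names = [], []
        for li in chosen:
            src = region_pool[labels[li]]
            r = int(rng.integers(src.n_regions))
            cols.append(src.values[:, r])
            names.append(f"{labels[li]}:{src.region_labels[r]}")
        first = region_pool[labels[chosen[0]]]
        out.append(BinaryTimeSeries(np.column_stack(cols), names,
                                    list(first.provenance)))
    return out


def temporal_shuffle(series: BinaryTimeSeries, n_perms: int,
                     seed: int = 0) -> list[BinaryTimeSeries]:
    """Independent whole-time-point shuffles of a binary series.

    Rows (multivariate state vectors) are permuted intact, so state
    frequencies are exactly preserved while temporal order is destroyed.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_perms):
        perm = rng.permutation(series.n_timepoints)
        out.append(BinaryTimeSeries(series.values[perm],
                                    series.region_labels,
                                    list(series.provenance)))
    return out


@dataclass
class NullComparison:
    """Where an original value sits relative to a null distribution."""

    original: float
    null_mean: float
    null_sd: float
    percentile: float            # empirical percentile of the original
    p_upper_bound: float         # 1/(n_null + 1), the extreme-rank bound
    welch_t: float | None = None
    welch_p: float | None = None


def compare_to_null(original_value: float, null_values,
                    original_sample=None) -> NullComparison:
    """Summarize an original metric value against permutation nulls.

    Reports the null mean/SD and the original's empirical percentile;
    when a sample of originals is supplied, adds a two-sided Welch
    comparison of the two samples.
    """
    null_values = np.asarray(list(null_values), dtype=float)
    if null_values.size < 2:
        raise ValueError("need at least 2 null values")
    pct = 100.0 * np.mean(null_values < original_value)
    sd = float(null_values.std(ddof=1))
    welch_t = welch_p = None
    if original_sample is not None and sd > 0:
        t, p = stats.ttest_ind(np.asarray(original_sample, dtype=float),
                               null_values, equal_var=False)
        welch_t, welch_p = float(t), float(p)
    return NullComparison(
        original=float(original_value),
        null_mean=float(null_values.mean()),
        null_sd=sd,
        percentile=float(pct),
        p_upper_bound=1.0 / (null_values.size + 1),
        welch_t=welch_t,
        welch_p=welch_p,
    )
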