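"""Modulation analysis: does a metric track the level of awareness?

For each network, a metric's mean value in the four conditions (Awake,
Mild, Deep, Recovery) is arranged into the vector
``M = [m_A, m_M, m_D, m_R]``.  Two summaries follow:

* the **magnitude** ``|M|`` (root sum of squares), the overall amount of
  the metric a network generates, and
* the **awareness similarity** ``S = cos(M, E)`` with the model vector
  ``E = [1, 0, -1, 1]`` — a pattern that decreases into deep sedation and
  rebounds in recovery.  ``S`` is scale-invariant; a network whose metric
  tracks the anesthetic closely has ``S`` near 1.

Uncertainty comes from leave-one-subject-out resampling: the metric is
computed on each concatenation of all-but-one subject, giving an
``N``-value sample per network and condition.  Following the convention
of the emulated study design, the sample SD is read as the standard
error, so the population SD is the sample SD times sqrt(N).  Condition
pairs are compared with Welch's t-test and the Benjamini-Hochberg
procedure controls the false discovery rate across the chosen family.

The analysis is exposed statsmodels-style: build a
:class:`ModulationAnalysis` from a cohort or precomputed samples, call
``fit()`` and inspect the returned :class:`ModulationResults` (with
``summary()`` and a magnitude-vs-similarity plot).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BinaryTimeSeries
from .preprocess import leave_one_out_concat

MODEL_VECTOR = np.array([1.0, 0.0, -1.0, 1.0])


# ---------------------------------------------------------------------------
# elementary operations

@dataclass
class MetricSample:
    """Leave-one-out metric values for one network and condition."""

    values: np.ndarray
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.failures


def loo_metric_sample(series_list: Sequence[BinaryTimeSeries],
                      metric: Callable[[BinaryTimeSeries], float]
                      ) -> MetricSample:
    """Evaluate a metric on every leave-one-subject-out concatenation.

    The i-th value corresponds to leaving out subject i.  A metric
    failure on one concatenation is recorded rather than fatal; the
    sample is then marked incomplete.
    """
    values, failures = [], []
    for i, concat in enumerate(leave_one_out_concat(list(series_list))):
        try:
            values.append(float(metric(concat)))
        except Exception as exc:  # noqa: BLE001 - failures are data here
            values.append(np.nan)
            failures.append((i, repr(exc)))
    return MetricSample(np.asarray(values), failures)


@dataclass
class ConditionVector:
    """A metric's 4-condition mean vector for one network."""

    values: np.ndarray
    metric_name: str = ""
    network_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4,):
            raise ValueError("condition vector must have exactly 4 entries")


def magnitude(v: ConditionVector | np.ndarray) -> float:
    """Root-sum-of-squares of the 4-condition vector."""
    values = v.values if isinstance(v, ConditionVector) else np.asarray(v)
    return float(np.linalg.norm(values))


def similarity(v: ConditionVector | np.ndarray) -> float:
    """Cosine similarity with the awareness model vector [1, 0, -1, 1]."""
    values = v.values if isinstance(v, ConditionVector) else np.asarray(v)
    norm = np.linalg.norm(values)
    if norm == 0:
        raise ValueError("similarity undefined for the zero vector")
    return float(values @ MODEL_VECTOR / (norm * np.linalg.norm(MODEL_VECTOR)))


def magnitude_variability(per_network_m: Sequence[float]) -> float:
    """Percent spread of magnitudes: 100 * (max - min) / max."""
    m = np.asarray(list(per_network_m), dtype=float)
    if m.size < 2:
        raise ValueError("need magnitudes from at least 2 networks")
    if m.max() == 0:
        raise ValueError("all magnitudes are zero")
    return float(100.0 * (m.max() - m.min()) / m.max())


def welch_bh(samples: Mapping[str, np.ndarray], alpha: float = 0.05
             ) -> pd.DataFrame:
    """Welch's t-test for every condition pair, with BH-adjusted flags.

    Returns one row per unordered condition pair with the unequal-
    variance t statistic, two-sided p, and the step-up BH decision at
    level ``alpha`` across the six pairs.  A pair where both samples
    have zero variance is flagged untestable (NaN statistics).
    """
    conds = list(samples)
    rows = []
    for a, b in itertools.combinations(conds, 2):
        xa = np.asarray(samples[a], dtype=float)
        xb = np.asarray(samples[b], dtype=float)
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            if np.allclose(xa.mean(), xb.mean()):
                rows.append((a, b, 0.0, 1.0, False))
            else:
                rows.append((a, b, np.nan, np.nan, False))
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append((a, b, float(t), float(p), True))
    df = pd.DataFrame(rows, columns=["cond_a", "cond_b", "t", "p_raw",
                                     "testable"])
    ok = df["p_raw"].notna()
    sig = np.zeros(len(df), dtype=bool)
    if ok.any():
        sig[ok.to_numpy()] = multipletests(df.loc[ok, "p_raw"], alpha=alpha,
                                           method="fdr_bh")[0]
    df["significant_bh"] = sig
    return df


# ---------------------------------------------------------------------------
# model / results

class ModulationAnalysis:
    """Modulation-and-magnitude model for a cohort of metric samples.

    Parameters
    ----------
    samples : mapping network -> mapping condition -> array of values
        Leave-one-out metric samples (one value per left-out subject).
    conditions : ordered condition labels (length 4).
    metric_name : for labeling output.
    """

    def __init__(self, samples: Mapping[str, Mapping[str, np.ndarray]],
                 conditions: Sequence[str] = ("Awake", "Mild", "Deep",
                                              "Recovery"),
                 metric_name: str = "metric"):
        if len(conditions) != 4:
            raise ValueError("the modulation analysis expects 4 conditions")
        self.conditions = tuple(conditions)
        self.metric_name = metric_name
        self.samples = {
            net: {c: np.asarray(conds[c], dtype=float) for c in conditions}
            for net, conds in samples.items()
        }
        if not self.samples:
            raise ValueError("no networks supplied")

    @classmethod
    def from_cohort(cls, cohort, metric: Callable[[BinaryTimeSeries], float],
                    metric_name: str = "metric",
                    networks: Sequence[str] | None = None
                    ) -> "ModulationAnalysis":
        """Build leave-one-out samples for every network and condition."""
        spec = cohort.spec
        names = list(networks) if networks is not None else list(spec.networks)
        samples: dict[str, dict[str, np.ndarray]] = {}
        for net in names:
            samples[net] = {}
            for cond in spec.conditions:
                ms = loo_metric_sample(cohort.subject_series(net, cond), metric)
                samples[net][cond] = ms.values
        return cls(samples, conditions=spec.conditions,
                   metric_name=metric_name)

    def fit(self, alpha: float = 0.05,
            bh_family: str = "across_networks") -> "ModulationResults":
        """Compute condition vectors, M, S, and the significance table.

        ``bh_family`` selects the multiple-comparison family: BH across
        networks within each condition pair (``across_networks``, the
        default) or across the six pairs within each network
        (``within_network``).
        """
        if bh_family not in ("across_networks", "within_network"):
            raise ValueError("unknown bh_family")
        vectors, mags, sims = {}, {}, {}
        mag_sd, sim_se = {}, {}
        mean_rows = []
        raw_stats = []
        for net, conds in self.samples.items():
            means = np.array([np.nanmean(conds[c]) for c in self.conditions])
            vec = ConditionVector(means, self.metric_name, net)
            vectors[net] = vec
            mags[net] = magnitude(vec)
            sims[net] = similarity(vec)
            # per-replicate vectors give the leave-one-out spread of M and S
            reps = np.column_stack([conds[c] for c in self.conditions])
            n = reps.shape[0]
            m_r = np.linalg.norm(reps, axis=1)
            with np.errstate(invalid="ignore"):
                s_r = reps @ MODEL_VECTOR / (
                    np.linalg.norm(reps, axis=1) * np.linalg.norm(MODEL_VECTOR))
            mag_sd[net] = float(np.nanstd(m_r, ddof=1) * np.sqrt(n))
            sim_se[net] = float(np.nanstd(s_r, ddof=1))
            for c in self.conditions:
                x = conds[c]
                mean_rows.append((net, c, float(np.nanmean(x)),
                                  float(np.nanstd(x, ddof=1) * np.sqrt(len(x)))))
            tab = welch_bh(conds, alpha=alpha)
            tab.insert(0, "network", net)
            raw_stats.append(tab.drop(columns="significant_bh"))
        stats_df = pd.concat(raw_stats, ignore_index=True)
        ok = stats_df["p_raw"].notna()
        sig = np.zeros(len(stats_df), dtype=bool)
        if bh_family == "within_network":
            groups = stats_df.groupby("network").groups
        else:
            groups = stats_df.groupby(["cond_a", "cond_b"]).groups
        for _, idx in groups.items():
            idx = [i for i in idx if ok[i]]
            if idx:
                sig[idx] = multipletests(stats_df.loc[idx, "p_raw"],
                                         alpha=alpha, method="fdr_bh")[0]
        stats_df["significant_bh"] = sig
        means_df = pd.DataFrame(
            mean_rows, columns=["network", "condition", "mean",
                                "population_sd"])
        return ModulationResults(
            model=self, conditions=self.conditions,
            metric_name=self.metric_name, vectors=vectors,
            magnitudes=mags, similarities=sims, magnitude_sd=mag_sd,
            similarity_se=sim_se, condition_means=means_df,
            stat_table=stats_df, alpha=alpha, bh_family=bh_family)


@dataclass
class ModulationResults:
    """Fitted modulation/magnitude summary for a cohort."""

    model: ModulationAnalysis
    conditions: tuple[str, ...]
    metric_name: str
    vectors: dict[str, ConditionVector]
    magnitudes: dict[str, float]
    similarities: dict[str, float]
    magnitude_sd: dict[str, float]
    similarity_se: dict[str, float]
    condition_means: pd.DataFrame
    stat_table: pd.DataFrame
    alpha: float
    bh_family: str

    @property
    def median_similarity(self) -> float:
        return float(np.median(list(self.similarities.values())))

    @property
    def variability_percent(self) -> float:
        """Percent spread of per-network magnitudes, 100*(max-min)/max."""
        return magnitude_variability(list(self.magnitudes.values()))

    def magnitude_similarity_table(self) -> pd.DataFrame:
        rows = [(net, self.magnitudes[net], self.magnitude_sd[net],
                 self.similarities[net], self.similarity_se[net])
                for net in self.vectors]
        return pd.DataFrame(rows, columns=["network", "M", "M_sd", "S",
                                           "S_se"])

    def summary(self) -> str:
        """Human-readable summary table of the fitted analysis."""
        lines = [
            f"Modulation analysis: {self.metric_name}",
            f"conditions: {', '.join(self.conditions)}",
            f"networks: {len(self.vectors)}; "
            f"median S = {self.median_similarity:.3f}; "
            f"magnitude variability = {self.variability_percent:.1f}%",
            "",
            self.magnitude_similarity_table().to_string(
                index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            f"significant condition pairs (BH, alpha={self.alpha}, "
            f"family={self.bh_family}):",
        ]
        sig = self.stat_table[self.stat_table["significant_bh"]]
        if len(sig):
            lines.append(sig.to_string(index=False,
                                       float_format=lambda v: f"{v:.4g}"))
        else:
            lines.append("  (none)")
        return "\n".join(lines)

    def plot_magnitude_similarity(self, ax=None):
        """Scatter of magnitude M against awareness similarity S."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for net in self.vectors:
            ax.errorbar(self.similarities[net], self.magnitudes[net],
                        yerr=self.magnitude_sd[net],
                        xerr=self.similarity_se[net], fmt="o", capsize=2)
            ax.annotate(net, (self.similarities[net], self.magnitudes[net]),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
        ax.axvline(self.median_similarity, ls="--", color="gray", lw=1)
        ax.set_xlabel("awareness similarity S")
        ax.set_ylabel(f"magnitude M ({self.metric_name})")
        return ax
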