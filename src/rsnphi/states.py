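"""State-space machinery for binary network time-series.

A binary network of ``N`` regions occupies one of ``2**N`` discrete states
at every time point.  States are indexed in *little-endian* (LE)
convention: node 0 is the least significant bit, so ``[1, 0, 0, 0, 0]`` has
index 1 and ``[1, 1, 0, 0, 0]`` has index 3.

This module converts binary series to LE state sequences, estimates the
empirical state-by-state transition probability matrix (TPM), converts
between the state-by-state and state-by-node TPM forms, and provides the
two diagnostics that probe the assumptions behind the integrated
information analysis: a chi-squared contingency test of the first-order
Markov property, and a conditional-independence distance that measures how
far a TPM is from factorizing across nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BinaryTimeSeries

UnvisitedPolicy = Literal["uniform", "self", "error"]


# ---------------------------------------------------------------------------
# indexing

def state_to_index(state: Sequence[int]) -> int:
    """Little-endian index of a binary state vector (node 0 = LSB)."""
    idx = 0
    for k, s in enumerate(state):
        if s not in (0, 1):
            raise ValueError(f"non-binary entry {s!r} at position {k}")
        idx += int(s) << k
    return idx


def index_to_state(i: int, n_nodes: int) -> np.ndarray:
    """Binary state vector for little-endian index ``i``."""
    if not 0 <= i < 2**n_nodes:
        raise ValueError(f"index {i} out of range for {n_nodes} nodes")
    return (i >> np.arange(n_nodes)) & 1


def all_states(n_nodes: int) -> np.ndarray:
    """(2**N, N) array whose row ``i`` is the LE state vector of index ``i``."""
    return (np.arange(2**n_nodes)[:, None] >> np.arange(n_nodes)) & 1


# ---------------------------------------------------------------------------
# containers

@dataclass
class StateSequence:
    """Ordered LE state indices with subject-segment boundaries."""

    indices: np.ndarray
    n_nodes: int
    segment_boundaries: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 1 or self.indices.size == 0:
            raise ValueError("indices must be a nonempty 1-D array")
        if self.indices.min() < 0 or self.indices.max() >= 2**self.n_nodes:
            raise ValueError("state index out of range for n_nodes")
        b = list(self.segment_boundaries)
        if b != sorted(b) or b[0] != 0 or b[-1] >= self.indices.size:
            raise ValueError("segment boundaries must be sorted, start at 0 "
                             "and lie within the sequence")

    def __len__(self) -> int:
        return self.indices.size

    @property
    def n_states(self) -> int:
        return 2**self.n_nodes

    def segments(self) -> list[np.ndarray]:
        """The per-segment slices of the index sequence."""
        bounds = list(self.segment_boundaries) + [self.indices.size]
        return [self.indices[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def encode(series: BinaryTimeSeries) -> StateSequence:
    """LE state sequence of a binary series, carrying its provenance."""
    weights = 1 << np.arange(series.n_regions)
    idx = series.values.astype(np.int64) @ weights
    return StateSequence(idx, series.n_regions, series.segment_boundaries)


@dataclass
class StateByStateTPM:
    """Row-stochastic ``2**N x 2**N`` matrix of state transitions."""

    probs: np.ndarray
    counts: np.ndarray | None = None
    visited_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        m, k = self.probs.shape
        if m != k or m & (m - 1):
            raise ValueError("state-by-state TPM must be square with 2**N rows")
        if (self.probs < -1e-12).any() or (self.probs > 1 + 1e-12).any():
            raise ValueError("TPM entries must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("TPM rows must sum to 1")
        if self.visited_mask is None:
            self.visited_mask = np.ones(m, dtype=bool)

    @property
    def n_nodes(self) -> int:
        return int(np.log2(self.probs.shape[0]))


@dataclass
class StateByNodeTPM:
    """``2**N x N`` matrix: P(node j ON next | current system state i)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        m, n = self.probs.shape
        if m != 2**n:
            raise ValueError("state-by-node TPM must have 2**N rows for N columns")
        if (self.probs < -1e-12).any() or (self.probs > 1 + 1e-12).any():
            raise ValueError("TPM entries must lie in [0, 1]")
        self.probs = np.clip(self.probs, 0.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return self.probs.shape[1]


# ---------------------------------------------------------------------------
# TPM estimation

def transition_counts(seq: StateSequence, respect_boundaries: bool = True
                      ) -> np.ndarray:
    """Raw i -> j transition counts; boundary-spanning pairs optionally excluded."""
    n = seq.n_states
    counts = np.zeros((n, n), dtype=np.int64)
    chunks = seq.segments() if respect_boundaries else [seq.indices]
    for chunk in chunks:
        if chunk.size < 2:
            continue
        np.add.at(counts, (chunk[:-1], chunk[1:]), 1)
    return counts


def estimate_tpm(seq: StateSequence,
                 unvisited_policy: UnvisitedPolicy = "uniform",
                 respect_boundaries: bool = True) -> StateByStateTPM:
    """Empirical state-by-state TPM from a state sequence.

    Each row is the count of transitions out of that state, normalized by
    the number of times the state appeared *and transitioned onward* (a
    state occurring only at the end of a segment contributes no row mass).
    Rows never observed to transition are filled per ``unvisited_policy``:
    ``uniform`` (maximum entropy, the default), ``self`` (absorbing
    self-loop) or ``error``.
    """
    counts = transition_counts(seq, respect_boundaries)
    totals = counts.sum(axis=1)
    visited = totals > 0
    if not visited.any():
        raise ValueError("no transitions observed; sequence too short")
    if unvisited_policy == "error" and not visited.all():
        missing = np.flatnonzero(~visited)
        raise ValueError(f"states never observed to transition: {missing.tolist()}")
    probs = np.empty_like(counts, dtype=float)
    probs[visited] = counts[visited] / totals[visited, None]
    if unvisited_policy == "self":
        probs[~visited] = np.eye(counts.shape[0])[~visited]
    else:
        probs[~visited] = 1.0 / counts.shape[0]
    return StateByStateTPM(probs, counts=counts, visited_mask=visited)


def state_frequencies(seq: StateSequence) -> np.ndarray:
    """Occurrence frequency of each LE state; nonnegative, sums to 1."""
    counts = state_counts(seq)
    return counts / counts.sum()


def state_counts(seq: StateSequence) -> np.ndarray:
    """Occurrence count of each LE state in the sequence."""
    return np.bincount(seq.indices, minlength=seq.n_states).astype(np.int64)


# ---------------------------------------------------------------------------
# state-by-state <-> state-by-node

def sbs_to_sbn(tpm: StateByStateTPM) -> StateByNodeTPM:
    """Marginal per-node ON-probability given each current system state."""
    n = tpm.n_nodes
    bits = all_states(n)                      # (2**N, N), row j = state j
    return StateByNodeTPM(tpm.probs @ bits.astype(float))


def sbn_to_sbs(tpm: StateByNodeTPM) -> StateByStateTPM:
    """The unique conditionally independent state-by-state TPM.

    Next-state probability factorizes as the product over nodes of each
    node's marginal ON/OFF probability.
    """
    n = tpm.n_nodes
    bits = all_states(n)                      # (2**N, N)
    p_on = tpm.probs[:, None, :]              # (rows, 1, N)
    node_probs = np.where(bits[None, :, :] == 1, p_on, 1.0 - p_on)
    return StateByStateTPM(node_probs.prod(axis=2))


@dataclass
class CITestResult:
    """Relative Frobenius distance between a TPM and its factorized form."""

    distance: float
    original: StateByStateTPM
    independent: StateByStateTPM


def conditional_independence_distance(tpm: StateByStateTPM) -> CITestResult:
    """How far a TPM is from conditional independence across nodes.

    The TPM ``A`` is converted to state-by-node form and back, yielding the
    conditionally independent variant ``B``; the reported distance is
    ``||A - B||_F / ||B||_F``.  Zero iff ``A`` already factorizes.
    """
    indep = sbn_to_sbs(sbs_to_sbn(tpm))
    denom = float(np.linalg.norm(indep.probs))
    if denom == 0.0:  # impossible for a stochastic matrix; guarded anyway
        raise ZeroDivisionError("independent TPM has zero Frobenius norm")
    dist = float(np.linalg.norm(tpm.probs - indep.probs)) / denom
    return CITestResult(distance=dist, original=tpm, independent=indep)


# ---------------------------------------------------------------------------
# Markov-property test

@dataclass
class MarkovTestResult:
    """Chi-squared contingency test for first-order (Markov) dependence.

    ``table`` has one row per observed three-state sequence ``(x, b, c)``
    sharing the final two states ``(b, c)`` of the most frequent such
    triple; columns are the sequence count SC and non-sequence count NSC.
    Under the Markov property, P(c | b) does not depend on ``x``, so the
    SC/NSC proportions are homogeneous across rows.
    """

    table: pd.DataFrame
    chi2: float
    dof: int
    p_value: float
    reject: bool
    seed_triple: tuple[int, int, int]
    alpha: float


def _triples(seq: StateSequence) -> np.ndarray:
    """All within-segment consecutive state triples, shape (n, 3)."""
    rows = []
    for chunk in seq.segments():
        if chunk.size >= 3:
            rows.append(np.column_stack([chunk[:-2], chunk[1:-1], chunk[2:]]))
    if not rows:
        raise ValueError("sequence has no three-state runs within a segment")
    return np.concatenate(rows, axis=0)


def markov_chi2_test(seq: StateSequence, alpha: float = 0.05,
                     min_expected_warn: float = 5.0) -> MarkovTestResult:
    """Test the state sequence for violations of the Markov property.

    Seeds on the most frequent triple ``(a, b, c)`` with ``b != c``; rows
    enumerate every observed first state ``x`` preceding the bigram
    ``(b, c)``-context, i.e. triples ``(x, b, *)``.  The chi-squared
    statistic compares SC = #(x, b, c) against NSC = #(x, b, not-c) across
    rows, with ``H - 1`` degrees of freedom.  Rejection indicates that the
    third state's probability depends on the state two steps back.
    """
    trip = _triples(seq)
    mask = trip[:, 1] != trip[:, 2]
    if not mask.any():
        raise ValueError("no three-state sequence with b != c; not testable")
    sub = trip[mask]
    # most frequent (a, b, c) triple with b != c
    key = (sub[:, 0] * seq.n_states + sub[:, 1]) * seq.n_states + sub[:, 2]
    vals, cnt = np.unique(key, return_counts=True)
    best = vals[np.argmax(cnt)]
    a = int(best // seq.n_states**2)
    b = int((best // seq.n_states) % seq.n_states)
    c = int(best % seq.n_states)

    ctx = trip[trip[:, 1] == b]               # all (x, b, *)
    first_states = np.unique(ctx[:, 0])
    rows = []
    for x in first_states:
        block = ctx[ctx[:, 0] == x]
        sc = int((block[:, 2] == c).sum())
        nsc = int((block[:, 2] != c).sum())
        rows.append((x, sc, nsc))
    table = pd.DataFrame(rows, columns=["first_state", "SC", "NSC"])
    table["TSC"] = table["SC"] + table["NSC"]
    h = len(table)
    if h < 2:
        raise ValueError("only one first state observed (H < 2); not testable")

    observed = table[["SC", "NSC"]].to_numpy(dtype=float)
    n = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    if (expected < min_expected_warn).any():
        warnings.warn(
            "Markov test: some expected counts are below "
            f"{min_expected_warn}; the chi-squared approximation may be poor",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = (observed - expected) ** 2 / expected
    chi2 = float(np.nansum(cells))
    dof = h - 1
    p = float(stats.chi2.sf(chi2, dof))
    return MarkovTestResult(table=table, chi2=chi2, dof=dof, p_value=p,
                            reject=bool(p < alpha), seed_triple=(a, b, c),
                            alpha=alpha)
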