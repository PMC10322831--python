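"""Integrated information (IIT 3.0) for small binary networks.

Given a network's state-by-node TPM and its current state, this module
computes cause and effect repertoires, mechanism-level integrated
information (small phi) via the minimum-information partition, the
conceptual structure, and system-level big Phi as the minimum over
unidirectional cuts of the extended earth mover's distance between the
intact and cut conceptual structures.  ``phi_max`` maximizes big Phi over
candidate subsystems and ``mu_phi_max`` averages it over a time-series,
weighting each visited state by its occurrence frequency.

Conventions (the canonical IIT 3.0 choices, stated explicitly because the
quantities are only defined relative to them):

* Unconstrained priors are uniform (maximum entropy).
* Cause repertoires factorize over mechanism elements: each mechanism
  node's likelihood over the purview is marginalized separately over
  non-purview inputs ("virtual elements"), then multiplied and
  renormalized.  Effect repertoires factorize over purview elements.
* The mechanism-level ground metric is the Hamming distance between
  purview states; the system-level distance transports concept mass
  (weighted by small phi) between conceptual structures, with destroyed
  concepts moved to the null concept (the unconstrained repertoires).
* Conditioning on an event of zero empirical probability substitutes the
  uniform repertoire and sets a flag (empirical TPMs are not strictly
  positive).
* Ties between purviews or partitions break toward the larger purview,
  then the lowest little-endian node-mask, so results are deterministic.
"""

from __future__ import annotations

import functools
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from ..containers import BinaryTimeSeries
from ..states import (StateByNodeTPM, all_states, encode, estimate_tpm,
                      index_to_state, sbs_to_sbn, state_frequencies,
                      state_to_index)
from .emd import _min_cost_transport, emd_hamming

PHI_TOL = 1e-10          # threshold for "a concept exists"
_EQ_TOL = 1e-12


# ---------------------------------------------------------------------------
# cached combinatorics

@functools.lru_cache(maxsize=64)
def _nonempty_subsets(k: int) -> tuple[tuple[int, ...], ...]:
    nodes = range(k)
    return tuple(s for r in range(1, k + 1)
                 for s in itertools.combinations(nodes, r))


@functools.lru_cache(maxsize=4096)
def _unordered_bipartitions(items: tuple[int, ...]
                            ) -> tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]:
    """All unordered two-part splits of ``items``, including ((), items)."""
    out = []
    n = len(items)
    for r in range(n // 2 + 1):
        for first in itertools.combinations(items, r):
            second = tuple(x for x in items if x not in first)
            if r == n - r and first > second:
                continue  # avoid double-counting the balanced splits
            out.append((first, second))
    return tuple(out)


@functools.lru_cache(maxsize=4096)
def _ordered_bipartitions(items: tuple[int, ...]
                          ) -> tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]:
    """All ordered two-part splits of ``items``, including empty parts."""
    out = []
    for r in range(len(items) + 1):
        for first in itertools.combinations(items, r):
            second = tuple(x for x in items if x not in first)
            out.append((first, second))
    return tuple(out)


def _mask(nodes: tuple[int, ...]) -> int:
    m = 0
    for n in nodes:
        m |= 1 << n
    return m


# ---------------------------------------------------------------------------
# results

@dataclass
class SmallPhiResult:
    """Mechanism-level irreducibility in one direction."""

    phi: float
    purview: tuple[int, ...]
    partition: tuple | None
    repertoire: np.ndarray


@dataclass
class Concept:
    """A mechanism with its maximally irreducible cause and effect."""

    mechanism: tuple[int, ...]
    small_phi: float
    cause: SmallPhiResult
    effect: SmallPhiResult


@dataclass
class ConceptualStructure:
    """All concepts of a subsystem in its current state."""

    concepts: list[Concept]
    unconstrained_cause: np.ndarray
    unconstrained_effect: np.ndarray

    @property
    def total_phi(self) -> float:
        return float(sum(c.small_phi for c in self.concepts))


@dataclass
class PhiTimeAverage:
    """Per-state big Phi and its occurrence-weighted time average."""

    per_state_phi: np.ndarray     # NaN for states never visited
    weights: np.ndarray
    mu_phi_max: float
    subset_mode: str
    n_nodes: int


# ---------------------------------------------------------------------------
# subsystem

class Subsystem:
    """A set of nodes of a binary network, in a fixed current state.

    Nodes outside the subsystem are background conditions: they are frozen
    at their current state when the subsystem TPM is extracted.  All
    repertoire and integration computations then live in the subsystem's
    own ``2**k`` state space.
    """

    def __init__(self, tpm: StateByNodeTPM, state, nodes=None):
        state = tuple(int(s) for s in state)
        n = tpm.n_nodes
        if len(state) != n:
            raise ValueError("state length must equal network size")
        if any(s not in (0, 1) for s in state):
            raise ValueError("state entries must be 0 or 1")
        if nodes is None:
            nodes = tuple(range(n))
        nodes = tuple(sorted(int(v) for v in nodes))
        if len(set(nodes)) != len(nodes) or any(v < 0 or v >= n for v in nodes):
            raise ValueError("nodes must be distinct indices into the network")
        self.network_tpm = tpm
        self.network_state = state
        self.nodes = nodes
        self.k = len(nodes)
        self.state = tuple(state[v] for v in nodes)
        self.uniform_fallbacks = 0

        bits = all_states(self.k)                        # (2**k, k)
        frozen = sum(state[e] << e for e in range(n) if e not in nodes)
        full_idx = bits @ (np.array([1 << v for v in nodes])) + frozen
        self.node_tpm = tpm.probs[full_idx][:, list(nodes)]  # (2**k, k)
        self._bits = bits
        self._init_caches()

    def _init_caches(self) -> None:
        # likelihood of each node's *current* state given each past substate
        col = self.node_tpm
        s = np.array(self.state)
        self._likelihood = np.where(s[None, :] == 1, col, 1.0 - col)
        self._rep_cache: dict = {}
        self._marg_cache: dict = {}
        self._pidx_cache: dict = {}
        self._mask_cache: dict = {}

    @classmethod
    def _from_node_tpm(cls, node_tpm: np.ndarray, template: "Subsystem"
                       ) -> "Subsystem":
        sub = cls.__new__(cls)
        sub.network_tpm = template.network_tpm
        sub.network_state = template.network_state
        sub.nodes = template.nodes
        sub.k = template.k
        sub.state = template.state
        sub.uniform_fallbacks = 0
        sub.node_tpm = node_tpm
        sub._bits = template._bits
        sub._init_caches()
        return sub

    # -- index helpers ------------------------------------------------------

    def _purview_index(self, purview: tuple[int, ...]) -> np.ndarray:
        """Map each subsystem substate to its purview-substate index."""
        hit = self._pidx_cache.get(purview)
        if hit is None:
            pw = np.array([1 << j for j in range(len(purview))])
            hit = self._bits[:, list(purview)] @ pw
            self._pidx_cache[purview] = hit
        return hit

    def _mechanism_rows(self, mechanism: tuple[int, ...]) -> np.ndarray:
        """Rows of the subsystem TPM consistent with the mechanism's state."""
        hit = self._mask_cache.get(mechanism)
        if hit is None:
            cols = self._bits[:, list(mechanism)]
            want = np.array([self.state[i] for i in mechanism])
            hit = np.flatnonzero((cols == want[None, :]).all(axis=1))
            self._mask_cache[mechanism] = hit
        return hit

    # -- repertoires --------------------------------------------------------

    def _node_cause_likelihood(self, node: int, purview: tuple[int, ...]
                               ) -> np.ndarray:
        """One mechanism node's likelihood over purview past states.

        Non-purview past inputs are marginalized uniformly *per node*
        (the virtual-elements convention).
        """
        key = (node, purview)
        hit = self._marg_cache.get(key)
        if hit is None:
            pidx = self._purview_index(purview)
            hit = np.bincount(pidx, weights=self._likelihood[:, node],
                              minlength=2 ** len(purview))
            self._marg_cache[key] = hit
        return hit

    def cause_repertoire(self, mechanism: tuple[int, ...],
                         purview: tuple[int, ...]) -> np.ndarray:
        """Posterior over purview past states given the mechanism's state."""
        mechanism = tuple(sorted(mechanism))
        purview = tuple(sorted(purview))
        if not purview:
            return np.ones(1)
        if not mechanism:
            return np.full(2 ** len(purview), 1.0 / 2 ** len(purview))
        key = ("c", mechanism, purview)
        hit = self._rep_cache.get(key)
        if hit is not None:
            return hit
        joint = self._node_cause_likelihood(mechanism[0], purview).copy()
        for node in mechanism[1:]:
            joint *= self._node_cause_likelihood(node, purview)
        total = joint.sum()
        if total <= 0.0:
            self.uniform_fallbacks += 1
            rep = np.full(joint.size, 1.0 / joint.size)
        else:
            rep = joint / total
        self._rep_cache[key] = rep
        return rep

    def effect_repertoire(self, mechanism: tuple[int, ...],
                          purview: tuple[int, ...]) -> np.ndarray:
        """Forward distribution over purview next states given the mechanism.

        Inputs from non-mechanism nodes are marginalized uniformly; the
        joint factorizes over purview nodes.
        """
        mechanism = tuple(sorted(mechanism))
        purview = tuple(sorted(purview))
        if not purview:
            return np.ones(1)
        key = ("e", mechanism, purview)
        hit = self._rep_cache.get(key)
        if hit is not None:
            return hit
        rows = self._mechanism_rows(mechanism)
        p_on = self.node_tpm[rows][:, list(purview)].mean(axis=0)
        zbits = all_states(len(purview))
        rep = np.where(zbits == 1, p_on[None, :], 1.0 - p_on[None, :]).prod(axis=1)
        self._rep_cache[key] = rep
        return rep

    def repertoire(self, direction: str, mechanism: tuple[int, ...],
                   purview: tuple[int, ...]) -> np.ndarray:
        if direction == "cause":
            return self.cause_repertoire(mechanism, purview)
        if direction == "effect":
            return self.effect_repertoire(mechanism, purview)
        raise ValueError(f"unknown direction {direction!r}")

    def unconstrained_repertoire(self, direction: str,
                                 purview: tuple[int, ...]) -> np.ndarray:
        return self.repertoire(direction, (), purview)

    def _sub_purview_index(self, purview: tuple[int, ...],
                           part: tuple[int, ...]) -> np.ndarray:
        """Map purview-substate indices to part-substate indices."""
        key = ("sub", purview, part)
        hit = self._pidx_cache.get(key)
        if hit is None:
            zbits = all_states(len(purview))
            pos = [purview.index(p) for p in part]
            pw = np.array([1 << j for j in range(len(part))], dtype=np.int64)
            if part:
                hit = zbits[:, pos] @ pw
            else:
                hit = np.zeros(2 ** len(purview), dtype=np.int64)
            self._pidx_cache[key] = hit
        return hit

    def partitioned_repertoire(self, direction: str, purview, part0, part1
                               ) -> np.ndarray:
        """Product repertoire of a two-part (mechanism, purview) factorization."""
        (m0, z0), (m1, z1) = part0, part1
        r0 = self.repertoire(direction, m0, z0)
        r1 = self.repertoire(direction, m1, z1)
        i0 = self._sub_purview_index(purview, z0)
        i1 = self._sub_purview_index(purview, z1)
        return r0[i0] * r1[i1]

    # -- mechanism-level integration ----------------------------------------

    def small_phi(self, mechanism, direction: str) -> SmallPhiResult:
        """Irreducibility of a mechanism in one direction.

        For each candidate purview, phi is the EMD from the intact
        repertoire to the closest two-part factorization (the MIP); the
        purview maximizing that minimum wins, larger purviews then lower
        node-masks breaking ties.
        """
        mechanism = tuple(sorted(mechanism))
        if not mechanism:
            raise ValueError("mechanism must be nonempty")
        best: SmallPhiResult | None = None
        best_len = -1
        best_mask = 0
        for purview in _nonempty_subsets(self.k):
            whole = self.repertoire(direction, mechanism, purview)
            phi_z = np.inf
            mip = None
            for m0, m1 in _unordered_bipartitions(mechanism):
                for z0, z1 in _ordered_bipartitions(purview):
                    if not ((m0 or z0) and (m1 or z1)):
                        continue
                    part = self.partitioned_repertoire(
                        direction, purview, (m0, z0), (m1, z1))
                    if np.abs(part - whole).max() < _EQ_TOL:
                        phi_z, mip = 0.0, ((m0, z0), (m1, z1))
                        break
                    d = emd_hamming(whole, part, len(purview))
                    if d < phi_z:
                        phi_z, mip = d, ((m0, z0), (m1, z1))
                        if phi_z < _EQ_TOL:
                            break
                if phi_z < _EQ_TOL:
                    phi_z = 0.0
                    break
            pmask = _mask(purview)
            better = (
                best is None or phi_z > best.phi + _EQ_TOL
                or (abs(phi_z - best.phi) <= _EQ_TOL
                    and (len(purview) > best_len
                         or (len(purview) == best_len and pmask < best_mask)))
            )
            if better:
                best = SmallPhiResult(float(phi_z), purview, mip, whole)
                best_len, best_mask = len(purview), pmask
        assert best is not None
        return best

    def concept(self, mechanism) -> Concept | None:
        """The mechanism's concept, or None if it is reducible."""
        cause = self.small_phi(mechanism, "cause")
        if cause.phi <= PHI_TOL:
            return None
        effect = self.small_phi(mechanism, "effect")
        phi = min(cause.phi, effect.phi)
        if phi <= PHI_TOL:
            return None
        return Concept(tuple(sorted(mechanism)), float(phi), cause, effect)

    def conceptual_structure(self) -> ConceptualStructure:
        """All concepts with small phi > 0, plus the unconstrained references."""
        full = tuple(range(self.k))
        concepts = []
        for mech in _nonempty_subsets(self.k):
            c = self.concept(mech)
            if c is not None:
                concepts.append(c)
        return ConceptualStructure(
            concepts=concepts,
            unconstrained_cause=self.unconstrained_repertoire("cause", full),
            unconstrained_effect=self.unconstrained_repertoire("effect", full),
        )

    # -- system-level integration -------------------------------------------

    def apply_cut(self, cut_from: tuple[int, ...], cut_to: tuple[int, ...]
                  ) -> "Subsystem":
        """Sever connections from ``cut_from`` to ``cut_to`` (positions).

        Nodes in ``cut_to`` have their inputs from ``cut_from`` replaced by
        uniform noise (marginalized); everything else is untouched.
        """
        maskA = _mask(cut_from)
        new_tpm = self.node_tpm.copy()
        states = np.arange(2**self.k)
        base = states & ~maskA
        acc = np.zeros((2**self.k, len(cut_to)))
        patterns = [p for p in range(2**self.k) if p & ~maskA == 0]
        for p in patterns:
            acc += self.node_tpm[base | p][:, list(cut_to)]
        new_tpm[:, list(cut_to)] = acc / len(patterns)
        return Subsystem._from_node_tpm(new_tpm, self)

    def _expand_cause(self, rep: np.ndarray, purview: tuple[int, ...]
                      ) -> np.ndarray:
        """Expand a cause repertoire to the full subsystem space (uniform)."""
        pidx = self._purview_index(purview)
        missing = self.k - len(purview)
        return rep[pidx] / 2**missing

    def _expand_effect(self, rep: np.ndarray, purview: tuple[int, ...]
                       ) -> np.ndarray:
        """Expand an effect repertoire with the unconstrained effect marginals."""
        rest = tuple(j for j in range(self.k) if j not in purview)
        pidx = self._purview_index(purview)
        out = rep[pidx]
        if rest:
            u = self.unconstrained_repertoire("effect", rest)
            out = out * u[self._purview_index(rest)]
        return out

    def _expanded_concepts(self, ces: ConceptualStructure
                           ) -> list[tuple[float, np.ndarray, np.ndarray]]:
        return [(c.small_phi,
                 self._expand_cause(c.cause.repertoire, c.cause.purview),
                 self._expand_effect(c.effect.repertoire, c.effect.purview))
                for c in ces.concepts]

    def null_concept(self) -> tuple[np.ndarray, np.ndarray]:
        """Unconstrained cause and effect repertoires over the full space."""
        full = tuple(range(self.k))
        return (self.unconstrained_repertoire("cause", full),
                self.unconstrained_repertoire("effect", full))

    def system_phi(self) -> float:
        """Big Phi: minimum over unidirectional cuts of the CES distance."""
        if self.k < 2:
            raise ValueError("system-level Phi needs at least 2 nodes")
        intact = self.conceptual_structure()
        if not intact.concepts:
            return 0.0
        intact_x = self._expanded_concepts(intact)
        null = self.null_concept()
        best = np.inf
        positions = tuple(range(self.k))
        for cut_from, cut_to in _ordered_bipartitions(positions):
            if not cut_from or not cut_to:
                continue
            cut_sub = self.apply_cut(cut_from, cut_to)
            cut_ces = cut_sub.conceptual_structure()
            cut_x = cut_sub._expanded_concepts(cut_ces)
            d = _ces_distance(intact_x, cut_x, null, self.k)
            if d < best:
                best = d
                if best < _EQ_TOL:
                    return 0.0
        return float(max(best, 0.0))


def _ces_distance(c1: list, c2: list, null: tuple[np.ndarray, np.ndarray],
                  k: int) -> float:
    """Extended EMD between two conceptual structures.

    Concept mass (small phi) is transported between structures; surplus
    mass on either side goes to the null concept.  The ground distance
    between two concepts is the Hamming-metric EMD between their expanded
    cause repertoires plus that between their expanded effects.
    """
    if not c1 and not c2:
        return 0.0
    null_c, null_e = null

    def cdist(a_cause, a_eff, b_cause, b_eff) -> float:
        return (emd_hamming(a_cause, b_cause, k)
                + emd_hamming(a_eff, b_eff, k))

    n1, n2 = len(c1), len(c2)
    tot1 = sum(c[0] for c in c1)
    tot2 = sum(c[0] for c in c2)
    supply = np.array([c[0] for c in c1] + [tot2], dtype=float)
    demand = np.array([c[0] for c in c2] + [tot1], dtype=float)
    cost = np.zeros((n1 + 1, n2 + 1))
    for i, (_, ac, ae) in enumerate(c1):
        for j, (_, bc, be) in enumerate(c2):
            cost[i, j] = cdist(ac, ae, bc, be)
        cost[i, n2] = cdist(ac, ae, null_c, null_e)
    for j, (_, bc, be) in enumerate(c2):
        cost[n1, j] = cdist(null_c, null_e, bc, be)
    return float(_min_cost_transport(supply, demand, cost))


# ---------------------------------------------------------------------------
# network-level entry points

def system_phi(tpm: StateByNodeTPM, state, nodes=None) -> float:
    """Big Phi of a (sub)system of a network in a given state."""
    return Subsystem(tpm, state, nodes).system_phi()


def phi_max(tpm: StateByNodeTPM, state, subset_mode: str = "full") -> float:
    """Maximally integrated conceptual information at one state.

    ``full`` evaluates only the complete node set; ``exhaustive``
    maximizes over every node subset of size >= 2 (cost grows steeply: a
    warning is emitted beyond 5 nodes).
    """
    n = tpm.n_nodes
    if subset_mode == "full":
        return system_phi(tpm, state)
    if subset_mode != "exhaustive":
        raise ValueError("subset_mode must be 'full' or 'exhaustive'")
    if n > 5:
        warnings.warn("exhaustive subset search beyond 5 nodes is very "
                      "expensive", stacklevel=2)
    best = 0.0
    for size in range(2, n + 1):
        for nodes in itertools.combinations(range(n), size):
            best = max(best, system_phi(tpm, state, nodes))
    return best


def mu_phi_max(series: BinaryTimeSeries, subset_mode: str = "full",
               unvisited_policy: str = "uniform",
               respect_boundaries: bool = True) -> PhiTimeAverage:
    """Occurrence-weighted time average of Phi^max over a binary series.

    The TPM is estimated from the series (excluding transitions that span
    subject boundaries), Phi^max is computed once per distinct visited
    state, and the weighted mean uses each state's occurrence frequency.
    """
    seq = encode(series)
    tpm = estimate_tpm(seq, unvisited_policy=unvisited_policy,
                       respect_boundaries=respect_boundaries)
    sbn = sbs_to_sbn(tpm)
    weights = state_frequencies(seq)
    n = series.n_regions
    per_state = np.full(2**n, np.nan)
    for idx in np.flatnonzero(weights > 0):
        per_state[idx] = phi_max(sbn, index_to_state(idx, n), subset_mode)
    visited = weights > 0
    mu = float(np.dot(weights[visited], per_state[visited]))
    return PhiTimeAverage(per_state_phi=per_state, weights=weights,
                          mu_phi_max=mu, subset_mode=subset_mode, n_nodes=n)
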