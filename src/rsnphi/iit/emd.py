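"""Earth mover's distance between distributions over binary states.

The ground metric is the Hamming distance between the binary state
vectors of the support, the convention used throughout the integrated
information computation.  The transportation problem is solved exactly by
a successive-shortest-path min-cost-flow routine; when numba is available
it is JIT-compiled (these solves sit in the innermost loop of every
integration measure).  Results are memoized because the same repertoire
pairs recur across partitions and cuts.
"""

from __future__ import annotations

import functools

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _min_cost_transport(supply: np.ndarray, demand: np.ndarray,
                        cost: np.ndarray) -> float:
    """Exact transportation cost via successive shortest augmenting paths.

    Bellman-Ford on the bipartite residual graph; each augmentation is a
    shortest path from a supply with remaining mass to a demand with
    remaining capacity, so intermediate flows stay optimal.
    """
    m = supply.shape[0]
    k = demand.shape[0]
    rem_s = supply.copy()
    rem_d = demand.copy()
    flow = np.zeros((m, k))
    total = 0.0
    eps = 1e-15
    big = 1e30
    while True:
        active = False
        for i in range(m):
            if rem_s[i] > eps:
                active = True
                break
        if not active:
            break
        # Bellman-Ford over nodes: supplies 0..m-1, demands m..m+k-1
        dist = np.full(m + k, big)
        pred = np.full(m + k, -1, dtype=np.int64)
        for i in range(m):
            if rem_s[i] > eps:
                dist[i] = 0.0
        for _ in range(m + k):
            changed = False
            for i in range(m):
                di = dist[i]
                if di >= big:
                    continue
                for j in range(k):
                    nd = di + cost[i, j]
                    if nd < dist[m + j] - 1e-13:
                        dist[m + j] = nd
                        pred[m + j] = i
                        changed = True
            for j in range(k):
                dj = dist[m + j]
                if dj >= big:
                    continue
                for i in range(m):
                    if flow[i, j] > eps:
                        nd = dj - cost[i, j]
                        if nd < dist[i] - 1e-13:
                            dist[i] = nd
                            pred[i] = m + j
                            changed = True
            if not changed:
                break
        # best reachable demand with remaining capacity
        best_j = -1
        best_d = big
        for j in range(k):
            if rem_d[j] > eps and dist[m + j] < best_d:
                best_d = dist[m + j]
                best_j = j
        if best_j < 0:
            break
        # trace path back, find bottleneck
        bottleneck = rem_d[best_j]
        node = m + best_j
        while True:
            p = pred[node]
            if node >= m:  # arrived via forward edge p -> node
                pass
            else:  # arrived via reverse edge (p - m) <- node
                if flow[node, p - m] < bottleneck:
                    bottleneck = flow[node, p - m]
            node = p
            if node < m and pred[node] == -1:
                if rem_s[node] < bottleneck:
                    bottleneck = rem_s[node]
                break
        # apply augmentation
        node = m + best_j
        while True:
            p = pred[node]
            if node >= m:
                flow[p, node - m] += bottleneck
                total += bottleneck * cost[p, node - m]
            else:
                flow[node, p - m] -= bottleneck
                total -= bottleneck * cost[node, p - m]
            node = p
            if node < m and pred[node] == -1:
                break
        rem_s[node] -= bottleneck
        rem_d[best_j] -= bottleneck
    return total


@functools.lru_cache(maxsize=8)
def hamming_matrix(n_bits: int) -> np.ndarray:
    """Pairwise Hamming distances between all 2**n binary states."""
    idx = np.arange(2**n_bits)
    xor = idx[:, None] ^ idx[None, :]
    return np.array([[bin(v).count("1") for v in row] for row in xor],
                    dtype=float)


_CACHE: dict[bytes, float] = {}
_CACHE_LIMIT = 1_000_000


def emd(p: np.ndarray, q: np.ndarray, cost: np.ndarray) -> float:
    """EMD between two distributions under an explicit ground metric."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.shape[0] != cost.shape[0]:
        raise ValueError("distributions and cost matrix sizes must agree")
    if abs(p.sum() - 1.0) > 1e-6 or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("inputs must be normalized distributions")
    # transport only the residual mass: common mass moves at zero cost
    diff = p - q
    if np.abs(diff).max() < 1e-15:
        return 0.0
    src = np.flatnonzero(diff > 1e-15)
    dst = np.flatnonzero(diff < -1e-15)
    if src.size == 0 or dst.size == 0:
        return 0.0
    supply = diff[src]
    demand = -diff[dst]
    sub_cost = np.ascontiguousarray(cost[np.ix_(src, dst)])
    return float(_min_cost_transport(supply, demand, sub_cost))


def emd_hamming(p: np.ndarray, q: np.ndarray, n_bits: int) -> float:
    """Memoized EMD over binary states under the Hamming ground metric."""
    key = (np.round(p, 12).tobytes() + np.round(q, 12).tobytes()
           + bytes([n_bits]))
    hit = _CACHE.get(key)
    if hit is not None:
        return hit
    val = emd(p, q, hamming_matrix(n_bits))
    if len(_CACHE) < _CACHE_LIMIT:
        _CACHE[key] = val
    return val
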