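"""Independent brute-force oracle for the integrated-information engine.

Everything here is computed by explicit enumeration over full network
states with plain Python loops and dictionaries, and every optimal
transport is solved with ``scipy.optimize.linprog`` on the primal
transportation LP — deliberately sharing no code or algorithms with the
package implementation.  The conventions (uniform priors, per-element
marginalization for cause likelihoods, purview-factorized effects,
Hamming ground metric, unidirectional cuts, null-concept transport) are
the same by design; the *computations* are not.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def bits_of(i: int, n: int) -> list[int]:
    return [(i >> k) & 1 for k in range(n)]


def sub_index(full_state: list[int], nodes: tuple[int, ...]) -> int:
    return sum(full_state[v] << j for j, v in enumerate(nodes))


def lp_emd(p, q, cost) -> float:
    """Primal transportation LP: min <C, F> s.t. row/col sums = p, q."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    m, k = len(p), len(q)
    c = np.asarray(cost, float).reshape(-1)
    a_eq = []
    for i in range(m):
        row = np.zeros((m, k))
        row[i, :] = 1
        a_eq.append(row.reshape(-1))
    for j in range(k):
        col = np.zeros((m, k))
        col[:, j] = 1
        a_eq.append(col.reshape(-1))
    b_eq = np.concatenate([p, q])
    res = linprog(c, A_eq=np.array(a_eq), b_eq=b_eq, bounds=(0, None),
                  method="highs")
    assert res.success
    return float(res.fun)


def hamming(i: int, j: int) -> int:
    return bin(i ^ j).count("1")


def lp_emd_hamming(p, q, n_bits: int) -> float:
    cost = [[hamming(i, j) for j in range(2**n_bits)]
            for i in range(2**n_bits)]
    return lp_emd(p, q, cost)


def cause_repertoire(node_tpm, state, mechanism, purview):
    """Enumerate: per mechanism node, average likelihood per purview state."""
    n = len(state)
    nz = len(purview)
    if nz == 0:
        return np.ones(1)
    if not mechanism:
        return np.full(2**nz, 1.0 / 2**nz)
    joint = np.ones(2**nz)
    for i in mechanism:
        per_purview = {z: [] for z in range(2**nz)}
        for past in range(2**n):
            pb = bits_of(past, n)
            z = sub_index(pb, tuple(purview))
            p_on = node_tpm[past][i]
            lik = p_on if state[i] == 1 else 1.0 - p_on
            per_purview[z].append(lik)
        for z in range(2**nz):
            joint[z] *= sum(per_purview[z]) / len(per_purview[z])
    total = joint.sum()
    if total <= 0:
        return np.full(2**nz, 1.0 / 2**nz)
    return joint / total


def effect_repertoire(node_tpm, state, mechanism, purview):
    """Enumerate: per purview node, mean ON-prob over consistent rows."""
    n = len(state)
    nz = len(purview)
    if nz == 0:
        return np.ones(1)
    p_on = []
    for j in purview:
        vals = []
        for cur in range(2**n):
            cb = bits_of(cur, n)
            if all(cb[i] == state[i] for i in mechanism):
                vals.append(node_tpm[cur][j])
        p_on.append(sum(vals) / len(vals))
    rep = np.ones(2**nz)
    for z in range(2**nz):
        zb = bits_of(z, nz)
        v = 1.0
        for j in range(nz):
            v *= p_on[j] if zb[j] == 1 else 1.0 - p_on[j]
        rep[z] = v
    return rep


def repertoire(node_tpm, state, mechanism, purview, direction):
    fn = cause_repertoire if direction == "cause" else effect_repertoire
    return fn(node_tpm, state, mechanism, purview)


def partitions_of(mechanism, purview):
    """All admissible two-part factorizations of (mechanism, purview)."""
    mech = tuple(mechanism)
    pur = tuple(purview)
    mech_splits = set()
    for r in range(len(mech) + 1):
        for first in itertools.combinations(mech, r):
            second = tuple(x for x in mech if x not in first)
            mech_splits.add(tuple(sorted((first, second))))
    out = []
    for m0, m1 in mech_splits:
        for r in range(len(pur) + 1):
            for z0 in itertools.combinations(pur, r):
                z1 = tuple(x for x in pur if x not in z0)
                if (m0 or z0) and (m1 or z1):
                    out.append(((m0, z0), (m1, z1)))
    return out


def partitioned_repertoire(node_tpm, state, purview, part0, part1, direction):
    (m0, z0), (m1, z1) = part0, part1
    r0 = repertoire(node_tpm, state, m0, z0, direction)
    r1 = repertoire(node_tpm, state, m1, z1, direction)
    nz = len(purview)
    out = np.ones(2**nz)
    for z in range(2**nz):
        zb = bits_of(z, nz)
        full = [0] * len(state)
        for j, node in enumerate(purview):
            full[node] = zb[j]
        out[z] = r0[sub_index(full, tuple(z0))] * r1[sub_index(full, tuple(z1))]
    return out


def small_phi(node_tpm, state, mechanism, direction):
    """Max over purviews of the min-over-partitions EMD (value only)."""
    n = len(state)
    best = None
    best_rep = None
    best_purview = None
    for r in range(1, n + 1):
        for purview in itertools.combinations(range(n), r):
            whole = repertoire(node_tpm, state, mechanism, purview, direction)
            phi = None
            for part0, part1 in partitions_of(mechanism, purview):
                cut = partitioned_repertoire(node_tpm, state, purview,
                                             part0, part1, direction)
                d = lp_emd_hamming(whole, cut, len(purview))
                phi = d if phi is None else min(phi, d)
                if phi < 1e-12:
                    break
            # shared tie convention: larger purview, then lowest node mask
            mask = sum(1 << p for p in purview)
            bmask = sum(1 << p for p in best_purview) if best_purview else 0
            if (best is None or phi > best + 1e-12
                    or (abs(phi - best) <= 1e-12
                        and (len(purview) > len(best_purview)
                             or (len(purview) == len(best_purview)
                                 and mask < bmask)))):
                best = phi
                best_rep = whole
                best_purview = purview
    return max(best, 0.0), best_purview, best_rep


def concepts(node_tpm, state):
    """All mechanisms with positive phi in both directions."""
    n = len(state)
    out = []
    for r in range(1, n + 1):
        for mech in itertools.combinations(range(n), r):
            pc, zc, rc = small_phi(node_tpm, state, mech, "cause")
            if pc <= 1e-10:
                continue
            pe, ze, re_ = small_phi(node_tpm, state, mech, "effect")
            if pe <= 1e-10:
                continue
            out.append({"mechanism": mech, "phi": min(pc, pe),
                        "cause": (zc, rc), "effect": (ze, re_)})
    return out


def cut_tpm(node_tpm, cut_from, cut_to, n):
    """Sever cut_from -> cut_to by uniform marginalization over cut_from."""
    new = [list(row) for row in node_tpm]
    for cur in range(2**n):
        cb = bits_of(cur, n)
        for j in cut_to:
            vals = []
            for repl in itertools.product([0, 1], repeat=len(cut_from)):
                full = list(cb)
                for a, v in zip(cut_from, repl):
                    full[a] = v
                vals.append(node_tpm[sub_index_full(full)][j])
            new[cur][j] = sum(vals) / len(vals)
    return new


def sub_index_full(bits: list[int]) -> int:
    return sum(b << k for k, b in enumerate(bits))


def expand_cause(rep, purview, n):
    out = np.ones(2**n)
    for s in range(2**n):
        sb = bits_of(s, n)
        out[s] = rep[sub_index(sb, tuple(purview))] / 2 ** (n - len(purview))
    return out


def expand_effect(node_tpm, state, rep, purview, n):
    rest = tuple(j for j in range(n) if j not in purview)
    out = np.ones(2**n)
    if rest:
        u = effect_repertoire(node_tpm, state, (), rest)
    for s in range(2**n):
        sb = bits_of(s, n)
        v = rep[sub_index(sb, tuple(purview))]
        if rest:
            v *= u[sub_index(sb, rest)]
        out[s] = v
    return out


def ces_distance(c1, c2, null_cause, null_effect, n):
    if not c1 and not c2:
        return 0.0

    def cd(a, b):
        return (lp_emd_hamming(a[0], b[0], n) + lp_emd_hamming(a[1], b[1], n))

    tot1 = sum(c["phi"] for c in c1)
    tot2 = sum(c["phi"] for c in c2)
    supply = [c["phi"] for c in c1] + [tot2]
    demand = [c["phi"] for c in c2] + [tot1]
    null = (null_cause, null_effect)
    reps1 = [(c["xc"], c["xe"]) for c in c1] + [null]
    reps2 = [(c["xc"], c["xe"]) for c in c2] + [null]
    cost = [[cd(a, b) for b in reps2] for a in reps1]
    return lp_emd(supply, demand, cost)


def system_phi(node_tpm, state):
    """Min over unidirectional cuts of the conceptual-structure distance."""
    n = len(state)
    intact = concepts(node_tpm, state)
    if not intact:
        return 0.0
    for c in intact:
        c["xc"] = expand_cause(c["cause"][1], c["cause"][0], n)
        c["xe"] = expand_effect(node_tpm, state, c["effect"][1],
                                c["effect"][0], n)
    null_cause = np.full(2**n, 1.0 / 2**n)
    null_effect = expand_effect(node_tpm, state,
                                effect_repertoire(node_tpm, state, (),
                                                  tuple(range(n))),
                                tuple(range(n)), n)
    best = None
    nodes = list(range(n))
    for r in range(1, n):
        for cut_from in itertools.combinations(nodes, r):
            cut_to = tuple(x for x in nodes if x not in cut_from)
            for a, b in ((cut_from, cut_to), (cut_to, cut_from)):
                new_tpm = cut_tpm(node_tpm, a, b, n)
                cset = concepts(new_tpm, state)
                for c in cset:
                    c["xc"] = expand_cause(c["cause"][1], c["cause"][0], n)
                    c["xe"] = expand_effect(new_tpm, state, c["effect"][1],
                                            c["effect"][0], n)
                d = ces_distance(intact, cset, null_cause, null_effect, n)
                best = d if best is None else min(best, d)
    return max(best, 0.0)
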