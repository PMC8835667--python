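"""Independent brute-force oracles used by the test suite.

These never call the package's dynamic-programming code paths: scores
are obtained by explicitly enumerating every legal state path of the
model and summing (forward) or maximizing (Viterbi) raw path
probabilities.
"""

from __future__ import annotations

import itertools
import math
from typing import List, Tuple

from krabstrat.core import AA_INDEX
from krabstrat.hmm import ProfileHMM


def enumerate_path_scores(hmm: ProfileHMM, seq: str) -> List[float]:
    """Raw probability of every legal state path generating ``seq``.

    A path is: k_N flank emissions, B, a traversal of nodes 1..L as
    match or delete with optional inserts after match nodes (inserts
    force the next node to be a match, since the topology has no
    insert-to-delete edge), E, then k_C flank emissions.
    """
    codes = [AA_INDEX[c] for c in seq]
    T = len(codes)
    L = hmm.n_match
    p_loop = T / (T + 1.0)
    bg = hmm.background
    probs: List[float] = []

    for node_kinds in itertools.product("MD", repeat=L):
        n_match_nodes = node_kinds.count("M")
        # insert slots: after node k (1-based, k < L) when node k is M and
        # node k+1 is M (no insert-to-delete edge exists)
        slots = [k for k in range(L - 1)
                 if node_kinds[k] == "M" and node_kinds[k + 1] == "M"]
        max_ins = T - n_match_nodes
        if max_ins < 0:
            continue
        for ins_counts in _compositions(max_ins, len(slots)):
            n_core = n_match_nodes + sum(ins_counts)
            if n_core > T:
                continue
            for k_n in range(T - n_core + 1):
                k_c = T - n_core - k_n
                p = p_loop ** k_n * (1 - p_loop)
                for t in range(k_n):
                    p *= bg[codes[t]]
                pos = k_n
                # B -> first node
                p *= hmm.begin[0] if node_kinds[0] == "M" else hmm.begin[1]
                ins_at = dict(zip(slots, ins_counts))
                for k in range(L):
                    if node_kinds[k] == "M":
                        p *= hmm.match_emissions[k][codes[pos]]
                        pos += 1
                    if k == L - 1:
                        break  # M_L/D_L -> E with probability 1
                    n_ins = ins_at.get(k, 0)
                    if node_kinds[k] == "M":
                        if n_ins > 0:
                            p *= hmm.t_m[k][1]  # M -> I
                            for i in range(n_ins):
                                p *= hmm.insert_emissions[k][codes[pos]]
                                pos += 1
                                if i < n_ins - 1:
                                    p *= hmm.t_i[k][1]  # I -> I
                            p *= hmm.t_i[k][0]  # I -> M
                        else:
                            p *= hmm.t_m[k][0] if node_kinds[k + 1] == "M" else hmm.t_m[k][2]
                    else:
                        p *= hmm.t_d[k][0] if node_kinds[k + 1] == "M" else hmm.t_d[k][1]
                for t in range(pos, pos + k_c):
                    p *= p_loop * bg[codes[t]]
                p *= 1 - p_loop
                probs.append(p)
    return probs


def _compositions(total_max: int, n_slots: int):
    """All tuples of n_slots non-negative ints with sum <= total_max."""
    if n_slots == 0:
        yield ()
        return
    for first in range(total_max + 1):
        for rest in _compositions(total_max - first, n_slots - 1):
            yield (first,) + rest


def null_probability(hmm: ProfileHMM, seq: str) -> float:
    T = len(seq)
    p_loop = T / (T + 1.0)
    p = p_loop ** T * (1 - p_loop)
    for c in seq:
        p *= hmm.background[AA_INDEX[c]]
    return p


def forward_bits_by_enumeration(hmm: ProfileHMM, seq: str) -> float:
    total = sum(enumerate_path_scores(hmm, seq))
    return math.log2(total / null_probability(hmm, seq))


def viterbi_bits_by_enumeration(hmm: ProfileHMM, seq: str) -> float:
    best = max(enumerate_path_scores(hmm, seq))
    return math.log2(best / null_probability(hmm, seq))


def exact_wmw_p_by_enumeration(a, b) -> float:
    """Two-sided WMW p via direct enumeration of group assignments.

    Deviation-based two-sidedness: the fraction of assignments whose
    rank-sum U deviates from its mean at least as much as observed.
    """
    import numpy as np

    pooled = list(a) + list(b)
    n_a = len(a)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    svals = np.asarray(pooled, float)[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and svals[j + 1] == svals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    mu = n_a * len(b) / 2.0
    offset = n_a * (n_a + 1) / 2.0
    u_obs = ranks[:n_a].sum() - offset
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(combo)].sum() - offset
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
        total += 1
    return hits / total
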