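"""Independent brute-force reference implementations for cross-checks.

Everything here is written with explicit scalar loops directly from the
definitions, sharing no code with the package (only the conventions:
little-endian state indexing, bits-in-bits-out TPMs).
"""

from __future__ import annotations

import math
from itertools import product


def bits_of(idx, n):
    return [(idx >> k) & 1 for k in range(n)]


def per_unit_on_probability(tpm, m, row, unit):
    """p(x'_unit = 1 | row) by summing the row over matching columns."""
    total = 0.0
    for col in range(2**m):
        if (col >> unit) & 1:
            total += tpm[row][col]
    return total


def brute_partitions(m):
    """All directional system partitions as sets of severed (src, dst)."""
    if m == 1:
        return [frozenset({(0, 0)})]
    cuts = set()
    for assignment in product(range(m), repeat=m):
        blocks = {}
        for unit, block in enumerate(assignment):
            blocks.setdefault(block, []).append(unit)
        parts = list(blocks.values())
        if len(parts) < 2:
            continue
        for dirs in product(("in", "out"), repeat=len(parts)):
            cut = set()
            for part, d in zip(parts, dirs):
                rest = [u for u in range(m) if u not in part]
                for a in part:
                    for b in rest:
                        cut.add((a, b) if d == "out" else (b, a))
            cuts.add(frozenset(cut))
    return sorted(cuts, key=lambda c: (len(c), sorted(c)))


def noised_on_probability(tpm, m, row, unit, severed_sources):
    """Average p(x'_unit=1 | .) over states of the severed input units."""
    sources = sorted(set(severed_sources))
    if not sources:
        return per_unit_on_probability(tpm, m, row, unit)
    total, count = 0.0, 0
    for assignment in product((0, 1), repeat=len(sources)):
        r = row
        for src, bit in zip(sources, assignment):
            r = (r & ~(1 << src)) | (bit << src)
        total += per_unit_on_probability(tpm, m, r, unit)
        count += 1
    return total / count


def joint_from_on_probs(on_probs, target, m):
    prob = 1.0
    for i in range(m):
        p1 = on_probs[i]
        prob *= p1 if (target >> i) & 1 else 1.0 - p1
    return prob


def partitioned_joint(tpm, m, row, target, cut):
    on_probs = []
    for i in range(m):
        severed = [a for (a, b) in cut if b == i]
        on_probs.append(noised_on_probability(tpm, m, row, i, severed))
    return joint_from_on_probs(on_probs, target, m)


def brute_phi(cause_tpm, effect_tpm, s0):
    """System integrated information by direct enumeration."""
    m = max(1, (len(cause_tpm) - 1).bit_length())

    # effect direction: selected state maximizes p*log2(p/unconstrained)
    unconstrained_e = [
        sum(effect_tpm[r][c] for r in range(2**m)) / 2**m for c in range(2**m)
    ]
    best_e, ii_e = 0, -math.inf
    for sp in range(2**m):
        p = effect_tpm[s0][sp]
        ii = p * math.log2(p / unconstrained_e[sp]) if p > 0 else 0.0
        if ii > ii_e + 1e-10:
            best_e, ii_e = sp, ii

    # cause direction: Bayesian posterior selectivity, forward informativeness
    col = [cause_tpm[r][s0] for r in range(2**m)]
    denom = sum(col)
    unconstrained_c = denom / 2**m
    best_c, ii_c = 0, -math.inf
    for sp in range(2**m):
        post = col[sp] / denom
        ii = post * math.log2(col[sp] / unconstrained_c) if post > 0 else 0.0
        if ii > ii_c + 1e-10:
            best_c, ii_c = sp, ii

    p_e = effect_tpm[s0][best_e]
    p_c = cause_tpm[best_c][s0]
    sel_c = col[best_c] / denom

    best = None
    for cut in brute_partitions(m):
        pe_cut = partitioned_joint(effect_tpm, m, s0, best_e, cut)
        pc_cut = partitioned_joint(cause_tpm, m, best_c, s0, cut)
        phi_e = max(0.0, p_e * math.log2(p_e / pe_cut)) if p_e > 0 else 0.0
        phi_c = max(0.0, sel_c * math.log2(p_c / pc_cut)) if sel_c > 0 else 0.0
        phi = min(phi_c, phi_e)
        score = phi / len(cut)
        if best is None or score < best[0] - 1e-10:
            best = (score, phi, cut)
        elif abs(score - best[0]) <= 1e-10 and len(cut) > len(best[2]):
            best = (best[0], phi, cut)
    return best[1]


def brute_micro_tpms(sbn, n, system, current):
    """Cause and effect TPMs of a micro subsystem, straight from the
    background-marginalization definitions (uniform prior Bayes for causes,
    clamped current state for effects)."""
    background = [i for i in range(n) if i not in system]
    m = len(system)

    def full_state(s_idx, w_bits):
        state = [0] * n
        for k, i in enumerate(system):
            state[i] = (s_idx >> k) & 1
        for k, i in enumerate(background):
            state[i] = w_bits[k]
        return state

    def row_index(state):
        return sum(b << k for k, b in enumerate(state))

    def trans_prob(prev_state, next_state):
        prob = 1.0
        for i in range(n):
            p1 = sbn[row_index(prev_state)][i]
            prob *= p1 if next_state[i] == 1 else 1.0 - p1
        return prob

    # cause weights: q_c(w) ∝ sum over system states of p(current | s, w)
    weights = []
    for w_bits in product((0, 1), repeat=len(background)):
        total = 0.0
        for s_idx in range(2**m):
            total += trans_prob(full_state(s_idx, list(w_bits)), list(current))
        weights.append(total)
    norm = sum(weights)
    weights = [w / norm for w in weights]

    current_w = [current[i] for i in background]

    cause, effect = [], []
    for s_idx in range(2**m):
        cause_p1, effect_p1 = [], []
        for k, i in enumerate(system):
            avg = 0.0
            for widx, w_bits in enumerate(product((0, 1), repeat=len(background))):
                avg += weights[widx] * sbn[row_index(full_state(s_idx, list(w_bits)))][i]
            cause_p1.append(avg)
            effect_p1.append(sbn[row_index(full_state(s_idx, current_w))][i])
        cause.append([joint_from_on_probs(cause_p1, t, m) for t in range(2**m)])
        effect.append([joint_from_on_probs(effect_p1, t, m) for t in range(2**m)])
    return cause, effect
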