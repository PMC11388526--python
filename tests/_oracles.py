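"""Independent brute-force oracles for the profile-HMM scoring tests.

These enumerate every legal state path explicitly (no dynamic
programming) so they stay independent of the implementation they check.
Only usable at tiny scale (M <= ~4, sequences of length <= ~6).
"""

from __future__ import annotations

import math


def _emission_odds(model, node: int, letter_idx: int) -> float:
    """Match-emission odds e/bg for one letter (X handled as the
    background-weighted average over the background norm)."""
    bg = model.background
    e = model.match_emissions[node]
    if letter_idx >= model.K:  # X
        return float(e @ bg) / float(bg @ bg)
    return float(e[letter_idx]) / float(bg[letter_idx])


def enumerate_core_paths(model, sub_idx):
    """Yield the probability-odds of every begin->end core path consuming
    exactly the index sequence ``sub_idx``."""
    M = model.M
    n = len(sub_idx)

    def walk(kind, node, pos, odds):
        # transitions out of (kind, node); 'M' with node 0 is begin
        if kind == "M":
            nxt = [("M", model.t_mm[node]), ("I", model.t_mi[node])]
            if node < M:
                nxt.append(("D", model.t_md[node]))
        elif kind == "I":
            nxt = [("M", model.t_im[node]), ("I", model.t_ii[node])]
        else:  # D
            nxt = [("M", model.t_dm[node])]
            if node < M:
                nxt.append(("D", model.t_dd[node]))
        for nkind, t in nxt:
            if t == 0.0:
                continue
            if nkind == "I":
                if pos >= n:
                    continue
                # insert emits at the background -> odds factor 1
                yield from walk("I", node, pos + 1, odds * t)
            else:
                new_node = node + 1
                if new_node == M + 1:  # reached end
                    if pos == n:
                        yield odds * t
                    continue
                if nkind == "M":
                    if pos >= n:
                        continue
                    em = _emission_odds(model, new_node, sub_idx[pos])
                    yield from walk("M", new_node, pos + 1, odds * t * em)
                else:
                    yield from walk("D", new_node, pos, odds * t)

    yield from walk("M", 0, 0, 1.0)


def brute_force_scores(model, residues: str):
    """(viterbi_bits, forward_bits) by full path enumeration over every
    flank split, mirroring the glocal contract."""
    idx = list(model.encode(residues))
    n = len(idx)
    best = 0.0
    total = 0.0
    for i in range(n + 1):
        for j in range(i, n + 1):
            for odds in enumerate_core_paths(model, idx[i:j]):
                best = max(best, odds)
                total += odds
    assert total > 0.0, "no legal path found"
    return math.log2(best), math.log2(total)


def core_sequence_probability(model, sub_idx) -> float:
    """Plain probability that a begin->end core traversal emits exactly
    ``sub_idx`` (no flanks, no null normalization).

    enumerate_core_paths yields odds with emissions divided by the
    background (matches e/bg, inserts 1 = bg/bg); multiplying by the
    background product over the consumed residues restores raw probability.
    """
    prob = sum(enumerate_core_paths(model, sub_idx))
    null = 1.0
    for k in sub_idx:
        null *= float(model.background[k])
    return prob * null


# ---------------------------------------------------------------------------
# genotype decision table, written independently of denitscan.genotype

DECISION_TABLE = {
    # (NAR, NIR, NOR, NOS): fine label
    (True, True, True, True): "complete",
    (True, True, True, False): "truncated",
    (True, True, False, True): "modular",
    (True, True, False, False): "modular",
    (True, False, True, True): "modular",
    (True, False, True, False): "modular",
    (True, False, False, True): "modular",
    (True, False, False, False): "modular",
    (False, True, True, True): "modular",
    (False, True, True, False): "modular",
    (False, True, False, True): "modular",
    (False, True, False, False): "modular",
    (False, False, True, True): "modular",
    (False, False, True, False): "nor_only",
    (False, False, False, True): "nos_only",
    (False, False, False, False): "non_denitrifying",
}

COARSE_TABLE = {
    "complete": "C", "truncated": "T", "nor_only": "M", "nos_only": "M",
    "modular": "M", "non_denitrifying": "N",
}
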