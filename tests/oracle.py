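"""Brute-force alignment oracle: exhaustive enumeration of all alignments.

An alignment of sequences q, t is a monotone matching of residue positions;
its score is the sum of substitution scores over matched pairs plus an
affine penalty ``gap_open + g * gap_extend`` for every maximal gap of length
``g``.  Enumerating every matching is exponential but exact, and independent
of the dynamic-programming implementation it checks (feasible for lengths
up to ~8).
"""

from itertools import combinations

from rfxsurvey.align import ALPHABET


def _gap_cost(g: int, gap_open: int, gap_extend: int) -> int:
    return 0 if g == 0 else gap_open + g * gap_extend


def _enumerate_matchings(n: int, m: int):
    """Yield all monotone matchings as paired index tuples (qi, tj)."""
    for k in range(0, min(n, m) + 1):
        for qs in combinations(range(n), k):
            for ts in combinations(range(m), k):
                yield tuple(zip(qs, ts))


def _score_matching(q, t, pairs, sub, gap_open, gap_extend, *, global_mode):
    enc = {c: i for i, c in enumerate(ALPHABET)}
    score = 0
    for qi, tj in pairs:
        score += int(sub[enc[q[qi]], enc[t[tj]]])
    for (q1, t1), (q2, t2) in zip(pairs, pairs[1:]):
        score -= _gap_cost(q2 - q1 - 1, gap_open, gap_extend)
        score -= _gap_cost(t2 - t1 - 1, gap_open, gap_extend)
    if global_mode:
        if pairs:
            score -= _gap_cost(pairs[0][0], gap_open, gap_extend)
            score -= _gap_cost(pairs[0][1], gap_open, gap_extend)
            score -= _gap_cost(len(q) - 1 - pairs[-1][0], gap_open, gap_extend)
            score -= _gap_cost(len(t) - 1 - pairs[-1][1], gap_open, gap_extend)
        else:
            score -= _gap_cost(len(q), gap_open, gap_extend)
            score -= _gap_cost(len(t), gap_open, gap_extend)
    return score


def brute_force_local_score(q: str, t: str, scheme) -> int:
    """Best score over all local alignments (0 when nothing scores positive)."""
    best = 0
    for pairs in _enumerate_matchings(len(q), len(t)):
        s = _score_matching(q, t, pairs, scheme.matrix, scheme.gap_open,
                            scheme.gap_extend, global_mode=False)
        best = max(best, s)
    return best


def brute_force_global_score(q: str, t: str, scheme) -> int:
    """Best score over all end-to-end alignments."""
    best = None
    for pairs in _enumerate_matchings(len(q), len(t)):
        s = _score_matching(q, t, pairs, scheme.matrix, scheme.gap_open,
                            scheme.gap_extend, global_mode=True)
        best = s if best is None else max(best, s)
    return best
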