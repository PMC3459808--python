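"""Independent brute-force oracles used to pin down the fast implementations.

Each oracle re-derives a quantity by exhaustive enumeration or exact
arithmetic, sharing no code path with the module it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

_CANONICAL = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}


def brute_duplex_energy(m: str, t: str, params) -> float:
    """Minimum duplex energy by enumerating every monotone pairing.

    Energy model re-expressed from the parameter object: initiation,
    terminal A:U/G:U penalties, stacking for adjacent pairs, affine
    loop cost otherwise.  Returns min(0, best) in kcal/mol.
    """
    istack = {k: round(v * 100) for k, v in params.stack.items()}
    init = round(params.duplex_init * 100)
    loop_init = round(params.loop_init * 100)
    per_nt = round(params.loop_per_nt * 100)
    term = round(params.terminal_au * 100)
    r = t[::-1]
    M, N = len(m), len(r)
    cand = [(i, k) for i in range(M) for k in range(N) if (m[i], r[k]) in _CANONICAL]
    best = 0

    def energy(pairs) -> int:
        e = init
        for idx in (0, -1):
            i, k = pairs[idx]
            if m[i] + r[k] in ("AU", "UA", "GU", "UG"):
                e += term
        for (a, b), (c, d) in zip(pairs, pairs[1:]):
            if c == a + 1 and d == b + 1:
                e += istack[(m[a] + r[b], m[c] + r[d])]
            else:
                e += loop_init + per_nt * ((c - a - 1) + (d - b - 1))
        return e

    def rec(chosen, start):
        nonlocal best
        if chosen:
            best = min(best, energy(chosen))
        for idx in range(start, len(cand)):
            i, k = cand[idx]
            if not chosen or (i > chosen[-1][0] and k > chosen[-1][1]):
                chosen.append((i, k))
                rec(chosen, idx + 1)
                chosen.pop()

    rec([], 0)
    return best / 100.0


def brute_local_alignment_score(mr: str, t: str, scoring) -> float:
    """Best local complementarity alignment score by path enumeration.

    *mr* is the miRNA already reversed (3'->5'); affine gap costs are
    accumulated explicitly along every monotone path.  Returns 0 if no
    positive-scoring alignment exists.
    """

    def col_score(a: str, b: str) -> float:
        if (a, b) in _WC:
            return scoring.match
        if (a, b) in _CANONICAL:
            return scoring.wobble
        return scoring.mismatch

    best = 0.0
    M, N = len(mr), len(t)

    def extend(i: int, j: int, score: float, prev_gap: str | None) -> None:
        # alignment currently ends having consumed mr[:i], t[:j]
        nonlocal best
        best = max(best, score)
        if i < M and j < N:
            extend(i + 1, j + 1, score + col_score(mr[i], t[j]), None)
        if j < N:  # unpaired target base (gap in miRNA)
            cost = scoring.gap_extend if prev_gap == "t" else scoring.gap_open
            extend(i, j + 1, score + cost, "t")
        if i < M:
            cost = scoring.gap_extend if prev_gap == "m" else scoring.gap_open
            extend(i + 1, j, score + cost, "m")

    for i in range(M):
        for j in range(N):
            extend(i + 1, j + 1, col_score(mr[i], t[j]), None)
    return best


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p-value in exact rational arithmetic.

    Conditions on the margins, enumerates the hypergeometric support with
    ``math.comb`` Fractions and sums every table no more probable than the
    observed one.  No floating point, no scipy.
    """
    N = a + b + c + d
    K = a + c
    n = a + b
    denom = comb(N, n)
    lo = max(0, n + K - N)
    hi = min(n, K)
    p_obs = Fraction(comb(K, a) * comb(N - K, n - a), denom)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p_x = Fraction(comb(K, x) * comb(N - K, n - x), denom)
        if p_x <= p_obs:
            total += p_x
    return float(total)
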