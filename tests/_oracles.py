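"""Independent brute-force oracles used only by the tests.

The alignment oracle is a full (unbanded, unfiltered) affine-gap
semi-global dynamic program written from scratch: query aligned end-to-end,
free end gaps on the target, match +1 / mismatch -1 / gap open -2 /
extend -1.  It shares no code with the package's matcher.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18
_OPEN, _EXT = -2.0, -1.0


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@njit(cache=False)
def _fill(q, t):
    n, m = q.size, t.size
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in target: consumes query base
    Iy = np.full((n + 1, m + 1), NEG)  # gap in query: consumes target base
    for j in range(m + 1):
        M[0, j] = 0.0  # free leading target gap: start anywhere
    for i in range(1, n + 1):
        prev = M[i - 1, 0] if i == 1 else Ix[i - 1, 0]
        Ix[i, 0] = prev + (_OPEN if i == 1 else _EXT)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1.0 if q[i - 1] == t[j - 1] else -1.0
            best_prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = s + best_prev
            Ix[i, j] = max(
                M[i - 1, j] + _OPEN, Ix[i - 1, j] + _EXT, Iy[i - 1, j] + _OPEN
            )
            Iy[i, j] = max(
                M[i, j - 1] + _OPEN, Iy[i, j - 1] + _EXT, Ix[i, j - 1] + _OPEN
            )
    return M, Ix, Iy


@njit(cache=False)
def _traceback(q, t, M, Ix, Iy):
    n, m = q.size, t.size
    # final: free trailing target gap; alignment may end in M or Ix
    best, bj, bstate = NEG, 0, 0
    for j in range(m + 1):
        if M[n, j] > best:
            best, bj, bstate = M[n, j], j, 0
        if Ix[n, j] > best:
            best, bj, bstate = Ix[n, j], j, 1
    i, j, state = n, bj, bstate
    matches = 0
    cols = 0
    while i > 0:
        if state == 0:  # match/mismatch column
            s = 1.0 if q[i - 1] == t[j - 1] else -1.0
            cols += 1
            if q[i - 1] == t[j - 1]:
                matches += 1
            target = M[i, j] - s
            i -= 1
            j -= 1
            if M[i, j] == target:
                state = 0
            elif Ix[i, j] == target:
                state = 1
            else:
                state = 2
        elif state == 1:  # query base vs gap
            cols += 1
            val = Ix[i, j]
            i -= 1
            if M[i, j] + _OPEN == val:
                state = 0
            elif Ix[i, j] + _EXT == val:
                state = 1
            else:
                state = 2
        else:  # target base vs gap (internal insertion)
            cols += 1
            val = Iy[i, j]
            j -= 1
            if M[i, j] + _OPEN == val:
                state = 0
            elif Iy[i, j] + _EXT == val:
                state = 2
            else:
                state = 1
    return best, matches, cols


def semi_global_align(query: str, target: str) -> tuple[float, float, int]:
    """(score, percent identity, alignment length) by exhaustive DP."""
    q, t = _encode(query), _encode(target)
    M, Ix, Iy = _fill(q, t)
    score, matches, cols = _traceback(q, t, M, Ix, Iy)
    identity = 100.0 * matches / cols if cols else 0.0
    return float(score), identity, int(cols)


def semi_global_score(query: str, target: str) -> float:
    q, t = _encode(query), _encode(target)
    M, Ix, Iy = _fill(q, t)
    n = q.size
    return float(max(M[n, :].max(), Ix[n, :].max()))


def exhaustive_best_target(
    query: str, refs: dict[str, str]
) -> tuple[list[str], float]:
    """All argmax target ids by exhaustive DP score, and the best score."""
    scores = {rid: semi_global_score(query, seq) for rid, seq in refs.items()}
    best = max(scores.values())
    return sorted(rid for rid, s in scores.items() if s == best), best
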