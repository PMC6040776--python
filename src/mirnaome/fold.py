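"""Maximum base-pairing secondary structure by dynamic programming.

Hairpin-precursor candidates are scored with a Nussinov-style fold that
maximises the number of canonical pairs (A:U, G:C and the G:U wobble; the
genomic alphabet uses T for U) subject to a minimum hairpin-loop length.
Thermodynamic folding is deliberately out of scope: the maximum-pairing
structure is deterministic and exactly checkable against brute-force
enumeration, which is what the candidate-calling rules need.

The maximum-pairing objective is heavily degenerate (many structures tie on
pair count), so the DP breaks ties by the number of stacked pairs: among
all structures with the maximum pair count it returns one with the most
helix-contiguous pairs. The pair count itself is never compromised — each
pair scores ``_PAIR_SCORE`` and a stack scores 1, with the total stacking
bonus provably below one pair's worth — so brute-force enumeration of the
maximum pair count remains a valid oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MIN_LOOP = 3
_PAIR_SCORE = 1024  # > any possible stacking bonus for windows < 2 kb

# base codes: A=0, C=1, G=2, T=3
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# canonical pairs on the coded alphabet (A:T, C:G, G:T)
_CAN_PAIR = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in ((0, 3), (1, 2), (2, 3)):
    _CAN_PAIR[_a, _b] = True
    _CAN_PAIR[_b, _a] = True

_NEG = np.int32(-(10**9))


def encode(seq: str) -> np.ndarray:
    """Encode a DNA/RNA sequence as int8 codes (A=0, C=1, G=2, T/U=3)."""
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"non-nucleotide character in sequence: {exc}") from exc


@njit(cache=True)
def _fill(codes, pairable, min_loop, pair_score, neg):  # pragma: no cover
    n = codes.shape[0]
    q = np.zeros((n, n), dtype=np.int32)
    p = np.full((n, n), neg, dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            if pairable[codes[i], codes[j]]:
                inner = q[i + 1, j - 1]
                if p[i + 1, j - 1] + 1 > inner:  # stacked continuation
                    inner = p[i + 1, j - 1] + 1
                p[i, j] = pair_score + inner
            best = q[i, j - 1]
            if q[i + 1, j] > best:
                best = q[i + 1, j]
            if p[i, j] > best:
                best = p[i, j]
            for k in range(i + 1, j):
                v = q[i, k] + q[k + 1, j]
                if v > best:
                    best = v
            q[i, j] = best
    return q, p


def _matrices(seq: str, min_loop: int):
    codes = encode(seq)
    n = codes.shape[0]
    if n < 2:
        return codes, None, None
    q, p = _fill(codes, _CAN_PAIR, min_loop, _PAIR_SCORE, _NEG)
    return codes, q, p


def max_pair_count(seq: str, min_loop: int = MIN_LOOP) -> int:
    """Maximum number of canonical pairs over all non-crossing structures."""
    _, q, _ = _matrices(seq, min_loop)
    if q is None:
        return 0
    return int(q[0, -1]) // _PAIR_SCORE


def max_pairing(seq: str, min_loop: int = MIN_LOOP) -> list[tuple[int, int]]:
    """A maximum-pairing structure as a sorted list of (i, j) pairs, i < j.

    Among co-optimal structures the stacking tie-break selects one with the
    most stacked pairs, favouring long uninterrupted helices — the shape the
    hairpin caller looks for.
    """
    codes, q, p = _matrices(seq, min_loop)
    n = codes.shape[0]
    if q is None:
        return []
    pairs: list[tuple[int, int]] = []
    # states: 0 = free interval (q), 1 = (i, j) paired (p)
    stack = [(0, n - 1, 0)]
    while stack:
        i, j, state = stack.pop()
        if j - i <= min_loop:
            continue
        if state == 1:
            pairs.append((i, j))
            if p[i + 1, j - 1] != _NEG and p[i, j] == _PAIR_SCORE + p[
                i + 1, j - 1
            ] + 1:
                stack.append((i + 1, j - 1, 1))
            else:
                stack.append((i + 1, j - 1, 0))
            continue
        if p[i, j] != _NEG and q[i, j] == p[i, j]:
            stack.append((i, j, 1))
            continue
        if q[i, j] == q[i + 1, j]:
            stack.append((i + 1, j, 0))
            continue
        if q[i, j] == q[i, j - 1]:
            stack.append((i, j - 1, 0))
            continue
        for k in range(i + 1, j):
            if q[i, j] == q[i, k] + q[k + 1, j]:
                stack.append((i, k, 0))
                stack.append((k + 1, j, 0))
                break
    pairs.sort()
    return pairs


def stem_loops(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Decompose a non-crossing structure into its helix chains (stems).

    Pairs form a nesting forest (each pair's parent is the smallest pair
    enclosing it). A stem is a maximal chain of pairs in which every pair
    has exactly one direct child; the chain ends at a hairpin loop (no
    children) or at a branch point (two or more children, i.e. the loop
    region folds further). Internal loops and bulges stay within a stem;
    each returned chain is sorted outermost first, and its last pair closes
    the stem's loop.
    """
    if not pairs:
        return []
    ordered = sorted(pairs)
    # parent = smallest enclosing pair (pairs are non-crossing)
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    stack: list[tuple[int, int]] = []
    for p in ordered:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent[p] = stack[-1] if stack else None
        stack.append(p)
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {}
    for p, par in parent.items():
        children.setdefault(par, []).append(p)

    chains = []
    for p in ordered:
        par = parent[p]
        if par is not None and len(children.get(par, ())) == 1:
            continue  # interior of a chain; handled from the chain head
        chain = [p]
        while len(children.get(chain[-1], ())) == 1:
            chain.append(children[chain[-1]][0])
        chains.append(chain)
    return chains
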