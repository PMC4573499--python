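"""Independent brute-force oracles used by the test suite.

These re-derive quantities the package computes, through different
algorithms (loop-decomposition scoring, top-down memoized recursion, full
enumeration at tiny sizes, successor-relation stem chaining), so agreement
is a genuine cross-check rather than a tautology.  Model *constants*
(stacking table, penalties) are shared with the package: they define the
energy model; the optimization and scoring logic here is written
independently of the package's dynamic program.
"""

from __future__ import annotations

from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np

from edscape.structure_engine import (
    HAIRPIN_E,
    LOOP_BASE,
    LOOP_SLOPE,
    MAXLOOP,
    MIN_HAIRPIN,
    ML_BRANCH,
    ML_CLOSE,
    STACK,
    _BASE_CODE,
    _PAIR_INDEX,
)

INF = float("inf")


def _enc(seq: str) -> List[int]:
    return [_BASE_CODE[c] for c in seq.upper().replace("T", "U")]


def _ptype(a: int, b: int) -> int:
    return int(_PAIR_INDEX[a, b])


def structure_energy(seq: str, pairs: Sequence[int]) -> float:
    """Score a pair table by explicit loop decomposition (INF if illegal)."""
    enc = _enc(seq)
    plist = sorted((i, int(j)) for i, j in enumerate(pairs) if j > i)
    for i, j in plist:
        if _ptype(enc[i], enc[j]) < 0 or j - i - 1 < MIN_HAIRPIN:
            return INF

    def children(i: int, j: int) -> List[Tuple[int, int]]:
        kids = []
        k = i + 1
        while k < j:
            if pairs[k] > k:
                kids.append((k, int(pairs[k])))
                k = int(pairs[k]) + 1
            else:
                k += 1
        return kids

    total = 0.0
    for i, j in plist:
        kids = children(i, j)
        if not kids:
            total += HAIRPIN_E
        elif len(kids) == 1:
            (k, l) = kids[0]
            s1, s2 = k - i - 1, j - l - 1
            if s1 == 0 and s2 == 0:
                total += STACK[_ptype(enc[i], enc[j]), _ptype(enc[k], enc[l])]
            else:
                if s1 + s2 > MAXLOOP:
                    return INF
                total += LOOP_BASE + LOOP_SLOPE * (s1 + s2)
        else:
            total += ML_CLOSE + ML_BRANCH * (len(kids) + 1)
    return total


def mfe_memo(seq: str, mask: Optional[Sequence[bool]] = None) -> float:
    """Top-down memoized minimum free energy under the same model."""
    enc = _enc(seq)
    n = len(enc)

    def can(i: int, j: int) -> bool:
        if mask is not None and (mask[i] or mask[j]):
            return False
        return j - i - 1 >= MIN_HAIRPIN and _ptype(enc[i], enc[j]) >= 0

    @lru_cache(maxsize=None)
    def pair_e(i: int, j: int) -> float:
        best = HAIRPIN_E
        for k in range(i + 1, j - 1):
            s1 = k - i - 1
            if s1 > MAXLOOP:
                break
            for l in range(k + MIN_HAIRPIN + 1, j):
                s2 = j - l - 1
                if s1 + s2 > MAXLOOP:
                    continue
                if not can(k, l):
                    continue
                if s1 == 0 and s2 == 0:
                    cost = STACK[_ptype(enc[i], enc[j]), _ptype(enc[k], enc[l])]
                else:
                    cost = LOOP_BASE + LOOP_SLOPE * (s1 + s2)
                best = min(best, cost + pair_e(k, l))
        best = min(best, ML_CLOSE + ML_BRANCH + multi(i + 1, j - 1, 2))
        return best

    @lru_cache(maxsize=None)
    def multi(i: int, j: int, need: int) -> float:
        if i > j:
            return 0.0 if need <= 0 else INF
        best = multi(i + 1, j, need)
        for l in range(i + MIN_HAIRPIN + 1, j + 1):
            if can(i, l):
                sub = multi(l + 1, j, max(0, need - 1))
                if sub < INF:
                    best = min(best, ML_BRANCH + pair_e(i, l) + sub)
        return best

    @lru_cache(maxsize=None)
    def ext(i: int) -> float:
        if i >= n:
            return 0.0
        best = ext(i + 1)
        for l in range(i + MIN_HAIRPIN + 1, n):
            if can(i, l):
                best = min(best, pair_e(i, l) + ext(l + 1))
        return best

    return min(0.0, ext(0))


def enumerate_pair_tables(seq: str) -> List[List[int]]:
    """All legal nested pair tables for a tiny sequence (exponential)."""
    enc = _enc(seq)
    n = len(enc)

    def can(i: int, j: int) -> bool:
        return j - i - 1 >= MIN_HAIRPIN and _ptype(enc[i], enc[j]) >= 0

    def gen(i: int, j: int) -> List[List[Tuple[int, int]]]:
        if i > j:
            return [[]]
        out = [s for s in gen(i + 1, j)]
        for l in range(i + MIN_HAIRPIN + 1, j + 1):
            if can(i, l):
                for inner in gen(i + 1, l - 1):
                    for rest in gen(l + 1, j):
                        out.append([(i, l)] + inner + rest)
        return out

    tables = []
    for s in gen(0, n - 1):
        tab = [-1] * n
        for i, j in s:
            tab[i], tab[j] = j, i
        tables.append(tab)
    return tables


def exhaustive_mfe(seq: str) -> float:
    """Minimum energy by full enumeration (tiny sequences only)."""
    best = 0.0
    for tab in enumerate_pair_tables(seq):
        e = structure_energy(seq, tab)
        best = min(best, e)
    return best


def stems_by_successor(pairs: Sequence[int], max_bulge: int) -> List[List[Tuple[int, int]]]:
    """All maximal bulge-bounded stems via an explicit successor relation."""
    plist = sorted((i, int(j)) for i, j in enumerate(pairs) if j > i)

    def successor(p: Tuple[int, int]) -> Optional[Tuple[int, int]]:
        i, j = p
        cands = [
            (k, l)
            for k, l in plist
            if i < k < l < j
            and k - i - 1 <= max_bulge
            and j - l - 1 <= max_bulge
            and all(pairs[x] < 0 for x in range(i + 1, k))
            and all(pairs[x] < 0 for x in range(l + 1, j))
        ]
        return min(cands) if cands else None

    succ = {p: successor(p) for p in plist}
    has_pred = set(q for q in succ.values() if q is not None)
    chains = []
    for p in plist:
        if p in has_pred:
            continue
        chain = [p]
        while succ[chain[-1]] is not None:
            chain.append(succ[chain[-1]])
        chains.append(sorted(chain))
    return chains


def anchored_stem_oracle(
    pairs: Sequence[int], anchor: int, min_pairs: int, max_bulge: int
) -> Optional[List[Tuple[int, int]]]:
    """The bulge-bounded stem containing/enclosing the anchor, or None."""
    if pairs[anchor] >= 0:
        target = tuple(sorted((anchor, int(pairs[anchor]))))
    else:
        enclosing = [
            (i, int(j))
            for i, j in enumerate(pairs)
            if j > i and i <= anchor <= j
        ]
        if not enclosing:
            return None
        target = min(enclosing, key=lambda ij: ij[1] - ij[0])
    for chain in stems_by_successor(pairs, max_bulge):
        if tuple(target) in [tuple(p) for p in chain]:
            return chain if len(chain) >= min_pairs else None
    return None
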