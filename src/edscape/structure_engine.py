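"""RNA secondary-structure engine: MFE folding, pair tables, stem extraction.

ADAR editing substrates are double-stranded RNAs formed between the
editing-site-containing strand and an editing complementary sequence (ECS).
This module provides the structural primitives used to locate and score those
duplexes:

* a deterministic minimum-free-energy (MFE) folder for nested secondary
  structures (Watson-Crick and G·U wobble pairs, nearest-neighbour stacking
  energies, hairpin loops of at least 3 nt, no pseudoknots),
* dot-bracket / CT interchange,
* extraction of the stem containing an anchor position under the field's
  stem/bulge definition (a run of consecutive base pairs in which every
  unpaired interruption is bounded by a maximum bulge size), and
* free-energy evaluation of two-segment duplexes joined by a non-pairing
  adenosine linker.

The folder is a pluggable contract: every downstream operation accepts an
externally computed :class:`RnaStructure` (e.g. parsed from dot-bracket), so
an alternative folding engine can be substituted without touching the rest of
the pipeline.

Energy model
------------
Free energies are in kcal/mol at the model's reference state.  A helix of
``k`` pairs contributes the sum of its ``k-1`` stacking energies (Watson-Crick
stack values from the Xia-Turner nearest-neighbour set; stacks involving one
wobble pair are assigned -1.3, two wobble pairs -0.5).  Hairpin closure costs
+3.0 regardless of loop size (loop >= 3 nt).  A bulge or internal loop of
total unpaired size ``s`` (both strands, 1 <= s <= 30) costs ``1.5 + 0.5*s``.
Multibranch loops cost ``3.0 + 0.4*(branches+1)`` with unpaired multiloop
nucleotides free.  The empty structure has energy 0, so the MFE is never
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


INF = 1e30

# Base encoding: A=0, C=1, G=2, U=3, N=4 (N never pairs).
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}
_CODE_BASE = "ACGUN"

# Pair-type indices for the stacking table.
# 0: A-U  1: U-A  2: C-G  3: G-C  4: G-U  5: U-G
_PAIR_INDEX = -np.ones((5, 5), dtype=np.int8)
_PAIR_INDEX[0, 3] = 0
_PAIR_INDEX[3, 0] = 1
_PAIR_INDEX[1, 2] = 2
_PAIR_INDEX[2, 1] = 3
_PAIR_INDEX[2, 3] = 4
_PAIR_INDEX[3, 2] = 5

_WOBBLE = -1.3  # stack with exactly one G·U pair
_WOBBLE2 = -0.5  # stack with two G·U pairs

# STACK[outer, inner] = dG of stacking inner pair (i+1, j-1) on outer (i, j),
# i.e. the 5'-> 3' dinucleotide step  5' a c 3' / 3' b d 5'.
STACK = np.array(
    [
        #  AU     UA     CG     GC     GU      UG     (inner)
        [-0.93, -1.10, -2.24, -2.08, _WOBBLE, _WOBBLE],  # outer AU
        [-1.33, -0.93, -2.35, -2.11, _WOBBLE, _WOBBLE],  # outer UA
        [-2.11, -2.08, -3.26, -2.36, _WOBBLE, _WOBBLE],  # outer CG
        [-2.35, -2.24, -3.42, -3.26, _WOBBLE, _WOBBLE],  # outer GC
        [_WOBBLE] * 4 + [_WOBBLE2, _WOBBLE2],  # outer GU
        [_WOBBLE] * 4 + [_WOBBLE2, _WOBBLE2],  # outer UG
    ],
    dtype=np.float64,
)

HAIRPIN_E = 3.0  # flat hairpin-closure penalty, loop size >= MIN_HAIRPIN
MIN_HAIRPIN = 3  # minimum unpaired nucleotides in a hairpin loop
MAXLOOP = 30  # maximum total unpaired size of a bulge/internal loop
LOOP_BASE = 1.5  # internal/bulge loop penalty: LOOP_BASE + LOOP_SLOPE * size
LOOP_SLOPE = 0.5
ML_CLOSE = 3.0  # multiloop closing penalty
ML_BRANCH = 0.4  # per-branch multiloop penalty (closing pair counts as one)


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an RNA/DNA string to integer codes (T treated as U)."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        return np.array([_BASE_CODE[c] for c in sequence.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"invalid nucleotide {exc.args[0]!r}") from exc


def bases_pair(a: str, b: str) -> bool:
    """True if two nucleotides can pair (Watson-Crick or G·U wobble)."""
    return _PAIR_INDEX[_BASE_CODE[a.upper()], _BASE_CODE[b.upper()]] >= 0


def internal_loop_energy(s1: int, s2: int) -> float:
    """Penalty for a bulge/internal loop with s1, s2 unpaired on each strand."""
    s = s1 + s2
    if s < 1 or s > MAXLOOP:
        return INF
    return LOOP_BASE + LOOP_SLOPE * s


@dataclass
class RnaStructure:
    """A nested secondary structure over a sequence.

    ``pairs[i]`` is the partner of position ``i`` (0-based) or -1 if unpaired.
    """

    sequence: str
    pairs: np.ndarray
    energy: float = 0.0
    constraint_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        if len(self.pairs) != len(self.sequence):
            raise ValueError("pair table length does not match sequence")
        self.validate()

    @property
    def n(self) -> int:
        return len(self.sequence)

    def is_paired(self, i: int) -> bool:
        return self.pairs[i] >= 0

    def validate(self) -> None:
        p = self.pairs
        n = len(p)
        for i in range(n):
            j = p[i]
            if j < 0:
                continue
            if j == i or j >= n or p[j] != i:
                raise ValueError(f"pair table is not an involution at {i}")
            if self.constraint_mask is not None and self.constraint_mask[i]:
                raise ValueError(f"constrained position {i} is paired")
        # nestedness (no pseudoknots)
        stack: List[int] = []
        for i in range(n):
            j = p[i]
            if j > i:
                stack.append(j)
            elif j >= 0:
                if not stack or stack[-1] != i:
                    raise ValueError("pseudoknotted pair table")
                stack.pop()

    def to_dotbracket(self) -> str:
        return to_dotbracket(self.pairs)


@dataclass
class Stem:
    """A run of consecutive base pairs bounded by a maximum bulge size.

    ``left``/``right`` are 0-based half-open intervals on the folded sequence
    spanning the first to last paired base of each strand (the right interval
    is the ECS convention: its ends are the first and last paired bases).
    """

    pairs: List[Tuple[int, int]]
    left: Tuple[int, int]
    right: Tuple[int, int]
    n_pairs: int
    max_bulge: int
    max_bulge_left: int
    max_bulge_right: int
    contains: int

    def side_of(self, position: int) -> Optional[str]:
        if self.left[0] <= position < self.left[1]:
            return "left"
        if self.right[0] <= position < self.right[1]:
            return "right"
        return None


# ---------------------------------------------------------------------------
# dot-bracket interchange
# ---------------------------------------------------------------------------


def parse_dotbracket(s: str) -> np.ndarray:
    """Parse a dot-bracket string into a pair table (-1 = unpaired)."""
    pairs = np.full(len(s), -1, dtype=np.int64)
    stack: List[int] = []
    for i, c in enumerate(s):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def to_dotbracket(pairs: Sequence[int]) -> str:
    out = []
    for i, j in enumerate(pairs):
        if j < 0:
            out.append(".")
        elif j > i:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


def write_ct(structure: RnaStructure, title: str = "edscape") -> str:
    """Render a structure in connectivity-table (CT) format (1-based)."""
    n = structure.n
    lines = [f"{n}\t{title}"]
    for i in range(n):
        j = int(structure.pairs[i]) + 1
        lines.append(
            f"{i + 1}\t{structure.sequence[i]}\t{i}\t{(i + 2) if i + 1 < n else 0}"
            f"\t{j}\t{i + 1}"
        )
    return "\n".join(lines) + "\n"


def read_ct(text: str) -> RnaStructure:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    seq = []
    pairs = np.full(n, -1, dtype=np.int64)
    for ln in lines[1 : n + 1]:
        f = ln.split()
        i = int(f[0]) - 1
        seq.append(f[1])
        j = int(f[4]) - 1
        pairs[i] = j if j >= 0 else -1
    return RnaStructure("".join(seq), pairs, energy=0.0)


# ---------------------------------------------------------------------------
# MFE folding
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fill(ptype, stack_e, hairpin_e, loop_base, loop_slope, maxloop, ml_close, ml_branch):
    n = ptype.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    WM2 = np.full((n, n), INF)
    for d in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - d):
            j = i + d
            # --- V: i pairs j ---
            pt = ptype[i, j]
            if pt >= 0:
                best = hairpin_e
                # stacking / bulge / internal loop onto inner pair (k, l)
                for k in range(i + 1, j - 1):
                    s1 = k - i - 1
                    if s1 > maxloop:
                        break
                    for l in range(j - 1, k + MIN_HAIRPIN, -1):
                        s2 = j - l - 1
                        if s1 + s2 > maxloop:
                            break
                        v = V[k, l]
                        if v >= INF:
                            continue
                        if s1 == 0 and s2 == 0:
                            cost = stack_e[pt, ptype[k, l]]
                        else:
                            cost = loop_base + loop_slope * (s1 + s2)
                        if v + cost < best:
                            best = v + cost
                # multiloop
                if WM2[i + 1, j - 1] < INF:
                    cand = ml_close + ml_branch + WM2[i + 1, j - 1]
                    if cand < best:
                        best = cand
                V[i, j] = best
            # --- WM / WM2: >= 1 / >= 2 branches, unpaired free ---
            wm = WM[i + 1, j] if i + 1 <= j else INF
            wm2 = WM2[i + 1, j] if i + 1 <= j else INF
            for l in range(i + MIN_HAIRPIN + 1, j + 1):
                v = V[i, l]
                if v >= INF:
                    continue
                b = v + ml_branch
                if b < wm:
                    wm = b
                if l + 1 <= j:
                    t = WM[l + 1, j]
                    if t < 0 and b + t < wm:
                        wm = b + t
                    if t < INF and b + t < wm2:
                        wm2 = b + t
            WM[i, j] = wm
            WM2[i, j] = wm2
    # exterior loop
    W = np.zeros(n + 1)
    for j in range(n):
        w = W[j]
        for i in range(0, j - MIN_HAIRPIN):
            if V[i, j] < INF and W[i] + V[i, j] < w:
                w = W[i] + V[i, j]
        W[j + 1] = w
    return V, WM, WM2, W


def _build_ptype(enc: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    n = len(enc)
    ptype = _PAIR_INDEX[enc][:, enc].copy()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        ptype[mask, :] = -1
        ptype[:, mask] = -1
    return ptype


_EPS = 1e-9


def _traceback(ptype, stack_e, V, WM, WM2, W, n) -> np.ndarray:
    pairs = np.full(n, -1, dtype=np.int64)
    tasks: List[Tuple[str, int, int]] = []
    # exterior
    j = n - 1
    while j >= 0:
        if abs(W[j + 1] - W[j]) <= _EPS:
            j -= 1
            continue
        found = False
        for i in range(0, j - MIN_HAIRPIN):
            if V[i, j] < INF and abs(W[i] + V[i, j] - W[j + 1]) <= _EPS:
                tasks.append(("V", i, j))
                j = i - 1
                found = True
                break
        if not found:  # pragma: no cover - defensive
            raise RuntimeError("traceback failure in exterior loop")
    while tasks:
        kind, i, j = tasks.pop()
        if kind == "V":
            pairs[i] = j
            pairs[j] = i
            target = V[i, j]
            if abs(target - HAIRPIN_E) <= _EPS:
                continue
            done = False
            for k in range(i + 1, j - 1):
                s1 = k - i - 1
                if s1 > MAXLOOP:
                    break
                for l in range(j - 1, k + MIN_HAIRPIN, -1):
                    s2 = j - l - 1
                    if s1 + s2 > MAXLOOP:
                        break
                    if V[k, l] >= INF:
                        continue
                    if s1 == 0 and s2 == 0:
                        cost = stack_e[ptype[i, j], ptype[k, l]]
                    else:
                        cost = LOOP_BASE + LOOP_SLOPE * (s1 + s2)
                    if abs(V[k, l] + cost - target) <= _EPS:
                        tasks.append(("V", k, l))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            if abs(ML_CLOSE + ML_BRANCH + WM2[i + 1, j - 1] - target) <= _EPS:
                tasks.append(("WM2", i + 1, j - 1))
                continue
            raise RuntimeError("traceback failure in V")  # pragma: no cover
        elif kind in ("WM", "WM2"):
            M = WM if kind == "WM" else WM2
            target = M[i, j]
            if target >= INF:  # pragma: no cover - defensive
                raise RuntimeError("traceback into infeasible WM")
            if i + 1 <= j and abs(M[i + 1, j] - target) <= _EPS:
                tasks.append((kind, i + 1, j))
                continue
            done = False
            for l in range(i + MIN_HAIRPIN + 1, j + 1):
                if V[i, l] >= INF:
                    continue
                b = V[i, l] + ML_BRANCH
                if kind == "WM" and abs(b - target) <= _EPS:
                    tasks.append(("V", i, l))
                    done = True
                    break
                if l + 1 <= j and WM[l + 1, j] < INF:
                    if abs(b + WM[l + 1, j] - target) <= _EPS:
                        tasks.append(("V", i, l))
                        tasks.append(("WM", l + 1, j))
                        done = True
                        break
            if not done:  # pragma: no cover - defensive
                raise RuntimeError(f"traceback failure in {kind}")
    return pairs


def fold_mfe(sequence: str, constraint_mask: Optional[np.ndarray] = None) -> RnaStructure:
    """Fold a sequence into its minimum-free-energy nested structure.

    Parameters
    ----------
    sequence:
        RNA (or DNA; T read as U) over A/C/G/U/T/N.  N never pairs.
    constraint_mask:
        Optional boolean array; ``True`` positions are forbidden from pairing.

    Returns
    -------
    RnaStructure
        Deterministic MFE structure; ``energy <= 0`` (the empty structure has
        energy 0 and is always available).
    """
    enc = encode_sequence(sequence)
    n = len(enc)
    if constraint_mask is not None and len(constraint_mask) != n:
        raise ValueError("constraint mask length does not match sequence")
    if n <= MIN_HAIRPIN + 1:
        return RnaStructure(sequence, np.full(n, -1, dtype=np.int64), 0.0, constraint_mask)
    ptype = _build_ptype(enc, constraint_mask)
    V, WM, WM2, W = _fill(
        ptype, STACK, HAIRPIN_E, LOOP_BASE, LOOP_SLOPE, MAXLOOP, ML_CLOSE, ML_BRANCH
    )
    energy = float(W[n])
    pairs = _traceback(ptype, STACK, V, WM, WM2, W, n)
    return RnaStructure(sequence, pairs, energy, constraint_mask)


# ---------------------------------------------------------------------------
# stems
# ---------------------------------------------------------------------------


def _gap_unpaired(pairs: np.ndarray, a: int, b: int) -> bool:
    """True if every position in the open interval (a, b) is unpaired."""
    for x in range(a + 1, b):
        if pairs[x] >= 0:
            return False
    return True


def _extend_chain(pairs: np.ndarray, i: int, j: int, max_bulge: int) -> List[Tuple[int, int]]:
    """All pairs of the bulge-bounded helix chain through pair (i, j)."""
    chain = [(i, j)]
    # inward
    ci, cj = i, j
    while True:
        p = ci + 1
        while p < cj and pairs[p] < 0:
            p += 1
        if p >= cj:
            break
        q = int(pairs[p])
        if not (p < q < cj):
            break
        gl = p - ci - 1
        gr = cj - q - 1
        if gl > max_bulge or gr > max_bulge or not _gap_unpaired(pairs, q, cj):
            break
        chain.append((p, q))
        ci, cj = p, q
    # outward
    ci, cj = i, j
    n = len(pairs)
    while True:
        p = ci - 1
        while p >= 0 and pairs[p] < 0:
            p -= 1
        if p < 0:
            break
        q = int(pairs[p])
        if not (q > cj):
            break
        gl = ci - p - 1
        gr = q - cj - 1
        if gl > max_bulge or gr > max_bulge or not _gap_unpaired(pairs, cj, q):
            break
        chain.append((p, q))
        ci, cj = p, q
    chain.sort()
    return chain


def max_bulge(stem_pairs: Sequence[Tuple[int, int]]) -> int:
    """Maximum interruption between consecutive stem pairs (larger strand)."""
    left, right = bulge_runs(stem_pairs)
    runs = left + right
    return max(runs) if runs else 0


def bulge_runs(
    stem_pairs: Sequence[Tuple[int, int]],
) -> Tuple[List[int], List[int]]:
    """Unpaired run lengths between consecutive pairs, per strand."""
    sp = sorted(stem_pairs)
    lefts, rights = [], []
    for (i1, j1), (i2, j2) in zip(sp, sp[1:]):
        lefts.append(i2 - i1 - 1)
        rights.append(j1 - j2 - 1)
    return lefts, rights


def _chain_to_stem(chain: List[Tuple[int, int]], anchor: int) -> Stem:
    lefts = [p[0] for p in chain]
    rights = [p[1] for p in chain]
    lruns, rruns = bulge_runs(chain)
    return Stem(
        pairs=chain,
        left=(min(lefts), max(lefts) + 1),
        right=(min(rights), max(rights) + 1),
        n_pairs=len(chain),
        max_bulge=max([max(a, b) for a, b in zip(lruns, rruns)], default=0),
        max_bulge_left=max(lruns, default=0),
        max_bulge_right=max(rruns, default=0),
        contains=anchor,
    )


def extract_stem_at(
    structure: RnaStructure,
    anchor: int,
    min_pairs: int = 20,
    max_bulge: int = 8,
) -> Optional[Stem]:
    """Extract the stem containing ``anchor`` from a folded structure.

    Starting from the pair at the anchor (or the innermost pair enclosing it
    when the anchor itself is unpaired), consecutive pairs are accreted in
    both directions while every interruption -- the unpaired run on either
    strand between consecutive pairs -- is at most ``max_bulge``.  Returns the
    stem if it reaches ``min_pairs`` pairs, else ``None``.
    """
    n = structure.n
    if not 0 <= anchor < n:
        raise IndexError(f"anchor {anchor} outside sequence of length {n}")
    pairs = structure.pairs
    if pairs[anchor] >= 0:
        i, j = sorted((anchor, int(pairs[anchor])))
    else:
        best: Optional[Tuple[int, int]] = None
        for p in range(n):
            q = int(pairs[p])
            if q > p and p <= anchor <= q:
                if best is None or q - p < best[1] - best[0]:
                    best = (p, q)
        if best is None:
            return None
        i, j = best
    chain = _extend_chain(pairs, i, j, max_bulge)
    if len(chain) < min_pairs:
        return None
    return _chain_to_stem(chain, anchor)


def enumerate_stems(
    structure: RnaStructure, min_pairs: int = 1, max_bulge: int = 8
) -> List[Stem]:
    """All maximal bulge-bounded stems in a structure, sorted by position."""
    pairs = structure.pairs
    seen = set()
    stems = []
    for i in range(structure.n):
        j = int(pairs[i])
        if j <= i or (i, j) in seen:
            continue
        chain = _extend_chain(pairs, i, j, max_bulge)
        seen.update(chain)
        if len(chain) >= min_pairs:
            stems.append(_chain_to_stem(chain, chain[0][0]))
    return stems


# ---------------------------------------------------------------------------
# duplex constructs
# ---------------------------------------------------------------------------

LINKER_LENGTH = 100


def fold_duplex(
    edit_side: str, ecs: str, linker_length: int = LINKER_LENGTH
) -> RnaStructure:
    """Fold ``edit_side + A-linker + ecs`` with the linker forbidden to pair."""
    if not edit_side or not ecs:
        raise ValueError("both duplex segments must be nonempty")
    seq = edit_side + "A" * linker_length + ecs
    mask = np.zeros(len(seq), dtype=bool)
    mask[len(edit_side) : len(edit_side) + linker_length] = True
    return fold_mfe(seq, constraint_mask=mask)


def duplex_free_energy(
    edit_side: str, ecs: str, linker_length: int = LINKER_LENGTH
) -> float:
    """Free energy of the two-segment duplex construct (kcal/mol)."""
    return fold_duplex(edit_side, ecs, linker_length).energy
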