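"""Minimum-free-energy, pseudoknot-free RNA secondary structure.

The default backend is a Zuker-style dynamic program over a simplified
nearest-neighbour model: stacking energies for the 16 ordered pair-stacks
(restricted to the 6 canonical pairs), logarithmic hairpin/bulge/internal
loop penalties and a linear multiloop score.  The parameter table is embedded
below.  The pipeline's decisions consume only the structure (pair table), so
structural correctness — not thermodynamic fidelity to any particular
published parameter set — is the contract; the model is exposed so that an
independent evaluator can recompute the energy of any structure and an
exhaustive enumerator can certify optimality on short sequences.

Conventions: ``pair_of`` is a tuple indexed 0..n-1 whose entries are 1-based
partner positions (0 = unpaired).  Only {AU, UA, GC, CG, GU, UG} pair; ``N``
never pairs; hairpin loops hold at least 3 unpaired bases; bulge/internal
loops are capped at 30 unpaired bases total (larger loops are modelled as
forbidden).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

from .seqio import Interval

__all__ = [
    "FoldResult",
    "HairpinGeometry",
    "fold",
    "structure_energy",
    "dot_bracket",
    "parse_dot_bracket",
    "geometry",
    "MIN_HAIRPIN",
    "MAX_INTERNAL",
]

INF = 1e9
MIN_HAIRPIN = 3          # minimum unpaired bases in a hairpin loop
MAX_INTERNAL = 30        # maximum total unpaired bases in a bulge/internal loop

# Residue encoding: A=0 C=1 G=2 U=3 N=4
_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

# Pair indices: AU=0 UA=1 GC=2 CG=3 GU=4 UG=5, -1 = not pairable
_PAIR_IDX = -np.ones((5, 5), dtype=np.int8)
for _k, (_a, _b) in enumerate([(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)]):
    _PAIR_IDX[_a, _b] = _k

# Stacking free energies (kcal/mol), outer pair x inner pair.  Magnitudes
# follow the usual ordering (CG/GC stacks strongest, GU/UG weakest).
_STACK = np.array(
    [
        # inner:  AU    UA    GC    CG    GU    UG
        [-0.9, -1.1, -2.2, -2.1, -0.6, -1.4],  # outer AU
        [-1.3, -0.9, -2.4, -2.1, -1.0, -1.3],  # outer UA
        [-2.1, -2.2, -3.3, -2.4, -1.4, -2.1],  # outer GC
        [-2.4, -2.1, -3.4, -3.3, -2.1, -2.5],  # outer CG
        [-1.3, -1.4, -2.5, -2.1, -0.5, -0.4],  # outer GU
        [-1.0, -0.6, -2.1, -1.4, -0.3, -0.5],  # outer UG
    ],
    dtype=np.float64,
)

# Loop penalty coefficients
_HAIRPIN_A, _HAIRPIN_B = 4.8, 1.05       # H(s) = A + B ln(s/3)
_BULGE_A, _BULGE_B = 3.6, 1.05           # B(s) = A + B ln(s)
_INTERNAL_A, _INTERNAL_B, _INTERNAL_ASYM = 1.9, 1.05, 0.35
_ML_CLOSE, _ML_BRANCH, _ML_UNPAIRED = 3.4, 0.4, 0.1


def hairpin_penalty(size: int) -> float:
    if size < MIN_HAIRPIN:
        return INF
    return _HAIRPIN_A + _HAIRPIN_B * math.log(size / 3.0)


def bulge_penalty(size: int) -> float:
    if size < 1 or size > MAX_INTERNAL:
        return INF
    return _BULGE_A + _BULGE_B * math.log(float(size))


def internal_penalty(s1: int, s2: int) -> float:
    if s1 < 1 or s2 < 1 or s1 + s2 > MAX_INTERNAL:
        return INF
    return _INTERNAL_A + _INTERNAL_B * math.log((s1 + s2) / 2.0) + _INTERNAL_ASYM * abs(s1 - s2)


def multiloop_penalty(branches: int, unpaired: int) -> float:
    """Energy of a multiloop with ``branches`` helices (closing one included)."""
    return _ML_CLOSE + _ML_BRANCH * branches + _ML_UNPAIRED * unpaired


@njit(cache=True)
def _fill(enc, pair_idx, stack, hp_a, hp_b, bu_a, bu_b, in_a, in_b, in_asym,
          ml_a, ml_b, ml_c):  # pragma: no cover - exercised via fold()
    n = enc.shape[0]
    V = np.full((n, n), INF)
    WM1 = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for d in range(4, n):
        for i in range(0, n - d):
            j = i + d
            pij = pair_idx[enc[i], enc[j]]
            if pij >= 0:
                # hairpin closure
                size = j - i - 1
                best = hp_a + hp_b * np.log(size / 3.0)
                # stack / bulge / internal closures
                kmax = min(i + 1 + MAX_INTERNAL, j - 4)
                for k in range(i + 1, kmax + 1):
                    s1 = k - i - 1
                    lmin = max(k + 4, j - 1 - (MAX_INTERNAL - s1))
                    for l in range(lmin, j):
                        inner = V[k, l]
                        if inner >= INF / 2:
                            continue
                        s2 = j - l - 1
                        if s1 == 0 and s2 == 0:
                            pkl = pair_idx[enc[k], enc[l]]
                            cand = stack[pij, pkl] + inner
                        elif s1 == 0 or s2 == 0:
                            cand = bu_a + bu_b * np.log(float(s1 + s2)) + inner
                        else:
                            cand = (in_a + in_b * np.log((s1 + s2) / 2.0)
                                    + in_asym * abs(s1 - s2) + inner)
                        if cand < best:
                            best = cand
                # multiloop closure: >= 2 branches inside
                for mid in range(i + 2, j - 1):
                    a = WM[i + 1, mid - 1]
                    b = WM1[mid, j - 1]
                    if a < INF / 2 and b < INF / 2:
                        cand = ml_a + ml_b + a + b
                        if cand < best:
                            best = cand
                V[i, j] = best
            # WM1: one branch starting exactly at i, trailing unpaired on the right
            w = INF
            if V[i, j] < INF / 2:
                w = V[i, j] + ml_b
            if j - 1 >= i + 4 and WM1[i, j - 1] < INF / 2:
                alt = WM1[i, j - 1] + ml_c
                if alt < w:
                    w = alt
            WM1[i, j] = w
            # WM: >= 1 branch anywhere in i..j
            w = WM1[i, j]
            if i + 1 <= j - 4 and WM[i + 1, j] < INF / 2:
                alt = WM[i + 1, j] + ml_c
                if alt < w:
                    w = alt
            for k in range(i + 1, j - 3):
                a = WM[i, k - 1]
                b = WM1[k, j]
                if a < INF / 2 and b < INF / 2:
                    alt = a + b
                    if alt < w:
                        w = alt
            WM[i, j] = w
    W = np.zeros(n)
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        for i in range(0, j - 3):
            v = V[i, j]
            if v < INF / 2:
                left = W[i - 1] if i > 0 else 0.0
                if left + v < best:
                    best = left + v
        W[j] = best
    return V, WM1, WM, W


@dataclass(frozen=True)
class FoldResult:
    """A folded RNA window: residues, pair table, energy, backend name.

    ``pair_of`` is indexed 0..n-1 with 1-based partner values (0 = unpaired).
    """

    residues: str
    pair_of: tuple[int, ...]
    mfe: float
    backend: str = "builtin"

    def __len__(self) -> int:
        return len(self.residues)

    def partner(self, pos: int) -> int:
        """1-based partner of 1-based ``pos`` (0 if unpaired)."""
        return self.pair_of[pos - 1]

    def pairs(self) -> list[tuple[int, int]]:
        """Sorted 1-based pair list (i < j)."""
        return [(i + 1, p) for i, p in enumerate(self.pair_of) if p > i + 1]


_EPS = 1e-7


def _traceback(enc, V, WM1, WM, W) -> list[tuple[int, int]]:
    n = len(enc)
    pairs: list[tuple[int, int]] = []
    regions: list[tuple[str, int, int]] = []
    # exterior decomposition, right to left; co-optimal ties prefer leaving
    # the rightmost position unpaired (fixed, hence deterministic)
    j = n - 1
    while j >= 0:
        prev = W[j - 1] if j > 0 else 0.0
        if abs(W[j] - prev) <= _EPS:
            j -= 1
            continue
        found = False
        for i in range(0, j - 3):
            if V[i, j] < INF / 2:
                left = W[i - 1] if i > 0 else 0.0
                if abs(left + V[i, j] - W[j]) <= _EPS:
                    regions.append(("V", i, j))
                    j = i - 1
                    found = True
                    break
        if not found:
            j -= 1
    while regions:
        kind, i, j = regions.pop()
        if kind == "V":
            pairs.append((i, j))
            target = V[i, j]
            size = j - i - 1
            if abs(hairpin_penalty(size) - target) <= _EPS:
                continue
            done = False
            kmax = min(i + 1 + MAX_INTERNAL, j - 4)
            for k in range(i + 1, kmax + 1):
                if done:
                    break
                s1 = k - i - 1
                lmin = max(k + 4, j - 1 - (MAX_INTERNAL - s1))
                for l in range(lmin, j):
                    if V[k, l] >= INF / 2:
                        continue
                    s2 = j - l - 1
                    if s1 == 0 and s2 == 0:
                        pij = _PAIR_IDX[enc[i], enc[j]]
                        pkl = _PAIR_IDX[enc[k], enc[l]]
                        cand = _STACK[pij, pkl] + V[k, l]
                    elif s1 == 0 or s2 == 0:
                        cand = bulge_penalty(s1 + s2) + V[k, l]
                    else:
                        cand = internal_penalty(s1, s2) + V[k, l]
                    if abs(cand - target) <= _EPS:
                        regions.append(("V", k, l))
                        done = True
                        break
            if done:
                continue
            for mid in range(i + 2, j - 1):
                a, b = WM[i + 1, mid - 1], WM1[mid, j - 1]
                if a < INF / 2 and b < INF / 2 and abs(_ML_CLOSE + _ML_BRANCH + a + b - target) <= _EPS:
                    regions.append(("WM", i + 1, mid - 1))
                    regions.append(("WM1", mid, j - 1))
                    done = True
                    break
            if not done:  # numerical corner: fall back to hairpin
                continue
        elif kind == "WM1":
            # strip trailing unpaired positions until the branch V[i, jj] + b
            # explains the value
            jj = j
            while jj - 1 >= i + 4 and not (
                V[i, jj] < INF / 2 and abs(V[i, jj] + _ML_BRANCH - WM1[i, jj]) <= _EPS
            ):
                jj -= 1
            regions.append(("V", i, jj))
        else:  # WM
            target = WM[i, j]
            if abs(WM1[i, j] - target) <= _EPS:
                regions.append(("WM1", i, j))
                continue
            if i + 1 <= j - 4 and WM[i + 1, j] < INF / 2 and abs(WM[i + 1, j] + _ML_UNPAIRED - target) <= _EPS:
                regions.append(("WM", i + 1, j))
                continue
            for k in range(i + 1, j - 3):
                a, b = WM[i, k - 1], WM1[k, j]
                if a < INF / 2 and b < INF / 2 and abs(a + b - target) <= _EPS:
                    regions.append(("WM", i, k - 1))
                    regions.append(("WM1", k, j))
                    break
    return pairs


def fold(residues: str, backend: str = "builtin") -> FoldResult:
    """Fold an RNA string (length >= 10, alphabet {A,C,G,U,N}) to its MFE
    structure under the embedded nearest-neighbour model.

    Deterministic: the traceback resolves co-optimal structures with a fixed
    preference order (hairpin, then innermost-first stack/loop closures, then
    multiloops), so identical input always yields an identical pair table.
    """
    if backend != "builtin":
        raise ValueError(f"unknown folding backend {backend!r}")
    if len(residues) < 10:
        raise ValueError(f"fold requires length >= 10, got {len(residues)}")
    bad = set(residues) - set("ACGUN")
    if bad:
        raise ValueError(f"fold alphabet is ACGUN, found {sorted(bad)}")
    enc = np.array([_ENC[c] for c in residues], dtype=np.int8)
    V, WM1, WM, W = _fill(
        enc, _PAIR_IDX, _STACK, _HAIRPIN_A, _HAIRPIN_B, _BULGE_A, _BULGE_B,
        _INTERNAL_A, _INTERNAL_B, _INTERNAL_ASYM, _ML_CLOSE, _ML_BRANCH, _ML_UNPAIRED,
    )
    mfe = float(W[len(residues) - 1])
    pair_of = [0] * len(residues)
    if mfe < -_EPS:
        for i, j in _traceback(enc, V, WM1, WM, W):
            pair_of[i] = j + 1
            pair_of[j] = i + 1
    else:
        mfe = 0.0
    return FoldResult(residues=residues, pair_of=tuple(pair_of), mfe=mfe, backend="builtin")


def _children(pair_of: tuple[int, ...], i: int, j: int) -> list[tuple[int, int]]:
    """Maximal pairs strictly inside 1-based (i, j) (pass i=0, j=n+1 for root)."""
    out = []
    p = i + 1
    while p < j:
        q = pair_of[p - 1]
        if q > p:
            out.append((p, q))
            p = q + 1
        else:
            p += 1
    return out


def structure_energy(residues: str, pair_of: tuple[int, ...]) -> float:
    """Independent loop-decomposition evaluator for an arbitrary structure.

    Returns the model energy of the given pair table (INF for structures the
    model forbids: loop-size violations or non-canonical pairs).  Used to
    cross-check ``fold`` and as the scorer for exhaustive enumeration.
    """
    n = len(residues)
    enc = [_ENC[c] for c in residues]
    # validate involution / canonical pairs
    for i1 in range(1, n + 1):
        j1 = pair_of[i1 - 1]
        if j1:
            if pair_of[j1 - 1] != i1:
                raise ValueError("pair table is not an involution")
            if j1 > i1 and _PAIR_IDX[enc[i1 - 1], enc[j1 - 1]] < 0:
                return INF
    total = 0.0
    stack_regions = [(p, q) for p, q in _children(pair_of, 0, n + 1)]
    while stack_regions:
        i, j = stack_regions.pop()
        ch = _children(pair_of, i, j)
        if not ch:
            total += hairpin_penalty(j - i - 1)
        elif len(ch) == 1:
            (k, l) = ch[0]
            s1, s2 = k - i - 1, j - l - 1
            if s1 == 0 and s2 == 0:
                total += _STACK[_PAIR_IDX[enc[i - 1], enc[j - 1]], _PAIR_IDX[enc[k - 1], enc[l - 1]]]
            elif s1 == 0 or s2 == 0:
                total += bulge_penalty(s1 + s2)
            else:
                total += internal_penalty(s1, s2)
            stack_regions.append((k, l))
        else:
            unpaired = (j - i - 1) - sum(q - p + 1 for p, q in ch)
            total += multiloop_penalty(len(ch) + 1, unpaired)
            stack_regions.extend(ch)
        if total >= INF / 2:
            return INF
    return total


def dot_bracket(fr: FoldResult) -> str:
    """Vienna-dialect dot-bracket serialization (pseudoknot-free)."""
    out = []
    for i, p in enumerate(fr.pair_of, start=1):
        out.append("." if p == 0 else ("(" if p > i else ")"))
    return "".join(out)


def parse_dot_bracket(structure: str) -> tuple[int, ...]:
    """Pair table (1-based partners, 0 = unpaired) from dot-bracket."""
    pair_of = [0] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure, start=1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pair_of[i - 1] = j
            pair_of[j - 1] = i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unclosed '(' at position {stack[-1]}")
    return tuple(pair_of)


@dataclass(frozen=True)
class HairpinGeometry:
    """Positions of a folded window classified relative to one anchor.

    ``terminal_loop`` is the apical (head) loop of the hairpin that carries
    the anchor — for branched heads, the span of the first multibranch loop
    between the anchor and the tip.  ``branch_count`` counts the helices
    branching from that loop (0 for a linear stem-loop above the anchor).
    """

    pair_of: tuple[int, ...]
    anchor: Interval
    enclosing: tuple[int, int] | None
    terminal_loop: Interval | None
    branch_count: int

    def arm_of(self, pos: int) -> str:
        """Classify 1-based ``pos`` as '5p', '3p', 'loop' or 'exterior'."""
        if self.enclosing is None or self.terminal_loop is None:
            return "exterior"
        e0, e1 = self.enclosing
        if pos < e0 or pos > e1:
            return "exterior"
        if pos < self.terminal_loop.start:
            return "5p"
        if pos > self.terminal_loop.end:
            return "3p"
        return "loop"

    def branch_count_above(self, anchor: Interval | None = None) -> int:
        if anchor is None or (anchor.start == self.anchor.start and anchor.end == self.anchor.end):
            return self.branch_count
        g = _walk(self.pair_of, anchor)
        return g[2]


def _walk(pair_of: tuple[int, ...], anchor: Interval):
    """Walk from the anchor's outermost enclosing pair toward the hairpin tip.

    Returns (enclosing, terminal_loop_span, branch_count); branch loops whose
    one child still carries the anchor are below/beside the anchor and do not
    count.
    """
    n = len(pair_of)
    alo, ahi = anchor.start, anchor.end
    candidates = [
        (i + 1, p) for i, p in enumerate(pair_of)
        if p > i + 1 and (i + 1) <= ahi and p >= alo
    ]
    if not candidates:
        return None, None, 0
    enclosing = max(candidates, key=lambda ij: ij[1] - ij[0])
    cur = enclosing
    while True:
        ch = _children(pair_of, cur[0], cur[1])
        if not ch:
            return enclosing, (cur[0] + 1, cur[1] - 1), 0
        anchored = [c for c in ch if c[0] <= ahi and c[1] >= alo]
        if anchored:
            cur = max(anchored, key=lambda ij: ij[1] - ij[0])
            continue
        if len(ch) == 1:
            cur = ch[0]
            continue
        return enclosing, (cur[0] + 1, cur[1] - 1), len(ch)


def geometry(fr: FoldResult, anchor: Interval, seq_id: str = "window") -> HairpinGeometry:
    """Classify window positions relative to the hairpin holding ``anchor``.

    The anchor (e.g. the mature miRNA location within the window) selects the
    hairpin; positions are labelled 5p/3p/loop/exterior relative to its
    terminal loop.  ``branch_count`` counts helices branching from loops
    strictly between the anchor and the terminal loop (a multibranched head
    included); a clean stem-loop above the anchor gives 0.
    """
    if anchor.end > len(fr):
        raise ValueError(f"anchor {anchor.start}-{anchor.end} outside window of length {len(fr)}")
    enclosing, tl, branch_count = _walk(fr.pair_of, anchor)
    terminal = Interval(seq_id, tl[0], tl[1]) if tl is not None and tl[0] <= tl[1] else None
    return HairpinGeometry(
        pair_of=fr.pair_of,
        anchor=anchor,
        enclosing=enclosing,
        terminal_loop=terminal,
        branch_count=branch_count,
    )
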