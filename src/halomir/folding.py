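"""Self-contained RNA secondary-structure folding.

Minimum-free-energy folding of a single sequence under a compact
nearest-neighbor model: Watson-Crick and G:U stacking energies, hairpin,
bulge, and interior-loop size penalties with Jacobson-Stockmayer
extrapolation, a linear multibranch-loop model, hairpin loops of at least
three unpaired bases, and no pseudoknots, dangles, or terminal-pair
penalties. The parameter set is intentionally small; it is not the full
Turner-2004 table and its energies are not interchangeable with mfold or
ViennaRNA output, but it reproduces the qualitative stability ordering the
hairpin filters rely on.

The dynamic program is a Zuker-style recursion. Ties are broken toward the
structure with fewer base pairs (encoded directly into the DP score); among
equal-energy, equal-pair-count optima, a fixed traceback order makes the
returned structure deterministic.

:func:`structure_energy` scores an explicit structure by loop decomposition
and is the reference definition of the model; :func:`enumerate_structures`
lists every nested structure of a short sequence so that the DP can be
checked exhaustively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

MIN_HAIRPIN_LOOP = 3
MAXLOOP = 30  # max unpaired bases in one bulge/interior loop (standard cap)
_MAXN = 600
_PBITS = 512  # tie-break encoding: score = energy_tenths * 512 + n_pairs
_INF = 1 << 50

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair types: 0 CG, 1 GC, 2 GU, 3 UG, 4 AU, 5 UA (DNA T stands for U)
_PTYPE = -np.ones((4, 4), dtype=np.int8)
_PTYPE[1, 2] = 0  # C-G
_PTYPE[2, 1] = 1  # G-C
_PTYPE[2, 3] = 2  # G-U
_PTYPE[3, 2] = 3  # U-G
_PTYPE[0, 3] = 4  # A-U
_PTYPE[3, 0] = 5  # U-A

# Stacking energies (kcal/mol) for 5'-p q-3' helix continuation, indexed
# [outer pair][inner pair]; values follow the published nearest-neighbor
# convention for Watson-Crick and wobble stacks.
_STACK_KCAL = np.array(
    [
        #  CG     GC     GU     UG     AU     UA
        [-3.30, -3.40, -2.20, -1.40, -2.10, -2.10],  # CG
        [-2.40, -3.30, -2.50, -1.50, -2.20, -2.40],  # GC
        [-2.10, -2.50, -1.40, +0.30, -1.40, -1.30],  # GU
        [-1.40, -1.50, -0.50, -0.50, -0.60, -1.00],  # UG
        [-2.10, -2.40, -1.30, -1.00, -0.90, -1.30],  # AU
        [-2.10, -2.20, -1.40, -0.60, -1.30, -0.60],  # UA
    ]
)
_STACK = np.rint(_STACK_KCAL * 10).astype(np.int64)

_RT_FACTOR = 1.75 * 0.6163  # Jacobson-Stockmayer loop-entropy coefficient

# multibranch loop: closure + per-branch + per-unpaired (kcal/mol, tenths)
ML_CLOSE = 34
ML_BRANCH = 4
ML_UNPAIRED = 0


def _loop_tables(maxn: int = _MAXN) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hairpin = np.full(maxn + 1, _INF, dtype=np.int64)
    base_h = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
    for n in range(3, maxn + 1):
        if n in base_h:
            hairpin[n] = round(base_h[n] * 10)
        else:
            hairpin[n] = round(base_h[9] * 10 + _RT_FACTOR * 10 * math.log(n / 9))
    bulge = np.full(maxn + 1, _INF, dtype=np.int64)
    base_b = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
    for n in range(1, maxn + 1):
        if n in base_b:
            bulge[n] = round(base_b[n] * 10)
        else:
            bulge[n] = round(base_b[6] * 10 + _RT_FACTOR * 10 * math.log(n / 6))
    interior = np.full(maxn + 1, _INF, dtype=np.int64)
    base_i = {2: 1.5, 3: 1.6, 4: 1.7, 5: 1.8, 6: 2.0}
    for n in range(2, maxn + 1):
        if n in base_i:
            interior[n] = round(base_i[n] * 10)
        else:
            interior[n] = round(base_i[6] * 10 + _RT_FACTOR * 10 * math.log(n / 6))
    return hairpin, bulge, interior


_HAIRPIN, _BULGE, _INTERIOR = _loop_tables()
_ASYM_COEF = 5  # 0.5 kcal/mol per unit of interior-loop asymmetry
_ASYM_MAX = 30


def encode_sequence(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in sequence.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGTU character in sequence: {exc.args[0]!r}") from None


def _interior_energy(n1: int, n2: int) -> int:
    """Bulge/interior-loop penalty (tenths of kcal/mol); n1, n2 unpaired per side."""
    if n1 == 0 and n2 == 0:
        raise ValueError("stack, not a loop")
    if n1 == 0 or n2 == 0:
        return int(_BULGE[n1 + n2])
    return int(_INTERIOR[n1 + n2]) + min(_ASYM_MAX, _ASYM_COEF * abs(n1 - n2))


@njit(cache=False)
def _fill(seq, ptype, stack, hairpin, bulge, interior, asym_coef, asym_max):
    n = seq.shape[0]
    INF = 1 << 50
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    for j in range(n):
        for i in range(j, -1, -1):
            pt = ptype[seq[i], seq[j]]
            if j - i >= MIN_HAIRPIN_LOOP + 1 and pt >= 0:
                best = hairpin[j - i - 1] * 512
                # stacked pair, bulge, interior loop
                kmax = min(i + MAXLOOP + 1, j - 4) + 1
                for k in range(i + 1, kmax):
                    n1 = k - i - 1
                    lmin = j - 1 - (MAXLOOP - n1)
                    if lmin < k + 4:
                        lmin = k + 4
                    for l in range(j - 1, lmin - 1, -1):
                        if ptype[seq[k], seq[l]] < 0 or V[k, l] >= INF:
                            continue
                        n2 = j - l - 1
                        if n1 == 0 and n2 == 0:
                            e = stack[pt, ptype[seq[k], seq[l]]]
                        elif n1 == 0 or n2 == 0:
                            e = bulge[n1 + n2]
                        else:
                            a = asym_coef * (n1 - n2 if n1 > n2 else n2 - n1)
                            if a > asym_max:
                                a = asym_max
                            e = interior[n1 + n2] + a
                        cand = V[k, l] + e * 512
                        if cand < best:
                            best = cand
                # multibranch: closure + closing-branch + two WM segments
                for k in range(i + 1, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        cand = (
                            WM[i + 1, k]
                            + WM[k + 1, j - 1]
                            + (ML_CLOSE + ML_BRANCH) * 512
                        )
                        if cand < best:
                            best = cand
                V[i, j] = best + 1  # low bits count pairs
            # WM: >=1 branch inside a multiloop
            best = INF
            if V[i, j] < INF:
                cand = V[i, j] + ML_BRANCH * 512
                if cand < best:
                    best = cand
            if i + 1 <= j and WM[i + 1, j] < INF:
                cand = WM[i + 1, j] + ML_UNPAIRED * 512
                if cand < best:
                    best = cand
            if j - 1 >= i and WM[i, j - 1] < INF:
                cand = WM[i, j - 1] + ML_UNPAIRED * 512
                if cand < best:
                    best = cand
            for k in range(i, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    cand = WM[i, k] + WM[k + 1, j]
                    if cand < best:
                        best = cand
            WM[i, j] = best
    W = np.zeros(n + 1, dtype=np.int64)
    for j in range(n):
        best = W[j]
        for i in range(0, j - 3):
            if V[i, j] < INF:
                cand = W[i] + V[i, j]
                if cand < best:
                    best = cand
        W[j + 1] = best
    return V, WM, W


@dataclass(frozen=True)
class HairpinStructure:
    """A nested secondary structure with its minimum free energy."""

    pairs: frozenset[tuple[int, int]]
    dot_bracket: str
    mfe: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner_map(self) -> dict[int, int]:
        partner = {}
        for i, j in self.pairs:
            partner[i] = j
            partner[j] = i
        return partner


def _dot_bracket(n: int, pairs: frozenset[tuple[int, int]]) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i], out[j] = "(", ")"
    return "".join(out)


def _traceback(seq: np.ndarray, V: np.ndarray, WM: np.ndarray, W: np.ndarray) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    jobs: list[tuple[str, int, int]] = []
    # exterior loop
    j = seq.shape[0] - 1
    while j >= 0:
        if W[j + 1] == W[j]:
            j -= 1
            continue
        for i in range(0, j - 3):
            if V[i, j] < _INF and W[i] + V[i, j] == W[j + 1]:
                jobs.append(("V", i, j))
                j = i - 1
                break
        else:  # pragma: no cover - DP consistency guard
            raise AssertionError("traceback failed in exterior loop")
    while jobs:
        kind, i, j = jobs.pop()
        if kind == "V":
            pairs.append((i, j))
            target = V[i, j] - 1  # strip this pair from the count bits
            pt = _PTYPE[seq[i], seq[j]]
            if target == _HAIRPIN[j - i - 1] * _PBITS:
                continue
            found = False
            kmax = min(i + MAXLOOP + 1, j - 4) + 1
            for k in range(i + 1, kmax):
                n1 = k - i - 1
                lmin = max(k + 4, j - 1 - (MAXLOOP - n1))
                for l in range(j - 1, lmin - 1, -1):
                    if _PTYPE[seq[k], seq[l]] < 0 or V[k, l] >= _INF:
                        continue
                    n2 = j - l - 1
                    if n1 == 0 and n2 == 0:
                        e = int(_STACK[pt, _PTYPE[seq[k], seq[l]]])
                    else:
                        e = _interior_energy(n1, n2)
                    if V[k, l] + e * _PBITS == target:
                        jobs.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for k in range(i + 1, j - 1):
                if (
                    WM[i + 1, k] < _INF
                    and WM[k + 1, j - 1] < _INF
                    and WM[i + 1, k] + WM[k + 1, j - 1] + (ML_CLOSE + ML_BRANCH) * _PBITS
                    == target
                ):
                    jobs.append(("WM", i + 1, k))
                    jobs.append(("WM", k + 1, j - 1))
                    found = True
                    break
            if not found:  # pragma: no cover - DP consistency guard
                raise AssertionError("traceback failed in V")
        else:  # WM
            target = WM[i, j]
            if V[i, j] < _INF and V[i, j] + ML_BRANCH * _PBITS == target:
                jobs.append(("V", i, j))
                continue
            if i + 1 <= j and WM[i + 1, j] + ML_UNPAIRED * _PBITS == target:
                jobs.append(("WM", i + 1, j))
                continue
            if j - 1 >= i and WM[i, j - 1] + ML_UNPAIRED * _PBITS == target:
                jobs.append(("WM", i, j - 1))
                continue
            found = False
            for k in range(i, j):
                if WM[i, k] < _INF and WM[k + 1, j] < _INF and WM[i, k] + WM[k + 1, j] == target:
                    jobs.append(("WM", i, k))
                    jobs.append(("WM", k + 1, j))
                    found = True
                    break
            if not found:  # pragma: no cover - DP consistency guard
                raise AssertionError("traceback failed in WM")
    return pairs


def fold(sequence: str) -> HairpinStructure:
    """Fold a sequence to its minimum-free-energy nested structure.

    Returns the MFE (kcal/mol, <= 0) and the optimal structure; ties are
    broken toward fewer pairs, then by a deterministic traceback order.
    Raises ``ValueError`` on non-nucleotide characters.
    """
    seq = encode_sequence(sequence)
    n = seq.shape[0]
    if n == 0:
        return HairpinStructure(frozenset(), "", 0.0)
    V, WM, W = _fill(
        seq, _PTYPE, _STACK, _HAIRPIN, _BULGE, _INTERIOR, _ASYM_COEF, _ASYM_MAX
    )
    total = int(W[n])
    pairs = frozenset(_traceback(seq, V, WM, W))
    # score = e*512 + p with 0 <= p < 512, so floor division recovers e
    energy_tenths = total // _PBITS
    assert total % _PBITS == len(pairs)
    return HairpinStructure(pairs, _dot_bracket(n, pairs), energy_tenths / 10.0)


def structure_energy(sequence: str, pairs: frozenset[tuple[int, int]] | set[tuple[int, int]]) -> float:
    """Energy (kcal/mol) of an explicit nested structure by loop decomposition.

    This is the definitional scoring of the model: every closing pair
    contributes its loop energy (hairpin, stack, bulge/interior, or
    multibranch); the exterior loop is free. No interior-loop size cap is
    applied here.
    """
    seq = encode_sequence(sequence)
    pair_list = sorted(pairs)
    for i, j in pair_list:
        if not 0 <= i < j < seq.shape[0]:
            raise ValueError("pair index out of range")
        if _PTYPE[seq[i], seq[j]] < 0:
            raise ValueError(f"non-pairable bases at ({i}, {j})")
        if j - i - 1 < MIN_HAIRPIN_LOOP:
            raise ValueError("hairpin loop below minimum size")
    partner = {}
    for i, j in pair_list:
        if i in partner or j in partner:
            raise ValueError("base in more than one pair")
        partner[i] = j
        partner[j] = i

    def branches(lo: int, hi: int) -> tuple[list[tuple[int, int]], int]:
        """Top-level branches and unpaired count within (lo, hi) exclusive."""
        out = []
        unpaired = 0
        k = lo + 1
        while k < hi:
            if k in partner and partner[k] > k:
                out.append((k, partner[k]))
                k = partner[k] + 1
            elif k in partner:
                raise ValueError("pseudoknotted structure")
            else:
                unpaired += 1
                k += 1
        return out, unpaired

    total = 0
    for i, j in pair_list:
        inner, unpaired = branches(i, j)
        if not inner:
            total += int(_HAIRPIN[j - i - 1])
        elif len(inner) == 1:
            k, l = inner[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                total += int(_STACK[_PTYPE[seq[i], seq[j]], _PTYPE[seq[k], seq[l]]])
            else:
                total += _interior_energy(n1, n2)
        else:
            total += ML_CLOSE + ML_BRANCH * (1 + len(inner)) + ML_UNPAIRED * unpaired
    # exterior branches must be nested (checked via branches on the full span)
    branches(-1, seq.shape[0])
    return total / 10.0


def enumerate_structures(sequence: str) -> list[frozenset[tuple[int, int]]]:
    """Every nested structure (loop >= 3, WC + G:U pairs) of a short sequence.

    Intended as an exhaustive oracle for sequences of roughly <= 16 nt;
    the count grows quickly beyond that.
    """
    seq = encode_sequence(sequence)
    n = seq.shape[0]
    if n > 24:
        raise ValueError("exhaustive enumeration is limited to short sequences")

    @lru_cache(maxsize=None)
    def structures(i: int, j: int) -> tuple[frozenset, ...]:
        # all structures of seq[i..j] inclusive
        if j - i < MIN_HAIRPIN_LOOP + 1:
            return (frozenset(),)
        out = list(structures(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if _PTYPE[seq[i], seq[k]] < 0:
                continue
            for inner in structures(i + 1, k - 1):
                for rest in structures(k + 1, j):
                    out.append(frozenset({(i, k)}) | inner | rest)
        return tuple(out)

    if n == 0:
        return [frozenset()]
    result = list(structures(0, n - 1))
    structures.cache_clear()
    return result


def fold_exhaustive(sequence: str) -> tuple[float, int]:
    """Brute-force MFE and pair count by scoring every nested structure.

    Ties break toward fewer pairs, then lexicographically smallest
    dot-bracket, mirroring the DP's primary and secondary tie-breaks.
    """
    best: tuple[float, int, str] | None = None
    n = len(sequence)
    for pairs in enumerate_structures(sequence):
        key = (structure_energy(sequence, pairs), len(pairs), _dot_bracket(n, pairs))
        if best is None or key < best:
            best = key
    assert best is not None
    return best[0], best[1]
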