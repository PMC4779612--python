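"""Minimal progressive multiple alignment.

Guide tree from k-mer distances (UPGMA), then profile-profile merges by
global affine-gap alignment under BLOSUM62 (gap open 10, extend 0.5).
Adequate for desk-scale candidate families; an external aligner adapter
should be preferred for serious unequal-length data.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

_B62 = substitution_matrices.load("BLOSUM62")
_ALPHA = _B62.alphabet
_IDX = {a: i for i, a in enumerate(_ALPHA)}
_MAT = np.array(_B62)

GAP_OPEN = 10.0
GAP_EXTEND = 0.5


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    kb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    shared = sum((ka & kb).values())
    denom = min(sum(ka.values()), sum(kb.values())) or 1
    return 1.0 - shared / denom


def _col_score(col_a: list[str], col_b: list[str]) -> float:
    tot, n = 0.0, 0
    for x in col_a:
        if x == "-":
            continue
        for y in col_b:
            if y == "-":
                continue
            tot += _MAT[_IDX.get(x, _IDX["X"]), _IDX.get(y, _IDX["X"])]
            n += 1
    return tot / n if n else 0.0


def _align_profiles(pa: list[list[str]], pb: list[list[str]]):
    """Global affine alignment of two profiles (lists of columns)."""
    la, lb = len(pa), len(pb)
    na, nb = len(pa[0]), len(pb[0])
    S = np.empty((la, lb))
    for i in range(la):
        for j in range(lb):
            S[i, j] = _col_score(pa[i], pb[j])
    neg = -1e18
    M = np.full((la + 1, lb + 1), neg)
    X = np.full((la + 1, lb + 1), neg)  # gap in b
    Y = np.full((la + 1, lb + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -GAP_OPEN - GAP_EXTEND * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = -GAP_OPEN - GAP_EXTEND * (j - 1)
    ptr = np.zeros((3, la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            opts = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(opts))
            M[i, j] = opts[k] + S[i - 1, j - 1]
            ptr[0, i, j] = k
            opts = (M[i - 1, j] - GAP_OPEN, X[i - 1, j] - GAP_EXTEND)
            k = int(np.argmax(opts))
            X[i, j] = opts[k]
            ptr[1, i, j] = k
            opts = (M[i, j - 1] - GAP_OPEN, Y[i, j - 1] - GAP_EXTEND)
            k = int(np.argmax(opts))
            Y[i, j] = opts[k]
            ptr[2, i, j] = k
    state = int(np.argmax((M[la, lb], X[la, lb], Y[la, lb])))
    i, j = la, lb
    cols: list[list[str]] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            cols.append(pa[i - 1] + pb[j - 1])
            state = int(ptr[0, i, j])
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            cols.append(pa[i - 1] + ["-"] * nb)
            prev = int(ptr[1, i, j])
            state = 0 if prev == 0 else 1
            i -= 1
        else:
            cols.append(["-"] * na + pb[j - 1])
            prev = int(ptr[2, i, j])
            state = 0 if prev == 0 else 2
            j -= 1
    cols.reverse()
    return cols


def progressive_align(seqs: dict[str, str]) -> dict[str, str]:
    names = sorted(seqs)
    if len(names) == 1:
        return dict(seqs)
    n = len(names)
    if n == 2:
        order = [[0], [1]]
        merges = [(0, 1)]
    else:
        cond = []
        for i in range(n):
            for j in range(i + 1, n):
                cond.append(_kmer_distance(seqs[names[i]], seqs[names[j]]))
        z = linkage(np.array(cond), method="average")
        merges = [(int(a), int(b)) for a, b, _, _ in z]
        order = None
    profiles: dict[int, tuple[list[str], list[list[str]]]] = {
        i: ([names[i]], [[c] for c in seqs[names[i]]]) for i in range(n)
    }
    nxt = n
    for a, b in merges:
        names_a, pa = profiles.pop(a)
        names_b, pb = profiles.pop(b)
        cols = _align_profiles(pa, pb)
        profiles[nxt] = (names_a + names_b, cols)
        nxt += 1
    row_names, cols = profiles.popitem()[1]
    mat = list(zip(*cols))
    return {nm: "".join(row) for nm, row in zip(row_names, mat)}
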