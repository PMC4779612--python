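"""All-vs-all protein similarity search and hit post-processing.

This is a self-contained stand-in for an external BLAST step: local
alignment under BLOSUM62 (gap open 11, extend 1), converted to bit
scores with fixed Karlin-Altschul constants (lambda = 0.267, K = 0.041)
and to E-values as ``search_space * 2**(-bits)`` where the search space
is the total residue count of the run.  Precomputed BLAST tabular files
can be substituted via :func:`orthosift.io_formats.parse_blast_tabular`.

Two scoring paths produce identical results on indel-free data:

* ``score_pair`` - exact Smith-Waterman (Biopython's C aligner), always
  used for unequal-length inputs;
* a vectorized gapless local score (maximal-scoring subsegment of the
  position-wise BLOSUM62 profile), used by :func:`all_vs_all` when every
  sequence has the same length, which is the regime produced by the
  no-indel sequence simulator.  Without insertions or deletions the
  gapless local optimum coincides with the gapped optimum, while running
  orders of magnitude faster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord

KA_LAMBDA = 0.267
KA_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1
_LN2 = math.log(2.0)

_B62 = substitution_matrices.load("BLOSUM62")
_ALPHA = _B62.alphabet
_AIDX = {a: i for i, a in enumerate(_ALPHA)}
_MAT = np.array(_B62, dtype=np.float64)

_EVALUE_FLOOR = 1e-300


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = _B62
    al.open_gap_score = -GAP_OPEN
    al.extend_gap_score = -GAP_EXTEND
    al.mode = "local"
    return al


_SW = _aligner()


def bits_from_raw(raw: float) -> float:
    return (KA_LAMBDA * raw - math.log(KA_K)) / _LN2


def evalue_from_bits(bits: float, search_space: float) -> float:
    e = search_space * 2.0 ** (-bits)
    return max(e, _EVALUE_FLOOR)


@dataclass(frozen=True)
class Hit:
    query: str
    subject: str
    score_bits: float
    evalue: float

    def __post_init__(self):
        if self.query == self.subject:
            raise ValueError("self-hit")
        if not (self.evalue > 0 and self.score_bits >= 0):
            raise ValueError("invalid hit statistics")


def _hit_order(h: Hit):
    return (h.evalue, -h.score_bits, h.subject)


@dataclass
class HitTable:
    """Per-query hit lists, each sorted by ascending E-value
    (ties: descending bit score, then subject id)."""

    search_space: float
    hits: dict[str, list[Hit]] = field(default_factory=dict)

    def add(self, hit: Hit) -> None:
        self.hits.setdefault(hit.query, []).append(hit)

    def sort(self) -> None:
        for lst in self.hits.values():
            lst.sort(key=_hit_order)

    def queries(self) -> list[str]:
        return sorted(self.hits)

    def thresholded(self, evalue: float) -> "HitTable":
        out = HitTable(search_space=self.search_space)
        for q, lst in self.hits.items():
            kept = [h for h in lst if h.evalue <= evalue]
            if kept:
                out.hits[q] = kept
        return out

    def restrict(self, seq_ids: Iterable[str]) -> "HitTable":
        ids = set(seq_ids)
        out = HitTable(search_space=self.search_space)
        for q, lst in self.hits.items():
            if q not in ids:
                continue
            kept = [h for h in lst if h.subject in ids]
            if kept:
                out.hits[q] = kept
        return out

    def n_hits(self) -> int:
        return sum(len(v) for v in self.hits.values())

    def to_outfmt6(self, path: str | Path) -> None:
        """Export in 12-column BLAST tabular form.  Alignment-detail
        columns not tracked by the built-in scorer are written as 0."""
        lines = []
        for q in self.queries():
            for h in self.hits[q]:
                lines.append(
                    f"{h.query}\t{h.subject}\t0\t0\t0\t0\t0\t0\t0\t0\t"
                    f"{h.evalue:.6g}\t{h.score_bits:.6g}"
                )
        Path(path).write_text("\n".join(lines) + "\n")

    def __eq__(self, other) -> bool:
        if not isinstance(other, HitTable):
            return NotImplemented
        if set(self.hits) != set(other.hits):
            return False
        for q in self.hits:
            a, b = self.hits[q], other.hits[q]
            if len(a) != len(b):
                return False
            for ha, hb in zip(a, b):
                if (ha.subject != hb.subject
                        or abs(ha.score_bits - hb.score_bits) > 1e-6 * max(1, ha.score_bits)
                        or not math.isclose(ha.evalue, hb.evalue, rel_tol=1e-5)):
                    return False
        return True


def score_pair(a: SequenceRecord, b: SequenceRecord, search_space: float) -> Hit:
    """Exact Smith-Waterman local alignment score between two proteins."""
    raw = _SW.score(a.protein, b.protein)
    bits = bits_from_raw(max(raw, 0.0))
    return Hit(query=a.seq_id, subject=b.seq_id, score_bits=bits,
               evalue=evalue_from_bits(bits, search_space))


def _encode(seqs: Sequence[str]) -> np.ndarray:
    x = _AIDX["X"]
    return np.array(
        [[_AIDX.get(c, x) for c in s] for s in seqs], dtype=np.int32
    )


def _gapless_local_scores(enc: np.ndarray, qi: int) -> np.ndarray:
    """Best-scoring contiguous segment of the position-wise BLOSUM62
    profile of query ``qi`` against all later sequences (Kadane)."""
    prof = _MAT[enc[qi][None, :], enc[qi + 1 :]]
    cur = np.zeros(prof.shape[0])
    best = np.zeros(prof.shape[0])
    for t in range(prof.shape[1]):
        cur = np.maximum(cur + prof[:, t], 0.0)
        np.maximum(best, cur, out=best)
    return best


def all_vs_all(
    records: Sequence[SequenceRecord],
    loosest_evalue: float = 1e-10,
    scorer: str = "auto",
) -> HitTable:
    """Symmetric all-vs-all search; keeps hits with
    ``evalue <= loosest_evalue``.

    ``scorer``: ``"auto"`` (gapless fast path when all sequences share
    one length, Smith-Waterman otherwise), ``"gapless"`` or
    ``"smith-waterman"``.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    if scorer not in ("auto", "gapless", "smith-waterman"):
        raise ValueError(f"unknown scorer {scorer!r}")
    search_space = float(sum(len(r.protein) for r in records))
    equal_len = len({len(r.protein) for r in records}) == 1
    use_gapless = scorer == "gapless" or (scorer == "auto" and equal_len)
    if use_gapless and not equal_len:
        raise ValueError("gapless scorer requires equal-length sequences")
    table = HitTable(search_space=search_space)
    n = len(records)
    if use_gapless:
        enc = _encode([r.protein for r in records])
        for i in range(n - 1):
            raws = _gapless_local_scores(enc, i)
            bits = (KA_LAMBDA * raws - math.log(KA_K)) / _LN2
            needed = math.log2(search_space / loosest_evalue)
            for off in np.nonzero(bits >= needed)[0]:
                j = i + 1 + int(off)
                b = float(bits[off])
                e = evalue_from_bits(b, search_space)
                table.add(Hit(records[i].seq_id, records[j].seq_id, b, e))
                table.add(Hit(records[j].seq_id, records[i].seq_id, b, e))
    else:
        for i in range(n - 1):
            for j in range(i + 1, n):
                h = score_pair(records[i], records[j], search_space)
                if h.evalue <= loosest_evalue:
                    table.add(h)
                    table.add(Hit(h.subject, h.query, h.score_bits, h.evalue))
    table.sort()
    return table


def out_paralog_filter(
    hits: HitTable, group_of: Mapping[str, str], scope: str = "edge"
) -> tuple[HitTable, set[str]]:
    """Drop same-group hits ranked below the best other-group hit.

    For each query, let E* be the smallest E-value among its hits from
    the other taxonomic group; same-group hits with E-value strictly
    greater than E* are flagged as out-paralog hits.  ``scope="edge"``
    removes only the flagged hit from that query's list; ``"global"``
    removes every flagged subject from all lists.  Queries with no
    other-group hit are untouched.
    """
    if scope not in ("edge", "global"):
        raise ValueError(f"unknown scope {scope!r}")
    flagged: set[str] = set()
    out = HitTable(search_space=hits.search_space)
    for q, lst in hits.hits.items():
        qg = group_of[q]
        other = [h.evalue for h in lst if group_of[h.subject] != qg]
        if not other:
            out.hits[q] = list(lst)
            continue
        e_star = min(other)
        kept = []
        for h in lst:
            if group_of[h.subject] == qg and h.evalue > e_star:
                flagged.add(h.subject)
            else:
                kept.append(h)
        out.hits[q] = kept
    if scope == "global" and flagged:
        for q in list(out.hits):
            out.hits[q] = [h for h in out.hits[q] if h.subject not in flagged]
            if not out.hits[q]:
                del out.hits[q]
    return out, flagged


def best_hits(
    hits: HitTable, threshold: float, species_of: Mapping[str, str]
) -> dict[tuple[str, str], str]:
    """Per query and target species, the minimal-E-value hit at or below
    ``threshold`` (ties already resolved by hit-list order)."""
    best: dict[tuple[str, str], str] = {}
    for q, lst in hits.hits.items():
        for h in lst:  # sorted: first qualifying hit per species wins
            if h.evalue > threshold:
                continue
            key = (q, species_of[h.subject])
            if key not in best:
                best[key] = h.subject
    return best


def reciprocal_best_hits(
    best: Mapping[tuple[str, str], str], species_of: Mapping[str, str]
) -> set[frozenset]:
    """Unordered pairs (x, y) that are mutually best hits between their
    two (distinct) species."""
    pairs: set[frozenset] = set()
    for (q, target_sp), s in best.items():
        if species_of[q] == target_sp:
            continue
        if best.get((s, species_of[q])) == q:
            pairs.add(frozenset((q, s)))
    return pairs
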