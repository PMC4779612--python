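"""Composition-based screening for horizontally transferred genes.

Each species' coding sequences define a codon-composition model; a gene
whose codon usage deviates from its genome's model by a Pearson
chi-square test at P < 0.005 (adjustable) is flagged as an HGT
candidate and removed from the working sequence set.  This is a
deliberately simple composition test exposing the interface of the
full Bayesian composition classifiers used for the same purpose; see the
methods note.  The k-mer order is configurable (default 3, i.e. codons).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import SequenceRecord

logger = logging.getLogger("orthosift")

LEAVE_ONE_OUT_MIN_GENES = 20

_BASES = "ACGT"


def _kmer_index(k: int) -> dict[str, int]:
    return {"".join(t): i for i, t in enumerate(itertools.product(_BASES, repeat=k))}


def codon_counts(cds: str, k: int = 3) -> np.ndarray:
    """Counts of non-overlapping reading-frame k-mers (codons for k=3)."""
    idx = _kmer_index(k)
    counts = np.zeros(len(idx))
    for i in range(0, len(cds) - k + 1, k):
        word = cds[i : i + k]
        if word in idx:
            counts[idx[word]] += 1
    return counts


@dataclass
class CompositionModel:
    """Pooled codon-frequency model for one species (pseudocount 1)."""

    species: str
    expected_freqs: np.ndarray
    total_codons: int

    def __post_init__(self):
        s = self.expected_freqs.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError("frequencies must sum to 1")
        if (self.expected_freqs < 0).any():
            raise ValueError("negative frequency")


def train_model(
    cds_records: Sequence[SequenceRecord], species: str | None = None, k: int = 3
) -> CompositionModel:
    """Pooled codon frequencies over one species' usable CDS set."""
    usable = [r for r in cds_records if r.cds_usable]
    if not usable:
        sp = species or (cds_records[0].species if cds_records else "?")
        raise ValueError(f"no usable CDS to train a composition model for {sp!r}")
    sp = species or usable[0].species
    counts = np.ones(4 ** k)  # pseudocount 1 per codon
    total = 0
    for r in usable:
        c = codon_counts(r.cds, k)
        counts += c
        total += int(c.sum())
    return CompositionModel(species=sp, expected_freqs=counts / counts.sum(),
                            total_codons=total)


def hgt_test(
    gene: SequenceRecord,
    model: CompositionModel,
    p_threshold: float = 0.005,
    k: int = 3,
) -> tuple[str, float]:
    """Chi-square test of a gene's codon counts against its genome model.

    Cells with expected count < 1 are pooled into one; df is the number
    of retained cells minus one.  Returns ('hgt_candidate'|'native', p).
    An unusable CDS passes as native with a warning, never silently
    dropped.
    """
    if not gene.cds_usable:
        logger.warning("%s: CDS unusable, gene passes HGT screen as native",
                       gene.seq_id)
        return "native", 1.0
    obs = codon_counts(gene.cds, k)
    n = obs.sum()
    exp = model.expected_freqs * n
    low = exp < 1.0
    if low.any():
        obs = np.append(obs[~low], obs[low].sum())
        exp = np.append(exp[~low], exp[low].sum())
    chi2 = ((obs - exp) ** 2 / exp).sum()
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    verdict = "hgt_candidate" if p < p_threshold else "native"
    return verdict, p


def partition_hgt(
    records: Sequence[SequenceRecord],
    p_threshold: float = 0.005,
    k: int = 3,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split records into (retained, removed-as-HGT), per species.

    Training excludes the gene under test when its species has at least
    20 usable genes (leave-one-out); smaller genomes use the pooled
    model as is.
    """
    by_species: dict[str, list[SequenceRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    retained: list[SequenceRecord] = []
    removed: list[SequenceRecord] = []
    for sp in sorted(by_species):
        genes = by_species[sp]
        usable = [g for g in genes if g.cds_usable]
        pooled = train_model(usable, species=sp, k=k) if usable else None
        loo = len(usable) >= LEAVE_ONE_OUT_MIN_GENES
        for g in genes:
            if not g.cds_usable or pooled is None:
                logger.warning("%s: no usable CDS, retained without HGT screen",
                               g.seq_id)
                retained.append(g)
                continue
            model = (
                train_model([x for x in usable if x.seq_id != g.seq_id],
                            species=sp, k=k)
                if loo
                else pooled
            )
            verdict, _ = hgt_test(g, model, p_threshold=p_threshold, k=k)
            (removed if verdict == "hgt_candidate" else retained).append(g)
    return retained, removed


def write_partition(
    retained: Sequence[SequenceRecord],
    removed: Sequence[SequenceRecord],
    out_dir,
) -> None:
    """Per-species FASTA pairs: ``<species>.native.fasta`` and
    ``<species>.hgt.fasta`` ('HGT filtering only' output)."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for label, recs in (("native", retained), ("hgt", removed)):
        by_sp: dict[str, list[SequenceRecord]] = {}
        for r in recs:
            by_sp.setdefault(r.species, []).append(r)
        for sp, lst in by_sp.items():
            path = out_dir / f"{sp}.{label}.fasta"
            path.write_text(
                "".join(f">{r.seq_id}\n{r.protein}\n" for r in
                        sorted(lst, key=lambda r: r.seq_id))
            )
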