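"""Supermatrix construction: concatenated alignment, NJ tree with
bootstrap, and per-branch support from individual ortholog trees."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import phylo


@dataclass
class ConcatenatedAlignment:
    """Per-species residue rows tiled by ortholog blocks; species missing
    from a block are gap-filled."""

    rows: dict[str, str]
    block_offsets: list[tuple[str, int, int]]  # (ortholog id, start, end)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def species(self) -> list[str]:
        return sorted(self.rows)


def concatenate(
    ortholog_alignments: Sequence[tuple[str, phylo.Alignment]],
    species_of: Mapping[str, str] | None = None,
) -> ConcatenatedAlignment:
    """Concatenate trimmed per-ortholog alignments into one supermatrix.

    Alignment rows may be keyed by sequence id (then ``species_of`` maps
    them to species) or directly by species id.  Two rows of one species
    within a block are an error: in-paralog reduction must have run.
    """
    blocks: list[tuple[str, dict[str, str], int]] = []
    all_species: set[str] = set()
    for oid, aln in ortholog_alignments:
        rows: dict[str, str] = {}
        for name, row in aln.rows.items():
            sp = species_of[name] if species_of else name
            if sp in rows:
                raise ValueError(
                    f"ortholog {oid}: two rows for species {sp!r}"
                )
            rows[sp] = row
        blocks.append((oid, rows, aln.n_sites))
        all_species |= set(rows)
    species = sorted(all_species)
    parts: dict[str, list[str]] = {sp: [] for sp in species}
    offsets: list[tuple[str, int, int]] = []
    pos = 0
    for oid, rows, width in blocks:
        for sp in species:
            parts[sp].append(rows.get(sp, "-" * width))
        offsets.append((oid, pos, pos + width))
        pos += width
    return ConcatenatedAlignment(
        rows={sp: "".join(chunks) for sp, chunks in parts.items()},
        block_offsets=offsets,
    )


def concatenated_tree(
    concat: ConcatenatedAlignment,
    bootstrap_replicates: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[phylo.GeneTree, dict[frozenset, float]]:
    """NJ tree on Poisson-corrected distances of the supermatrix
    (pairwise deletion of gap sites), plus bootstrap percentages per
    internal split (empty dict when replicates = 0)."""
    if len(concat.rows) < 3:
        raise ValueError("need at least 3 species")
    aln = phylo.Alignment(rows=dict(concat.rows))
    d, names = phylo.distance_matrix(aln)
    tree = phylo.nj_tree(d, names)
    support: dict[frozenset, float] = {}
    if bootstrap_replicates > 0:
        rng = rng or np.random.default_rng(0)
        mat = np.array([list(concat.rows[n]) for n in sorted(concat.rows)])
        counts: dict[frozenset, int] = {s: 0 for s in tree.splits()}
        for _ in range(bootstrap_replicates):
            idx = rng.integers(concat.n_sites, size=concat.n_sites)
            rep_rows = {
                n: "".join(mat[i, idx]) for i, n in enumerate(sorted(concat.rows))
            }
            try:
                rd, rn = phylo.distance_matrix(phylo.Alignment(rows=rep_rows))
            except ValueError:
                continue  # replicate lost all comparable sites for a pair
            rep_splits = phylo.nj_tree(rd, rn).splits()
            for s in counts:
                if s in rep_splits:
                    counts[s] += 1
        support = {
            s: 100.0 * c / bootstrap_replicates for s, c in counts.items()
        }
        _annotate_support(tree, support)
    return tree, support


def _annotate_support(tree: phylo.GeneTree, support: dict[frozenset, float]) -> None:
    all_leaves = frozenset(n.name for n in tree.leaves())
    ref = min(all_leaves)
    sets = tree.leafsets()
    for n in tree.nodes():
        if n is tree.root or n.is_leaf:
            continue
        side = sets[n]
        if ref in side:
            side = all_leaves - side
        if side in support:
            n.support = support[side]


def branch_support_percentages(
    concat_tree: phylo.GeneTree,
    ortholog_trees: Sequence[phylo.GeneTree],
) -> dict[frozenset, float | None]:
    """Fraction of individual ortholog trees carrying each internal split
    of the concatenated tree.

    Each ortholog tree covers a species subset; the split is restricted
    to that subset and counts as informative only when both restricted
    sides keep at least two species.  Splits with no informative tree are
    reported as None.
    """
    all_leaves = frozenset(n.name for n in concat_tree.leaves())
    out: dict[frozenset, float | None] = {}
    tree_info = []
    for t in ortholog_trees:
        leaves = frozenset(n.name for n in t.leaves())
        tree_info.append((leaves, t.splits()))
    for side in concat_tree.splits():
        other = all_leaves - side
        informative = 0
        containing = 0
        for leaves, splits in tree_info:
            a = side & leaves
            b = other & leaves
            if len(a) < 2 or len(b) < 2:
                continue
            informative += 1
            canon = a if min(leaves) not in a else b
            if canon in splits:
                containing += 1
        out[side] = (100.0 * containing / informative) if informative else None
    return out
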