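"""Orchestration of the full ortholog-detection flow.

One run: optional composition-based HGT screen, one all-vs-all homology
search at the loosest threshold, out-paralog hit filtering, then a
descending ladder of E-value cycles.  Each cycle clusters the not yet
accepted sequences into candidates (single linkage over reciprocal best
hits, or Markov clustering), gates them on per-species paralog counts,
builds a neighbor-joining tree per candidate, roots it between the two
taxonomic groups, classifies monophyly at the group and species levels
(splitting polyphyletic trees at their longest conflicting branch when
enabled), reduces in-paralogs to one representative per species and
accepts groups passing the species-number check.  Accepted sequences
are frozen; everything else re-enters the next, stricter cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import clustering, homology, phylo
from .io_formats import RunConfig, SequenceRecord, SpeciesTable

logger = logging.getLogger("orthosift")


@dataclass
class OrthologGroup:
    """An accepted ortholog set (one gene per species) with provenance."""

    members: frozenset
    threshold: float
    path: str  # 'monophyletic', 'group_split', 'species_split', 'group+species_split'
    tree: phylo.GeneTree
    alignment: phylo.Alignment  # trimmed, rows = accepted members

    @property
    def threshold_exponent(self) -> int:
        return int(round(math.log10(self.threshold)))


@dataclass
class OrthologSet:
    groups: list[OrthologGroup]
    species_table: SpeciesTable
    discarded: frozenset = frozenset()

    def summary_table(self) -> pd.DataFrame:
        """Per-threshold counts: trees accepted as directly monophyletic,
        trees accepted after splitting, and total orthologs."""
        rows = []
        by_exp: dict[int, list[OrthologGroup]] = {}
        for g in self.groups:
            by_exp.setdefault(g.threshold_exponent, []).append(g)
        for exp in sorted(by_exp, reverse=True):
            gs = by_exp[exp]
            direct = sum(1 for g in gs if g.path == "monophyletic")
            rows.append(
                {
                    "e_value": f"1e{exp}",
                    "monophyletic_trees": direct,
                    "monophyletic_after_splitting": len(gs) - direct,
                    "orthologs": len(gs),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["e_value", "monophyletic_trees",
                     "monophyletic_after_splitting", "orthologs"],
        )


def species_number_check(
    members: Sequence[str] | frozenset,
    species_table: SpeciesTable,
    species_of: Mapping[str, str],
    min_per_group: int = 2,
) -> bool:
    """True iff each of the two groups contributes at least
    ``min_per_group`` distinct species."""
    if not members:
        raise ValueError("empty member set")
    per_group: dict[str, set] = {g: set() for g in species_table.groups}
    for m in members:
        per_group[species_table.group_of(species_of[m])].add(species_of[m])
    return all(len(v) >= min_per_group for v in per_group.values())


def reduce_in_paralogs(
    members: frozenset,
    tree: phylo.GeneTree,
    species_of: Mapping[str, str],
    rng: np.random.Generator,
) -> tuple[frozenset, phylo.GeneTree]:
    """Keep one uniformly chosen representative per species.

    Requires species-level monophyly (each species' genes form a clade);
    the returned tree is pruned to the representatives.
    """
    label_of = {m: species_of[m] for m in members}
    if phylo.classify_monophyly(tree, label_of) != "monophyletic":
        raise ValueError("in-paralog reduction requires species-level monophyly")
    by_species: dict[str, list[str]] = {}
    for m in sorted(members):
        by_species.setdefault(species_of[m], []).append(m)
    chosen = []
    for sp in sorted(by_species):
        genes = by_species[sp]
        chosen.append(genes[int(rng.integers(len(genes)))] if len(genes) > 1
                      else genes[0])
    reduced = frozenset(chosen)
    if reduced == members:
        return reduced, tree
    return reduced, phylo.restrict_to_leaves(tree, reduced)


def _process_candidate(
    cand: clustering.OrthologCandidate,
    records_by_id: Mapping[str, SequenceRecord],
    species_table: SpeciesTable,
    config: RunConfig,
    rng: np.random.Generator,
) -> OrthologGroup | None:
    """Tree stages for one candidate; None means defer to next cycle."""
    members = cand.members
    species_of = {m: records_by_id[m].species for m in members}
    group_of = {m: species_table.group_of(species_of[m]) for m in members}
    if clustering.paralog_count_gate(
        cand, species_of, limit=config.paralog_count_limit
    ) == "defer_to_next_threshold":
        return None
    # splitting only removes members, so a candidate whose full member set
    # fails the species-number check can never be accepted this cycle
    if not species_number_check(members, species_table, species_of,
                                config.min_species_per_group):
        return None
    if len(members) < 3:
        return None
    aln = phylo.align_candidate([records_by_id[m] for m in sorted(members)])
    trimmed = phylo.trim_alignment(aln)
    d, names = phylo.distance_matrix(trimmed)
    unrooted = phylo.nj_tree(d, names)
    tree = phylo.root_between_groups(unrooted, group_of)
    tags = []
    if phylo.classify_monophyly(tree, group_of) == "polyphyletic":
        if not config.tree_splitting_enabled:
            return None
        res = phylo.split_tree(tree, group_of, group_of, species_of,
                               config.min_species_per_group)
        if not res.success:
            return None
        tree = res.tree
        tags.append("group_split")
    current = frozenset(l.name for l in tree.leaves())
    sp_labels = {m: species_of[m] for m in current}
    if phylo.classify_monophyly(tree, sp_labels) == "polyphyletic":
        if not config.tree_splitting_enabled:
            return None
        res = phylo.split_tree(tree, sp_labels, group_of, species_of,
                               config.min_species_per_group)
        if not res.success:
            return None
        tree = res.tree
        tags.append("species_split")
    current = frozenset(l.name for l in tree.leaves())
    reduced, tree = reduce_in_paralogs(current, tree, species_of, rng)
    if not species_number_check(reduced, species_table, species_of,
                                config.min_species_per_group):
        return None
    return OrthologGroup(
        members=reduced,
        threshold=cand.origin_threshold,
        path="+".join(tags) if tags else "monophyletic",
        tree=tree,
        alignment=phylo.Alignment(
            rows={m: trimmed.rows[m] for m in reduced}
        ),
    )


def run_threshold_cycle(
    pool: frozenset,
    records_by_id: Mapping[str, SequenceRecord],
    hits: homology.HitTable,
    threshold: float,
    species_table: SpeciesTable,
    config: RunConfig,
    rng: np.random.Generator,
) -> tuple[list[OrthologGroup], frozenset]:
    """One E-value cycle over the unassigned pool; returns accepted
    groups and the deferred pool."""
    if not pool:
        return [], frozenset()
    sub = hits.restrict(pool).thresholded(threshold)
    species_of = {m: records_by_id[m].species for m in pool}
    if config.clustering_mode == "markov":
        candidates = clustering.markov_cluster(
            sub, threshold, species_of, inflation=config.mcl_inflation
        )
    else:
        best = homology.best_hits(sub, threshold, species_of)
        pairs = homology.reciprocal_best_hits(best, species_of)
        candidates = clustering.single_linkage(pairs, threshold, species_of)
    accepted: list[OrthologGroup] = []
    taken: set[str] = set()
    for cand in candidates:
        try:
            group = _process_candidate(cand, records_by_id, species_table,
                                       config, rng)
        except Exception:
            logger.exception("candidate %s deferred after error",
                             sorted(cand.members)[:3])
            group = None
        if group is not None:
            accepted.append(group)
            taken |= group.members
    return accepted, frozenset(pool) - taken


def run_pipeline(
    records: Sequence[SequenceRecord],
    species_table: SpeciesTable,
    config: RunConfig | None = None,
    hits: homology.HitTable | None = None,
) -> OrthologSet:
    """Full run over descending E-value thresholds.

    ``hits`` may carry a precomputed homology table (e.g. parsed BLAST
    tabular output); otherwise the built-in all-vs-all search is run once
    at the loosest threshold and re-thresholded per cycle.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    if config.hgt_filter_enabled:
        from . import hgt_filter

        records, removed = hgt_filter.partition_hgt(
            records, p_threshold=config.hgt_p_threshold, k=config.hgt_kmer_order
        )
        logger.info("HGT screen removed %d genes", len(removed))
    records_by_id = {r.seq_id: r for r in records}
    for r in records:
        if r.species not in species_table:
            raise ValueError(f"species {r.species!r} not in species table")
    if hits is None:
        hits = homology.all_vs_all(records, loosest_evalue=config.e_value_start)
    group_of = {r.seq_id: species_table.group_of(r.species) for r in records}
    hits, flagged = homology.out_paralog_filter(
        hits, group_of, scope=config.out_paralog_scope
    )
    if flagged:
        logger.info("out-paralog filter flagged %d sequences", len(flagged))
    pool = frozenset(records_by_id)
    groups: list[OrthologGroup] = []
    for threshold in config.thresholds():
        cycle_groups, pool = run_threshold_cycle(
            pool, records_by_id, hits, threshold, species_table, config, rng
        )
        groups.extend(cycle_groups)
        logger.info(
            "threshold 1e%d: %d orthologs accepted, %d sequences remain",
            int(round(math.log10(threshold))), len(cycle_groups), len(pool),
        )
    if not groups:
        logger.warning("no orthologs accepted at any threshold")
    if pool:
        logger.info("%d sequences discarded after the final cycle", len(pool))
    return OrthologSet(groups=groups, species_table=species_table,
                       discarded=pool)
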