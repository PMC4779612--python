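"""Simulation harness: generates the three study regimes (gene loss
after whole-family duplication, Poisson-distributed horizontal transfer,
and long-branch saturation) on balanced model trees, evolves protein
families under the JTT model, and scores how often the reconstructed
(concatenated and per-ortholog) trees match the generating topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import concat as concat_mod
from . import homology, phylo, pipeline
from ._jtt import JTT_ALPHABET, JTT_FREQS, transition_matrix
from .io_formats import RunConfig, SequenceRecord, SpeciesTable
from .phylo import GeneTree, Node


@dataclass
class SimConfig:
    """Parameters of one simulated condition.

    Defaults follow the standard study design: a balanced 32-OTU model
    tree with 0.04 substitutions/site on every branch, 200-residue
    protein families, exact per-family gene-loss counts, and Poisson
    transfer counts with the given mean.
    """

    n_otus: int = 32
    inter_node_branch: float = 0.04
    dup_root_distance: float | None = None  # {0.02, 0.04, 0.08} in the study
    loss_fraction: float = 0.0              # grid 0.30-0.85 step 0.05
    hgt_mean: float = 0.0                   # grid 0.0-5.0 step 0.5
    seq_length: int = 200
    n_families: int = 100
    n_trials: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_otus < 4 or self.n_otus & (self.n_otus - 1):
            raise ValueError("n_otus must be a power of two >= 4")
        if not (0 <= self.loss_fraction < 1):
            raise ValueError("loss_fraction must be in [0, 1)")
        if self.hgt_mean < 0:
            raise ValueError("hgt_mean must be >= 0")
        if self.dup_root_distance is not None and self.dup_root_distance <= 0:
            raise ValueError("dup_root_distance must be positive")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# tree generators


def make_model_tree(n_otus: int, branch_len: float) -> GeneTree:
    """Fully balanced binary tree, every branch ``branch_len``, leaves
    named sp01..spNN, annotated with ultrametric node times."""
    if n_otus < 2 or n_otus & (n_otus - 1):
        raise ValueError("n_otus must be a power of two")
    counter = iter(range(1, n_otus + 1))

    def build(depth: int, parent_time: float) -> Node:
        n = Node(length=branch_len)
        n.time = parent_time + branch_len
        if depth == 0:
            n.name = f"sp{next(counter):02d}"
        else:
            n.add(build(depth - 1, n.time))
            n.add(build(depth - 1, n.time))
        return n

    depth = int(math.log2(n_otus))
    root = Node()
    root.time = 0.0
    root.length = 0.0
    root.add(build(depth - 1, 0.0))
    root.add(build(depth - 1, 0.0))
    return GeneTree(root, rooted=True)


def duplicate_tree(model: GeneTree, root_distance: float) -> GeneTree:
    """Join two copies of the model tree (leaf suffixes _alpha/_beta) at a
    new root; the path between the copy roots is ``root_distance``,
    split equally."""
    half = root_distance / 2.0
    new_root = Node()
    new_root.time = 0.0
    for tag in ("alpha", "beta"):
        copy = model.copy()
        for leaf in copy.leaves():
            leaf.name = f"{leaf.name}_{tag}"
        sub = copy.root
        sub.length = half
        for n in GeneTree(sub).nodes():
            if n.time is not None:
                n.time += half
        new_root.add(sub)
    return GeneTree(new_root, rooted=True)


def apply_gene_loss(
    family_leaves: Sequence[str], loss_fraction: float, rng: np.random.Generator
) -> list[str]:
    """Remove exactly round(loss_fraction * n) leaves uniformly without
    replacement; returns the surviving leaf names (sorted)."""
    if not (0 <= loss_fraction < 1):
        raise ValueError("loss_fraction must be in [0, 1)")
    leaves = sorted(family_leaves)
    n_remove = round(loss_fraction * len(leaves))
    removed = set(rng.choice(len(leaves), size=n_remove, replace=False).tolist())
    return [l for i, l in enumerate(leaves) if i not in removed]


def _alive_edges(tree: GeneTree, t: float) -> list[Node]:
    """Edges (identified by their child node) spanning time t."""
    out = []
    for n in tree.nodes():
        if n.parent is None:
            continue
        if n.parent.time < t < n.time:
            out.append(n)
    out.sort(key=lambda n: min(l.name for l in GeneTree(n).leaves()))
    return out


def _tree_height(tree: GeneTree) -> float:
    return max(l.time for l in tree.leaves())


def apply_hgt_events(
    model: GeneTree, hgt_mean: float, rng: np.random.Generator
) -> GeneTree:
    """Poisson(hgt_mean) gene-displacement transfers on an ultrametric tree.

    Each event draws a time t uniformly over the tree height, picks a
    recipient and a distinct donor uniformly among lineages alive at t,
    prunes the recipient's subtree at t and regrafts it onto the donor
    lineage at t.  The leaf set and ultrametricity are preserved.
    """
    tree = model.copy()
    k = int(rng.poisson(hgt_mean))
    tree.hgt_events = k  # event count, for diagnostics and tests
    height = _tree_height(tree)
    for _ in range(k):
        for _attempt in range(1000):
            t = float(rng.uniform(0.0, height))
            alive = _alive_edges(tree, t)
            if len(alive) >= 2:
                break
        else:  # pragma: no cover - cannot happen below the first split
            continue
        r_i = int(rng.integers(len(alive)))
        recipient = alive[r_i]
        donors = alive[:r_i] + alive[r_i + 1 :]
        donor = donors[int(rng.integers(len(donors)))]
        # split the donor edge at time t
        p_d = donor.parent
        x = Node(length=t - p_d.time)
        x.time = t
        p_d.children[p_d.children.index(donor)] = x
        x.parent = p_d
        x.add(donor)
        donor.length = donor.time - t
        # move the recipient subtree under x
        p_r = recipient.parent
        p_r.children.remove(recipient)
        x.add(recipient)
        recipient.length = recipient.time - t
        # suppress the unifurcation left at the recipient's old parent
        if p_r.parent is not None and len(p_r.children) == 1:
            only = p_r.children[0]
            only.length += p_r.length
            gp = p_r.parent
            gp.children[gp.children.index(p_r)] = only
            only.parent = gp
        # a root left with one child is kept (its time anchors the clock)
    return tree


# ---------------------------------------------------------------------------
# sequence evolution


_AA_IDX = {a: i for i, a in enumerate(JTT_ALPHABET)}


def evolve_sequences(
    tree: GeneTree, seq_length: int, rng: np.random.Generator
) -> dict[str, str]:
    """Evolve a protein family down the tree under the JTT model.

    The root sequence is drawn from the JTT stationary frequencies; each
    branch applies P(t) = exp(Q t) independently per site.  No indels are
    introduced.  Deterministic for a given generator state.
    """
    root_state = rng.choice(20, size=seq_length, p=JTT_FREQS)
    states: dict[int, np.ndarray] = {id(tree.root): root_state}
    out: dict[str, str] = {}
    if tree.root.is_leaf:
        out[tree.root.name] = "".join(JTT_ALPHABET[i] for i in root_state)
    for node in tree.nodes():  # preorder: parents before children
        for child in node.children:
            p = transition_matrix(round(child.length, 12))
            cum = np.cumsum(p, axis=1)
            u = rng.random(seq_length)
            parent_state = states[id(node)]
            child_state = (u[:, None] > cum[parent_state]).sum(axis=1)
            states[id(child)] = child_state
            if child.is_leaf:
                out[child.name] = "".join(JTT_ALPHABET[i] for i in child_state)
    return out


# ---------------------------------------------------------------------------
# experiments


@dataclass
class AccuracyReport:
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["condition", "method", "accuracy_concat",
                     "accuracy_per_ortholog", "n_trials"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _species_name(leaf: str) -> str:
    return leaf.split("_")[0]


def species_table_for(model: GeneTree) -> SpeciesTable:
    """Two groups = the two clades under the model root."""
    a, b = model.root.children
    entries = {}
    for leaf in GeneTree(a).leaves():
        entries[leaf.name] = "G1"
    for leaf in GeneTree(b).leaves():
        entries[leaf.name] = "G2"
    return SpeciesTable(entries)


def _family_trees(kind: str, sim: SimConfig, model: GeneTree,
                  rng: np.random.Generator) -> Iterable[tuple[GeneTree, list[str]]]:
    """Yield (tree to evolve on, leaves kept) per family."""
    if kind == "gene_loss":
        dup = duplicate_tree(model, sim.dup_root_distance)
        all_leaves = [l.name for l in dup.leaves()]
        for _ in range(sim.n_families):
            kept = apply_gene_loss(all_leaves, sim.loss_fraction, rng)
            if not kept:
                continue
            yield dup, kept
    elif kind == "hgt":
        for _ in range(sim.n_families):
            t = apply_hgt_events(model, sim.hgt_mean, rng)
            yield t, [l.name for l in t.leaves()]
    elif kind == "saturation":
        leaves = [l.name for l in model.leaves()]
        for _ in range(sim.n_families):
            yield model, leaves
    else:
        raise ValueError(f"unknown experiment kind {kind!r}")


def simulate_trial_records(
    kind: str, sim: SimConfig, rng: np.random.Generator
) -> tuple[list[SequenceRecord], GeneTree, SpeciesTable]:
    """Generate one trial's anonymized per-species sequence records."""
    model = make_model_tree(sim.n_otus, sim.inter_node_branch)
    per_species: dict[str, list[str]] = {
        l.name: [] for l in model.leaves()
    }
    for tree, kept in _family_trees(kind, sim, model, rng):
        seqs = evolve_sequences(tree, sim.seq_length, rng)
        for leaf in kept:
            per_species[_species_name(leaf)].append(seqs[leaf])
    records: list[SequenceRecord] = []
    for sp in sorted(per_species):
        seqs = per_species[sp]
        order = rng.permutation(len(seqs))  # strip family identity
        for serial, idx in enumerate(order, 1):
            records.append(
                SequenceRecord(seq_id=f"{sp}g{serial:03d}", species=sp,
                               protein=seqs[int(idx)])
            )
    return records, model, species_table_for(model)


def score_trial(
    ortholog_set: pipeline.OrthologSet,
    records: Sequence[SequenceRecord],
    model: GeneTree,
) -> tuple[bool, int, int]:
    """(concatenated tree matches model, #accurate ortholog trees,
    #ortholog trees)."""
    species_of = {r.seq_id: r.species for r in records}
    model_species = set(l.name for l in model.leaves())
    n_groups = len(ortholog_set.groups)
    ok_orth = 0
    for g in ortholog_set.groups:
        sp_tree = phylo.relabel_leaves(g.tree, species_of)
        sub_model = phylo.restrict_to_leaves(model, sp_tree.leaf_names())
        try:
            if phylo.same_topology(sp_tree, sub_model):
                ok_orth += 1
        except ValueError:
            pass
    concat_ok = False
    if ortholog_set.groups:
        items = [(f"og{i}", g.alignment) for i, g in
                 enumerate(ortholog_set.groups, 1)]
        supermatrix = concat_mod.concatenate(items, species_of=species_of)
        if set(supermatrix.species) == model_species:
            try:
                tree, _ = concat_mod.concatenated_tree(
                    supermatrix, bootstrap_replicates=0
                )
                concat_ok = phylo.same_topology(tree, model)
            except ValueError:
                concat_ok = False
    return concat_ok, ok_orth, n_groups


def run_experiment(
    kind: str,
    sim: SimConfig,
    run: RunConfig | None = None,
    clustering_modes: Sequence[str] = ("single_linkage",),
) -> AccuracyReport:
    """Run ``sim.n_trials`` simulated trials of one condition through the
    ortholog pipeline and score concatenated-tree and per-ortholog-tree
    accuracy for each clustering mode."""
    run = run or RunConfig()
    report = AccuracyReport()
    condition = _condition_label(kind, sim)
    tallies = {m: {"concat": 0, "orth_ok": 0, "orth_n": 0} for m in clustering_modes}
    for trial in range(sim.n_trials):
        rng = np.random.default_rng((sim.seed, trial))
        records, model, table = simulate_trial_records(kind, sim, rng)
        hits = homology.all_vs_all(records, loosest_evalue=run.e_value_start)
        for mode in clustering_modes:
            cfg = run.with_(clustering_mode=mode, seed=sim.seed * 1009 + trial)
            oset = pipeline.run_pipeline(records, table, cfg, hits=hits)
            concat_ok, ok_orth, n_orth = score_trial(oset, records, model)
            tallies[mode]["concat"] += concat_ok
            tallies[mode]["orth_ok"] += ok_orth
            tallies[mode]["orth_n"] += n_orth
    for mode in clustering_modes:
        t = tallies[mode]
        report.rows.append(
            {
                "condition": condition,
                "method": mode,
                "accuracy_concat": 100.0 * t["concat"] / sim.n_trials,
                "accuracy_per_ortholog": (
                    100.0 * t["orth_ok"] / t["orth_n"] if t["orth_n"] else 0.0
                ),
                "n_trials": sim.n_trials,
            }
        )
    return report


def _condition_label(kind: str, sim: SimConfig) -> str:
    if kind == "gene_loss":
        return (f"gene_loss d={sim.dup_root_distance} "
                f"loss={sim.loss_fraction:.2f} b={sim.inter_node_branch}")
    if kind == "hgt":
        return f"hgt mean={sim.hgt_mean} b={sim.inter_node_branch}"
    return f"saturation b={sim.inter_node_branch}"
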