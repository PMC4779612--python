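"""Gene-tree machinery: distances, neighbor joining, rooting between the
two taxonomic groups, monophyly classification, tree splitting and
unrooted topology comparison.

Trees are lightweight rooted node structures; "unrooted" semantics
(neighbor-joining output, Robinson-Foulds comparison) are handled by
treating the root as an unlabeled internal vertex and comparing splits.
Newick serialization goes through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np

# ---------------------------------------------------------------------------
# tree structure


class Node:
    __slots__ = ("name", "length", "children", "parent", "support", "time")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.support: float | None = None
        self.time: float | None = None  # ultrametric node age, root = 0

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class GeneTree:
    """A (possibly rooted) tree over named leaves with branch lengths."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    # -- traversal ---------------------------------------------------------
    def nodes(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def postorder(self) -> list[Node]:
        return list(reversed(self.nodes()))

    def leaves(self) -> list[Node]:
        return [n for n in self.nodes() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return sorted(n.name for n in self.leaves())

    def __len__(self) -> int:
        return len(self.leaves())

    def copy(self) -> "GeneTree":
        def rec(n: Node) -> Node:
            m = Node(n.name, n.length)
            m.support, m.time = n.support, n.time
            for c in n.children:
                m.add(rec(c))
            return m

        return GeneTree(rec(self.root), rooted=self.rooted)

    # -- splits ------------------------------------------------------------
    def leafsets(self) -> dict[Node, frozenset]:
        """Leaf-name set under every node (postorder accumulation)."""
        sets: dict[Node, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf:
                sets[n] = frozenset([n.name])
            else:
                acc: set = set()
                for c in n.children:
                    acc |= sets[c]
                sets[n] = frozenset(acc)
        return sets

    def splits(self) -> set[frozenset]:
        """Nontrivial unrooted splits, each canonicalized as the side not
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(n.name for n in self.leaves())
        ref = min(all_leaves)
        out: set[frozenset] = set()
        sets = self.leafsets()
        for n in self.nodes():
            if n is self.root or n.is_leaf:
                continue
            side = sets[n]
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def clades(self) -> set[frozenset]:
        """Leaf sets of all rooted clades (internal nodes and leaves)."""
        return set(self.leafsets().values())


# ---------------------------------------------------------------------------
# newick via dendropy


def to_newick(tree: GeneTree) -> str:
    def rec(n: Node) -> str:
        if n.is_leaf:
            core = n.name or ""
        else:
            core = "(" + ",".join(rec(c) for c in n.children) + ")"
            if n.support is not None:
                core += f"{n.support:g}"
        if n.parent is not None:
            core += f":{n.length:.10g}"
        return core

    return rec(tree.root) + ";"


def from_newick(text: str) -> GeneTree:
    try:
        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True,
                               preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"newick parse error: {exc}") from exc

    def rec(dn) -> Node:
        name = dn.taxon.label if dn.taxon is not None else None
        n = Node(name=name, length=dn.edge.length or 0.0)
        if dn.label is not None and not dn.is_leaf():
            try:
                n.support = float(dn.label)
            except ValueError:
                pass
        for dc in dn.child_nodes():
            n.add(rec(dc))
        return n

    return GeneTree(rec(dt.seed_node))


# ---------------------------------------------------------------------------
# alignments


@dataclass
class Alignment:
    """Fixed-length residue rows keyed by sequence id; gap is '-'."""

    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def names(self) -> list[str]:
        return sorted(self.rows)


def align_candidate(members, aligner: Callable | None = None) -> Alignment:
    """Multiple alignment of an ortholog candidate.

    Equal-length inputs (the no-indel simulation regime) pass through
    unaligned.  Otherwise a configured external-aligner adapter is used
    when given, falling back to a built-in progressive alignment
    (neighbor-joining guide tree on k-mer distances, profile-profile
    merge under BLOSUM62 with affine gaps 10/0.5).
    """
    if len(members) < 2:
        raise ValueError("need at least two sequences to align")
    seqs = {m.seq_id: m.protein for m in members}
    if len({len(s) for s in seqs.values()}) == 1:
        return Alignment(rows=dict(seqs))
    if aligner is not None:
        return aligner(seqs)
    from ._progressive import progressive_align

    return Alignment(rows=progressive_align(seqs))


def mafft_aligner(seqs: Mapping[str, str]) -> Alignment:
    """External-aligner adapter calling a ``mafft`` binary on PATH."""
    import subprocess
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
        for name, s in seqs.items():
            fh.write(f">{name}\n{s}\n")
        path = fh.name
    proc = subprocess.run(
        ["mafft", "--quiet", "--auto", path], capture_output=True, text=True
    )
    if proc.returncode != 0:
        raise RuntimeError(f"mafft failed: {proc.stderr}")
    rows: dict[str, str] = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            rows[name] = ""
        elif name is not None:
            rows[name] += line.strip().upper()
    return Alignment(rows=rows)


def trim_alignment(aln: Alignment) -> Alignment:
    """Remove every column containing a gap (conserved-block stand-in)."""
    if not aln.rows:
        return aln
    mat = np.array([list(aln.rows[n]) for n in aln.names()])
    keep = ~(mat == "-").any(axis=0)
    if not keep.any():
        raise ValueError("alignment empty after trimming")
    trimmed = mat[:, keep]
    return Alignment(rows={n: "".join(r) for n, r in zip(aln.names(), trimmed)})


SATURATION_P = 0.95


def distance_matrix(aln: Alignment) -> tuple[np.ndarray, list[str]]:
    """Poisson-corrected pairwise distances d = -ln(1 - p).

    p is the mismatch proportion over mutually ungapped sites;
    p >= 0.95 is clamped to -ln(0.05) (saturation).
    """
    names = aln.names()
    if len(names) < 2:
        raise ValueError("need at least two rows")
    mat = np.frombuffer(
        "".join(aln.rows[n] for n in names).encode(), dtype=np.uint8
    ).reshape(len(names), aln.n_sites)
    gap = mat == ord("-")
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        both = ~gap[i] & ~gap[i + 1 :]
        comp = both.sum(axis=1)
        if (comp == 0).any():
            j = i + 1 + int(np.argmax(comp == 0))
            raise ValueError(
                f"no mutually ungapped sites between {names[i]} and {names[j]}"
            )
        mism = ((mat[i] != mat[i + 1 :]) & both).sum(axis=1)
        p = mism / comp
        p = np.minimum(p, SATURATION_P)
        d[i, i + 1 :] = d[i + 1 :, i] = -np.log1p(-p)
    return d, names


def nj_tree(d: np.ndarray, labels: Sequence[str]) -> GeneTree:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcate
    root for n >= 3).  Negative branch lengths are clamped to zero.
    Exact on additive matrices."""
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.asarray(d, dtype=float).copy()
    nodes: list[Node] = [Node(name=l) for l in labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(int(np.argmin(q)), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        ci, cj = nodes[ai], nodes[aj]
        ci.length = max(li, 0.0)
        cj.length = max(lj, 0.0)
        parent.add(ci)
        parent.add(cj)
        # distances from the new node to the remaining taxa
        rest = [a for a in active if a not in (ai, aj)]
        newd = 0.5 * (d[ai, rest] + d[aj, rest] - dij)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, rest] = d[rest, -1] = newd
        active = rest + [len(nodes) - 1]
    # final three branches
    a, b, c = active
    root = Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, l in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(l, 0.0)
        root.add(nodes[idx])
    return GeneTree(root, rooted=False)


# ---------------------------------------------------------------------------
# rooting and classification


def _edge_key(tree: GeneTree, node: Node, sets: Mapping[Node, frozenset]) -> str:
    return min(sets[node])


def _flip_path_above(node: Node) -> None:
    """Reverse all parent links on the path from ``node`` to the root, so
    ``node`` can become (a child of) the new root.  Reversed edges keep
    their lengths."""
    path = []
    p = node
    while p is not None:
        path.append(p)
        p = p.parent
    up_len = [p.length for p in path]
    for i in range(len(path) - 1):
        upper, lower = path[i + 1], path[i]
        upper.children.remove(lower)
        lower.add(upper)  # resets upper.parent
        upper.length = up_len[i]


def reroot_at_edge(tree: GeneTree, child: Node, fraction: float = 0.5) -> GeneTree:
    """Reroot ``tree`` (mutating it) on the edge above ``child``;
    ``fraction`` of the edge length goes to the child side."""
    old_parent = child.parent
    if old_parent is None:
        raise ValueError("cannot root on the root edge")
    old_parent.children.remove(child)
    _flip_path_above(old_parent)
    l = child.length
    new_root = Node()
    child.parent = None
    child.length = l * fraction
    new_root.add(child)
    old_parent.parent = None
    old_parent.length = l * (1 - fraction)
    new_root.add(old_parent)
    t = GeneTree(new_root, rooted=True)
    _suppress_unifurcations(t)
    return t


def _suppress_unifurcations(tree: GeneTree) -> None:
    changed = True
    while changed:
        changed = False
        for n in tree.nodes():
            if n.is_leaf:
                continue
            if len(n.children) == 1 and n.parent is not None:
                child = n.children[0]
                child.length += n.length
                p = n.parent
                p.children[p.children.index(n)] = child
                child.parent = p
                changed = True
            elif len(n.children) == 1 and n.parent is None:
                child = n.children[0]
                child.parent = None
                tree.root = child
                changed = True


def root_between_groups(tree: GeneTree, group_of: Mapping[str, str]) -> GeneTree:
    """Root on the branch separating the two taxonomic groups.

    If no branch cleanly separates them (a polyphyletic gene tree), root
    on the branch whose split misplaces the fewest leaves, breaking ties
    by the longest branch then by a deterministic edge id.
    """
    work = tree.copy()
    leaves = work.leaves()
    groups = sorted({group_of[l.name] for l in leaves})
    if len(groups) < 2:
        raise ValueError("cannot root: one group absent")
    g0 = groups[0]
    all_names = frozenset(l.name for l in leaves)
    sets = work.leafsets()
    best = None  # (misplaced, -length, edge_key, node)
    for n in work.nodes():
        if n is work.root:
            continue
        side = sets[n]
        other = all_names - side
        if not other:
            continue
        in0_side = sum(1 for x in side if group_of[x] == g0)
        in0_other = sum(1 for x in other if group_of[x] == g0)
        mis = min(
            (len(side) - in0_side) + in0_other,       # side ~ g0
            in0_side + (len(other) - in0_other),      # side ~ g1
        )
        key = (mis, -n.length, _edge_key(work, n, sets))
        if best is None or key < best[0]:
            best = (key, n)
    rooted = reroot_at_edge(work, best[1])
    rooted.rooted = True
    return rooted


def classify_monophyly(tree: GeneTree, label_of: Mapping[str, str]) -> str:
    """'monophyletic' iff every label's leaves form a clade of the rooted
    tree (single-leaf labels are trivially clades), else 'polyphyletic'."""
    clades = tree.clades()
    by_label: dict[str, set] = {}
    for leaf in tree.leaves():
        by_label.setdefault(label_of[leaf.name], set()).add(leaf.name)
    for members in by_label.values():
        if len(members) > 1 and frozenset(members) not in clades:
            return "polyphyletic"
    return "monophyletic"


@dataclass
class SplitResult:
    success: bool
    tree: GeneTree          # retained subtree on success, original otherwise
    cut_edge_key: str | None = None


def _component_trees(tree: GeneTree, child: Node) -> tuple[GeneTree, GeneTree]:
    """Bisect at the edge above ``child``: (subtree below, remainder rooted
    at the attachment point).  Operates on copies."""
    # map nodes by id via parallel copy
    work = tree.copy()
    # find corresponding node by path of child indices
    path = []
    n = child
    while n.parent is not None:
        path.append(n.parent.children.index(n))
        n = n.parent
    node = work.root
    for idx in reversed(path):
        node = node.children[idx]
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    below = GeneTree(node, rooted=True)
    # remainder: reroot at the attachment node so monophyly is judged from
    # the cut point
    rest = GeneTree(work.root, rooted=True)
    rest = _reroot_at_node(rest, parent)
    _suppress_unifurcations(below)
    _suppress_unifurcations(rest)
    return below, rest


def _reroot_at_node(tree: GeneTree, node: Node) -> GeneTree:
    """Hang the tree (mutating it) from an existing internal ``node``."""
    if node.parent is None:
        _suppress_unifurcations(tree)
        return tree
    _flip_path_above(node)
    node.parent = None
    node.length = 0.0
    t = GeneTree(node, rooted=True)
    _suppress_unifurcations(t)
    return t


def split_tree(
    tree: GeneTree,
    level_of: Mapping[str, str],
    group_of: Mapping[str, str],
    species_of: Mapping[str, str],
    min_species_per_group: int = 2,
) -> SplitResult:
    """Bisect a polyphyletic rooted gene tree at its longest conflicting
    branch to isolate a monophyletic component.

    Branches are tried in descending length (ties by a deterministic edge
    id).  A component qualifies when it is monophyletic at the requested
    level and contains at least ``min_species_per_group`` species of each
    group.  With one qualifying component it is retained; with two, the
    one with more leaves (ties: more species, then smallest leaf id) is
    retained.  If no cut succeeds the original tree is returned unchanged.
    """
    sets = tree.leafsets()
    groups = sorted(set(group_of.values()))

    def qualifies(component: GeneTree) -> bool:
        names = [l.name for l in component.leaves()]
        if len(names) < 2:
            return False
        per_group: dict[str, set] = {g: set() for g in groups}
        for x in names:
            per_group[group_of[x]].add(species_of[x])
        if any(len(v) < min_species_per_group for v in per_group.values()):
            return False
        return classify_monophyly(component, level_of) == "monophyletic"

    candidates = [
        n for n in tree.nodes() if n is not tree.root
    ]
    candidates.sort(key=lambda n: (-n.length, _edge_key(tree, n, sets)))
    for child in candidates:
        below, rest = _component_trees(tree, child)
        ok_below, ok_rest = qualifies(below), qualifies(rest)
        if not ok_below and not ok_rest:
            continue
        if ok_below and ok_rest:
            def rank(t: GeneTree):
                names = [l.name for l in t.leaves()]
                return (-len(names), -len({species_of[x] for x in names}), min(names))

            chosen = min((below, rest), key=rank)
        else:
            chosen = below if ok_below else rest
        return SplitResult(True, chosen, cut_edge_key=_edge_key(tree, child, sets))
    return SplitResult(False, tree)


def same_topology(t1: GeneTree, t2: GeneTree) -> bool:
    """True iff the unrooted Robinson-Foulds distance is zero."""
    n1, n2 = set(t1.leaf_names()), set(t2.leaf_names())
    if n1 != n2:
        raise ValueError("leaf sets differ")
    return t1.splits() == t2.splits()


def rf_distance(t1: GeneTree, t2: GeneTree) -> int:
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("leaf sets differ")
    return len(t1.splits() ^ t2.splits())


def restrict_to_leaves(tree: GeneTree, keep: Iterable[str]) -> GeneTree:
    """Prune the tree down to ``keep`` leaves, suppressing unifurcations
    and adding up branch lengths."""
    keep = set(keep)
    work = tree.copy()
    changed = True
    while changed:
        changed = False
        for n in work.nodes():
            if n.is_leaf and n.name not in keep and n.parent is not None:
                n.parent.children.remove(n)
                changed = True
    _suppress_unifurcations(work)
    return work


def relabel_leaves(tree: GeneTree, mapping: Mapping[str, str]) -> GeneTree:
    work = tree.copy()
    for leaf in work.leaves():
        work_name = mapping.get(leaf.name, leaf.name)
        leaf.name = work_name
    return work
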