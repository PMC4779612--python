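"""Grouping ortholog pairs into candidates.

Two modes: single-linkage clustering of reciprocal-best-hit pairs
(connected components of the pair graph) and a built-in Markov
clustering (MCL) of the similarity graph, a simplified substitute for an
external OrthoMCL step.  A paralog-count gate defers candidates in which
one species contributes too many members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .homology import HitTable

EVALUE_FLOOR = 1e-180  # before -log10 weighting, avoids infinities


@dataclass
class OrthologCandidate:
    members: frozenset
    origin_threshold: float
    deferred: bool = False

    def species_counts(self, species_of: Mapping[str, str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            sp = species_of[m]
            counts[sp] = counts.get(sp, 0) + 1
        return counts


def _to_candidates(components: Iterable[Iterable[str]], threshold: float,
                   species_of: Mapping[str, str]) -> list[OrthologCandidate]:
    cands = []
    for comp in components:
        comp = frozenset(comp)
        if len(comp) < 2:
            continue
        if len({species_of[m] for m in comp}) < 2:
            continue
        cands.append(OrthologCandidate(members=comp, origin_threshold=threshold))
    cands.sort(key=lambda c: min(c.members))
    return cands


def single_linkage(pairs: Iterable[frozenset], threshold: float,
                   species_of: Mapping[str, str]) -> list[OrthologCandidate]:
    """Candidates are the connected components of the RBH pair graph."""
    g = nx.Graph()
    for p in pairs:
        a, b = sorted(p)
        g.add_edge(a, b)
    return _to_candidates(nx.connected_components(g), threshold, species_of)


def markov_cluster(
    hits: HitTable,
    threshold: float,
    species_of: Mapping[str, str],
    inflation: float = 1.5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> list[OrthologCandidate]:
    """MCL on the -log10(E-value)-weighted, symmetrized similarity graph.

    Self-loops are added with weight equal to the maximal incident edge
    (standard regularization).  Expansion/inflation iterates until the
    column-stochastic matrix change falls below ``tol``; non-convergence
    produces clusters from the last iterate with a warning.
    """
    sub = hits.thresholded(threshold)
    ids = sorted(set(sub.hits) | {h.subject for lst in sub.hits.values() for h in lst})
    if not ids:
        return []
    idx = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    w = np.zeros((n, n))
    for q, lst in sub.hits.items():
        for h in lst:
            weight = -np.log10(max(h.evalue, EVALUE_FLOOR))
            i, j = idx[q], idx[h.subject]
            w[i, j] = max(w[i, j], weight)
    w = np.maximum(w, w.T)
    incident_max = w.max(axis=1)
    np.fill_diagonal(w, incident_max)
    col = w.sum(axis=0)
    col[col == 0] = 1.0
    m = w / col
    converged = False
    for _ in range(max_iter):
        m2 = m @ m                      # expansion
        m2 = np.power(m2, inflation)    # inflation
        m2[m2 < 1e-12] = 0.0
        col = m2.sum(axis=0)
        col[col == 0] = 1.0
        m2 /= col
        if np.abs(m2 - m).max() < tol:
            m = m2
            converged = True
            break
        m = m2
    if not converged:
        import logging

        logging.getLogger("orthosift").warning(
            "MCL did not converge in %d iterations; clustering last iterate",
            max_iter,
        )
    g = nx.Graph()
    g.add_nodes_from(range(n))
    attractors = np.nonzero(np.diag(m) > tol)[0]
    for i in attractors:
        for j in np.nonzero(m[i] > 1e-5)[0]:
            g.add_edge(int(i), int(j))
    comps = ({ids[i] for i in comp} for comp in nx.connected_components(g))
    return _to_candidates(comps, threshold, species_of)


def paralog_count_gate(
    candidate: OrthologCandidate, species_of: Mapping[str, str], limit: int = 3
) -> str:
    """``defer_to_next_threshold`` iff any one species contributes
    ``limit`` or more members; else ``proceed_to_trees``."""
    counts = candidate.species_counts(species_of)
    if counts and max(counts.values()) >= limit:
        return "defer_to_next_threshold"
    return "proceed_to_trees"
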