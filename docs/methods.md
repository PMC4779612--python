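# Methods

## Problem and approach

Species phylogenies are usually built from concatenated ortholog
alignments. Two classes of genes corrupt such supermatrices: *out-paralogs*
(duplicates that arose before the divergence of the taxa under study, so
that a gene tree mixes the two duplicate lineages) and *horizontally
transferred genes* (whose gene trees follow the donor lineage rather than
the species). orthosift builds ortholog data sets that exclude both, for
whole-proteome inputs of species partitioned into **two taxonomic groups**
— the group labels are what make out-paralogs detectable, because a clean
ortholog tree must place the root on the branch separating the groups.

The detection flow per run:

1. *(optional)* *HGT screen* — per-species codon-composition chi-square
   test; deviant genes are set aside (disabled by default).
2. *All-vs-all similarity search* — built-in local alignment under
   BLOSUM62 (gap open 11, extend 1), bit scores via fixed Karlin–Altschul
   constants (λ = 0.267, K = 0.041), E-value = N·2^(−bits) with N the
   total residue count. A precomputed BLAST tabular file can be
   substituted.
3. *Out-paralog hit filter* — for each query, same-group hits ranked
   strictly below the best other-group hit are removed (a same-group gene
   less similar than another group's genes must predate the group split).
4. *Threshold ladder* — E-value cycles from 1e-10 down to 1e-100 in ten
   decades. Per cycle: best hits per (query, species), reciprocal best
   hits, single-linkage components (or built-in Markov clustering of the
   −log10 E-value graph) form candidates; candidates in which one species
   contributes ≥ 3 members are deferred to the next, stricter cycle.
5. *Tree stage per candidate* — align (equal-length families pass
   through; otherwise an external-aligner adapter or the built-in
   progressive aligner), remove gapped columns, Poisson-corrected
   distances, neighbor joining, root between the two groups, classify
   monophyly at the group then the species level. Polyphyletic trees are
   *split*: branches are cut longest-first and a cut is kept when one
   component is monophyletic at the level and contains at least
   `min_species_per_group` (default 2) species of each group; otherwise
   the cut is undone and the next branch is tried. In-paralogs are then
   reduced to one uniformly chosen representative per species, and groups
   passing the species-number check are frozen as orthologs. Everything
   else returns to the pool for the next cycle.
6. *Supermatrix* — accepted ortholog alignments are concatenated (gaps
   for missing species), an NJ tree is built on pairwise-deletion
   distances, with site-bootstrap percentages and *branch-support
   percentages* (fraction of individual ortholog trees, restricted to
   their species subset, containing each internal split; a tree counts
   only when both restricted sides keep ≥ 2 species).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `e_value_start` / `e_value_end` | 1e-10 / 1e-100 | threshold ladder bounds, ten cycles at one decade × 10 per step |
| `hgt_p_threshold` | 0.005 | chi-square P below which a gene is an HGT candidate |
| `paralog_count_limit` | 3 | per-species member count at which a candidate skips the tree stage |
| `min_species_per_group` | 2 | species each group must contribute for acceptance |
| `clustering_mode` | `single_linkage` | or `markov` (built-in MCL, inflation 1.5) |
| `bootstrap_replicates` | 100 | site-resampling replicates for the concatenated tree |
| `seed` | 0 | drives in-paralog selection and all simulation draws |

## Numerical and design choices

- **Similarity scoring.** `score_pair` is exact Smith–Waterman
  (Biopython's C aligner). `all_vs_all` uses a vectorized *gapless* local
  score (maximal-scoring subsegment of the position-wise BLOSUM62
  profile) whenever all sequences share one length — exactly the regime
  the no-indel simulator produces, where the gapless local optimum equals
  the gapped one. The two paths are asserted equal on indel-free families
  in the test suite.
- **Distances.** Poisson correction d = −ln(1 − p) on the mismatch
  proportion over mutually ungapped sites, clamped at p ≥ 0.95
  (d = −ln 0.05) with a saturation warning; a species pair with zero
  comparable sites is an error. Chosen over heavier corrections because
  it is the exact inverse of the no-indel simulation regime at small
  distances and keeps the estimator monotone at large ones.
- **Neighbor joining.** Saitou–Nei with negative branch lengths clamped
  to zero; deterministic tie-breaks (first minimal Q entry, stable leaf
  order). Exact on additive matrices (property-tested, and cross-checked
  against an independent implementation).
- **Rooting polyphyletic trees.** When no branch cleanly separates the
  groups, the root goes to the branch whose bipartition misplaces the
  fewest leaves (ties: longest branch, then smallest leaf id). This makes
  runs reproducible; the subsequent monophyly test and splitting do the
  actual filtering.
- **Tree splitting.** Since a qualifying component must already be
  monophyletic at the requested level, a single successful cut suffices;
  the search is longest-branch-first with deterministic tie-breaks, and
  exhaustion returns the input tree unchanged.
- **Out-paralog filter scope.** Default removes only the offending hit
  from the query's list (`edge`); `global` removal of the flagged gene
  everywhere is available but can delete genuine orthologs of other
  families, and a single `global` pass can change another query's best
  other-group E-value, so only the `edge` scope is idempotent.
- **MCL details.** Edge weights −log10(E) floored at E = 1e-180;
  self-loops at the maximal incident weight; inflation 1.5; convergence
  at max column change < 1e-6 or 200 iterations (warning on
  non-convergence).
- **HGT screen.** The composition test is a deliberately simple stand-in
  exposing the standard interface (chi-square, adjustable P, default
  0.005) for the Bayesian composition classifiers used for this purpose:
  codon (k = 3, configurable) frequencies pooled per species with
  pseudocount 1, cells with expected count < 1 pooled, leave-one-out
  training when a genome has ≥ 20 usable genes. Its empirical
  false-positive rate on model-drawn genes is consistent with the nominal
  threshold (test suite, 1000 replicates). It is *not* a phylogenetic
  HGT detector.

## The simulator

`orthosift.simulate` generates the three validation regimes on a balanced
binary model tree (default 32 OTUs, every branch 0.04 substitutions/site,
families of 200 residues, groups = the two root clades):

- **gene loss after duplication** — the model tree is duplicated at a new
  root (copy-to-copy distance 0.02–0.08); per family an exact
  round(loss × n) of the 64 leaves is deleted uniformly;
- **horizontal transfer** — per family, k ~ Poisson(mean) events; each
  event picks a time uniform over the tree height and moves a uniformly
  chosen recipient lineage onto a distinct contemporaneous donor lineage
  (subtree prune and regraft at equal times), preserving the leaf set and
  the molecular clock;
- **saturation** — the plain model tree with every branch on a
  0.02–0.24 grid.

Sequences evolve site-independently under the JTT replacement model
(DCMut estimate; root drawn from the stationary frequencies, P(t) = exp(Qt)
per branch). **No indels are generated**, so alignment and trimming are
identity operations in simulations and the algorithmic stages are tested
in isolation from aligner artifacts; no among-site rate variation is
applied. Family identity is stripped by re-keying sequences per species
in shuffled order, so the pipeline receives exactly what a real run
would.

Accuracy is scored per trial as: the concatenated NJ tree contains all
species and has Robinson–Foulds distance 0 to the model tree
(*concatenated-tree accuracy*, % of trials), and per accepted ortholog as
an exact topology match on its species subset (*ortholog-tree accuracy*,
% of trees). A trial with no accepted orthologs counts as inaccurate.

### What passing simulations do and do not show

The generator emulates clock-like, equal-length, indel-free families with
uniform loss and uniform transfer times. Real proteomes add indels,
rate variation across sites and lineages, domain shuffling, unequal gene
lengths and biased loss — so the simulation results bound the
algorithmic behavior of the pipeline, not its end-to-end performance on
real data (where external aligner/trimmer quality also enters).

One consequence is deliberate and worth stating: at the longest grid
branch (0.24/branch, deepest pairwise distance 2.4), the expected JTT
difference proportion is p ≈ 0.81 — well below both the distance clamp
(0.95) and the JTT saturation plateau (p∞ ≈ 0.94). Indel-free
supermatrices of a few thousand sites therefore still carry enough
signal, and the concatenated tree is typically recovered even there;
workflows whose aligners introduce and trim indels, or whose distance
corrections diverge near p ≈ 0.85, lose the topology at such depths.
The `run_experiment` harness reports whatever the measurement yields.

Problem sizes used by `scripts/acceptance.py`: 20 families per trial,
20 trials for the single-condition regimes and 10 trials per grid point,
which keeps every regime's expected outcome scale-free while a full run
completes in a few minutes.

## Known limitations

- The built-in search is O(n²) exact scoring with no heuristic indexing;
  genome-scale inputs should supply precomputed BLAST tabular hits.
- NJ gene trees inherit long-branch attraction; affected orthologs can
  enter the data set.
- The composition HGT screen detects only compositionally deviant
  transfers (recent, between compositionally distinct donors).
- Only protein-level simulation is provided; the HGT screen is tested on
  separate codon-composition fixtures.
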