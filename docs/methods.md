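# Methods

This note records the models, algorithms, defaults and design decisions
behind `cogevo`, in the order the pipeline runs them.

## Substitution model

Proteins evolve under a reversible 20-state Markov model defined by a
symmetric exchangeability matrix `S` and equilibrium frequencies `π`:
`Q_ij = S_ij·π_j` off the diagonal, rows summing to zero, scaled so one
unit of branch length equals one expected substitution per site.  The
packaged exchangeabilities and default frequencies are the published WAG
values (Whelan & Goldman 2001).  "+F" replaces the published frequencies
with frequencies counted from the (gap-filtered) alignment, floored at
1e-6 and renormalised, and rescales `Q` accordingly.  Transition matrices
`P(t) = exp(Qt)` come from a single symmetric eigendecomposition of
`D^{1/2} Q D^{-1/2}` (`D = diag(π)`), which is stable and cheap to
re-evaluate at many branch lengths; entries are clipped at zero and rows
renormalised to absorb rounding.  Rates are uniform across sites — no
gamma heterogeneity — matching the modelling choice the pipeline
reproduces.

## Synthetic data

The generator exists to produce inputs with *known* answers; its defaults
are the study conditions the analyses assume.

* **Taxonomy.** Five reference categories (Proteobacteria, other bacteria,
  thermophilic/halophilic/other archaea).  The category partition drives
  everything downstream; organism names are decorative.
* **Species tree.** A fixed backbone `((PROTEO, OTHER_BACT), (THERMO,
  (HALO, OTHER_ARCH)))` with 0.4-substitutions/site edges joins pure-birth
  within-category clades, guaranteeing the clade-respecting structure that
  sister-clade attribution assumes.  Within-clade branch lengths are
  uniform on [0.5, 2] × 0.08 subs/site rather than exponential: the random
  join order still gives the Yule topology, while bounded lengths keep the
  median pendant length stable so that planted NC versus donor-clade
  attachments are unambiguous relative to the median-pendant NC cutoff
  used by the classifier.
* **Gene trees.** Each focal allele attaches on an edge chosen uniformly
  among the edges strictly inside its planted donor clade, with a pendant
  branch uniform on [0.02, 0.12].  NC ("no cluster") alleles attach on an
  arbitrary edge with a pendant of 8 × the median pendant length —
  comfortably past the 5 × classification cutoff, so NC ground truth is
  unambiguous by construction.  Multiple alleles per COG attach
  sequentially and independently.
* **Sequences.** One root sequence is drawn from π and evolved
  site-independently down the tree via `P(t)`.  A configurable fraction of
  columns (default 5 % in the pipeline) is masked with `-` in a random
  ~30 % subset of members, at least one per masked column.
* **Genomes.** IID bases at a target GC; gene intervals drawn from a
  length range and placed without overlap, slack distributed multinomially
  over the intergenic gaps.  1-based inclusive coordinates with strand.
* **Batch cultures.** A two-substrate Euler-integrated model (inner step
  ≤ 0.02 h): growth is Monod in both the nitrogen source (monosodium
  glutamate) and total sugars; glucose and sucrose are consumed in
  parallel during growth, proportional to availability.  When glutamate is
  depleted, growth stops and PHB synthesis switches on, drawing on glucose
  while it exceeds a repression threshold (default 1 g/L) and only then on
  sucrose — reproducing the observed sucrose plateau during the early PHB
  phase.  Defaults (15 g/L sucrose, 10 g/L glucose, 2 g/L glutamate,
  0.2 g/L inoculum, μmax 0.45 h⁻¹, yields 2.2 gX/gN, 0.45 gX/gS,
  0.35 gP/gS, specific PHB rate 0.045 gP/gX/h) emulate a shake-flask PHB
  production run on a 1.5 %/1 % (w/v) sucrose/glucose medium; they were
  chosen once for qualitative realism, not fitted to data.  CDW is defined
  as RCM + PHB, so that conservation holds identically even when
  observation noise (lognormal, default off) is applied to RCM and PHB.

What the generator does **not** emulate: indel evolution (gaps are column
masks, not evolutionary events), rate heterogeneity across sites or
lineages, compositional heterogeneity, gene duplication/loss, codon
structure, operon structure, and real COG orthology noise.  Passing the
recovery tests therefore shows the pipeline is correct and well-calibrated
*under its own model assumptions*; it does not certify accuracy on real
alignments, where model misspecification dominates.

## Tree inference

1. **Complete deletion.** Any column with `-` or `?` in any member is
   removed; an alignment losing all its columns is a hard, named error.
2. **+F frequencies** from the filtered alignment.
3. **ML pairwise distances.** `argmax_{t∈[0,10]} Σ_sites log(π_x
   P(t)_{xy})` by bounded Brent (xatol 1e-8) on the 20×20 site-pattern
   count matrix; identical sequences short-circuit to 0; an optimum at the
   bound sets a saturation flag.
4. **Neighbor joining** with the standard Q-criterion; ties break on the
   smallest (i, j) index pair, negative branch-length estimates clamp to
   zero; the final three lineages resolve by the three-point formulas.
5. **NNI hill climb.** For every internal edge of the binary tree, the
   current and both swapped quartet arrangements are scored with the five
   local branch lengths re-optimised by coordinate-wise bounded scalar
   search (bracket [1e-9, 10], two passes), using cached directional
   partial likelihoods so each evaluation costs four small matrix
   products.  Strict improvements are applied immediately; a sweep with no
   topology change ends the search (default one sweep in the pipeline —
   on simulated 30-taxon, 300-site alignments the NJ topology is already
   close, and one sweep recovers category-level structure at a third of
   the cost of running to convergence).  Per-site scaling protects the
   pruning likelihood from underflow; the likelihood is root-invariant
   under reversibility, which the tests check to 1e-9.

## Donor attribution

Locate the focal pendant edge; among the subtrees adjacent to its
attachment node, the sister group is the one with the smallest mean path
distance to the focal leaf (other focal alleles are never candidates, so
paralogs cannot vote for their own category).  The neighbour set is the
sister group's k = 10 nearest leaves.  Purity ≥ τ = 0.75 gives that
category's code; otherwise all categories with share ≥ 0.25 join an
alphabetical combination code.  If the nearest neighbour is farther than
δ = 5 × the tree's median pendant branch length, NC overrides everything.
All three thresholds are exposed in `AssignmentParams` and the pipeline
config.  Summary classes: P → vertical; B and purely bacterial
combinations → other-bacteria HGT; T/HA/A and archaeal combinations →
archaeal HGT; mixed combinations follow the larger summed share, ties to
other-bacteria; NC → no cluster.

These defaults are this package's operationalisation of what is usually a
visual judgement; they are deliberately conservative and config-exposed
rather than claimed to match any particular published hand-annotation.

## Supernetworks

Splits are harvested per internal edge (weight = branch length; pendant
splits excluded by default); identical splits merge with summed weights
and accumulated tree support.  The Z-closure extension rule — for partial
splits `A1|B1`, `A2|B2` with `A1∩A2 ≠ ∅`, `B1∩B2 ≠ ∅`, `A1∩B2 = ∅`,
replace the pair with `A1|(B1∪B2)` and `(A1∪A2)|B2` — is applied over all
ordered pairs in a deterministic canonical sweep until a fixpoint
(capped at 10,000 passes).  The rule is not confluent in general: different
processing orders can reach different fixpoints.  The deterministic sweep
makes this package's output reproducible, and the tests verify that the
result is one of the exhaustively enumerable fixpoints on small cases and
always contains an extension of every input split.  Support filtering
(`min_trees`, default 1 = unfiltered) retains splits seen in at least that
many trees, with the mean of contributing weights.  Two full splits are
incompatible iff all four side intersections are non-empty; the
incompatible-pair count is the reticulation diagnostic, and a compatible
full system round-trips to the unique tree realising it.  Output is a
NEXUS TAXA + SPLITS file for standard split-network viewers; layout is
deliberately out of scope.

In the pipeline the focal organism's allele leaf is relabelled to a single
shared taxon name (extra paralog leaves pruned) before harvesting, since
the focal organism is one taxon across gene trees.

## Genome statistics and composition screen

GC is 100·(G+C)/(A+C+G+T) with N excluded from the denominator.  "Length
occupied by genes" is the length of the union of gene intervals (overlaps
merged, strand ignored) — a coverage notion, so gene + intergenic length
equals the chromosome exactly, by construction.  Coordinates are 1-based
inclusive everywhere.  Percentages are rounded half-away-from-zero to two
decimals only at the presentation layer.

The composition screen counts D+E as acidic and K+R+H as basic (the
textbook charged set; a switch restricts to K+R for sensitivity), over all
standard residues after stripping gap/missing symbols.  The
acidic-to-basic ratio is reported at one decimal; a zero basic count flags
the ratio undefined instead of raising.

## Cultivation metrics

RCM = CDW − PHB pointwise; PHB content (wt%) = 100·PHB/CDW; volumetric
productivity divides the maximum PHB concentration by the elapsed time
from the first sample to the sample achieving it.  Published productivity
figures rarely state the elapsed time they divide by, so the denominator
convention is explicit and switchable (`max` | `end`); no smoothing or
interpolation is applied to the sampled series.

## Problem sizes and determinism

The acceptance-scale run uses 160 single-allele COGs over 30 reference
taxa (6 per category) at 300 sites with 5 % gapped columns — large enough
that planted fractions of 0.44/0.34/0.13/0.09 are recoverable within
±0.08 multinomial noise, small enough to run in minutes on one core.  All
randomness descends from explicit per-call seeds (numpy `default_rng`); a
pipeline run is reproducible to identical artifact checksums from its
config, and no function touches global random state.
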