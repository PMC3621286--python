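# Methods

## Problem and model

The pipeline decides, per market sample, whether the DNA of the product
matches its commercial label. Identification rests on two mitochondrial
fragments — a 358-bp cytochrome *b* fragment and a ~650-bp COI barcode —
compared against a curated, pre-aligned reference set with species labels.
Multiple-alignment construction is treated as reference curation, i.e. as
an input: queries are mapped into the reference coordinate frame by global
pairwise alignment against the reference consensus (match +1, mismatch −1,
gap −2, end gaps free). Reference columns not covered by a short fragment
are filled with `N`; internal deletions become `-`; insertions relative to
the reference have no column and are dropped. A query under 50% identity to
the consensus is flagged as a possible non-homolog. Coordinates are 0-based,
IUPAC ambiguity codes are preserved and never silently resolved.

### Distances

All distances are Kimura 2-parameter:
`d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)` with transition proportion *P* and
transversion proportion *Q* computed over the pair's usable sites. Pairwise
deletion is the default (a site is usable when both residues are
unambiguous bases); partial deletion at a column-coverage threshold of 0.95
is available for tree building. Saturation (a non-positive log argument) is
an error, never a clamp. Within-species summaries first collapse haplotypes
— sequences equal at every mutually unambiguous site count once — and
within-species means/maxima and the net between-groups distance
`d_net = d̄_AB − (d̄_A + d̄_B)/2` are computed over the collapsed sets. A
species with one sequence reports "not available"; one with several
sequences but a single haplotype reports a maximum of 0. Standard errors
come from resampling alignment columns with replacement (default B = 1000)
and recomputing the statistic, haplotype collapse included. Whether the
original survey used pairwise or complete deletion for its within-species
maxima is not recoverable; pairwise is used here.

The barcode-gap screen flags, per species and on the ×100 scale:
`within_ok` (max within < 1.5), `between_ok` (d_net to the sister species
> 2.5), `hebert_ok` (max within < 3), `fold_ok` (d_net ≥ 10 × mean within),
and `overlap` (max within ≥ d_net, a reportable state rather than an
error). The sister map is an input (from a curated phylogeny) or defaults
to each species' nearest neighbor by d_net.

### Trees

Neighbor joining is implemented directly so its determinism is specifiable:
tied Q-criterion minima break by the lexicographic pair of cluster names (a
cluster is named by its smallest member tip) and negative branch lengths
clamp to zero. Maximum likelihood uses the K80 rate matrix with equal base
frequencies and uniform rates among sites; the likelihood is computed by
pruning with site-pattern compression, ambiguity codes as partial
likelihood vectors and gaps/N as uninformative. κ (the
transition/transversion rate ratio) is estimated by a grid over [1, 20] at
0.5 steps plus bounded refinement; the search starts from the NJ tree
(standard practice; the original analysis does not name its start tree) and
hill-climbs over nearest-neighbor interchanges with per-branch Brent
re-optimization (tolerance 1e-6), accepting only log-likelihood gains above
1e-8 in a fixed neighbor order, so the local optimum is reproducible.
Bootstrap support is the fraction of column-resampled replicates
reproducing each split of the full-data tree; the consensus writer can
collapse splits below 50%. Monophyly is a bipartition test on the unrooted
tree; "high support" is quantified as ≥ 70% (configurable), since the
source analysis never defines it numerically.

### Diagnostic characters

The character-based classifier learns, per species class, columns where a
base is fixed within the class (columns with any in-class gap are
ineligible) and absent from every other class. If no single column is
diagnostic, a conjunction of fixed columns is grown greedily (default limit
3 literals), maximizing out-of-class exclusion; classes with no sound rule
are reported undiagnosable rather than forced. Every emitted rule has
purity 1.0 and specificity 0.0 on the training data by construction, and a
small-instance exhaustive enumerator of all sound ≤2-literal conjunctions
anchors the greedy learner in tests. The published classifier's internal
learning algorithm is proprietary to its own publication lineage; this
transparent learner reproduces the observable behaviors that matter here —
full-efficiency classes, unassigned elements, misclassified training
entries, and non-exclusion on ambiguity — without reverse-engineering
external software. Classification is deterministic and rule-order
invariant: exactly one exactly-matching species ⇒ assigned; no exact match
but exactly one ambiguity-compatible species ⇒ non-excluded (the forensic
outcome — an ambiguous base cannot positively assign, but cannot rule the
species out); anything else ⇒ unassigned. A 4:1 reference-to-test ratio is
encoded as an "under-referenced" warning, not a failure.

### Assignment and scoring

Per dissection and marker, the species call is the consensus of the three
tracks. *Validated* requires perfect-or-strong identity (100% / >97%),
monophyly with support ≥ 70, and diagnostic status assigned or
non-excluded. Concordant tracks with a diagnostic ambiguity give
*non-excluded* with the species retained. On disagreement the similarity
leader wins at *similarity_only* confidence (the original survey resolved
disagreements narratively per taxon; a mechanical tie-break is this
package's choice). Nothing resolving gives *unidentified*. On a shared tree
containing many queries, the monophyly evidence for a query is the
best-supported split side containing the species' references plus the query
and no other species' reference — co-queries may sit inside the cluster,
and the species-versus-rest bipartition carries the support, not unstable
within-species subclades.

A sample is *correct* iff every assignment matches the label species,
*false* if any resolved assignment contradicts it, *unresolved* otherwise;
two or more species across dissections flag a mixture, and false samples
are classed as domestic/alien or other-wild substitutions. Substitution
tables report counts and percentages at two precisions (two decimals per
stratum, nearest integer for narrative per-label figures, one decimal for
the game-only percentage that excludes the beef stratum), matching the
mixed precision of the published tables. Mixed samples count once in their
label row.

`wildmeat.survey` carries the published per-label and per-product count
tables and expands them into per-sample verdicts by north-west-corner
allocation (both margins hold exactly; 146 samples, 101 false). The
expansion exists because per-sample species identities of the real market
are not recoverable from printed counts; aggregate statistics computed from
the expansion are exact.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
under the same K80 process used for inference (a gamma-site-rates toggle
exists for misspecification experiments only; it is off by default).

* **Species tree**: random topology; every edge `species_tree_depth/2`
  long, so sister species sit `species_tree_depth` apart (default 0.10
  substitutions/site — deep in the barcode gap).
* **Within-species structure**: `n_pop_clusters` (default 2, echoing the
  east/south phylogeographic splits common in African ungulates) cluster
  ancestors at distance *c* from the species ancestor, individuals at
  *w* from their cluster ancestor, with *w* = θ/4 and *c* solved from the
  realized cross-cluster pair fraction so the expected mean pairwise
  within-species distance equals `within_theta` (default 0.01).
* **Markets**: product types drawn at survey-like proportions (biltong
  dominant); sausages carry two dissections; each sample's true species is
  redrawn from the other species with probability `p_sub` (default 0.69,
  the observed survey rate of 101/146) and sausages gain a second species
  with probability `p_mix` (default 0.48 ≈ 15 mixtures among 31 sausages);
  both markers are "sequenced" per dissection and transition-compatible
  IUPAC ambiguities are injected at rate `p_ambig` (default 0.001).
* κ defaults to 4, fragment lengths to 358 (cytb) and 650 (COI).

What the simulator does **not** model: indels (alignments are generated
gap-free), sequencing error beyond ambiguity injection, base-composition
bias, rate variation among lineages, coalescent demography, and
incomplete lineage sorting or hybridization between species. Passing tests
on synthetic data therefore certify the machinery — distance computation,
tree reconstruction, rule learning, scoring arithmetic — not robustness to
those real-data pathologies; the barcode-gap screen exists precisely
because real African ungulates (recent speciation in wildebeest,
bontebok/blesbok, kudu phylogeography) violate the clean-gap assumption.

## Numerical and design choices

* Bootstrap and simulation RNG: explicit seeds throughout (default 1);
  same seed ⇒ bit-identical databases, markets, supports and reports.
* Branch lengths bounded to [1e-9, 5] substitutions/site during
  optimization; κ grid [1, 20].
* Internal distances in substitutions/site; the ×100 scale appears only in
  reports.
* Degenerate inputs: empty overlaps raise (no silent NaNs); saturated pairs
  raise; all-ambiguous queries are rejected by the similarity ranking; an
  unalignable query maps to an all-N row with a non-homolog warning.
* Test problem sizes: tree-engine oracles use 5 taxa × 600 sites (where
  exhaustive topology search is feasible); substitution-rate recovery uses
  100 markets of 200 samples at p_sub ∈ {0.2, 0.5, 0.76}, checked against
  the exact binomial 95% interval; the acceptance script uses 50 markets at
  p_sub = 0.5. These sizes make the suite run in minutes while keeping
  every check statistically meaningful.
* The recovery harness runs the similarity + diagnostics tracks without
  per-market trees: the recovered quantity is the substitution fraction,
  which those tracks determine; per-market bootstrapped phylogenies would
  add cost but no information to that estimate.

## Known limitations

* NJ is O(n³) in pure Python and the shared bootstrap tree is NJ-based;
  very large reference-plus-query sets (thousands of tips) would need a
  compiled implementation.
* The ML search explores NNI neighborhoods only; for heavily conflicting
  signal an SPR-capable searcher would escape more local optima.
* The similarity track has no e-value model — appropriate at reference-set
  scale, not for genome-scale databases.
* Subspecies are distinct classes only if the references label them so;
  classes the diagnostics cannot separate should be merged by the caller
  (e.g. certifying wildebeest at genus level).
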