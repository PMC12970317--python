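# Methods

`otudelim` turns a single-locus barcode alignment (COI-style, ~600 bp) plus
specimen metadata into a table of species hypotheses. The procedure chains
four models, each exposed as its own module so every stage can be tested
against an independent oracle.

## Kimura two-parameter distances (`distances`)

All downstream stages consume pairwise K2P distances,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

with P and Q the observed transition and transversion proportions. Columns
containing a gap, `N` or any ambiguity code in either sequence are excluded
per pair (*pairwise deletion*), the usual convention for mixed-provenance
barcode compilations; a `complete-deletion` switch was deliberately not
added because barcode fragments from public databases rarely share a common
coverage window. Distances are stored as proportions (substitutions/site)
and converted to percent only in reports.

Pairs whose divergence saturates the logarithms are flagged and assigned a
connectivity cap (default 1.0 subs/site) so the matrix stays finite; capped
pairs take part in clustering but never in barcode-gap statistics.

## Guide tree (`genetree`)

PTP and the reconciliation layer need a rooted tree. An externally built ML
tree (newick) is preferred when supplied. The built-in default is
Saitou–Nei neighbor joining on the K2P matrix, with the Q-criterion
minimiser and ties broken by the smallest index pair so runs are exactly
reproducible; negative branch-length estimates are clamped to zero and
counted. On additive matrices NJ reproduces the generating path lengths to
numerical precision, which the tests verify. Rooting is at the midpoint of
the longest leaf-to-leaf path — the rooting used when none is stated with
an external tree.

## Barcode-gap partitioner (`gap_partition`)

A deterministic, fully specified stand-in for ASAP-style gap partitioning:

1. candidate thresholds are the midpoints between consecutive distinct
   pairwise distances;
2. at each threshold, OTUs are single-linkage clusters (connected
   components of the graph joining pairs with d ≤ t), which makes
   partitions nest monotonically in t;
3. each candidate partition is scored by its *relative barcode gap*,
   `(min between-OTU d − max within-OTU d) / t`, rewarding wide gaps low in
   the distance distribution;
4. recursive refinement: an OTU whose internal distances show a stronger
   relative gap than its parent partition contributes the refined partition
   as an extra candidate (scored globally like any other);
5. a gap narrower than `min_gap` (default 0.003 subs/site, about two
   substitutions on a 615 bp marker) is treated as quantization noise
   between discrete distance values, not a barcode gap. If no candidate
   clears it, the result carries a `no_barcode_gap` flag.

This scoring is intentionally simpler than ASAP's composite probability
rank; it preserves the barcode-gap principle and is exactly testable, but
it will not byte-match the ASAP web service in edge cases.

## Poisson tree processes (`ptp`)

PTP classifies every branch of the rooted gene tree as *speciation*
(between species) or *coalescent* (within species), each class exponential
with its own rate. A delimitation is a rooted ancestral set S of internal
"speciation" nodes; species are the maximal subtrees hanging below S. Rates
are profiled analytically (λ̂ = 1/mean class branch length), so each state
has the closed-form log-likelihood Σ_class (n ln(n/Σb) − n). Numerical
guards:

- branches ≤ `min_branch` (1e-4 subs/site) are excluded from the likelihood
  — the same guard multi-rate PTP tools apply — because a class of
  near-zero branches (identical sequences) otherwise has unbounded
  likelihood and the argmax shatters clusters into singletons;
- zero-length terminal branches are perturbed to 1e-9 before any
  likelihood, since the exponential density is undefined at zero mean;
- the two-class model carries one more parameter than the single-rate
  null, so `ptp_ml_search` only accepts a multi-species partition when it
  beats the null by more than `null_penalty` (default 1.0 log-units, the
  AIC margin). On a lone coalescent cluster this returns one species;
  oracle comparisons in the tests disable the margin.

The ML search enumerates all valid S exhaustively up to 12 leaves
(verified against an independent brute-force enumeration) and hill-climbs
with single-node flips from 16 seeded random starts above that. The
Bayesian variant runs a Metropolis sampler over S (symmetric single-flip
proposals, uniform prior; default 500,000 generations, thinning 100, 10%
burn-in) and reports the best partition encountered, the posterior
mean/mode species count, per-OTU support, and the acceptance rate with a
non-mixing warning outside [1%, 99%]. On flat likelihood surfaces the
posterior is intentionally diffuse — with a uniform prior the many
multi-species states absorb mass, the overprediction barcoding studies
consistently report for this method class; the ML search with its null
margin is the robust point estimate.

## Reconciliation (`reconcile`)

The integrative layer mirrors how practitioners combine two single-locus
delimiters with geography and vouchered morphology:

- OTUs with identical membership in both partitions are **congruent** and
  pass through.
- Disagreements form conflict blocks (components of the overlap graph of
  non-identical OTUs). Within a block the finer partition supplies
  candidate sub-OTUs; sister pairs are read off the guide tree most recent
  first and decided by, in order:
  1. morphology overrides (`distinct` keeps, `conspecific` merges) —
     matched by representative specimens so overrides survive earlier
     merges;
  2. `t_negligible` (default 1%): near-identical sister OTUs are delimiter
     noise and merge regardless of geography;
  3. sympatry: sister OTUs sharing a biogeographic region are retained
     (`retained_sympatric`) — co-occurrence without interbreeding is the
     only observable evidence of isolation at one locus;
  4. allopatric pairs merge below `t_strong` (default 5.5% K2P,
     `merged_allopatric` + `tentative`) and are retained at or above it
     (`strong_divergence_retained`);
  5. pairs with unknown geography are kept but flagged `tentative`.
  Merging repeats until no rule applies. When interleaved non-monophyletic
  sub-OTUs leave no clean sister pair, evaluation falls back to the
  nearest pair by K2P (logged).
- `t_strong = 0.055` sits midway between the largest allopatric divergence
  merged in comparable curation work (~5.5%) and the smallest retained
  (~5.7%); it is a config knob, and merges under it are always flagged
  tentative. Raising `t_strong` can only lower the final species count.
- Naming: an OTU containing type-locality specimens of exactly one label
  takes that name; otherwise the plurality label; ties stay `unassigned`.
  OTUs mixing labels, and labels scattered over several OTUs, are flagged
  `name_incongruent` (both directions detailed in the table's name
  report) — public-database misidentification is the rule, not the
  exception, in barcode compilations.

The output always partitions the input specimens; this is asserted on
every run.

## Synthetic data (`synthdata`)

The generator produces datasets whose truth is known, emulating a curated
barcode compilation: a Yule species tree rescaled to root depth `mu`
(default 0.06 subs/site, i.e. up to ~12% between-species K2P, inside the
1–15% window typical of congeneric fish barcodes); within-species subtrees
of depth `pop_scale × mu` (default 0.05) grafted at the tips; sequences
evolved under K80 with κ = 4 — model-matched to the K2P estimator so
estimator consistency is itself a test; one region per species from the
eight-province vocabulary with sister species sympatric with probability
0.5; 5% of non-type specimens mislabeled with another species' name. One
specimen per species is marked as a type-locality sample and never
mislabeled.

Species-tree draws are resampled until the youngest split is at least
`min_split_frac` (default 0.5) of the depth. With `pop_scale = 0.05` this
pins the within/between depth ratio at ≤ 0.1 — the separable regime the
recovery experiments assume. Without the floor, a Yule draw can place two
species arbitrarily close, where no single-locus method can separate them;
lowering `min_split_frac` is the supported way to study that failure mode.

What the generator does **not** emulate: indels and alignment error,
among-site rate variation, base-composition bias, gene flow/introgression,
geographically structured sampling within species, and real ASAP/bPTP web
services. Passing recovery tests therefore demonstrate correctness of the
pipeline's logic in its intended regime, not field performance on real
COI compilations.

Recovery is scored with the adjusted Rand index (chance-corrected
partition agreement) plus split/merge error counts against the true
partition.

## Problem sizes and determinism

The shipped experiments use desk-scale sizes chosen to make every check
exhaustive or repeatable: 5 species × 6 specimens × 615 bp for recovery
(100 replicates), ≤ 12-leaf trees for exhaustive PTP verification, 4–10
taxon additive matrices for NJ exactness. All randomness flows from one
master seed expanded per stage (`pipeline.stage_seed`); identical seeds
give byte-identical artifacts.

## Known limitations

- The gap partitioner is a documented simplification of ASAP; on real
  data its best partition can differ from the web service's.
- PTP here is single-locus and two-rate; no multi-rate extension, no
  GMYC/BPP.
- Sister-pair logic depends on the guide tree; with many identical
  sequences NJ topology among them is arbitrary and the nearest-pair
  fallback takes over.
- The sympatry predicate is a discrete region overlap; no range modeling.
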