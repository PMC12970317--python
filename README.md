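# otudelim

Single-locus DNA-barcode species delimitation with integrative
reconciliation.

Taxonomists compiling COI barcode libraries for species-rich marine groups
face a recurring problem: morphospecies labels on public sequences are
unreliable, single-locus delimiters disagree with each other, and the
decision of whether two clusters are one species or two depends on
evidence — geography, divergence, type material — that no single algorithm
sees. `otudelim` packages that whole workflow as a tested library and CLI:

1. **K2P distances** — pairwise Kimura two-parameter distances
   (`d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`, transitions P, transversions Q,
   pairwise deletion of gaps/ambiguities);
2. **guide tree** — neighbor joining + midpoint rooting, or your own ML
   tree in newick;
3. **two independent delimiters** — a barcode-gap partitioner (threshold
   sweep, single-linkage clustering, relative-gap ranking with recursive
   refinement, in the spirit of ASAP) and a Poisson-tree-processes model
   (ML search over speciation/coalescent branch classes, with a Bayesian
   MCMC variant reporting per-OTU posterior support);
4. **reconciliation** — congruent OTUs pass through; conflicts are
   resolved sister pair by sister pair on the guide tree: near-identical
   OTUs merge, sympatric sisters are retained, allopatric sisters merge
   unless their divergence exceeds a strong-evidence threshold (default
   5.5% K2P), optional per-pair morphology overrides take precedence.
   Names are assigned from type-locality specimens when possible, and
   label/cluster mismatches are flagged as probable misidentifications;
5. **synthetic data** — a coalescent-style generator (Yule species tree,
   grafted within-species subtrees, K80 sequences, region assignments,
   label noise) with known truth, so the whole pipeline is verifiable
   offline.

## Worked example

Simulate a 5-species dataset (30 specimens, 615 bp) and run the full
pipeline:

```bash
delim simulate --seed 7 --out demo/sim
delim run --fasta demo/sim/simulated.fasta --meta demo/sim/simulated.tsv \
          --seed 7 --out demo/run
```

The run report printed at the end:

```json
{
 "n_specimens": 30,
 "alignment_length": 615,
 "otu_counts": {"gap_best": 5, "gap_at_t_low": 5, "ptp_ml": 5},
 "final_species_count": 5,
 "flag_tallies": {"congruent": 5}
}
```

Both delimiters found the same 5 OTUs (`gap_best`, `ptp_ml`), the 3%
fixed-threshold partition agrees (`gap_at_t_low`), so all five hypotheses
are flagged `congruent` and the final count matches the simulated truth.
`demo/run/species_hypotheses.tsv` holds the per-species detail; the first
row

```text
otu_id  n_members  labels           regions  flags      assigned_name  name_basis     sister_min_pct
OTU001  6          Simulus sp01:6   ECS      congruent  Simulus sp01   type_locality  6.1279
```

reads: six specimens, all labeled `Simulus sp01`, occurring in the East
China Sea region, supported by both delimiters, named via a type-locality
specimen, and 6.13% K2P from the nearest other species.

The same stages are available as a library (`otudelim.run_all`,
`distance_matrix`, `rank_partitions`, `ptp_ml_search`, `bptp_mcmc`,
`reconcile`, `simulate`) and as separate subcommands
(`delim dist|nj|gap|ptp|reconcile`).

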