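# barcode-associate

Associating the life stages and sexes of insects whose taxonomy rests on
adult males is a long-standing problem: for many aquatic insects (caddisfly
genera are the canonical case) the larvae and females of most species cannot
be identified morphologically. DNA barcoding offers a way out — the 658-bp
mtCOI fragment usually shows low intraspecific and high interspecific
divergence (the *barcoding gap*), so an unidentified larva or female can be
matched to the species of an identified adult male by sequence similarity
and tree placement.

`barcode-associate` implements that workflow end to end for aligned mtCOI
datasets:

- **Sequence QC** — minimum ungapped length filter (default 325 sites) and
  automated reading-frame checks (stop codons, frame shifts) under the
  invertebrate mitochondrial code.
- **Divergence** — raw p-distances and Kimura 2-parameter distances
  `d = −½ ln[(1 − 2P − Q)·√(1 − 2Q)]` under *pairwise deletion* of gaps,
  Ns and ambiguity codes, with per-species-pair min/max summary tables and
  barcoding-gap verdicts.
- **Trees** — deterministic Saitou–Nei neighbor-joining with Felsenstein
  (column-resampling) bootstrap, and maximum likelihood under JC / K2P /
  HKY / TIM2 (+G4 discrete-gamma, 4 categories) via Felsenstein pruning,
  NJ-start branch-length optimization and greedy NNI search, with
  AIC/AICc/BIC model comparison.
- **Association** — the explicit three-rule criterion: R1, the unknown's
  sequence is identical to a confirmed male's (pairwise distance zero);
  R2, it is nested among near-identical male sequences of one species
  (default threshold 0.02, the conventional 2% COI species boundary);
  R3, it is nested in a bootstrap-supported monophyletic group of one
  species on **both** the NJ and ML trees. Conflicts and tree discordance
  yield `ambiguous`, and residual unknowns are grouped into lettered
  ambiguity clades (A, B, C, …) — candidate cryptic or unsampled species.
- **Two-tier design** — the rule cascade runs on the pooled dataset, then
  on per-region (east/west) datasets filtered to the species that gained
  associations; an association is final only when both tiers agree.
- **Synthetic data** — a seed-deterministic generator that evolves
  specimen-level alignments along planted species trees (exact transition
  matrices, configurable ts/tv ratio and gamma heterogeneity) with mixed
  life stages, unknown labeling, truncated fragments, and scenario plants:
  a clean barcoding gap, a cryptic species with 4–5% intraspecific
  divergence, and a species pair with no gap where one is nested inside the
  other.

## Worked example

Generate a clean-gap dataset (10 species × 5 specimens, 658 bp, 20% of
larvae/females unlabeled) and run the full two-tier pipeline:

```bash
barcode-associate simulate --scenario clean_gap --n-species 10 \
    --specimens 5,5 --fraction-unknown 0.2 --seed 42 --out-dir sim
barcode-associate associate sim/simulated.fasta sim/simulated.tsv \
    --nj-bootstrap 100 --seed 7 --out-dir run
```

which prints

```
wrote 50 records (5 unknowns) to sim
5 unknowns: 5 associated, 0 ambiguous
```

`run/associations.tsv` then lists one verdict per unknown, e.g.

```
specimen_id  status      species  rule                     tier
sp01-04      associated  sp01     R3_monophyly_both_trees  east
sp02-04      associated  sp02     R2_near_identical_nest   west
```

Here `sp02-04` sat within 2% of conspecific males only (rule R2), while
`sp01-04` was farther from its male but fell inside the species' supported
clade on both trees (rule R3); both verdicts survived the region-filtered
confirmation run. Scoring against the generator's truth table
(`barcode-associate recover …`) reports sensitivity 1.000 and a
false-assignment rate of 0.000 for this run.

The same library surface is available from Python
(`barcode_associate.two_tier_workflow`, `barcode_associate.simulate_dataset`,
…); see the module docstrings.

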