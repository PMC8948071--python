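# Methods

## Problem and data model

The pipeline assigns species names to unidentified larvae and females in an
aligned mtCOI barcode dataset by comparing them with identified adult males
(the reference sex in male-based taxonomies). A dataset is a rectangular
alignment of specimen records, each carrying a species label (or `UNKNOWN`),
a life stage, and a biogeographic region (`east` / `west` / `unassigned`).
Regions come from metadata, not coordinates: the east–west partition of a
fauna is a curatorial decision, so the code treats it as input.

Two length thresholds exist in barcoding practice: a looser inclusion
screen (~300 ungapped sites) applied when assembling candidate material and
a stricter analysis filter. The analysis default here is **325** unambiguous
A/C/G/T sites; both values are configuration, not constants. Ambiguity
codes and N count as missing throughout — for the length filter and for
distances — so the two stages agree on what a "site" is.

Reading-frame QC translates each fragment in all three frames under the
invertebrate mitochondrial code (NCBI table 5), picks the frame minimizing
internal stop codons, and flags (a) records where no frame is stop-free
(typical of uncorrected indels) and (b) records whose best frame, expressed
in alignment coordinates, deviates from the dataset's majority frame.
The per-dataset consensus is used because fragments amplified with
different primer sets legitimately start at different offsets. QC is
advisory; a strict mode drops flagged records.

## Distances

For each sequence pair, sites missing in either member are excluded
(pairwise deletion); over the `n` remaining sites `P` is the transition
and `Q` the transversion proportion. The raw p-distance is `P + Q`; the
Kimura 2-parameter distance is

    d = −½ ln[(1 − 2P − Q) · √(1 − 2Q)]

The reported divergence defaults to K2P with raw p-distance behind a flag:
in barcoding studies the tabulated "p-distances" are routinely computed
under the K2P model, and this package follows the computation rather than
the label. When `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` the distance is undefined
(saturation); such pairs are reported with a reason and never clamped,
because a silently clamped distance would corrupt both the summaries and
the trees. Divergence summaries give per-species-pair min/max ranges; the
barcoding-gap verdict for a species (max intraspecific < min interspecific
to every other species) and the high-intraspecific flag (max intraspecific
above 0.02, the conventional 2% COI species-delineation value) are computed
on unrounded values. Two-decimal rounding is presentation only.

## Neighbor-joining and bootstrap

NJ is the Saitou–Nei agglomeration on the Q-criterion with the standard
branch-length formulas; negative length estimates are clamped to zero
(topology is unaffected; downstream display and monophyly logic need
non-negative lengths). Determinism is part of the contract: taxa are
processed in canonical sorted-ID order and Q-ties break lexicographically
on the cluster-representative pair, so the tree is identical across input
orders and platforms. Because the Q matrix is only symmetric to rounding,
candidate argmin pairs are canonicalized before tie-breaking. On an
additive matrix NJ is exact, and the test suite verifies topology and
distance recovery on random additive matrices.

Bootstrap support resamples alignment columns with replacement, rebuilds
the distance matrix and NJ tree per replicate, and annotates each internal
bipartition of the point-estimate tree with the percentage of replicates
containing it (no consensus tree is built). Replicates that produce an
undefined (saturated or zero-overlap) pair are dropped and counted, with a
warning above 5% — the choice of dropping rather than imputing keeps every
replicate a genuine re-analysis.

## Maximum likelihood

Likelihoods use Felsenstein pruning over unique site patterns with
per-node rescaling. Transition probabilities come from the
eigendecomposition of the reversible rate matrix (symmetrized via
`diag(√π) Q diag(1/√π)`), scaled to mean rate 1 so branch lengths are
expected substitutions per site. Rate heterogeneity is the discrete-gamma
approximation with 4 equal-probability categories and category-mean rates.
Gaps and ambiguities are fully missing leaf states.

The model family is the nested set JC → K2P → HKY → TIM2, with TIM2
realized as GTR constrained by `r_AC = r_AT` and `r_CG = r_GT`
(`r_GT` fixed at 1 for identifiability) over unequal base frequencies.
Base frequencies are empirical counts (with a pseudocount), not
ML-optimized — the common, cheaper, and stable default. Free-parameter
counts for the information criteria are branches (2n − 3) plus 0/1/4/6
substitution parameters plus 1 for the gamma shape; AIC, AICc
(not-applicable when `n − k − 1 ≤ 0`) and BIC use the site count as `n`.
No proportion-invariant term is included.

Branch lengths are optimized coordinate-wise with bounded scalar
minimization (bounds `[1e−6, 10]`, log-likelihood sweep tolerance `1e−4`).
For a single edge the subtree conditional likelihoods on both sides are
computed once, making each trial length a 4×4 contraction — valid for
reversible models, where the root may sit anywhere. Topology search is
greedy best-improvement NNI: both alternatives at every internal edge are
scored with the central branch re-optimized, the best improving move is
accepted and followed by a full branch sweep, until no move improves the
log-likelihood beyond tolerance. This is deliberately a desk-scale search:
its acceptance surface is simulation-based recovery (stable at the true
topology, recovers a one-NNI perturbation, exhaustive on quartets), not
bit-level agreement with large-scale ML packages. ML bootstrap repeats
NJ-start (+NNI) per column-resampled replicate and maps supports onto the
point-estimate tree.

With homogeneous simulated data the fitted gamma shape runs to its upper
bound — the expected degenerate limit; alpha ordering (0.3 < 8) is
recovered when heterogeneity is actually present. At `alpha = 10⁶` the
four category rates still differ from 1 at order `1/√alpha`, so the G4
likelihood approaches the homogeneous one with a residual that grows with
alignment length and divergence; the equivalence checks therefore run at
barcode-scale divergence (658 sites, d ≈ 0.1), where the residual is well
below 1e−6.

## Association rules

References default to identified adult males; a flag admits identified
females. Rules are checked in order per unknown:

- **R1 — identical.** Some reference has distance exactly zero. Zero
  distance to references of two species is a conflict → `ambiguous`.
- **R2 — near-identical nest.** Let S be the references within the
  near-identity threshold (default 0.02; configurable, since
  "near-identical" has no canonical value). Assign iff S is non-empty and
  single-species; mixed S → `ambiguous`.
- **R3 — monophyly on both trees.** In each tree, the smallest bipartition
  side containing the unknown and at least one reference determines the
  candidate species. If both trees agree on a single species, the support
  gate is evaluated on the *largest* side around the unknown whose labeled
  members are purely that species — the species-level clade — rather than
  on an arbitrary minimal subclade, whose support reflects haplotype noise
  inside the species, not the species boundary. The gate (default 50, the
  usual display threshold for bootstrap values) must be met in at least one
  tree; when neither tree carries support annotations (point-estimate
  mode) the gate is waived. Discordant trees block assignment.

Unknowns left unresolved are grouped by the largest unknown-only clades
they share on both trees and lettered A, B, C, … in sorted-ID discovery
order. Groups of two or more are `ambiguous` (a co-located unidentified
lineage); a singleton keeps status `unassociated` but still receives a
letter, since an isolated unknown on its own branch is exactly the
candidate-novel-lineage case worth reporting.

In the two-tier workflow, the cascade runs on the pooled dataset; then
east and west datasets are built containing every specimen of each species
that gained at least one pooled association, plus the unknowns associated
to them, and fully re-analyzed (a filtered tier with fewer than three
species runs distances only and skips trees). The final status of an
unknown is `associated` only when pooled and filtered verdicts name the
same species; a pooled association that dissolves under the filtered run
is downgraded to `ambiguous` with both verdicts in the evidence. By
default the pipeline computes NJ bootstrap supports and an ML point tree
without ML bootstrap (`ml_replicates = 0`): the R3 gate then rests on NJ
supports, which keeps the two-tree concordance requirement while avoiding
an ML bootstrap whose cost grows quickly with taxon count. ML supports can
be switched on where wanted.

## Synthetic data generator

The generator emulates a multi-species barcoding study: a random
ultrametric species tree whose pairwise depths are drawn inside the
configured interspecific range (default 0.03–0.19 substitutions/site, the
envelope observed in published COI divergence tables), per-species
haplotype clouds (default intraspecific depth 0–0.02), 658-site
alignments, a K2P simulation model with ts/tv ratio 5 (a typical COI
value; TIM2-style simulation is available through the model classes),
optional discrete-gamma site rates, uniform life-stage assignment with at
least one male per species guaranteed (the reference-set requirement), and
a configurable fraction of larvae/females stripped of labels (default
0.2). Sequences evolve edge-by-edge by sampling from exact
transition-probability matrices, not approximate per-site thinning, so
distance- and likelihood-recovery tests are unbiased. Default study shape
is ~24 species with 1–10 specimens each; the headline recovery experiment
uses 10 species × 5 specimens at 658 bp with 20% unknowns — large enough
for distinct R2 and R3 associations and east/west filtered tiers, small
enough to re-run routinely.

Scenarios plant known truth: `clean_gap` (all species separated; every
unknown should be recovered with zero false assignments), `cryptic_species`
(one species split into two haplogroups 0.04–0.05 apart with an unknown in
the far group — trips the >2% intraspecific flag while remaining
monophyletic), `nested_pair` (one species' specimens all share the host
male's haplotype, so the intraspecific range is (0, 0), the minimum
interspecific distance is 0, neither species shows a gap, and the host is
paraphyletic; unknowns of the pair must be flagged ambiguous, never
assigned), and `short_fragments` (a subset truncated below the 325-site
filter). Scenario species are guaranteed to contribute at least one
unknown, or the scenario would plant nothing to test.

What passing these tests shows — and does not. The generator produces
gap-free alignments with uniform-ish base composition, no indels, no
sequencing error beyond truncation, and star-shaped intraspecific
variation. Success on it demonstrates the correctness of the distance,
tree, and rule machinery under the model's own assumptions; it does not
demonstrate robustness to alignment error, heterogeneous sampling, or
base-composition bias in real barcoding data.

## Numerical choices and degenerate inputs

- Distance model domain violations raise (scalar API) or are recorded as
  undefined entries (matrix API); NJ refuses matrices with undefined pairs.
- `-0.0` distances from `−½ ln 1` are normalized to `+0.0`.
- Branch-length bounds `[1e−6, 10]`; optimizer keeps the old length when a
  bounded search finds no improvement, so sweeps are monotone.
- Datasets with no variable sites leave the gamma shape unidentifiable; it
  is reported and fixed at 1.0.
- Species with a single specimen have no intraspecific range
  (not-applicable, never zero) and default to a positive gap verdict.
- Bootstrap supports live on the point tree's internal splits only; leaf
  edges carry no support.

## Known limitations

- The ML search is NNI-only from an NJ start; severely misleading starting
  trees could leave it in a local optimum that SPR-based searches escape.
- TIM2 is the richest supported model; the full model-selection space of
  dedicated tools (and codon partitioning) is out of scope.
- The generator does not simulate indels or chromatogram-level error, so
  frame QC is exercised on constructed fixtures rather than simulated data.
- Associations are only as good as the reference males: a misidentified
  male propagates its label, exactly as in the real workflow.
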