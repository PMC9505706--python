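# Methods

## The feature encoding

The pipeline starts at a genus-annotated OTU count table; upstream read
processing (trimming, merging, chimera removal, OTU picking) is out of
scope. Counts of OTUs sharing a genus label are summed (two OTUs with the
same genus label but different upper ranks are rejected — a genus feature
must have one lineage), scaled `log2(count + 1)` and normalised so each
sample's genus vector sums to one (`V_G`). The accumulated feature is

    V_ACC(g) = V_G(g) + Σ_{i=1..5} k_i · V_rank_i(g),   k_i = 10^-(1+i),

with `rank_1..rank_5` = family, order, class, phylum, kingdom and
`V_rank(g)` the per-sample sum of `V_G` over all genera sharing g's label
at that rank, the genus itself included. Each sample is encoded
independently; the result is invariant to row/column order and bounded by
`V_G ≤ V_ACC ≤ V_G + 0.011111` (each clade sum is at most 1).

Numerical choices:

- **Pseudocount.** `log2(count + 1)` maps zeros to exactly zero, avoiding
  `-inf` while keeping the zero-inflation structure visible to the model.
- **Order of operations** is fixed as collapse → log2 → per-sample
  normalisation → accumulation. Normalising raw counts before the log
  would be an alternative reading; the implemented order is the one the
  encoding is defined with here, applied consistently to training and
  external cohorts, which is what transfer scoring requires.
- **Clade sums include the genus itself.** The alternative (exclusive
  sums) differs only by a rank-wise multiple of `V_G` and changes nothing
  qualitative; inclusive sums make the single-genus value an exact
  closed form, `V_ACC = V_G · 1.011111` for a sole genus.
- **Multiple kingdoms** are supported: `V_K` is the per-kingdom sum, not
  necessarily 1.
- The weight schedule is exposed as a parameter; non-default schedules
  are accepted but not validated.

Placeholder genera: an OTU unresolved at genus carries the label
`(<deepest resolved label>)`, e.g. `(Lachnospiraceae)` for a family-level
assignment, and participates in collapsing and accumulation like any
other genus. Bracketed database names (`[Ruminococcus] gnavus group`) are
genuine labels, not placeholders. Two lineage dialects are read (SILVA
`D_k__`, Greengenes `k__`), auto-detected from the first lineage and
overridable; a seventh species field is tolerated and ignored after genus
collapsing.

## Statistics

- **Alpha diversity** (observed taxa, Chao1 `S_obs + F1²/(2·F2)` with the
  `F2 = 0` fallback `S_obs + F1(F1-1)/2`, Shannon with natural log,
  Gini–Simpson `1 - Σp²`) is computed on counts rarefied to a common
  depth — default 1099 reads, the depth floor of the emulated study — by
  a single seeded multivariate-hypergeometric draw per sample (an
  averaged-draw variant is available). Samples below the depth are
  dropped with a warning. The inverse-Simpson variant is available by
  flag; Gini–Simpson is the reported default.
- **Beta diversity** uses Bray–Curtis on relative abundances (no
  rarefaction; collapsing to phylum or genus happens before the
  distance), classical PCoA by eigendecomposition of the double-centred
  `-D²/2` matrix (negative eigenvalues reported, their axes discarded,
  proportions computed over the positive spectrum), and a vectorised
  PERMANOVA with `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` over seeded
  label shuffles (default 999; an exhaustive-enumeration mode exists for
  small designs and exact tests).
- **Differential abundance** offers two designs mirroring common
  practice: clinical two-group comparisons use a t-test whose pooled vs
  Welch variant is gated by a two-sided variance-ratio F test at
  α = 0.05, reported with raw p-values; multi-group animal comparisons
  use Mann–Whitney U (exact enumeration with midrank tie handling when
  both sides have ≤ 8 observations, tie-corrected normal approximation
  otherwise) with Benjamini–Hochberg correction applied per rank × group
  pair. Fold changes are ratios of group mean relative abundances and are
  flagged undefined (NaN, row retained) when the control mean is zero.
- Chi-squared on 2×2 tables is Pearson without continuity correction
  (the correction is a flag); on the 106:186 vs 61:50 case/control sex
  table this reproduces the reported p ≈ 0.001.

## Risk model

A `GradientBoostingRegressor` (least-squares boosting) is fit to 0/1
labels; the continuous output is the risk score. Defaults: 500 stages,
learning rate 0.1, depth-3 trees, no subsampling — unexceptional boosting
settings, all exposed. Feature selection keeps features with nonzero
variance and at least one nonzero value. Evaluation repeats a stratified
70/30 split 30 times (iteration i seeded `base_seed + i`; splits lacking
a class on either side are redrawn with a logged note), recording
test-set AUC (ties get half credit), the ROC curve, and the Youden
operating point — ties in J broken toward the highest threshold, i.e. the
more specific point. Importance comes in two flavours with a method tag:
impurity shares (non-negative, sum to 1) and permutation AUC drop on
held-out data (may be negative). External cohorts are aligned by exact
genus label: model features absent from the cohort are scored as zero
abundance, cohort-only features are dropped, and the coverage fraction is
reported. Scores are compared between external groups by exact MWU with
BH across group pairs; the conventional 0.5 threshold is used only for
display (scores clipped to [0, 1] there, never for ROC). The final
transfer model is a single refit on all training data (an ensemble-mean
variant over the CV models is a natural extension, not implemented).

## Synthetic cohorts

The generator emulates the statistical shape of stool 16S tables, not
their biology:

- A random 6-rank taxonomy (defaults: 6 phyla, 10 classes, 15 orders,
  30 families, 150 genera, uniform parent assignment) with 10% of genera
  unresolved at genus (placeholder labels).
- Genus baseline log-abundances `N(0, 2)` — a heavy right tail, so a few
  genera dominate as in real data; per-sample log-normal noise with
  sd 0.7; per-genus structural zeros with probability π = 0.3; multinomial
  read sampling at uniform depths in [1099, 4000].
- Planted case/control effects: fold changes (23, 13, 7, 0.17, 0.27,
  0.32, 0.34) — the magnitudes reported for gut-disease case/control
  contrasts — assigned to mid-abundance resolved genera (baseline
  |log-mean| ≤ 1), where the effect is neither lost in sampling noise nor
  heavily compressed by renormalisation. Observed fold changes still
  compress somewhat below the planted value because adding case-group
  mass renormalises every share downward.
- Transfer arms (Normal, HFD, NFE, NFW; 8 animals each): all share a
  host shift — per-genus log-normal factors (sd 0.5) plus 10% of genera
  absent outright — so human→animal feature alignment is genuinely lossy.
  Arms retain the planted disease-direction effects with factors 0, 1,
  0.2, 1 respectively (NFE's reversal parameter 0.8 attenuates the
  effects toward Normal; NFW retains them).
- Taxonomy, baselines and planted-genus identity derive from the spec's
  own seed so clinical and transfer cohorts share a genus universe;
  sample-level randomness derives from the per-call seed. Same spec +
  seed reproduces tables exactly.

What the generator does **not** emulate: phylogenetic correlation among
genera, compositional interactions beyond renormalisation, strain-level
or longitudinal dynamics, batch effects, and any real taxonomic identity
(planted genera are arbitrary names). Passing tests therefore show the
pipeline recovers known structure of this kind at these scales — they
say nothing about classifier performance on real patient data.

## Problem sizes and determinism

The end-to-end studies run at 100 controls vs 100 cases (planted-effect
recovery: 30-split CV, a permuted-label null with an independent
permutation per iteration, importance aggregation over the 30 CV models)
and 50 independently drawn transfer cohorts of 4 × 8 animals scored by one
clinical model. Test batteries are calibrated on 400–500 null
simulations. These sizes give stable recovery statistics at desk scale;
everything consumes explicit seeds and reruns bit-identically.

## Known limitations

- The exact-MWU path enumerates `C(n+m, n)` assignments and is used only
  up to 8 per side; beyond that the tie-corrected normal approximation is
  used (agreement within 0.02 at the boundary is tested).
- PERMANOVA p-values are permutation estimates; identical-partition
  shuffles tie `F_obs` by construction, so the minimal attainable p is
  `(1 + #ties)/(1 + n_perm)`.
- With 8 animals per arm, BH-adjusted exact-MWU significance between two
  arms requires near-complete score separation; across study replicates
  the significant fraction for Normal-vs-HFD is high but variable.
- Feature alignment is exact-label only; cross-database or cross-host
  taxonomy harmonisation is out of scope.
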