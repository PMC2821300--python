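# Methods

## The activity statistic

The screen rests on a single idea: if a miRNA is destabilising its target
mRNAs in a tissue, the expression values of its predicted targets form a
sample shifted toward low values relative to comparable genes measured in
the same profile. Per profile, each family's expressed predicted targets
are compared to a background by a one-sided Wilcoxon rank-sum test with the
alternative "targets stochastically lower". The test is rank-based, so it
is invariant under any strictly increasing transform of the signal scale —
normalisation choices that preserve within-profile ordering cannot change a
p-value.

**Background composition.** The natural background is the set of *all*
genes predicted to be targeted by any miRNA (the "universe"): comparing
targets to targeted genes rather than to the whole array controls for the
fact that predicted targets are not a random draw from the transcriptome.
Read literally, that background contains the tested family's own targets,
which makes the two rank-sum samples overlap. The default here excludes
the tested family's targets from the background so the samples are
disjoint, as the test's derivation assumes; `background="inclusive"`
restores the literal overlapping composition for comparison. With ~100
families sharing a universe of a few thousand genes the two differ little.

**Meta-analysis.** Profiles of the same tissue are independent
experiments, so per-family p-values are merged by Fisher's combined
probability test, χ² = −2·Σ ln pᵢ on 2k df, computed in log space. When a
family passes the minimum-target filter in only some profiles, the
available p-values are combined and the degrees of freedom shrink
accordingly. Families with combined p below `alpha_table` (default 0.05)
are called active. No multiple-testing correction is applied to the
headline calls; `add_bh=True` attaches Benjamini–Hochberg q-values as a
clearly separated extension.

**Null controls.** For each profile, `n_random_sets` (default 5)
replicates assign every family a uniform random gene sample from the
universe. Size-matching is applied to the *expressed* target-set size
(post-intersection), not the raw prediction size, so null and observed
tests have identical sample sizes and hence identical power; passing the
prediction table to `generate_random_sets` restores the literal pre-filter
randomisation. Per-family, per-replicate random substreams are derived
from the master seed and a hash of the family id, so adding or reordering
families does not perturb existing draws.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_targets` | 50 | strict lower bound (>) on expressed targets per tested family; counted after expression filtering, where it reflects the test's effective sample size |
| `n_random_sets` | 5 | null replicates per profile |
| `alpha_table` | 0.05 | combined-p threshold for the candidate call |
| `alpha_group` | 0.1 | combined-p split for the abundance group comparison |
| `background` | exclusive | rank-sum background composition (see above) |

Probeset filtering keeps plain `_at` probesets (the single-gene-specific
design; qualified suffixes `_s_at`, `_x_at`, `_a_at`, `_f_at`, `_g_at`,
`_i_at`, `_r_at`, `_b_at` may cross-hybridise and are dropped) that carry a
`present` call; profiles without detection calls fall back to keeping
signals strictly greater than the median of the suffix-passing probesets.
Marginal calls are treated as not expressed — detection-call semantics make
`marginal` a borderline call, and requiring `present` keeps the expressed
set conservative. In median-fallback mode the retained records are
re-labelled `present`, recording the designation and making the filter
idempotent. Genes measured by several retained probesets take the
arithmetic mean of their signals; gene symbols are uppercased so
predictions and annotations from different sources join reliably.

## Numerical choices

- **Exact vs approximate rank-sum.** With pooled sample size ≤ 12 the null
  is enumerated exactly over all rank assignments; midranks make the
  enumeration valid under ties, within or across groups. Above 12, a
  normal approximation with midranks, tie-corrected variance and a 0.5
  continuity correction is used. The cutoff keeps the exact path
  instantaneous while the approximation is already accurate at these sizes.
- Degenerate inputs: all values identical → p = 1 with a warning; empty
  samples are errors; p-values are clamped to (0, 1].
- Fisher combination clamps non-positive inputs to the smallest positive
  float (warned) and rejects p > 1; a single p combines to itself.
- Orderings are made deterministic everywhere: per-profile results sort by
  average target signal (ties by family id), combined results by combined
  p (ties by family id), gene rankings by count descending then symbol.
- Spearman correlation uses an exact permutation null for n ≤ 9 and the
  t-approximation above; the group comparison reuses the rank-sum engine
  with the "greater" alternative. Both drop unmatched family ids with a
  logged count and refuse constant vectors.
- qPCR: efficiency comes from an ordinary least-squares standard curve
  (slope must be negative); the absolute estimate R₀ = R_Ct/(1+E)^Ct is an
  exact arithmetic inversion of exponential amplification. The threshold
  fluorescence R_Ct is instrument-specific and treated as an opaque
  positive constant. One efficiency per amplicon (per target), not per
  reaction; the alternative linear-regression efficiency estimator is not
  implemented — the standard-curve path is the single supported method.

## The synthetic generator

`SyntheticConfig` defaults describe a mid-sized screen: 5000 genes, 100
families with Poisson(200) predicted targets (the field's usual order of
magnitude for conserved-family target sets), three profiles per tissue.
Each gene is expressed in the tissue with probability 0.6 (latent state);
expressed genes draw an independent log2 baseline N(8, 0.5) per profile,
non-expressed genes sit at N(4, 0.5), and N(0, 0.4) log2 measurement noise
is added. Detection calls report the latent state (`call_rule="calls"`);
`call_rule="none"` omits them to exercise the median-filter fallback. An
active family represses a fixed random subset (`fraction_functional`) of
its targets by log2(`fold_change`), accumulating additively in log2 for
genes targeted by several active families — the standard multiplicative
model of microarray effects. Signals are emitted as 2^log2 at probeset
level, with a second probeset for 20% of genes and a decoy `_x_at`/`_s_at`
probeset for 5%.

Two structural choices matter and are deliberate:

- **Calls come from the latent state, not the observed signal.** A
  threshold on the *observed* signal couples the expression filter to the
  planted effect: a repressed target is pushed below the threshold,
  filtered out, and its depression erased from the tested sample — a
  truncation that absorbs most of a median-filter's worth of shift. Real
  detection calls are driven by hybridisation quality and absolute
  abundance, and a 1.5-fold repression of a well-expressed gene rarely
  flips it to absent, so latent-state calls are both the realistic and the
  statistically transparent choice. The interaction is real, though: on
  call-free data filtered by the median rule, moderate planted effects are
  strongly attenuated, and the same caution applies to real profiles
  analysed without detection calls.
- **Gene baselines are independent across profiles.** Profiles stand for
  separate experiments (different laboratories, platforms, animals);
  modelling their gene-level variation as independent makes the Fisher
  combination across profiles genuinely informative. The generator
  compresses between-gene dynamic range relative to real arrays (total
  log2 spread ≈ 0.64 among expressed genes, versus 1.5–2 on typical MAS5
  exports among present calls, where much of the spread is a stable
  gene-identity component shared across experiments). Passing tests
  therefore show the machinery is correct and calibrated, not that any
  particular real-data effect size will reach significance: on real
  arrays, equal per-gene fold-changes spread over a wider static baseline
  yield larger p-values for the same target-set size.

The truth record (planted families, their expressed affected genes, the
expressed-gene set) is a first-class output, so tests compare pipeline
calls against it directly instead of re-deriving ground truth.

qPCR simulation sets each target's true starting fluorescence
proportional, on the log scale, to a supplied activity strength, draws an
efficiency uniformly from [0.85, 1.0], solves the threshold cycle from
R_Ct = R₀(1+E)^Ct at a fixed threshold, and emits a noiseless ten-fold
dilution series from the same efficiency, making curve fitting exactly
invertible.

## Problem sizes

The statistical checks run at 100 families × 5000 genes × 3 profiles; the
planted-recovery analysis repeats that over 20 independent simulations
with five active families (40% functional targets, 1.5-fold repression);
pipeline-level fixtures use 15 families × 800 genes × 2 profiles with two
strong repressors, sized for an unambiguous truth comparison at a 10⁻³
call threshold.

## Known limitations

- Predictions are consumed as given; no seed matching, conservation
  scoring or prediction-version reconciliation is attempted, and prediction
  files from different releases are treated as interchangeable inputs.
- The pipeline starts from processed signal tables: no CEL-file
  processing, normalisation, or direct GEO retrieval.
- Per-profile p-values combined within a tissue are treated as
  independent; shared biology between profiles of the same tissue makes
  the combined p anti-conservative in a way the method inherits by design.
- The group-comparison statistic for abundance (rank-sum) and the
  correlation's sidedness (two-sided default) are choices exposed as
  parameters, since different conventions are defensible.
- The simulator does not model probe-level hybridisation physics,
  MAS5 call generation beyond the latent threshold rule, or qPCR
  fluorescence baseline drift.
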