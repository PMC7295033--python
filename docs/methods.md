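# Methods

## Quantification and normalization

Two label-free abundance proxies are carried in parallel and never
mixed: spectral counts (linear scale) and precursor ion intensities
(log2 scale throughout).

**Spectral counts.** Raw per-protein counts are integers.  Each sample
is scaled by (grand mean of per-sample totals) / (its own total), the
classic total-spectrum-count normalization; afterwards every sample's
total equals the grand mean (checked to 1e-9 relative tolerance) and
the overall matrix sum is conserved.  A sample with zero total is an
error — it cannot be scaled.

**Ion intensities.** Spectrum records assigned to more than one
protein are pruned before anything else, because a shared spectrum's
intensity cannot be apportioned without a peptide-inference model (out
of scope).  Remaining intensities are log2-transformed and iteratively
median-centered: each sample's median is subtracted until the largest
per-sample shift falls below `tol` (default 1e-6; error at `max_iter`
= 50).  Exact median subtraction converges in a single pass, so the
iteration exists for numerical safety, and a second pass is a no-op
(idempotence is a tested invariant, as is invariance to a constant
per-sample shift).  Per protein and sample, the summary value is the
median of its surviving spectra; a protein with no spectrum in a
sample is *absent* (NaN), never zero — counts of zero are genuine
observations, censored intensities are not.  No proprietary adaptive
intensity weighting is applied; the protein summary is the plain
median.

**Replicate averaging** differs by method: arithmetic mean for counts,
median of present values for intensities (absent if no replicate
observed the protein).  This choice is recorded in the normalization
report so downstream users can see it.

A caveat worth knowing: global median centering assumes most spectra
are unchanged between samples.  When a majority of the specific
interactome shifts in one direction (as the planted effects do), the
centering absorbs a small part of the shift; on the default synthetic
study this biases recovered log2 effects by about −0.1 of a planted
1.0.  The same limitation applies to real data normalized this way.

## Specificity filter

With averages in hand, a protein is removed iff any of:

* **KO-only** — zero/absent in every WT and variant average under
  both methods, but detected in KO;
* **KO-enriched** — KO average ≥ r × WT average or ≥ r × variant
  average, under either method, with r = 1.5 (inclusive, exposed as
  config).  Intensity ratios are `2^(KO_log2 − other_log2)`.  A zero
  or absent denominator with detected KO counts as enriched (ratio
  +∞, no pseudocount) — the limiting case of KO-only detection;
* **ribosomal** — annotated translation machinery, removed
  regardless of quantification.

"Enriched against either genotype" is deliberately read as OR:
removal whenever the background lane beats *any* bait lane is the
conservative specificity choice.  Decisions depend only on a protein's
own rows, so the kept set grows monotonically with r; a protein with
no KO signal can only ever be removed as ribosomal.  The filter
reports a funnel (input, kept, per-reason removals with overlap
accounting), mirroring how such studies narrow ~1000 identified
proteins to a specific-interactor list.

## Differential interaction

log2(WT/Ala56) fold changes: for counts,
`log2((WT + c)/(Ala56 + c))` with pseudocount c = 0.5 (configurable;
c = 0 yields ±∞ for single-sided zeros); for intensities, the plain
difference of genotype-averaged log2 values, undefined if either side
is absent.  Both-absent proteins are excluded from classification
with a logged reason.

The three-way category is driven by the **ion-intensity** fold change
with threshold t = 0.5 and a closed "unchanged" interval [−t, t]; the
spectral-count fold change, under the same rule, sets `discordant`
(categories disagree — e.g. a protein at 2.57 by counts but −0.02 by
intensity is unchanged, discordant, and nominated) and `nominated`
(outside the band by at least one method).  Swapping the WT and
variant labels negates every fold change and exactly exchanges the
increased/decreased tallies — a tested invariant.

Replicate-level tests use the two-sided Mann–Whitney U.  `exact` mode
enumerates the permutation null with midranks (correct under ties;
feasible whenever C(n1+n2, n1) ≤ 200 000, and delegated to the exact
tie-free U distribution beyond that).  `normal` mode is the
tie-corrected normal approximation with continuity correction.  With
three replicates per genotype the exact two-sided p can never fall
below 2/C(6,3) = 0.1, so an unadjusted 0.05 criterion is unreachable
in exact mode — the implementation warns about this collision, and the
pipeline default is `normal` to mirror what typical analysis software
reports at this design size.  BH q-values are emitted per method for
reference but never gate classification, matching the unadjusted
significance convention of exploratory interactome screens.

## Overlap statistics

Gene-set overlap uses the upper-tail hypergeometric probability
P[X ≥ k], identical to a one-sided Fisher exact test.  The background
size N is never guessed: it defaults to 16918 (the mouse UniProt
release size used for peptide search in the targeted study design) and
is echoed in every result, because overlap p-values are meaningless
without it.  Symbols are matched case-insensitively (mouse `Shank3`
vs human `SHANK3`).  The direction-bias test is a Pearson chi-square
goodness-of-fit of the decreased vs increased counts against an equal
split.

## Network clustering

Edges carry combined confidence scores in [0, 1] (STRING's 0–1000
dialect is converted only when explicitly declared — score scale is
never inferred).  Thresholding keeps edges with score ≥ 0.9
(inclusive) and retains isolated nodes.

Markov Clustering is implemented directly: the column-stochastic flow
matrix (self-loops at each node's maximum incident score, 1.0 when
isolated) is alternately expanded (matrix square) and inflated
(entrywise power 2.0, column renormalization) with pruning of entries
below 1e-5, until the flow matrix changes by less than 1e-8 in max
norm.  Clusters are read from attractor rows; overlapping attractor
systems are merged; nodes whose columns lost all mass to pruning have
their self-loop restored.  The computation runs per connected
component (flow cannot cross components), which keeps large sparse
graphs cheap.  Inflation 2.0 is the canonical default — published
interactome maps name the algorithm but rarely its granularity — and
clusters below the minimum size (default 7) are reported as
unclustered rather than silently dropped.  The implementation is
cross-checked in the tests against an independent plain
reimplementation (dense, unpruned, no component decomposition).

STRING's analytical protein–protein enrichment p-value conditions on
the degree sequence in a way that cannot be reproduced from published
outputs, so the package substitutes a transparent resampling test:
draw uniformly random node sets of the subset's size, count internal
edges, and report `(1 + #{null ≥ observed}) / (1 + n_perm)`.

## Synthetic study design

The generator emulates the targeted experiment: 3 genotypes × 3
technical replicates, 1000 proteins.  Ground truth assigns each
protein a specificity label, a planted class, a true log2 effect and
a ribosomal flag.  Defaults (all configurable):

| parameter | default | meaning |
|---|---|---|
| `frac_nonspecific` | 0.50 | background binders, so the funnel drops ~half the input as in published knockout-controlled co-IPs |
| `frac_ribosomal` | 0.05 | ribosomal proteins, drawn from the non-specific pool |
| `frac_decreased` / `frac_increased` | 0.67 / 0.15 | of specific proteins, matching the ~67%/15% decrease/increase split such studies report |
| `effect_log2` | 1.0 | planted |log2(WT/Ala56)| |
| `ko_leak_frac` | 0.05 | KO recovery of specific interactors — nonzero so the 1.5× *ratio* rule, not mere presence/absence, is exercised |
| `ko_enrichment` | 3.0 | KO multiplier for non-specific binders |
| `nonspecific_abundance_log2` | −1.0 | background binders are individually less abundant than bait-complex members |
| `frac_ko_only` | 0.20 | of non-specific proteins: detected only in KO |
| `count_dispersion` | 0.05 | negative-binomial overdispersion |
| `intensity_sigma` | 0.25 | log2 spectrum noise SD |
| `depth_bias`, `intensity_shift_log2` | drawn | per-sample lognormal(σ=0.15) depth factors and N(0, 0.75) log2 shifts, removed by normalization |

Counts are negative binomial with mean = abundance × genotype effect ×
sample depth (variance μ + φμ²; Poisson as φ→0).  Setting the
dispersion to exactly 0 disables sampling entirely (rounded means), so
analytic identities — e.g. zero fold change everywhere when no effect
is planted — hold exactly in tests.  One spectrum is emitted per
counted MS/MS event, with log2 intensity = abundance + genotype effect
+ sample shift + N(0, σ); a 5% admixture of two-protein spectra
exercises the pruning rule.

The background model deserves a note.  Non-specific binders are *not*
given identical abundance in all genotypes: bait-free (KO) beads
recover modestly more background (3×), a fifth of the background
appears only in KO, and background binders sit ~1 log2 unit below
specific complex members.  Two reasons: mechanistically, bait
complexes occupy bead capacity in WT/variant lanes; statistically, a
background with KO ratio exactly 1 is invisible to any ratio filter,
and because total-count normalization rescales the KO lane, the
*effective* KO ratio is bounded by the inverse of the background's
mass share — the chosen abundance offset keeps that bound well above
the 1.5× threshold.  With these defaults the filter recovers planted
labels at ≥ 0.99 sensitivity and specificity across seeds.

What the simulation does **not** model: peptide sequences and
search-engine scores, protein inference and parsimony grouping,
shared-peptide apportioning, intensity-dependent missingness,
between-animal biological variance (the emulated design pools animals
and runs technical replicates), and correlated contaminant structure.
Passing tests therefore demonstrate the pipeline's arithmetic and its
behavior under the stated generative model, not performance on real
spectra.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline at the
default 1000-protein scale (~350k spectrum records, a few seconds) and
use 100–10 000 resamples for permutation nulls; exact-test oracles
enumerate up to C(10,5) relabelings and N ≤ 25 backgrounds.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; fixture bundles are byte-identical under a
fixed seed.  Ties in the Mann–Whitney use midranks; the empty category
tally is defined (zero counts); degenerate graphs (edgeless, single
node) are valid MCL inputs.
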