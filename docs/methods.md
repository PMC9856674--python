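# Methods

## Study design emulated

Five conditions: ground control (GC), four-day simulated-microgravity
exposure (MG), and three return-to-ground timepoints at four-day intervals
(R1_GC, R2_GC, R3_GC), three replicates each. All contrasts are condition
versus GC. The cultures the design emulates are mixed-stage worm populations
in axenic liquid medium; the generator does not model stage mixture — each
sample is a single population-level expression profile (see Limitations).

## Differential expression

Per gene, the effect is the difference of mean log2(x + pseudocount)
(pseudocount 1.0) between the two conditions, and the p-value is a
two-sided **pooled-variance Student t-test** on those log values, BH-adjusted
across the genes of one contrast. Calls are strict: `up` iff
log2FC > 2 and p_adj < 0.05, `down` symmetric (threshold and alpha are
parameters; the relaxed 1.5 threshold used for pathway-level screens is the
same code path).

Why pooled rather than Welch: with three replicates a group, the Welch
degrees of freedom collapse toward 2 whenever the two sample variances
differ by chance — which at n = 3 is the typical case, not the exception —
and the resulting heavy p-value tail destroys power at stringent
BH-realized thresholds (measured per-gene power ≈ 0.69 versus ≈ 0.99 pooled
at the shipped noise level, at the ~4×10⁻⁴ threshold a 48-signal contrast
induces over 5000 genes). Same-protocol replicate groups justify the
equal-variance assumption; the generator satisfies it by construction.

Degenerate genes: zero variance in both groups with equal means → p = 1;
with unequal means → p = 0 and a warning (directionally informative but
untestable). The pseudocount guards log2(0).

Thresshold boundary behavior is strict (`>` / `<`) on both the fold change
and alpha; an exactly-threshold gene is not a DEG.

ncRNA expression calling: an ncRNA is expressed in a condition iff its
replicate-mean abundance is ≥ the cutoff (default FPKM 24.7, the minimum
observed expression of the housekeeping gene pmp-3). The comparison is
inclusive because the cutoff is itself the minimum of an expressed gene.

Sample clustering is Ward linkage on Euclidean distances between
log2(x + 1) sample profiles, serialized as Newick.

## Persistence

A gene is *maintained* at a return timepoint iff it is called DE there in
the same direction as at exposure. Opposite-direction calls are a separate
*conflicting* category (not folded into *lost*), and maintained ∪ lost ∪
conflicting partitions the exposure DEG set exactly. Fractions are
|maintained| / |exposure set of that direction|; a direction with no
exposure DEGs reports "not applicable" rather than 0. The overall fraction
uses the union over directions. Subset reports apply the same algebra after
restricting every set to the subset. The integer percentages printed by
the drivers are rounded half-up.

ncRNA persistence: *induced throughout* = expressed in exposure and every
return but not in ground control; *silenced throughout* = expressed only in
ground control.

## Cross-study signature

Order of operations mirrors the source analysis: (1) *common* = genes
called DE (any direction) in both studies; (2) the overlap is tested with a
one-sided hypergeometric upper tail P[X ≥ k] (via scipy's log-gamma
implementation; an exact integer-summation oracle backs it in tests);
(3) sign-conflicting common genes are discarded; (4) the remainder is the
signature. Sign agreement affects membership only, not the overlap test.
The universe size N is a required explicit parameter: the original analyses
never state their universe, so their printed p-values are not exactly
recomputable and no default could be defended. The same machinery drives
GMT-based gene-set enrichment (per-set upper-tail tests, BH across sets).

## Lipid statistics

Replicate QC: per replicate, Pearson r against each same-group replicate
across species, computed on log10 concentrations (so no single abundant
species dominates), squared and averaged; the single worst replicate in a
group is excluded when its mean R² < 0.9, at most one exclusion per group
per pass — mirroring a workflow in which exactly one decorrelated ground
control was dropped. Whether the original correlations were pairwise or
versus the replicate mean is unstated; pairwise-mean was adopted.

Per species: mean-centered (classic) Levene check first — the workflow
gates on confirmed equal variances — then a two-tailed pooled t-test on the
kept replicates; if Levene rejects at 0.05 the test falls back to Welch
with a warning. The mean-centered Levene is anticonservative at n ≈ 3–5
(measured ~8% at n = 5); it holds its level at moderate n, and the shipped
workflow treats it as a gate, not an inferential endpoint. Fold changes are
ratios of group means reported as magnitude ≥ 1 plus an explicit
increase/decrease direction, so "27-fold increase" and "3.6-fold decrease"
are both positive magnitudes; ties report direction "increase" with fold 1.

## Clinostat particle model

Rotating-frame complex coordinate q = x_rot + i·y_rot = z·e^(−iωt). The
equation of motion

    m q̈ + (2iωm + λ) q̇ − ω²(m − m_w) q = −i g (m − m_w) e^(−iωt)

is integrated as a 4-dimensional real linear system with the implicit Radau
scheme and an analytic Jacobian (λ/m reaches ~10⁶–10⁷ s⁻¹ for micron
particles, so the problem is stiff; an explicit scheme is unusable). The
printed second derivative in the source formula is with respect to time
(dimensional necessity). A first-order overdamped reduction (inertia
dropped) is provided as a fast cross-check mode.

Closed forms: substituting q = A·e^(−iωt) gives the orbit amplitude
A = −i·g(m − m_w) / (ω(ω·m_w − iλ)), reducing to |v_T|/ω in the overdamped
limit (v_T = g(m − m_w)/λ, signed); the slow root of
m s² + (2iωm + λ)s − ω²(m − m_w) = 0 gives the centrifugal drift rate,
overdamped form ω²v_T/g. Measurement from a trajectory: the orbit radius is
the modulus of the e^(−iωt) Fourier coefficient over the last full rotation
period (the slow mode averages out over a period); the drift rate is the
log-slope of the per-period orbit-center modulus over the second half of
the run. Integration matches both closed forms to well under 1% across
a ∈ [1, 50] µm, Δρ ∈ [−200, 500] kg/m³, ω ∈ [0.1, 10] rad/s.

Drag comes from Stokes' law 6πηa when a viscosity is given, or is implied
by a measured terminal velocity; supplying both v_T and λ requires
consistency to 10⁻⁶ relative. The calibration system uses the measured
microsphere terminal velocity (3.2 ± 0.2 µm/s; 5.6 µm melamine spheres,
1.51 g/cm³) directly, since the 3% BSA suspension viscosity is not known.
Instability (solution escaping the analytic envelope) raises an error
advising a smaller step / implicit scheme rather than returning garbage.
No wall effects, particle–particle hydrodynamics, or active swimmers.

## Synthetic-data generators

All generators are seeded (`numpy.random.default_rng`) and bit-reproducible;
every integer-countable feature (which genes are DE, how many retained per
timepoint and direction, shared/conflicting id counts) is realized exactly
as configured, with rounding nearest-integer-ties-to-even.

**Expression.** Gene baselines are lognormal: log2-mean 9, log2-SD 2 in the
shipped config — a deep bulk library with a median of ~500 counts per gene.
Counts are negative-binomial via the gamma–Poisson mixture with dispersion
0.02 (tight biological replication of isogenic, environment-controlled
cultures). DE genes (10% of 5000; 60% up) shift their mean by 2^±3.5 at
exposure and are drawn only from genes with baseline ≥ 2^9
(`de_min_baseline_log2`): a DEG passing a 4-fold + FDR filter in real data
is by construction detectably expressed, and this floor is what gives the
caller near-unit per-gene power at n = 3, which in turn is what makes
maintained-fraction estimates binomially accurate rather than biased by
power conditioning (the estimate conditions on calling a gene twice, so it
scales with E[power²]/E[power]). Retention at each return timepoint keeps
the identical exposure log2FC (no attenuation, so recovery is unambiguous);
retained sets are leading slices of one per-direction permutation, hence
nested across timepoints whenever the configured fractions are
non-increasing. Shipped retention: 75% at R1 (both directions), 70%/55%
(up/down) at R2, 16%/0% at R3. The TF variant designates a 20-gene panel
forced DE-up with its own retention (90/75/15%) via `subset_persistence`,
baselines drawn from the truncated upper part of the baseline distribution
(curated regulator panels are biased toward expressed genes), and effect
size 4.0 so that 20-gene percentages are not blurred by call misses.
FPKM-mode output divides counts by (library size / 10⁶) with a fixed 1 kb
pseudo-length.

**Lipid panel.** Twenty sphingolipid species with control means spanning
2–1500 ng/ml and the study's fold changes (LacCer ×27 up, HexCer ×3.6 down,
d18:1-C20 ×3.7 up, a borderline ×1.9 SB decrease, and several species at
fold 1.0 — quantified but unaffected, as a real MRM analyte list would be;
they also anchor the correlation QC). Concentrations are lognormal with
log-space SD (cv) 0.22 and the −σ²/2 offset so expected concentrations
equal the configured means exactly. cv was chosen so that (a) honest
replicates robustly show pairwise R² > 0.9 across 20 species and (b) the
1.9-fold species at n = 3 is genuinely borderline at α = 0.05 (measured
rejection rate ≈ 45% across seeds — the regime in which a p of 0.055 is a
coin-flip away). The optional outlier replicate's log profile is
constructed by Gram–Schmidt to have sample correlation exactly
√0.6 with the true species profile, so its mean pairwise R² sits near 0.6 —
decisively below the 0.9 threshold — by construction rather than in
expectation.

**Overlap lists.** Exact set construction: n_shared ids common to both
tables, exactly n_conflicting of them sign-flipped, remaining ids disjoint,
all drawn from an N-gene universe (shipped: 600- and 300-gene lists sharing
134 ids with 16 conflicts in a 20 000-gene universe — the worm genome
scale). Effect sizes and p-values on the emitted records are decorative
(above-threshold by construction); the structure is the content.

Infeasible configurations (fractions outside [0, 1], overlap counts
exceeding list sizes, universes smaller than the union, single replicates)
are rejected with specific messages before any sampling.

## Pipeline and reproducibility

`run_pipeline` validates its whole configuration fail-fast (nothing is
written if any enabled stage's inputs are unresolvable), derives per-stage
seeds as sha256("{seed}:{stage}") mod 2³¹, writes per-stage artifacts plus
a manifest of content hashes, and aborts naming the failing stage while
preserving partial artifacts. Gene identifiers are opaque case-sensitive
strings throughout.

Problem sizes used by the repeated-run summaries (chosen as comfortable
Monte-Carlo sizes for the quantities' variances): 12 expression runs for
the persistence percentages, 25 TF-panel runs, 200 lipid panels (fold
medians; the median is the unbiased location for a lognormal ratio
estimate, whereas the mean of ratio-of-means carries an
E[1/mean]-inflation of a few percent at n = 2–3 denominators).

## What passing tests do and do not show

The generators produce clean, single-cause structure: equal variances,
exactly retained effects, no batch effects, no library-size drift, no
stage-mixture drift across generations, no correlated genes, and DE placed
on detectably expressed genes. Recovery of the configured fractions
therefore validates the *bookkeeping and statistics* — thresholds, BH,
set algebra, QC, fold estimation — not the biology of any real dataset, and
says nothing about dispersion estimation or normalization, which this
pipeline deliberately does not do (no size-factor models, no dispersion
shrinkage, no probe-level microarray handling, no read simulation or
alignment). Real-data analyses with this package should treat the DE caller
as a transparent baseline, not as a DESeq2 replacement.

## Known limitations

- The per-gene t-test ignores count discreteness at very low expression;
  below ~10 counts its p-values are approximate (the shipped configs avoid
  that regime by design).
- Persistence "maintained" requires a same-direction *call*, so it inherits
  the caller's power; with weak effects the maintained fraction is biased
  downward by power conditioning.
- Published overlap p-values of this kind depend on an unstated universe;
  all overlap p-values here are conditional on the caller's explicit N.
- The Levene gate at n = 3 has low power against variance differences, so
  the pooled t-test is effectively the default path.
- The clinostat model is a single passive sphere in unbounded fluid;
  chamber walls and swimming animals are out of scope.
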