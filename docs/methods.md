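# Methods

This note records the models and procedures `plantcompart` implements, the
defaults and why, the numerical choices, and what the synthetic-data tests do
and do not establish.

## Design model and data

The unit of analysis is an OTU × sample count table whose sample names encode
a factorial common-garden design: soil origin (2 levels) × plant genotype
(3) × replicate plant (≤ 5), with up to four compartment samples per plant
(rhizosphere, root endosphere, nodule, leaf). `plant_id` =
soil × genotype × replicate is the pairing key for all within-plant
statistics. The name parser is pluggable; the default dialect is
`<soil letter><genotype number><replicate letter><compartment letter>`
(e.g. `C96bN`), and the synthetic generator emits the same dialect so every
downstream stage is shared between real and simulated data.

Rare-OTU filtering defaults to a dataset-wide total of ≥ 10 reads. The
cutoff is a convention, not an estimate; it is exposed so replication runs
can sweep it.

## Iterative subsampling

All depth-sensitive estimators rarefy each sample to a fixed depth *m*
(default 1500) without replacement — a multivariate hypergeometric draw, so
each OTU's subsampled count has expectation m·(count/total) and every draw
sums exactly to *m* — and average over *T* iterations (default 1000).
Samples with fewer than *m* reads are excluded with a logged warning.
Monte-Carlo error of the averaged estimators scales as 1/√T; halving T to
500 changes Bray-Curtis entries by < 0.005 on the default synthetic world.

## Alpha diversity

Per draw: S_obs = number of OTUs with ≥ 1 read; the bias-corrected Simpson
concentration D̂ = Σ nᵢ(nᵢ−1)/(N(N−1)); diversity 1 − D̂; evenness
E_D = (1/D̂)/S_obs. E_D can exceed 1 on tiny, perfectly even draws, and is
undefined on the (pathological) all-singleton draw, which is skipped with a
warning.

Before ANOVA the proportion-scale estimators are logit transformed
(ln p/(1−p); exact 0/1 inputs are clamped to [ε, 1−ε], ε = 1/(2m), with a
warning) and richness is Box-Cox transformed with fixed per-compartment
exponents λ = 1.6 (rhizosphere), 0 (root), −0.2 (leaf), −0.2 (nodule);
`estimate_boxcox_lambda` provides profile-MLE estimation for new data. The
three-way ANOVA treats all factors as fixed and uses sequential (Type I)
sums of squares, which are order-invariant on balanced data; designs
unbalanced beyond a configurable cell-size ratio raise rather than silently
reporting order-dependent tests. Tukey HSD runs on the transformed scale
(the interaction of HSD with the transforms is a choice; letters are
reported per response). The compact letter display assigns one letter per
maximal clique of the "not significantly different" graph.

## Beta diversity and ordination

Bray-Curtis BC(x, y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) is averaged element-wise over
subsampling iterations; one averaged matrix feeds all downstream tests (not
per-iteration tests).

NMDS minimizes Kruskal stress-1,
√(Σ(d − d̂)²/Σd²), by SMACOF majorization alternated with monotone
(isotonic) regression of configuration distances on the observed
dissimilarities. The study tool's "1000 iterations" is ambiguous; here the
optimization effort is controlled by `restarts` (default 32; the first start
is the classical-MDS configuration, the rest random) × `max_iter` (default
500) majorization steps with tolerance 1e−7 on the stress decrease. The
iteration stops at the first step that fails to lower stress, so the stress
trace is non-increasing by construction; the best configuration over
restarts is centered and rotated to principal axes. Per-axis community
variation R²ₐ is defined as the squared Pearson correlation between the
observed dissimilarities and the distances computed from axis *a* alone — a
documented, swappable convention, since the original implementation's
definition is not recoverable.

PerMANOVA uses Anderson's formulas (SS_total = Σ_{i<j} d²ᵢⱼ/N;
SS_within pooled per group; pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)))
with the (b+1)/(m+1) permutation p-value estimator and the seed recorded.
`permutations="exact"` enumerates all distinct label assignments for small
designs, which the tests exploit to check exact agreement with brute-force
enumeration.

## Modified PVCA

For each of the first *k* NMDS axes (default 10), the axis scores are fitted
with an intercept-only mixed model in which soil, genotype, compartment and
all their interactions are random effects with one variance component each
plus a residual. Components are estimated by REML: the restricted
log-likelihood is maximized directly over log-variances (L-BFGS-B, three
starting points, bounds log σ² ∈ [−25, 6] on variance-standardized scores),
so non-negativity is structural and boundary components come back as ~0.
This choice followed a failed attempt with a general mixed-model package
whose optimizer stalled on this all-random model; the direct implementation
reproduces lme4's REML estimates to four decimals on a frozen test fixture.
Per-axis components are converted to percentages, weighted by the axis R²
values (renormalized over the retained axes), and rescaled to sum to 100.
Axes whose fit fails are dropped with a warning and the weights
renormalized. On pure-noise scores the residual component averages ~92%;
on scores carrying a single injected factor the factor dominates.

## Composition effects

Paired effect size between compartments A and B of the same plant:
ES = (rel_A − rel_B)/(rel_A + rel_B) on per-sample relative abundances, for
the top-N most abundant OTUs (default 20). (rel_A > 0, rel_B = 0) gives
exactly +1 and the mirror −1; plants where the OTU is absent from both
compartments are excluded from that OTU's ES set (the alternative —
counting them as 0 — would shrink every distribution toward zero with
uninformative pairs). Quintiles and a two-sided Wilcoxon signed-rank test
(exact null for n ≤ 25 without ties, tie-corrected normal approximation
otherwise, zeros dropped) are reported per OTU.

Core taxa use strict prevalence: present (≥ 1 read) in *more than* the
threshold fraction of the compartment's samples (default 0.5). Presence/Venn
accounting calls an OTU present in a compartment iff its summed reads there
strictly exceed 10.

The Monte-Carlo χ² test samples null tables with both margins fixed
(Patefield's algorithm) and reports p = (#{χ²_null ≥ χ²_obs} + 1)/(R + 1),
R = 10,000 by default. Note the exact conditional reference differs from
the asymptotic χ² on small/discrete tables; convergence to the asymptotic
p holds on large-margin tables.

## Raup-Crick β_RC

Presence is ≥ 1 read. Null assemblages preserve each sample's observed
richness and draw species without replacement with probability proportional
to occurrence frequency over a reference sample set — by default the table
handed in, which the pipeline sets to the union of the two compartments
being compared (the species-pool definition is exposed because it matters).
Sampling uses the Efraimidis–Spirakis weighted-reservoir construction,
which is exactly equivalent to successive weighted draws. The comparison
statistic is the shared-species count;
percentile = (#{null > obs} + ½·#{null = obs})/replicates and
β_RC = 2·percentile − 1, so ties split symmetrically. |β_RC| > 0.95 is
significant (two-tailed α = 0.05); β_RC < −0.95 means more shared taxa than
null — deterministic establishment. Monte-Carlo β_RC at the default 1000
replicates has standard error ≤ 0.03 near the tails; the tests verify
agreement within 0.02 of exact enumeration at 100k replicates on small
pools.

Assembly-rate contrasts (e.g. root→nodule vs rhizosphere→nodule) use a
two-tailed Fisher exact test on the significant-vs-not 2×2 table.

## Co-occurrence null models

The observed statistic is COMBO: the number of distinct species
presence/absence combinations across samples. The default randomization
(named sim6 after the Gotelli algorithm family) preserves the total number
of occurrences, treats species as equiprobable, and fills samples with
probability proportional to their observed richness — the constraint set
matching the stated rationale that occurrence probability within nodules
scales with richness; sim2 (row totals fixed, samples equiprobable) and
sim4 (row totals fixed, richness-weighted samples) are also provided and
the registry is pluggable. Z = (obs − mean_null)/sd_null with a two-tailed
p from the null distribution. When every null matrix yields the same COMBO
(common when every sample's composition is unique, as in sparse
high-richness matrices), the null is degenerate and the function raises;
the pipeline records the degeneracy instead of fabricating a Z.

## SparCC

Fractions are estimated with pseudocount 1; t_ij is the n−1-denominator
sample variance of ln(xᵢ/xⱼ). Under sparsity the row sums of t give the
linear system ((D−2)I + J)ω² = t·1 for basis variances; correlations follow
as ρᵢⱼ = (ωᵢ² + ωⱼ² − t_ij)/(2ωᵢωⱼ), clipped to [−1, 1]. Up to 10
exclusion rounds (the "iterations" of the original tool) remove the
strongest pair above |ρ| = 0.1 from the system and re-solve, never reducing
an OTU below two partners; negative basis variances are clamped to a small
positive value with a warning. Estimates are averaged over 10 Dirichlet
posterior draws of the fractions. Significance: each OTU's counts are
permuted independently across samples and the full estimator recomputed;
two-tailed p = (#{|ρ_null| ≥ |ρ_obs|} + 1)/(P + 1), so the smallest
attainable p is 1/(P+1). Input filtering defaults to mean count ≥ 1 and
prevalence ≥ 20% (recorded in `filter_spec`). At n samples the sampling SD
of any ρ estimate is ≈ 1/√n; expectations about the *maximum* null
correlation must account for the number of pairs (at 50 OTUs × 200 samples
the null maximum is ~0.24 even for a perfectly calibrated estimator).

## Replicon ratios

Per sample, ratio = (plasmid reads/Mb)/(chromosome reads/Mb); since every
cell carries the chromosome and only carriers the plasmid, the ratio
estimates the plasmid-carrying cell fraction under equal per-copy coverage.
Reads are per-replicon sums of per-CDS counts (a converter aggregates
feature-level tables). Samples with < 20 rpoB reads are excluded before the
root-vs-nodule Wilcoxon-Mann-Whitney test (exact for small tie-free groups).
The summary is the median ratio with quartiles per compartment. The ratio is
invariant to total sequencing depth by construction.

## Synthetic generator: what it emulates, and what a green test means

`generate_experiment` draws a lognormal rank-abundance base profile (OTU1
most abundant), applies per-OTU lognormal soil effects (SD 0.8) in the
rhizosphere and genotype effects (SD 0.8) in the root, forces OTU1 to a
per-compartment dominance target (0.10 rhizosphere / 0.40 root / 0.40
leaf / 0.85 nodule), derives leaf from root with extra dominance, and —
when `nodule_from_root` — seeds each nodule from its own plant's *realized*
root counts with OTU1 raised to the nodule target, making nodule presence a
near-subset of root presence (deterministic nested colonization). Counts are
Dirichlet-multinomial with per-compartment concentration 200/60/60/15 (the
single diversity knob producing rhizosphere > root/leaf > nodule) at
lognormal depths around 20k. Default scale is 120 samples × 300 OTUs.

Because leaf and nodule derive from root, genotype effects propagate weakly
into those compartments — the colonization chain is biologically sensible
but means per-compartment tests on synthetic data can detect genotype
outside the root, unlike the motivating study's real-data result. The
generator also omits: sequencing error, chimeras, taxonomic structure,
spatial/temporal autocorrelation, and any OTU-level phylogenetic signal. A
green end-to-end test therefore establishes that the estimators recover the
generative structure they target at realistic sample sizes and depths — not
that any biological conclusion about real communities is correct.

`generate_replicon_counts` draws Poisson reads proportional to replicon
length × carriage fraction at default replicon sizes (chromosome 3.78 Mb,
pSymA 1.57 Mb, pSymB 1.245 Mb) with an rpoB-proportional marker count, so
the expected ratio equals the simulated carriage fraction exactly.

## Pipeline

`run_pipeline` executes io → alpha → beta/NMDS → PVCA → per-compartment
PerMANOVAs → effect sizes → core taxa → Raup-Crick + Fisher → co-occurrence
→ SparCC → replicon ratios, any stage skippable. One master seed
deterministically derives a distinct seed per stage (SeedSequence spawn
keys), all recorded in `manifest.json` together with parameters and output
content hashes; a rerun with an unchanged configuration verifies the hashes
and recomputes nothing. Excluded samples (depth filter, rpoB filter) are
surfaced as warnings so replication discrepancies are diagnosable.

## Known limitations

- NMDS and PVCA reproduce the *method*, not the original tool's exact
  numerics; stress values and axis partitions match published tables only
  up to implementation differences in the ordination.
- The SIM6 constraint mapping follows the stated rationale
  (richness-proportional sample weights); other tools' SIM6 may differ.
- β_RC uses shared-species as the comparison statistic; a
  dissimilarity-based variant would need only a different statistic but is
  not included.
- The factorial ANOVA refuses strongly unbalanced designs rather than
  implementing Type II/III sums of squares.
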