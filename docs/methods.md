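# Methods

## The design

A chromosome substitution strain (CSS) carries one donor-strain chromosome
on an otherwise host-strain background.  An F2 intercross from a CSS
therefore segregates 1:2:1 at every locus of that single chromosome and is
isogenic elsewhere: any genetic signal in a phenotype — behavioral or
transcriptomic — must map to the focal chromosome.  The package implements
the analysis chain that exploits this: map the behavior, map every
transcript, find co-expression modules correlated with the behavior, and
intersect the three lines of evidence to rank candidate genes.

## Simulated crosses (`cssqtl.sim`)

Gametes are two-state Markov chains along the marker map with switch
probability given by the Haldane map function,
`r = (1 − e^(−2d/100))/2` for d in cM (no crossover interference; adequate
for a single chromosome and exactly invertible in tests).  An F2 individual
is the union of two independent gametes; only females are modeled, so no
X-chromosome logic exists.  Genotype calls are dropped to missing
independently at a configurable rate (default 0.05); the pre-dropout calls
stay available as ground truth.

Behavioral traits follow

    y_t = a·x_add + d·x_dom + Σ_m γ_m·F_m + σ·ε_t

with additive coding x_add ∈ {−1, 0, +1} (donor homozygote → −1) and
dominance indicator x_dom.  Each planted co-expression module m has a latent
factor F_m shared between expression and traits whenever both are simulated
from the same seed; module members load on it with λ (their pairwise
correlation is then λ²).  A module factor may itself carry a genotype
loading δ, `F = δ·x_add/sd + √(1−δ²)·η`, making the module trans-regulated by
the QTL — the mechanism by which a cis-regulated hub gene can drive both a
pathway and a behavior.

Expression is generated on the log2 scale (baseline ≈ N(8.5, 1) for
expressed probes, N(4.5, 0.3) for "absent" probes) and exponentiated to raw
intensities.  cis genes get an additive shift at the marker nearest their own
position; trans targets respond to a regulator locus; SNP-in-probe artifact
probes lose intensity in proportion to donor-allele dosage (default 3 log2
units for the donor homozygote), which mimics a strong cis-eQTL.  Detection
p-values are Beta(0.1, 10) for expressed and Uniform(0, 1) for absent
probes, so the detection filter removes a tunable fraction.

### Default study conditions

The defaults emulate the motivating experimental regime and were fixed once:
57 genotyped and phenotyped females with expression on a 37-sample subset
(behavioral cohorts are typically larger than dissected ones); 33 markers at
~3 Mb / 2 cM covering a whole ~100 Mb chromosome, so genes can fall inside
or outside a support interval; 2000 probes with five 40-gene modules
(λ = 0.75); one trait-coupled module (γ = 1.3, δ = 0.5) and one weakly
negatively coupled module (γ = −0.8); behavioral additive effect a = 0.5, so
most of the QTL's effect on behavior flows through the module pathway.
Under these conditions the two traits correlate at r ≈ 0.75 and the
behavioral peak LOD is ~2–4 with support intervals of tens of Mb.  The
planted candidate gene sits at the QTL position with a 1.5 σ cis effect
inside the trait-coupled module; eleven competitor cis genes have graded
effects (0.9–1.5 σ), giving an eQTL LOD spectrum with a few strong hits and
a tail of marginal ones.

What the generator does **not** emulate: array background and spatial
artifacts, batch effects, non-Gaussian expression noise, crossover
interference, X-linked or sex-specific effects, epistasis, and
population-level LD beyond the cross.  Passing tests therefore show
correctness of the statistical machinery under the cross's idealized
generative model, not robustness to real-array nuisance structure.

## Preprocessing

Probes are kept when the detection p-value is below α (default 0.01) in at
least `min_detected_samples` samples (default 1 — the most permissive
reading; configurable).  Variance stabilization is `log2(x + 1)`; the
downstream analyses depend only on a monotone, roughly
variance-stabilizing transform, so array-model-specific transforms are not
re-derived.  Quantile normalization replaces each sample's sorted vector
with the across-sample mean of sorted vectors (ties get the average of the
tied reference values); it is idempotent.  Sample outliers are flagged (not
removed) when a sample's mean inter-sample correlation falls more than 3 SDs
below the cohort mean of that statistic.

## Interval mapping

Genotype probabilities come from a 3-state forward–backward pass with
Haldane transitions, genotyping-error emission (default 0.002; typed calls
are certain at error 0) and the F2 prior (¼, ½, ¼) — an individual with no
typed markers simply keeps the prior.  Pseudomarkers are inserted so
adjacent evaluation points are at most `step_cm` apart (default 1 cM);
their bp coordinates interpolate the marker map.

Multiple imputation samples full genotype vectors by forward filtering /
backward sampling, preserving linkage within a draw.  At each position the
2-df additive + dominance regression is evaluated as the genotype
group-means model (algebraically identical, and fast via group sums), and

    LOD = (n/2)·log10(RSS0/RSS1)

is combined across draws as `log10(mean_d 10^LOD_d)` — likelihood-scale
averaging, which reduces exactly to the closed form when data are complete.
A perfect fit (RSS1 < 1e−12·RSS0) is capped at LOD 50.  LOD curves are
invariant under affine transforms of the trait.  Support intervals are the
contiguous run of evaluation positions around the (leftmost) peak with LOD
within `drop` (default 1) of the maximum, reported in bp.

Behavioral significance uses the fixed single-chromosome rule LOD ≥ 1.5.
For one trait, a permutation threshold is the (1−α) quantile (upper order
statistic) of max-LOD over trait permutations.  For the transcriptome-wide
scan, permutations shuffle sample rows jointly across all probes
(preserving inter-gene correlation under the null) and the threshold is the
smallest t on a 0.01-LOD grid with estimated
`FDR(t) = mean permuted count(maxLOD ≥ t) / observed count(≥ t) ≤ target`
(capped at 1; +∞ with a warning if unattainable).  The exact construction
behind published single-number FDR thresholds of this kind is rarely
specified; the expected-exceedance estimator is this package's choice and is
calibrated on nulls in the test suite.

## Co-expression network

Unsigned adjacency `a_ij = |cor(x_i, x_j)|^β` with β = 7 (signed networks
are out of scope; the unsigned form is the classical default).  Topological
overlap

    ω_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),  l_ij = Σ_u a_iu·a_uj

is computed by matrix product; 1 − ω is clustered by average linkage.
Branches are cut at `cut_height` (default 0.99) **of the range between the
5th percentile and the maximum of the joining heights** — the
scale-adaptive variant of the static branch cut.  Soft thresholding with
β = 7 compresses dissimilarities into a narrow band just below 1, so an
absolute height of 0.99 is brittle: it recovers planted modules in some
datasets and shatters or merges them in others, while the relative cut
recovers λ = 0.7 five-module designs with ARI > 0.98.  Degenerate
dendrograms (all joins at one height) form a single module.  Candidates
smaller than `min_module_size` (default 25) are labelled `unassigned`;
labels are color names by descending size; unassigned genes are excluded
from eigengene significance by default (configurable).

The module eigengene is the first principal component of the z-scored
module block, scaled to unit variance (ddof = 1) and oriented to correlate
non-negatively with the module's mean standardized profile.  Eigengene
significance is the Pearson correlation with each trait and its two-sided
p from `t = r√(n−2)/√(1−r²)`, reported unadjusted (as is conventional for
per-module reporting; multiplicity is noted in outputs).

## Integration and ranking

An eQTL is *cis* when its gene resides on the focal chromosome — in a CSS
cross the focal chromosome is the only place an eQTL can map, so the
distinction is purely about the gene's own location (a distance-based
definition is available by configuration).  SNP-in-probe-flagged records
are removed from evidence but kept in an audit list and in the report with
evidence 0.  Genomic intervals are 1-based, closed at both ends.

Evidence per significant, non-artifact eQTL gene:

- significant cis eQTL;
- eQTL −LOD1 interval overlaps the behavioral −LOD1 interval — scored once
  per trait by default (published overlap tables grade exactly this way:
  "both traits" vs "one trait"), with an all-traits-or-nothing variant
  available;
- gene position inside the behavioral interval — likewise per trait;
- membership in a module whose eigengene is significant for **all** traits
  with a consistent sign (p < 0.05 default);
- gene–trait correlation significant for all traits (p < 0.05 default).

Ranking is the deterministic total order (evidence count desc, max
|gene–trait r| desc, gene symbol asc).

## Knockout behavioral statistics

The open-field comparison of knockout vs wildtype uses the classical
univariate two-factor repeated-measures decomposition; only the
between-subject genotype effect is reported, `F = MS_group /
MS_subject-within-group` with df (groups−1, subjects−groups), which needs no
sphericity correction.  Per-bin tests are pooled-variance t-tests (Welch
optional) with Bonferroni adjustment `min(1, p·m)`; both raw and adjusted
p-values are reported because published per-bin values are often printed
after adjustment without saying so.

## Numerical and validation notes

- All randomness flows from integer seeds through `numpy` `SeedSequence`
  spawning; identical seeds give byte-identical CLI outputs (floats are
  written with a fixed format).
- Oracles in the test suite are independent of the code paths they check:
  exhaustive 3-state enumeration for the HMM, direct `lstsq` regression for
  LOD, triple-loop topological overlap, power iteration for eigengenes,
  closed-form ARI cross-checked against scikit-learn, and pingouin's mixed
  ANOVA for the repeated-measures decomposition.
- Validation problem sizes (the package's own choices): 20 complete-data
  scan datasets for the regression oracle; 500 null datasets × 200
  permutations for type-I calibration; 100 simulations for QTL recovery; 50
  seeds for module recovery; 100 seeds for end-to-end candidate recovery.

## Known limitations

- −LOD1 support intervals are not confidence intervals: across the
  recovery experiments they cover the true QTL in roughly 75–90% of runs
  depending on effect size, and requiring a candidate to win interval-based
  evidence on *two* correlated traits compounds the miss rate.  In ~12% of
  end-to-end runs a competing linked cis gene captures the interval evidence
  and outranks the planted candidate; this is a property of the interval
  rule at these sample sizes, not of the implementation.
- The FDR threshold for the transcriptome scan depends on the number of
  probes, their correlation structure and the permutation count; it is
  internally calibrated but not comparable across datasets of different
  size.
- The static-height branch cut (even the relative variant) is cruder than
  hybrid dynamic branch cutting, which is deliberately out of scope.
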