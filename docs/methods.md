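# Methods

## Model and estimator

Protein-level selection on a tumor genome is summarised by the genome-level
dN/dS ratio. The coding reference is treated as one concatenated sequence;
per-codon site counting assigns each of the three codon positions a
synonymous fraction equal to the share of its three possible substitutions
that preserve the amino acid (standard genetic code, all nine neighbours
weighted equally), the remainder being nonsynonymous. Substitutions creating
a stop codon are counted as nonsynonymous, consistent with counting nonsense
mutations as protein-changing; codons that *are* stops are excluded (they
carry no protein-level information, and real CDS inputs only contain them
terminally or as annotation errors). Genes with internal stops, ambiguous
bases or length not divisible by 3 are skipped with a warning, never
repaired. These choices make the per-codon identity nN + nS = 3 exact.

With N nonsilent and S silent point substitutions in a sample and genome
site totals nN, nS, the estimate is (N/nN)/(S/nS). The estimator assumes
synonymous mutations are neutral and unsaturated; no
transition/transversion or trinucleotide-context weighting is applied, so
mutational-signature composition can bias estimates on real data (a known
limitation, isolated behind `site_model` so a weighted scheme could be
substituted).

Only point substitutions enter the counts. Missense, nonsense, nonstop and
translation-start-site labels are nonsilent; Silent/Synonymous are silent;
indels, splice and non-coding classes are `other` and excluded, because
codon-level dN/dS theory does not cover them. Published cohorts differ on
whether nonsense mutations were included in N; they are included by default
and a switch (`default_class_map(include_nonsense=False)`) exposes the
alternative.

## Validity gating

Small samples give unstable ratios. A sample is valid when N + S ≥ 10
(`min_mutations`, configurable) and S > 0; otherwise the estimate is flagged
with a reason code and excluded, never smoothed with pseudocounts. The
default of 10 is supported by `min_mutation_threshold`, which simulates
neutral samples of increasing burden m (each mutation nonsilent with
probability nN/(nN+nS)) and returns the smallest m whose estimator
distribution has ≥ 95% finite estimates and a median within 0.25 of 1. The
binding constraint is the finite-estimate clause: with a typical exome site
ratio nN/nS ≈ 3, P(S ≥ 1) ≥ 0.95 first holds near m = 11, the same order as
the conventional threshold. The criterion (tolerance, confidence) is
configurable since more than one reasonable formalisation exists; an
infinite tolerance disables the gate entirely. Whether the threshold should
apply to N + S or to S alone is ambiguous; N + S is used.

Replicate error is the pooled within-group standard deviation of dN/dS over
groups of same-patient, same-status replicates. At exome-typical burdens
(N + S ≈ 100) and a near-neutral cohort (true ω ~ N(0.9, 0.1), emulating a
cohort whose estimates concentrate just below neutrality), the pooled SD is
≈ 0.2 — order 0.1, dominated by counting noise: the estimator's relative SD
is ≈ √(1/N + 1/S).

## Region estimates and background attribution

Somatic mutations are sparse, so a gene region's own silent count is
supplemented with the sample's background silent mutations — those in genes
harbouring only silent mutations — attributed proportionally to the
region's share of synonymous-site mass: S_eff = S_region(non-background) +
B·nS_region/nS_total. Background genes are removed from the region's own
silent count first so nothing is counted twice; with the region equal to the
whole genome the formula reduces exactly to the plain sample estimate.
Synonymous-site mass is the attribution measure because it is the quantity
that scales expected silent counts; nucleotide length is available as an
alternative. Regions need ≥ 100 genes by default (`min_genes`), relaxable
for toy inputs.

## Clonal partition and AF windows

Trunk mutations are those whose identity key occurs in every sample of a
patient; the key uses the most specific information the input provides
(genomic position or protein change), falling back to gene + class + AF
rounded to 0.01. Branch mutations are each sample's remainder; leaves are
whole samples. Trunk, pooled-branch and leaf estimates share the validity
gate, and partitions are exact (trunk and branches disjoint, jointly
covering every observed mutation).

AF windows are half-open, (low, high], so windows partitioning [0, 1] are
exact; "AF > t" maps to (t, 1] and "AF < t" to [0, t). Records with missing
AF are skipped and counted. The AF-resolved analysis (`af_dynamics`)
computes, per patient with ≥ 5 samples, the Pearson correlation across
samples between windowed burden N and windowed dN/dS for each threshold and
panel; cells need ≥ 3 contributing valid samples. Correlations are never
pooled across patients, and AF is used only as an ordinal time proxy — no
CCF/purity adjustment and no calendar-time calibration.

## Paired regressions and the reference-model test

Each quantifiable patient (≥ 2 valid estimates) contributes ordered pairs of
consecutive samples. Ordering uses recorded timepoints; when absent or tied,
the sample with fewer mutations is taken as earlier (burden is near-monotone
in time), with sample-id as the final deterministic tie-break.

The cohort line is fitted by OLS (reported with slope/intercept p-values and
a 95% mean-response band) and, where outliers such as hypermutators occur,
by iteratively reweighted least squares with Tukey bisquare weights
(c = 4.685, ≤ 50 iterations, weight-change tolerance 1e-6). Two fitted
cohorts are compared by the nested extra-sum-of-squares F-test (pooled
single line vs. separate lines, F(2, n_a + n_b − 4)).

Deviation from a stable identity-line relationship is tested against an
artificial reference cohort (x_i, x_i + e_i) built from the observed fit's
residuals. Because least-squares residuals are orthogonal to x, the
reference fit is *exactly* the identity line and the reference set
contributes no independent error; the naive duplicated-sample ANOVA is then
conservative by exactly a factor of 2 in F and overstates its error degrees
of freedom. The default test therefore applies the exact correction —
statistic 2F against F(2, n − 2) — which coincides with the classical Wald
F-test of (intercept, slope) = (0, 1) and is exactly calibrated under
Gaussian noise (simulated type-I 0.051 at n = 30 over 3000 cohorts, power
1.0 against a contraction of slope 0.5 at noise sd 0.1). A
permuted-residual variant (`residuals="permuted"`), which is calibrated by
independence and needs no correction, is provided for sensitivity analysis.
These calibration statements are with respect to noise in the response
only: when both axes carry estimation noise (regression of estimated dN/dS
on estimated dN/dS), errors-in-variables attenuation biases the slope below
1 and the identity test picks that up as a real deviation — a property of
the design, not of the implementation, and the reason the estimator's own
noise is characterised separately.

## Survival analyses

Kaplan-Meier curves and log-rank tests use lifelines. Two scans relate the
selection regime to outcome. The range scan splits patients into
dN/dS ∈ [µ − σ, µ + σ] vs. outside, for every grid point. The paired scan
classifies each patient pair as *neutral* (in or approaching the neutral
regime) or *escape*: escape iff DIS ≥ dis_thr, or |Δ| ≥ delta_thr with
dN/dS₂ outside the strict neutral band 1 ± 0.1 — a large swing that lands
inside the band still counts as neutral. |Δ| (not signed Δ) is the default
because both exit directions leave neutrality; a signed option exists.
Prognosis direction per cell is the sign of the restricted-mean-survival
difference (to the last observed event time), which remains defined under
heavy censoring where medians may not. Cells with either group below 5
patients are masked. Raw p-value grids are reported without
multiple-testing correction, matching the heatmap convention; a
Benjamini-Hochberg overlay can be applied downstream and is deliberately
not part of the scan output.

Drug effects are summarised by a Cox proportional-hazards model whose
*duration* variable is DIS with every record an event — DIS is fully
observed, not censored — and per-drug 0/1 exposure covariates. HR > 1 means
exposure is associated with smaller distance from neutrality (the drug
pushes tumors toward the neutral regime). This construction is unusual; the
conventional alternative (survival time as duration, DIS and drugs as
covariates) is provided as `cox_survival_with_dis`. Drugs lacking both
exposed and unexposed patients are dropped with a warning, as are drugs
that break convergence.

MSI classification of a provided instability score uses the fixed rule
score > 3.5 ⇒ unstable, with the boundary value itself classified stable;
the score computation is out of scope.

## Synthetic cohorts

The generator produces everything the pipeline consumes, deterministically
from one seed. Defaults are the study conditions of the validation suite:

* reference: 120 genes × 300 codons drawn uniformly from the 61 sense
  codons (site ratio nN/nS ≈ 3, like a real exome);
* per-sample burden: log-uniform over [100, 5000] mutations, spanning the
  range of real whole-exome samples; 5% of patients get a deliberately
  sub-threshold sample so the validity gate is exercised;
* selection: ω₁ log-uniform on [0.3, 3] (wide inter-patient spread around
  neutrality); ω₂ = 1 + κ(ω₁ − 1) + N(0, 0.1), κ = 0.5 by default — the
  contraction-toward-neutrality regime of treated resistant cohorts; each
  mutation is nonsilent with probability ω·nN/(ω·nN + nS), genes drawn by
  class-matching site mass;
* clonal structure: trunk ω = 1.5 at AF ~ Beta(8,8) scaled to (0.3, 0.6),
  branch ω = 0.7 at Beta(2,8) on (0, 0.35) — straddling the conventional
  early (AF > 0.25) and late (AF < 0.33) window anchors;
* survival: event times exponential with hazard h₀·exp(β(c − DIS)),
  h₀ = 0.05/month, β = 2, c = 0.5, 20% censoring — near-neutral patients
  fail faster;
* drugs: multiplicative effects on the DIS scale (effect 0.5 ⇒ true HR 2).

The generator reproduces the statistical structure the analyses assume —
binomial class splits, shared trunks, AF-ordered compartments, a
DIS-dependent hazard — but not per-gene mutation-rate heterogeneity
(a gamma-rate option exists for stress-testing background attribution),
trinucleotide signatures, forward-time clonal dynamics, or calling/coverage
artefacts. Passing tests therefore demonstrate correctness and calibration
of the estimators and tests under their stated assumptions, not robustness
to every real-data pathology.

## Validation scales and numerical choices

The test suite and `scripts/acceptance.py` use problem sizes chosen to pin
each property with comfortable statistical margin on a single CPU: 200
replicates at 10⁴ mutations for estimator recovery (mean within 5% of ω over
ω ∈ [0.3, 3]); 500/2000 cohorts of 30 patients for reference-test power and
type-I; 40 cohorts of 200 patients per κ for slope recovery; 200 simulated
patients for trunk/branch sign recovery; 40 cohorts of 200 for scan power
and 20 null cohorts (~180 cells) for scan calibration; 100 cohorts of 500
for Cox CI coverage. Ties in ranks and survival times are handled by the
default scipy/lifelines conventions (tie-corrected normal approximation;
Efron approximation). Degenerate inputs — zero-variance regressors,
all-censored groups, empty windows, constant correlation inputs — return
flagged/invalid results or typed errors rather than NaNs leaking through.
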