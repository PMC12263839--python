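# tumordnds

Genome-level selection analysis of multi-sample tumor cohorts: per-sample
dN/dS estimation from somatic mutation tables, shift-to-neutrality tests
across ordered sample pairs, survival scans linking selection regimes to
clinical outcome, and allele-frequency-resolved selection dynamics — with a
seeded synthetic-cohort generator so the whole pipeline can be exercised and
validated without any patient data.

## The scientific problem

The selection regime of a tumor genome — positive selection of drivers
(dN/dS > 1), effective neutrality (dN/dS ≈ 1), or purifying selection
against deleterious passengers (dN/dS < 1) — is a compact, per-sample
summary of how the tumor is evolving. In patients with two or more sequenced
samples (regional primaries, primary vs. metastasis, pre- vs.
post-treatment), comparing the earlier and later dN/dS asks whether natural
progression or therapy changes that regime. A systematic contraction of
dN/dS toward 1 in tumors that resist treatment, and worse survival for
patients in or approaching the neutral regime, make the selection regime a
candidate resistance biomarker. This package implements that analysis chain
for anyone working with MAF-style somatic mutation tables and clinical
follow-up.

## The estimator

The exome is treated as one concatenated coding sequence. From a CDS FASTA,
each sense codon contributes fractional site counts — position-wise, the
share of its three single-nucleotide substitutions that preserve the amino
acid is synonymous; substitutions creating a stop are protein-changing — so
each codon contributes nN + nS = 3 sites. With N nonsilent and S silent
point mutations in a sample,

    dN/dS = (N / nN) / (S / nS)

Estimates are gated: a sample needs N + S ≥ 10 total mutations and S > 0,
otherwise it is flagged invalid rather than smoothed. The threshold of 10 is
itself recoverable by simulation (`min_mutation_threshold`): the smallest
burden at which a neutral genome's estimator distribution is centred on 1
with ≥ 95% finite estimates.

On top of the per-sample estimate the package provides

* region-level dN/dS with background-silent attribution (silent mutations in
  genes harbouring only silent mutations, attributed proportionally to the
  region's synonymous-site mass);
* trunk/branch partitions of multi-sample patients (mutations shared by all
  samples vs. private) with per-compartment dN/dS;
* AF-windowed estimates, `(t, 1]` for early/clonal-enriched and `[0, t)` for
  late/subclonal-enriched mutations;
* paired regressions (`dN/dS_2 = a·dN/dS_1 + b`, least-squares and Tukey
  bisquare), the two-line extra-sum-of-squares ANOVA, and the
  reference-model test of deviation from the identity line at the data's own
  residual noise;
* Kaplan-Meier scans: the (µ ± σ) range scan and the paired (DIS, Δ)
  neutral-vs-escape scan, with DIS = |1 − dN/dS₂| and Δ = dN/dS₂ − dN/dS₁;
* Cox proportional-hazards summaries of per-drug effects on the distance
  from neutrality (HR > 1: the drug pushes tumors toward the neutral regime).

## Worked example

The numbered scripts under `analysis/` run the full chain on a synthetic
cohort of 100 two-sample patients whose later selection strength is
contracted halfway toward neutrality (κ = 0.5):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_estimate_selection.py
python analysis/03_pair_regressions.py
python analysis/04_survival_scans.py
python analysis/05_af_dynamics.py
```

which prints (abridged):

```
200 samples profiled; 195 valid, 5 gated out
median dN/dS of valid samples: 1.031
simulation-derived minimum burden: 11 mutations
replicate error at ~100 mutations/sample: 0.190 (order 0.1)

95/100 patients quantifiable (95 pairs)
LMS fit: slope=0.438, intercept=0.574, R^2=0.758 (p_slope=2.04e-30)
identity-reference ANOVA: F=278.78 df=(2,93) p=5.21e-40
=> the cohort's later samples shifted toward neutrality

range scan: ... mu=1.0 sigma=0.2 p=0.0001 in_group_worse
trunk dN/dS = 1.33 (> 1: positive selection)
branch dN/dS = 0.63 (< 1: purifying)
mean Pearson r(N, dN/dS): early windows +0.70, late windows -0.90
```

Read: the fitted slope ≈ 0.44 recovers the generative contraction κ = 0.5
(the intercept 1 − slope ≈ 0.56 places the fixed point at dN/dS = 1); the
reference-model ANOVA rejects a stable identity-line relationship; the
survival scan flags patients inside the neutral band 1 ± 0.2 as the
worse-prognosis group; and the clonal trunk / subclonal branch estimates
bracket neutrality from above and below.

The same stages are available as a CLI over real cohort files
(`tumordnds estimate|pairs|scan|af|simulate|all`, see `tumordnds --help`),
expecting a MAF-like TSV (`Hugo_Symbol`, `Variant_Classification`,
`Tumor_Sample_Barcode`, optional read counts/AF), a per-sample metadata TSV
and a clinical TSV with `drug_*` indicator columns.

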