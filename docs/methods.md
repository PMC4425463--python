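# Methods

## The problem

Two components of the somatic genome vary with an individual's state
rather than their inherited sequence: the number of mitochondrial
genome copies per cell, and the length of the telomeric repeat tracts
capping each chromosome. Both have been linked to chronic stress and
to major depression (MD). Quantifying them from low-coverage
whole-genome sequencing is attractive — no extra assay — but both
measures are ratios of read counts and inherit every bias of the
sequencing run, so the pipeline is mostly a chain of corrections. The
inferential question downstream is structural: whether adversity
(stressful life events, SLE; childhood sexual abuse, CSA) changes the
markers directly, whether the markers mediate the path from adversity
to MD, or whether marker changes are contingent on the depressed state
itself.

## mtDNA abundance

Depth on the mitochondrial reference, relative to nuclear depth, is
proportional to mtDNA copies per cell (with a factor of 2 for the
diploid nucleus — a convention, stated here because calibration
depends on it). Three corruptions are handled in order:

1. **Alignment quality.** Reads are kept when MAPQ ≥ 59 and
   FLAG ∧ 1804 = 0. The MAPQ floor ("≥ 59") is read as a Phred-scale
   mis-mapping bound just under the aligner's 60 cap; the FLAG mask
   excludes unmapped, mate-unmapped, secondary, QC-fail and duplicate
   records. Bacterial contaminants in the simulation carry low MAPQ
   and the QC-fail bit, so this single filter removes them — the
   package treats alignments (including any contaminant screening
   encoded in MAPQ/FLAGs) as inputs.
2. **NUMTs.** Nuclear copies of mitochondrial sequence make depth
   locally uninterpretable: reads of true mitochondrial origin inside
   a NUMT-homologous window lose mapping confidence (filtered depth
   drops) and reads of the nuclear copy appear as secondary
   alignments (unfiltered depth rises). Rather than a fixed exclusion
   list, affected 100-bp segments are detected per the data: a segment
   is excluded when unfiltered − filtered depth exceeds 5% of the
   filtered depth. Segments with zero filtered depth are excluded too
   (the relative rule is undefined at 0, and they carry no signal).
   The depth excess is non-negative by construction whenever the
   filtered reads are a subset of the unfiltered reads.
3. **Sample-level nuisance.** The raw measure (mean filtered depth
   over retained segments) is regressed on sequencing batch
   (indicator-coded, first level as reference), age, and mean filtered
   depth on a nuclear proxy region (default: a chromosome-20 segment;
   whether the original covariate was all of chr20 or a subset is not
   determinable, so the region is configurable). One joint multiple
   regression is used rather than sequential residualisation — the
   natural reading of "regress on A, B and C" — and the residuals are
   mapped through the rank-based inverse normal transform.

The transform uses Φ⁻¹((r − ½)/n) with average ranks for ties; the
offset is configurable (Blom's 3/8 variant is one switch away) because
conventions differ and nothing downstream depends on the choice.

## Telomere length

Telomeric tracts are pure TTAGGG repeat, so reads from them are
recognisable by content alone: ≥ 7 non-overlapping repeat units on
either strand (TTAGGG or CCCTAA), the convention of repeat-counting
telomere estimators. The count t is normalised by a coverage
reference s — reads whose GC fraction falls in [0.48, 0.52], bracketing
the repeat's own 50% GC — which cancels total sequencing depth and
first-order GC bias in one step. Reads mapped to the mitochondrial
reference are excluded from s because mtDNA depth varies enormously
between samples and the denominator must track nuclear coverage only.

The scaling

    length_kb = (t / s) × genome_scale_kb / n_ends

spreads total telomeric content over n_ends = 92 tract ends (46
chromosomes × 2). `genome_scale_kb` — the genome equivalent
represented by s — is the one quantity with no principled universal
value: it depends on the read length and GC window via the acceptance
probability of the reference reads. The simulator provides its own
calibration (`simulation_genome_scale_kb`), under which true lengths
of 5/10/20 kb are recovered at 5.0/10.0/21.1 kb; for real data the
absolute scale should be treated as uncalibrated and only ranks,
ratios, and normalised scores interpreted. Depth invariance holds to
~2% at a threefold coverage change (Poisson noise only; both counts
scale together).

Normalisation matches the mtDNA marker with covariates batch and age
only (the coverage correction is already inside the ratio).

## Association models

Case-control association uses maximum-likelihood logistic regression
of MD status on the normalised marker plus covariates (by default the
first three genetic principal components, supplied as table columns —
no genotype processing happens here). Effects are reported per marker
SD as odds ratios with Wald 95% CIs (exp(β ± 1.96·se)); Wald rather
than profile intervals matches the symmetric intervals these analyses
conventionally print. Perfect separation is flagged
(`converged=False`) rather than raised; collinear designs (e.g. the
marker duplicated as a covariate) raise immediately — never silent.
Adversity models use OLS of the marker on SLE count or ordinal CSA
coding, same reporting in slope form.

## Conditional inference

The decision procedure encodes three competing structures as
significance patterns over four fitted quantities (α = 0.05 default,
two-sided throughout, no multiplicity correction — these are a priori
contrasts):

- p(SLE) and p(marker) in logistic `MD ~ SLE + marker + covars`;
- p(SLE) in linear `marker ~ SLE + MD + covars`;
- the per-stratum case-control p-values from the SLE-stratified table
  (strata 0, 1, 2, 3, 4+; group SE = SD/√n; t from summary statistics
  with a normal-approximation p above a combined n of 100, else
  Welch–Satterthwaite).

Classification:

- **STATE_DEPENDENT** — SLE predicts MD given the marker, the marker
  predicts MD given SLE, the marker–SLE association is absent given
  MD, and at least one stratum shows a case-control contrast. The
  last two conditions are part of the definition here because they are
  the actual evidence for state dependence (persistent stratified
  differences plus a vanishing conditional association); they also
  keep the null false-call rate near α³ rather than α.
- **MEDIATED** — SLE no longer predicts MD once the marker is in the
  model, while the marker does.
- **INDEPENDENT** — no stratified contrast, but a marginal marker–SLE
  association exists.
- **INCONCLUSIVE** — anything else.

The verdict is a pure function of the stored p-values and α, so it is
reproducible from the returned object and invariant to sample order.

In published summary tables of this design, recomputing t from printed
(rounded) means and SEs reproduces the printed t statistics only to
about 2% relative — that tolerance is input rounding, not method
disagreement. Two typographic anomalies in the source summaries (a
conditional p printed as "2.x10^−100", a negative "SE") are treated as
unusable and never asserted against.

## qPCR

Relative quantification is the efficiency-corrected ΔΔCq ratio
(1+E)^(−ΔCq_target) / (1+E_ref)^(−ΔCq_ref), each ΔCq against the
baseline group's mean Cq; E defaults to 1 (perfect doubling), making
the ratio exactly 2^(−ΔΔCq). Baseline ratios therefore have geometric
mean 1; the exact arithmetic mean-1 normalisation used in time-course
figures is a separate explicit step (`fold_change`). The T/S telomere
measure is the same computation with (telomere, single-copy gene)
targets.

The run-QC list is phrased in the laboratory literature as criteria a
run "fails to meet", yet enumerates failure conditions; it is
implemented as discard conditions — NTC Cq < 38 (contamination),
sample Cq > 30 (too little template), efficiency outside 90–110%,
standard-curve R² < 0.980, replicate-group Cq SD > 0.20 — because the
literal reading (keep runs whose no-template control amplifies early)
is biochemically inverted. Missing metrics mark the rule
not-evaluable and flag the run rather than passing it.

## The synthetic-data generator

**Reads.** One sample is a mixture over origins, all Poisson-sampled:
nuclear reads on a 2-Mb chromosome-20 proxy at 1.7× (the study-scale
coverage); mitochondrial reads at depth = nuclear × copies/2 on a
circular 16,569-bp genome (origin-spanning reads split in two), with a
default of 120 copies/cell so mitochondrial coverage lands near the
~102× seen at scale; NUMT confounding as described above, with
per-read ambiguity probability (1 − divergence)^read_length (the
chance a 100-bp read samples no diverged site); bacterial contaminants
(default 1% of mitochondrial-aligned reads, MAPQ 20 + QC-fail flag);
and unplaced pure-repeat telomeric reads at rate
depth × 92 ends × length / (2 × read length), default 5 kb/end. A
single seed drives fixed-offset sub-streams, so equal configurations
are byte-identical. Truth origins ride in a side column (SAM tag `XO`)
that estimators never read — enforced by a shuffle test.

Not emulated: sequencing error, real mitochondrial or bacterial
sequence, interstitial telomeric repeats, GC-coverage coupling beyond
base composition, saliva cell-mixture composition (its measured
contribution to the case-control marker differences was under 10%).
Passing read-level tests therefore demonstrates correctness of the
counting/masking logic and depth algebra under the stated mixture, not
robustness to those real-data artifacts.

**Cohorts.** SLE ~ Poisson(1.2) (rate matched to the stratified-table
margins at scale); CSA a 4-level ordinal with probabilities
(0.938, 0.023, 0.024, 0.015); batch, age and PCs enter the markers
with small configurable effects (defaults 0.05 SD batch spread,
0.005 SD/yr, 0.02 SD/PC). Three scenario kinds fix which causal paths
exist; each declares only its own parameters (anything else non-zero
is rejected). Defaults: baseline prevalence 0.5 (case-control
design); state-dependent marker shifts ln(1.33) = 0.285 SD for mtDNA
and ln(0.85) = −0.163 SD for telomere (so a logistic fit recovers the
per-SD odds ratios these cohorts print, via the normal-discriminant
equivalence); SLE→MD log-odds ln(1.6)/event, a literature-typical
figure for the strong documented association; mediation defaults
0.1 SD/event and 0.3 log-odds/SD. The cohort carries two markers but
one primary scenario drives MD (a secondary scenario may add the
telomere marker's terms into the same logit); state-dependent shifts
are applied to the realised disease state after the Bernoulli draw, so
marker ⫫ SLE | MD holds exactly by construction.

**Plates.** Cq = base − log(quantity)/log(1+E) plus N(0, 0.05²) cycle
noise, duplicate wells, fixed NTC at Cq 40. Mouse-style time courses
program a 2.4× mtDNA rise and 0.7× telomere fall at week 4 — the
magnitudes reported for chronic stress in blood/saliva, read as fold
changes against a week-0 mean of 1.

## Study sizes and numerical choices

The validation studies use: a 200-sample read-level grid over
copies ∈ {100, 200, 400, 800} (batch and age assigned balanced across
levels, as a validation experiment would be designed — randomly
confounded covariates would let the nuisance regression fit chance
correlations with an 8-fold copy spread); telomere recovery at
5/10/20 kb and a 1.7×→5.1× depth change; 500 null cohorts of 2,000
for type-I error; 100 cohorts of 10,000 for OR recovery and CI
coverage; 50 cohorts of 10,000 per scenario for classification rates.
With four tied truth levels the attainable Spearman ρ is ≈ 0.97, not
1, which the recovery threshold (≥ 0.95) respects. The full suite and
the reproduction script each run in well under five minutes on one
CPU.

Degenerate inputs are contracts, not surprises: zero retained
segments and zero coverage-reference counts raise `NoSignalError`;
all-equal values reject the rank transform; constant covariates are
dropped with a warning; empty strata record NaN contrasts; a MEDIATED
scenario with all-zero effects warns but runs.

## Known limitations

Absolute telomere kb and absolute copies-per-cell are calibrated only
under the simulator's own conventions. The NUMT rule is a per-sample
data filter, not an annotation-based mask, and will also exclude
segments inflated by any other multi-mapping source. The
classification procedure is significance-pattern logic, not a formal
mediation decomposition (no natural direct/indirect effects), and its
labels inherit the power of its component tests: under weak effects
it returns INCONCLUSIVE rather than guessing. The exact covariate
sets used in the original cohort models (beyond three PCs) are not
recoverable; covariates are therefore fully configurable everywhere.
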