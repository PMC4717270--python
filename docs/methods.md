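# Methods

## Background and scope

`proturn` analyzes heavy-label (²H₃-leucine) diet-switch proteomics time
courses of the kind used to measure protein turnover in mouse skeletal
muscle: animals are moved to a diet in which light leucine is fully replaced
by deuterated leucine, cohorts are sacrificed at fixed labeling times, and
peptide isotopologue envelopes quantified from MS1 peak areas are converted
into percent newly synthesized protein, per-protein half-lives, group
comparisons of turnover, and differential protein abundance. The package
starts from label-count-resolved envelopes (the granularity at which
turnover software such as Topograph emits its quantitation); raw spectrum
processing, peptide identification, and natural-abundance isotope fine
structure are out of scope.

## Forward model

For a protein with first-order turnover rate k = ln(2)/t½, the fraction of
its pool synthesized after the diet switch is

    f(t) = 1 − e^(−k·t).

A peptide carrying n leucines occupies label-count channels 0..n.
Pre-existing molecules are fully unlabeled (channel 0); newly synthesized
molecules draw each leucine independently from the free-leucine precursor
pool, which is heavy with probability p (the pool enrichment), giving a
Binomial(n, p) channel distribution. The observed envelope is the mixture

    m(f, p) = (1 − f)·e₀ + f·Binomial(n, p).

The simulator applies this model per peptide and sample, with
multiplicative mean-one log-normal noise of configurable coefficient of
variation on channel intensities and whole-envelope missingness completely
at random. Pool enrichment is constant at `enrichment_max` by default
(p = 0.5), optionally rising as p(t) = p_max·(1 − e^(−r·t)) and optionally
group-specific; published studies of this design rarely report the achieved
enrichment, so it is a parameter, not an assertion.

## Deconvolution and enrichment estimation

Given p, the mixture is linear in f, so the constrained least-squares
estimate on the unit-normalized envelope has a closed form: the projection
coefficient of (x − e₀) on (b − e₀), clipped to [0, 1], where b is the
binomial channel distribution. The inversion is exact (zero residual)
whenever the envelope lies on the model manifold, and is invariant to
envelope scaling.

Pool enrichment is estimated per sample by minimizing the summed
least-squares objective over p ∈ [0, 1], with each peptide's f profiled out
at fixed p. Peptides with a single leucine are excluded (`min_leu = 2`):
for n = 1 the envelope is [1 − fp, fp], so only the product fp is
identified; envelope shape beyond the all-or-none channels is what pins p.
The optimizer is a deterministic 101-point grid scan followed by bounded
Brent refinement (xatol 1e-10). On noiseless multi-peptide samples this
recovers p to well under 1e-6; with known p the whole inversion chain is
exact to machine precision.

Cross-run transfer of peptides quantified in only one run uses an ordinary
least-squares line between shared retention coordinates (retention time and
scan number are treated interchangeably as a 1-D coordinate), with a match
window of 3 residual standard deviations on either side of the predicted
coordinate. The window multiplier is a convention; no standard rule exists.

## Turnover kinetics

Percent newly synthesized follows y(t) = 100 + β₁·e^(αt); taking
ln(100 − y) linearizes it. Per protein and group, the package fits

    ln(100 − y_ij) = b_i + α·t_j

by unweighted least squares with one intercept per peptide (the blocking
factor absorbing peptide-specific offsets) and a common slope α.
β₁ is reported as −exp(mean bᵢ) and is not constrained to −100, i.e.
y(0) = 0 is not imposed. The half-life is t½ = ln(2)/|α| (slopes of the
log-survival regression are negative by construction; the absolute value
guards against sign conventions). Observations at y ≥ 100 are clipped to
100 − ε with ε = 0.01 before the transform. Observations slightly below
zero (possible for noisy measurements of slow proteins at early times) are
left as-is — the transform handles them naturally and clipping them would
bias the fit. All-zero measurements give α = 0 and an infinite half-life,
flagged rather than raised. Slopes within 1e-12 of zero are snapped to
zero: they are machine noise from an exactly constant response.

Group comparison is ANCOVA on the joint log-linear model: intercepts per
peptide-within-group, a common slope, and a group × time interaction whose
coefficient is Δα = α_B − α_A. The reported p-value is the interaction
t-test. Per-group intercepts make the test robust to group-level envelope
offsets (for example unequal pool enrichment). When the joint fit has
residuals at machine precision the t-test is meaningless and the exact
answer is reported instead (p = 1 for a zero interaction, p = 0 otherwise).
q-values are computed over all proteins within each contrast (per-muscle
family), and direction labels follow the half-life: Δα > 0 at q below the
threshold is "longer_lived". Proteins whose half-life exceeds 365 days in
any group are excluded from all summaries, as is conventional when the
labeling window is a few weeks: such slopes are dominated by noise.

The nonlinear form could be fit directly; the log-linear fit is primary
because the error model (multiplicative on the surviving fraction) makes it
the exact maximum-likelihood regression, and it is what the classical
ANCOVA machinery applies to.

## Measurement-level noise convention for calibration studies

`simulate_percent_new_measurements` generates percent-new observations with
multiplicative log-normal noise on the *surviving* (unlabeled) fraction,
i.e. iid Gaussian noise with the stated SD on ln(100 − y). This matches the
fitted model exactly, so the ANCOVA interaction t-test is exactly
calibrated under the null — the property the calibration suite verifies.
Channel-intensity noise propagated through deconvolution is heteroscedastic
on the log-survival scale (the error SD grows with f and hence with time),
so full-pipeline p-values are approximate; with balanced designs the
deviation is modest, and the full-pipeline recovery and change-count tests
quantify the practical consequence. This is a known limitation shared by
any log-transform regression on ratio data.

## Differential abundance

Per protein, log2 peptide AUCs are modeled with one intercept per peptide
plus a group effect, estimated by OLS; the group coefficient is the log2
old/young fold change and its t-test the p-value. This reduces to a
two-sample t-test for a single peptide while sharing the contrast across
peptides otherwise, and is invariant to rescaling any single peptide's
areas. Areas are log-transformed because MS1 peak-area noise is
multiplicative; base 2 is presentation only. Missing observations are
dropped per observation; there is no imputation and no cross-run
normalization beyond the peptide blocks.

Multiplicity is adjusted with Benjamini–Hochberg step-up q-values by
default. Storey's estimate (π₀ at λ = 0.5 multiplying the BH values) is
available as `method="storey"` for closer fidelity to q-value-package
conventions; BH is the default because it is deterministic and
assumption-light.

Mitochondrial content per sample is the summed AUC of annotated
mitochondrial proteins over the total AUC; unannotated proteins count
toward the denominator only. Group differences use a two-sided two-sample
t-test on per-sample fractions.

## Reporting surfaces

Compartment annotation maps reference identifier lists (mito and cyto, in
the style of a mitoP2-like reference) onto detected proteins, with mito
taking precedence on conflict (logged). Half-life summaries report median,
mean and count per stratum (total/mito/cyto × group) after the one-year
exclusion — medians are the headline statistic because a handful of very
long-lived proteins dominates means. Change classification counts
longer/shorter/unchanged per contrast (the three counts partition the
tested set) and reports Venn overlaps across contrasts twice: restricted
to proteins tested in both muscles and unrestricted, because the natural
denominator is ambiguous. Gene-set enrichment uses the one-sided Fisher's
exact test on the hit/non-hit × in-set/out-of-set table, the overlap ratio
(hits in set over set size within the universe), and excludes sets with
fewer than 4 hits before computing q-values. The abundance–turnover
correlation regresses the log2 old/young half-life ratio on the log2
abundance fold change and reports r², slope, intercept and p; log-ratio
axes are a choice, made because both quantities are naturally ratios.

## Synthetic study defaults

The default study design is four labeling times {3, 7, 12, 17} days, four
animals per group, and young/old cohorts for two muscles (EDL and SOL as
generic fast/slow labels). Ground-truth half-lives are log-normal with
median 22 days and log-SD 1.0 — centered on published muscle-proteome
medians, with a tail beyond a year so the exclusion rule has work to do.
Compartment proportions default to 35% mito / 21% cyto / 44% other,
matching a mitochondria-enriched fraction. Peptides per protein are
truncated-Poisson (mean 4, minimum 1); leucine counts are Poisson (mean
1.5) reflecting ~10% leucine frequency in tryptic peptides; ionization
factors are log-normal. Channel noise CV defaults to 0.15 and envelope
missingness to 10%. Simulated data are label-count resolved and carry no
chromatographic peak shapes, identification errors, charge states, or
natural-isotope structure — so passing tests demonstrate correctness of
the statistical pipeline on its stated input granularity, not robustness
to upstream spectral artifacts.

An aged-group half-life multiplier per protein (default 1, no change)
drives turnover-change scenarios; a per-compartment log2 abundance effect
drives content-change scenarios. The validation suite's two-muscle study
uses 120 proteins with longer-lived mito proteins (median 35 vs 18 days,
log-SD 0.3), a +0.6 log2 mito-skewed abundance increase with age in the
fast muscle, and 50 slowed (×1.6) plus 7 accelerated (×0.6) proteins in the
slow muscle — sizes chosen so each stage's power is high while the whole
study runs in well under a minute on one core.

## Numerical and degenerate-input conventions

- All model envelopes are normalized and sum to 1 within 1e-9; deconvolved
  f̂ always lies in [0, 1].
- Peptides without leucines are uninformative and excluded from
  deconvolution (error at the single-envelope API, silent drop at the table
  level); zero-intensity envelopes are an error.
- Fewer than 3 alignment anchors, fewer than 2 distinct time points, a
  group absent from a contrast, fewer than 3 correlation pairs, a constant
  correlation predictor, and an empty enrichment universe are all explicit
  errors with stable messages.
- The enrichment optimizer and all fits are deterministic given inputs;
  simulation is reproducible to the byte for a fixed seed.

## Known limitations

- The enrichment objective treats the pool as a single well-mixed
  compartment; amino-acid recycling is represented only through the
  enrichment parameter itself.
- ANCOVA p-values from the full envelope pipeline inherit mild log-scale
  heteroscedasticity (see above).
- Fixed-effect peptide blocks assume peptide offsets are stable across
  samples; no hierarchical shrinkage is applied.
- Storey's π₀ uses a single λ rather than the smoother fit of the original
  implementation.
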