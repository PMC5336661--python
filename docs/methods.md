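# Methods

## Multi-state model

States are observed at interviews only; the model is a time-homogeneous
continuous-time Markov chain with intensity matrix Q(z) whose allowed
off-diagonal entries follow a proportional-intensity regression
q_rs(z) = q_rs⁰·exp(β_rsᵀz). Covariates are baseline values (the subject's
first record), so intensities are constant over follow-up for a given subject;
age enters the analysis through the Cox engine's time scale, not through the
intensities. The likelihood over a subject's observation sequence multiplies:

- **observed interval r→s of length Δt**: P_rs(Δt) = [exp(Δt·Q(z))]_rs, the
  standard interval-censored panel term (the path between visits is unknown);
- **death at exact age** after a last living observation in r:
  Σ_u P_ru(Δt)·q_u,death(z), summing over the unobserved living state at the
  instant before death — deaths are registry-dated, not interval-censored;
- **loss to follow-up**: treated as non-informative administrative right
  censoring, contributing nothing past the last observation. An optional
  "alive, state unknown" term (Σ over living states at the censoring age) is
  available behind `censored_policy="alive_unknown"` for data where a
  subject is known alive at a wave but unexamined.

Observed transitions with zero probability under the structure (e.g. recovery
out of dementia) make the subject's contribution −∞ rather than raising, so a
mis-specified structure surfaces as an infinite deviance, not a crash.

**Structures.** The four-state structure (CN ⇄ MCI, CN→dementia,
MCI→dementia, all living→death, dementia absorbing except into death) serves
the clinical-MCI analyses; the three-state structure (CN ⇄ MCI-TB,
both→death) serves the test-based ones, where dementia is not separated.
Misclassification (hidden-Markov) estimation and time-inhomogeneous
intensities are out of scope.

**Estimation.** The per-subject-mean log likelihood is maximised by BFGS
(normalising by subject count keeps the objective O(1) regardless of cohort
size). Initial baseline intensities are crude rates — observed panel jumps
over exposure time in the source state — with covariate effects starting at
zero; `multistart=k` adds k starts with intensities jittered by up to ±50% on
the rate scale and keeps the best final likelihood. Standard errors come from
inverting a central-difference observed-information matrix (step 1e-4 on log
intensities and log hazard ratios, both O(1) parameters); Wald 95% intervals
are exp(β ± 1.96·SE), which matches the asymmetric intervals such models
report. When a transition saw no events its log intensity drifts to −∞ and
the information matrix acquires a flat direction; the curved submatrix is
inverted and only the flat parameters get NaN variances. A transition with no
observed panel jumps at all is flagged as non-identifiable on the results
object.

**Matrix exponential.** Each likelihood evaluation needs exp(Δt·Q(z)) for one
small matrix per observation interval (thousands per evaluation, since z
differs by subject). These are computed by a vectorised scaling-and-squaring
Padé [7/7] approximant over the whole stacked batch (`_linalg.expm_batch`),
with the scaling power set by the largest 1-norm in the stack — the norms here
are at most a few units, so the shared power costs little. Tests verify
agreement with `scipy.linalg.expm` to 1e-10 and with direct integration of
the Kolmogorov forward equations dP/dt = PQ to 1e-6, plus the
Chapman–Kolmogorov identity and two-state closed forms.

## Cox model on the age time scale

Age, not time-on-study, is the time scale: a subject enters the risk set at
their baseline age (left truncation) and exits at their event or censoring
age, so risk sets at an event age a are {entry < a ≤ exit}. Event age for a
diagnosis made at wave k is the age at wave k (not an interval midpoint);
since wave ages produce heavy ties, the Efron correction is the default tie
handler. Newton–Raphson with step halving iterates to gradient norm < 1e-8;
a coefficient exceeding 10 in absolute value (hazard ratio > e¹⁰) is taken as
a monotone partial likelihood (separation) and flagged rather than reported as
converged. Harrell's C counts pairs (event i, comparator j) usable under
delayed entry — entry_j before and exit_j after the event age — scoring ties
in the linear predictor 0.5; its SE uses the first-order U-statistic
(projection) variance of per-subject mean kernels. The Cox engine is written
in-package; `lifelines` serves as an independent oracle in the tests (exact
agreement on tied, left-truncated data) rather than as the implementation.

## Risk index

Per-category point values for the eleven sub-indices live in a YAML config;
the shipped `adri_default.yaml` is a **synthetic** table — the published
per-category points are not reproduced here — constrained so the sub-index
minima sum to −13 and maxima to +19, preserving the instrument's raw range,
sign convention (protective factors negative) and the +13 shift to 0..32.
Rules fixed by the instrument itself are code, not config: sex-specific
light-to-moderate alcohol bands (0.25–20.5 drinks/week for men, 0.25–13.5 for
women, with intake below 0.25 counted as abstaining — the published bands
start at 0.25, so the (0, 0.25) gap is resolved downward), PHQ-9 strictly
greater than 10 for depression, physical-activity hours weighted 1/2/3 for
mild/moderate/vigorous, and the unavailable fifth social-engagement domain
computed pro rata as the mean of the four observed domains. Absent variables
contribute zero points and are listed on the returned score; scoring a value
with no configured category is an error naming the sub-index. The three
sub-indices never available here (cholesterol, fish intake, pesticide
exposure) are simply absent from the config schema.

## Genetic score

EV-GRS = Σ_j ln(OR_j)·√(2·MAF_j(1−MAF_j))·G_j with natural log (the cited
explained-variance weighting is on the ln scale) and G counting copies of the
weight table's risk allele. Subjects with any missing dosage are excluded
upstream, never imputed. The z-score uses the n−1 sample SD and is computed
on the post-exclusion analysis sample, so downstream hazard ratios are per SD
of the analysed cohort. The shipped 25-SNP weight table
(`snp_weights_synthetic.csv`) is synthetic, with plausible late-onset-AD locus
ORs/MAFs; only the formula, not the weights, carries scientific weight here.

## Test-based MCI classifier

Per wave, means and SDs (n−1) of the four tests are computed over the full
available sample within education strata (0–12 vs 13+ years); a record is
MCI-TB when at least `min_tests_impaired` (1 lenient, 2 stringent) scores fall
strictly below mean − 1.5·SD. A score exactly at the threshold is not
impaired (documented boundary choice; configurable via the SD multiplier).
Norms are recomputed each wave by default — the classifier was applied per
wave — with a `baseline_norms` switch to anchor them at wave 1.

## Imputation

Only item-level missingness at observed waves is imputed; records missing
because of attrition do not exist in the panel and are handled as censoring,
never filled in. The contract is missForest's: initialise with column
mean/mode, then cycle variables in increasing order of missingness, fitting a
random forest of each on all others and re-predicting its missing cells,
until the relative change between successive imputations falls below 1e-4 or
10 iterations. scikit-learn supplies the forests; the chained loop is
implemented here because no installed imputer handles mixed numeric and
categorical columns under this contract. Observed cells are bit-identical on
output, and the procedure is deterministic given the seed.

## Synthetic cohort generator

The generator emulates the study design the analysis assumes: n subjects
(default 2000) entering cognitively normal at a uniform age in 60–64,
trajectories drawn exactly from the continuous-time chain (competing
exponential sojourns — exact for time-homogeneous intensities, which matters
for recovery experiments), observed at waves 0/4/8/12 years, deaths recorded
at exact age, and per-wave non-informative dropout with probabilities
0.135/0.093/0.206 at waves 2–4 (the published attrition fractions). The risk
index is normal(9.4, 5.9²) truncated to [0, 32] — the published baseline mean
and SD — and the genetic score standard normal. Covariates enter the
intensities centred, so the default baseline log intensities are those of an
average subject; they were calibrated once so that exp(4·Q) reproduces the
published wave-to-wave transition frequencies (CN row 2.8%/0.7%/3.9% to
MCI/dementia/death conditional on observation, MCI row 52%/7.8%/6.5%, and the
three-state analogues), and the default transition effects are the published
hazard ratios (1.07 per index point on CN→MCI, 4.19 per score SD on
CN→dementia). Options off by default: state-dependent dropout (multiplier on
the dropout probability when currently impaired), ±0.25-year uniform wave
jitter, and state-shifted normal psychometric scores for classifier testing.

What the generator does **not** emulate: correlated psychometric batteries,
practice effects, informative dropout, age-varying intensities, covariate
measurement error, or linkage between the risk scores and the raw profile
variables. Passing recovery tests therefore show that the estimators recover
the parameters of the assumed data-generating process at these sample sizes —
not that the published estimates are correct for the real cohort.

## Recovery experiments and problem sizes

`cogmsm.experiments` injects one published effect at a time (the other
effects null) and attaches the covariate to its own transition in the fit, so
each experiment isolates one estimate: CN→MCI at n=2000, CN→dementia at
n=5000 (the rarer outcome needs the larger cohort), Cox at n=2000 with
events generated from a constant baseline hazard of 0.011/year at the
covariate mean on the age scale and 12-year administrative censoring. Wald
coverage of the multi-state engine is checked over 50 replicate cohorts at
n=2000 for the CN→MCI effect and over 200 replicate two-state cohorts for a
survival intensity and covariate effect. Single count-based starts are used
in the replicate loops; multi-start robustness is exercised separately.

## Numerical choices and limitations

- BFGS tolerance 1e-6 on the per-subject-mean gradient; 500 iterations cap.
- Transition probabilities below 1e-300 are treated as structural zeros
  (−∞ log likelihood) rather than underflowing to NaN.
- Exclusion order is fixed: missing genotype first, then single observation;
  a subject failing both is counted once, under genotype.
- The interaction term between the two risk scores (reported null in the
  source analyses) is available in the pipeline (`interaction: true`), off by
  default.
- Known limitations: no hidden-Markov misclassification layer, no
  time-inhomogeneity, Wald (not profile) intervals, and the Cox engine has no
  stratification or time-varying covariates. Information for effects on rare
  transitions is weak at cohort sizes in the low thousands; expect very wide
  or unavailable intervals there, as the NaN-SE policy makes explicit.
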