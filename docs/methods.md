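# Methods

## Data and counting rules

The observable record of the invasion is the set of discovered nests.  A
colony occupies one primary nest (spring) and then one secondary nest
(summer–autumn); destruction only removes the colony's future reproduction
if the nest is still occupied.  Because occupancy was rarely recorded, it is
inferred from the calendar: a primary nest destroyed after 31 July, or a
secondary (or stage-unrecorded) nest destroyed after 15 November, is treated
as already abandoned.  Both cut-offs are inclusive on the active side and
configurable (`ActivityCutoffs`); moving them later reclassifies
destructions as active and would raise the inferred carrying capacity.

Detected colonies per year are counted as active-destroyed primaries plus
all detected secondaries (a colony whose primary was destroyed while active
never built a secondary; an inactive primary implies its colony moved on and
is counted through its secondary, detected or not).  For 2007–2008, when
stage was not recorded, the raw nest total stands in for the colony count; a
mixed year would count unclassified nests as secondaries (conservative) with
a warning.  A nest with destruction date missing or recorded as the sentinel
`0` is counted as detected but never as an active destruction.

Densities divide colony counts by 20.59 km² (whole commune) or
0.47 × 20.59 km² (urban area).  The urban fraction default is 0.47 rather
than the land-cover figure of ~48% because 0.47 reproduces the published
density table and the 22.63 nests/km² equilibrium density; 0.48 is available
as a documented alternative configuration.  Rounding conventions: densities
to 2 dp, activity percentages to integers, habitat percentages to 1 dp; raw
values are always retained alongside.

The packaged habitat fixture reproduces every reported marginal (201
structure-recorded nests; 135 natural; 126 on trees including four plain
"tree" records and one stump; 81 oaks; 106/136 secondaries natural; 30/39
primaries man-made); the unreported cell-level split of genera across stages
is synthetic and marked as such in `datasets.py`.

## Demographic model

Colonies founded in year *y*:

    P_y ~ Poisson( r · S_{y−1} / (1 + S_{y−1}/κ) )

with S_{y−1} the successful secondaries of the previous year.  The mean map
is a saturating (Beverton–Holt-type) function: increasing, concave, bounded
by rκ.  Detection with destruction is layered binomial thinning within a
year: active primaries are found with probability d_AP (removing the
colony), active secondaries among the survivors with d_AS (removing the
colony's foundress output), and inactive secondaries among the successful
colonies with d_IS (no demographic effect — foundresses have already
dispersed; hibernating queens possibly remaining inside a seemingly inactive
nest are ignored).  Every colony therefore ends in exactly one of three
fates: destroyed as primary, destroyed as secondary, successful.

Equilibria: without control the non-zero fixed point of the mean map is
K = κ(r−1) (0 if r ≤ 1).  With per-colony survival q = (1−d_AP)(1−d_AS) the
successful-secondary equilibrium is S* = κ(rq−1) if rq > 1 (else extinction)
and the colony equilibrium is P* = S*/q.  Expected annual discoveries at
equilibrium are (P*·d_AP, P*(1−d_AP)·d_AS, S*·d_IS).

Detection probabilities vary over the study period.  The default form is
linear on the logit scale in the year index (0 at 2007), which keeps
probabilities inside (0,1) without clipping; a raw-linear-with-clipping
variant is available (`run_mcmc(..., detection_form="linear")`) for
sensitivity analysis.  On the study data the raw-linear variant mixes far
worse and was not adopted.  "Maximum detection" for equilibrium predictions
means the schedule evaluated at the final observed year.

Inactive-primary detections (present in the data, e.g. twelve primaries
found in 2014 none of which was active) are ingested and tallied but carry
no likelihood term: the observation model has exactly three detection
classes.

## Likelihood

Latent state: P_2007..P_2014 (integers) and S_init, the successful
secondaries of 2006.  Given the observed removals the successful secondaries
are deterministic: S_y = P_y − A_P,y − A_S,y in stage-recorded years, and
S_y = P_y − D_y in 2007–2008 where D_y is the count destroyed while active
(1 and 12).  Per year the likelihood contributes the Poisson reproduction
term and, for stage-recorded years,

    Binom(A_P,y; P_y, d_AP) · Binom(A_S,y; P_y−A_P,y, d_AS) · Binom(I_S,y; S_y, d_IS).

For 2007–2008 only the detected-colony total C_y enters, as
Binom(C_y; P_y, d_AS + (1−d_AS)·d_IS): a colony in those years was counted
whether its nest was found while active or later while inactive, so the
detection probability is the combined chance of either event.  This choice
is load-bearing: with d_AS alone the early years force implausibly large
latent populations and the posterior degenerates into a weakly identified
r–κ ridge.  The combined form is verified against an independent
exhaustive-enumeration oracle in the test suite (tolerance 10⁻¹⁰), as is the
stage-recorded likelihood.  Any observed count exceeding its latent
denominator yields −∞, never an exception.  The narrative lower bound of
three successful nests in 2007 is implied automatically: P_2007 ≥ C_2007 = 4
and D_2007 = 1 give S_2007 ≥ 3.

## Priors

The source analysis states none, so defaults are weakly informative and
explicit: log-normal r (median 5, log-sd 1) and κ (median 50, log-sd 1.5);
normal logit intercepts (sd 2) and slopes (sd 0.5); S_init discrete uniform
on {1..20}.  All are fields of `PriorSpec` for sensitivity runs.  The
posterior pulls r well above its prior median (data-dominated), and S_init
concentrates around 3–7.

## Sampler

Blocked random-walk Metropolis–Hastings, numba-compiled, exactly
reproducible from a seed (chain *c* uses seed + *c*).  Blocks per iteration:

- each continuous parameter (log r, log κ, six schedule coefficients) with a
  Gaussian step, scales adapted toward ~25% acceptance during burn-in;
- one joint Gaussian proposal along the Cholesky factor of the empirical
  covariance of the continuous block, estimated from the second half of the
  burn-in history and refreshed every 500 iterations — this is what lets the
  chain traverse the strong r–κ anticorrelation;
- S_init with a symmetric ±{1,2} step;
- each latent P_y with a symmetric ±{1..5} step;
- one whole-trajectory shift (the same ±{1..12} step added to every P_y),
  which moves the overall population level jointly with nothing else — the
  population level is strongly coupled to the detection intercepts and
  single-year moves alone mix it pathologically slowly.

All adaptation happens during burn-in only; the transition kernel is fixed
afterwards.  Defaults: 200,000 iterations, 40,000 burn-in, thinning 20, 4
chains (~45 s on one CPU), giving split-R̂ ≈ 1.01 and ESS of a few hundred
for r and κ on the study data.  A 50k/10k configuration fits in ~6 s but
leaves κ's split-R̂ around 1.05–1.07, hence the longer default.  Derived
quantities (equilibria, expected discoveries, discovery percentages) are
computed per retained sample and then summarised; point estimates are
posterior medians, with means reported alongside.

Discovery percentages use colonies as the denominator: per sample, the
probability a colony is ever discovered is d_AP + (1−d_AP)d_AS + q·d_IS and
while active d_AP + (1−d_AP)d_AS, both at final-year detection.  An
alternative using nest counts (one primary plus one secondary per surviving
colony) as denominator is also reported
(`pct_nests_discovered_alt`); the two differ because a colony builds up to
two nests, and the reported headline uses the colony basis, which matches
the magnitudes of the published posterior.  The 2014 colony estimate is
reported as the posterior of the latent P_2014.

## Synthetic data

`generate_invasion` iterates the stochastic cohort model from a seed
population; defaults mirror the study conditions: 8 years from 2007, three
pre-study successful secondaries, r = 9.64, κ = 219/(r−1), detection rising
over the years (active primary 0.03→0.10, active secondary 0.10→0.28,
inactive secondary flat 0.20 — the magnitudes implied by the published
equilibrium discovery rates).  `generate_records` expands a count table into
record-level rows with discovery/destruction dates drawn uniformly inside
invented but cut-off-consistent windows (active primaries 1 April–31 July;
active secondaries 1 August–15 November; inactive discoveries after the
relevant cut-off) and structures drawn independently of the dynamics from
the observed habitat frequencies; tallying the records reproduces the input
counts exactly, for every seed.

What the generator does not emulate: spatial structure and immigration from
neighbouring communes (the study area is treated as closed), year-to-year
environmental variation in r, reporting-effort artefacts beyond the smooth
detection trends, and any coupling between habitat and survival.  Passing
recovery tests therefore demonstrate correctness of the inference machinery
under the model's own assumptions, not robustness to these violations.

Parameter recovery at the study design (8 years, r = 8, κ = 30, rising
schedules, 20 replicates) achieves ≥17/20 coverage of r and κ by the 95%
intervals; the long-run mean of the stochastic simulator matches the
closed-form controlled equilibrium within batch-mean Monte-Carlo error.

## Numerical notes

Log-pmfs are evaluated with `lgamma` in compiled code; detection
probabilities in the clipped-linear variant are bounded to [10⁻¹², 1−10⁻¹²];
impossible latent configurations short-circuit to −∞.  Fixed-point identity
mean(K) = K holds to 10⁻⁹ in tests.  Initial states start latent colonies at
twice the detected colonies (at least the observed minimum) and retry with
jitter until the posterior is finite, failing loudly otherwise.

## Known limitations

- The commune is not closed; immigration inflates the apparent carrying
  capacity (acknowledged in the source's discussion). Nothing in the model
  corrects for it.
- r and κ are only jointly well-identified because the early colony counts
  pin the low-density growth; the posterior remains right-skewed with a
  heavy upper tail for both.
- The 2007–2008 colony-count likelihood folds two detection classes into one
  binomial; the stage composition of those years is unknowable from the
  data.
- Calendar activity cut-offs are step functions; nests destroyed exactly at
  a cut-off are active by convention.
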