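# Methods

This note documents the models and numerical choices behind `dfcstates`,
what the synthetic cohort generator does and does not emulate, and the
decisions taken where the analysis recipe left room for interpretation.

## The synthetic regime-switching cohort

Each subject's C component time courses (default C = 42, grouped into 7
labelled sub-networks; T = 240 samples at TR = 2 s; 22 subjects per group)
are generated from a hidden first-order Markov chain over K = 4
connectivity states. At each time step the chain leaves its current state
with a group-specific probability (defaults 0.10 for the high group, 0.05
for the low group) and, when it leaves, moves to one of the other K − 1
states uniformly. Because the destination is uniform, the chain can be
written as a cumulative sum of offsets mod K, which keeps simulation fully
vectorized.

While in state k the observation is drawn i.i.d. from N(0, R_k) plus
independent N(0, σ²) observation noise. The default σ = 1/√2 sets the
in-state edge signal-to-noise ratio (signal variance over noise variance)
to 2; the observed correlation is the generating one attenuated by
1/(1 + σ²), which keeps per-state correlations analytically known.
Noise-free configurations are used wherever a test needs exact targets.

State correlation matrices are block-patterned: each state assigns its
full within-block correlation (default 0.6) to a state-specific subset of
sub-networks (the rest get half strength) and couples a state-specific set
of block pairs at the between strength (default 0.35). Matrices are
repaired to the positive-definite correlation cone by iterated eigenvalue
clipping and rescaling; construction fails loudly if repair does not
converge or if any two states' patterns correlate at 0.8 or above.

Behaviour scores are linear in the subject's true transition count
(score = group intercept + coupling × transitions + N(0, 4²)), with the
coupling nonzero in the high group only (0.8) — large enough that the
covariate-adjusted correlation at n = 22 is detected with high
probability, mirroring the r ≈ 0.47-scale associations this kind of
analysis reports. IQ-like and age-like covariates and a balanced binary
gender code are drawn independently of the dynamics. Motion fixtures are
Gaussian random walks (0.02 mm and 4·10⁻⁴ rad step sd).

What the generator does **not** emulate: hemodynamic autocorrelation
(observations are i.i.d. within a state), spatial maps, scanner drift or
physiological artifacts beyond white observation noise, and any dwell-time
structure richer than geometric. A green recovery test therefore
establishes that the estimator chain is correct and well calibrated under
the stated model — not that real fMRI would behave as cleanly.

## Cleaning

Order: detrend → low-pass → nuisance regression → despike (each step can
be toggled).

- Detrend projects onto the orthogonal complement of a Legendre basis up
  to cubic (well-conditioned equivalent of {1, t, t², t³}).
- The low-pass filter is a 4th-order Butterworth applied
  forward-backward (zero phase), cutoff 0.15 Hz. Note an IIR filter is
  not exactly idempotent — re-filtering attenuates the band edge again —
  so the idempotence that holds exactly for the projection steps holds
  only approximately (passband content changes by well under 1%).
- Nuisance regression always includes an intercept; rank-deficient
  designs are solved by pseudo-inverse with a warning. Six motion
  parameters are the default regressors (12/24-parameter expansions can
  be passed explicitly).
- Outlier detection uses a robust z-score (median/MAD, |z| > 3.5) on the
  first difference. Outlying differences implicate the samples on both
  sides; candidates are confirmed by comparing each against linear
  interpolation from the nearest clean neighbours, so a spike's clean
  shoulders are not flagged with it. Confirmed outliers are replaced by a
  cubic spline fitted through the clean samples. A column with more than
  half its samples flagged raises. Framewise displacement sums absolute
  parameter steps with rotations converted on a 50 mm sphere.

## Windowed connectivity

The taper is a unit rectangle (22 TRs) convolved with a Gaussian kernel
(σ = 3 TRs, half-width 3σ), truncated to the central 22 samples,
renormalized, and symmetrized against floating-point drift. The window
count convention is floor((T − L)/step), which reproduces 213 windows from
235 time points (L = 22, step 1); the alternative T − L + 1 convention
would give 214.

Per window, means and variances are taper-weighted. With λ > 0 the
weighted correlation matrix is passed through the graphical lasso
(penalized precision; the regularized covariance is converted back to
correlation). λ defaults to 0.1 in the pipeline configuration; the recipe
literature selects λ by cross-validation, which is out of scope for a
default. The λ = 0 path is exact weighted correlation, and test and
acceptance runs use it — at 22-sample windows of 42 components the lasso
adds minutes of runtime without changing what the recovery tests measure.
Correlations of ±1 map to z = ±atanh(1 − 10⁻⁷) under Fisher transform to
avoid infinities.

Exemplar windows are strict interior local maxima of the across-edge
variance; a plateau contributes its first index; a series with no interior
maximum falls back to the global maximum.

## State clustering

Correlation-distance k-means: rows are centered and scaled to unit norm so
1 − r is computed by dot products; centroids are updated as means of the
standardized member rows; an emptied cluster is re-seeded at the point
farthest from its centroid (repeated up to k rounds, since stealing a
singleton can empty another cluster), keeping runs deterministic given the
seed. Stage 1 clusters the pooled exemplars with 500 random restarts;
stage 2 clusters every window of every subject in one run initialized at
the stage-1 centroids and iterates to convergence (a flag reduces stage 2
to a single assignment pass). Windows are clustered as raw correlations;
a flag enables Fisher-z clustering.

The elbow criterion is operationalized as the interior k maximizing the
second difference W(k−1) − 2W(k) + W(k+1) of the within-cluster distance
curve; when the best second difference is under 5% of the curve's first
value the result carries a `weak_elbow` flag (calibrated on pure-noise
inputs, which show no reliable elbow).

Recovered-vs-true state matching for evaluation uses Hungarian assignment
on the centroid correlation matrix. The ground-truth label of a window is
taken as the majority hidden state over the window's 22 samples.

## State statistics

Occupancy (reoccurrence time) and per-unordered-pair transition counts are
tallied per subject. Group tests pool counts across subjects (matching
the df and N conventions of the published analyses this pipeline
replicates); because pooling ignores within-subject dependence a
subject-level permutation test is provided as an alternative, and
subject-level group means are always written alongside the pooled tables.

Two chi-squares address two different questions:

- the 2 × M contingency on the pair (or occupancy) table tests whether the
  *distribution* over categories differs between groups (df = M − 1;
  6 pairs for K = 4 gives df = 5);
- the 2 × 2 table of switches vs non-switch window steps tests the overall
  transition *frequency*. Only the latter has power against a uniform
  rate difference (the contingency test conditions on row totals), so it
  is the statistic used for the power analysis, and it is exactly
  calibrated under the generator because leave events are i.i.d.
  Bernoulli.

Post-hocs partition the table into per-category 2 × 2 tests against the
pooled remainder, BH-FDR corrected across categories; both corrected and
uncorrected flags are always reported. No continuity correction is used
(large-count regime). Behaviour correlations residualize both variables
on the covariates plus intercept (gender coded 0/1; zero-variance
covariates dropped), giving r with df = n − 2 − q. The
summary-statistics t-test is the pooled-variance two-sample form.

## Hub structure

Each state's member windows (pooled across subjects; a subject-mean mode
is available) are Fisher z-transformed and each edge is tested against
zero with a one-sample t-test; BH-FDR at α = 0.05 across all E edges zeros
the non-surviving edges, and survivors carry the mean z.

Community detection is Louvain on the signed graph under the asymmetric
signed modularity Q = Q⁺ − (v⁻/(v⁺+v⁻))·Q⁻, with the resolution γ applied
to both null terms. Consensus over 100 seeded runs uses the module
allegiance matrix (co-assignment fraction, values in [0, 1], not
thresholded), re-clustered by Louvain at γ = 1. An all-zero graph returns
a single module with Q = 0.

"Degree" in the hub formulas is interpreted as positive strength
(weighted), negative weights excluded — the standard weighted
generalization. The module-degree z-score standardizes within-module
strength inside each module (singleton or zero-spread modules get z = 0);
the participation index is P_i = 1 − Σ_m (k_im/k_i)² with P = 0 for
isolated nodes. Boundaries are strict: z = 1 is a non-hub, P = 0.3 a
provincial hub.

## MTD

The temporal derivative of each component is standardized over the whole
series (mean removed, population sd — so self-coupling averages exactly
+1); pairwise products give the per-timepoint coupling, smoothed by a
width-15 moving average in "valid" mode (length T − 1 − w + 1) to avoid
edge bias. The published MTD formulation does not print its smoothing
width; 15 samples (30 s at TR = 2 s) is in the range its authors explored.
Timepoints are clustered with the same correlation k-means as the windowed
analysis. Spatial similarity across coupling matrices is summarized on a
seeded subsample of at most 500 timepoints (the full pairwise matrix over
all subjects and timepoints would be quadratic in cohort size).

## Pipeline

Stage seeds derive from the master seed by SHA-256 over
(master, stage, subject), truncated below 2³¹ — deterministic, and safe
under subject-level parallelism. Artifacts are plain text (TSV/CSV/JSON),
every run writes a manifest with config echo, stage seeds, timings and
input hashes, and the report is markdown. Figures are deliberately not
generated.

## Known limitations

- The pooled chi-squares inherit the published convention of treating
  windows as independent observations; the permutation alternative is the
  statistically conservative route.
- k-means with correlation distance cannot represent state-dependent
  overall connectivity magnitude (by design of the distance).
- The MTD stage shares the generator's i.i.d.-within-state assumption;
  with temporally autocorrelated data its derivative standardization
  would need revisiting.
- Louvain at aggregation level operates on separately aggregated positive
  and negative layers, which preserves the signed modularity exactly but,
  like all Louvain variants, offers no global optimality guarantee.
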