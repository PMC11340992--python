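# Methods

This note documents the statistical model behind `cpmkit`, the choices
made where the design was open, and what the synthetic validation does and
does not establish.

## Connectome construction and QC

Connectivity is the Fisher z-transform of the Pearson correlation between
node time courses. Correlations are clipped to |r| ≤ 1 − 1e−7 before
`atanh`, so perfectly (anti)correlated inputs map to z ≈ ±8.43 rather than
±∞; the clip is far outside the range of real connectivity values and does
not affect means in practice. A constant time course is an error (its
correlation is undefined), while an all-NaN row is treated as a missing
node and propagates NaN through its row/column.

A "missing node" is operationalized as an absent/all-NaN row; matrices
with dropped rows are also accepted since node ids travel with every
matrix. Harmonization removes any node missing from ≥ 3 participants
(configurable) from *all* participants, preserving the surviving order;
the operation is idempotent.

Participant QC applies two rules in a fixed order — coverage flag first,
then mean framewise displacement — so each exclusion has exactly one
reason and the per-reason counts sum to the total. The motion rule is a
strict inequality: FD = 0.15 mm is retained, FD > 0.15 mm is excluded.
Coverage is consumed as a boolean flag; detecting coverage failures from
images is out of scope.

## CPM training

Edge selection uses the Pearson correlation of each edge with the
behavioral measure and a two-tailed p threshold (default p < 0.01, always
a config value). Edges that are constant across training participants are
never selected. The per-fold predictive model is a simple ordinary
least-squares regression of behavior on the single network-strength
summary — not a multi-edge regression — fitted separately for the high
(positively correlated) and low (negatively correlated) networks. A fold
that selects no edges contributes an undefined prediction and an empty set
to the consensus intersection; training fails only if every fold of both
polarities is empty.

Consensus masks are the intersection of fold selections, so they shrink
(weakly) as the threshold tightens. Network strength is the arithmetic
mean of z over a mask's edges, each unordered edge counted once; an empty
mask has *undefined* strength — reported as NaN and flagged, never as
zero. An optional combined score (high − low strength) is available but
off by default, as its interpretation is less settled than the two
polarity-specific scores.

## Associations

Outcomes such as CSF biomarker ratios and cognitive composites are
typically skewed, so associations use Spearman correlations. With
covariates, the partial Spearman is computed as the partial Pearson
correlation of average-ranked variables via the inverse correlation
matrix; the p-value uses t = ρ·√((n−2−k)/(1−ρ²)) with n−2−k degrees of
freedom. Both the predictor and the outcome are adjusted (symmetric
partial correlation); adjusting only the predictor is a defensible
alternative that typically yields slightly larger |ρ| — the symmetric form
matches common implementations (e.g. pingouin) and is what the test oracle
(residualize-ranks-then-correlate) computes. Covariates that are constant
after listwise deletion are dropped with a warning, reducing k, so a
degenerate covariate reproduces the plain Spearman exactly. No
multiple-testing adjustment is applied; outputs record this.

Steiger's (1980) Z compares two dependent correlations sharing one
variable (the outcome), as arises when whole-brain and lesioned strengths
are both correlated with the same biomarker. The implementation uses the
pooled standard error evaluated at the back-transformed mean correlation
r̄ = tanh((z₁+z₂)/2):

    ψ  = r_kh(1 − 2r̄²) − ½·r̄²(1 − 2r̄² − r_kh²)
    s̄  = ψ / (1 − r̄²)²
    Z  = (z₁ − z₂)·√((n − 3)/(2 − 2s̄)),   p = 2(1 − Φ(|Z|))

Inputs with |r| = 1 are rejected rather than clipped: a degenerate
correlation signals an upstream problem. A triple (r_jk, r_jh, r_kh) that
is not jointly realizable (non-positive-semidefinite) is flagged in the
result rather than silently accepted. Rank-based correlations are fed into
this normal-theory formula, matching common practice when Spearman ρ is
the reported effect size; this is an approximation, and the Monte-Carlo
calibration below shows its type-I error is nominal at the sample sizes
used here.

## Computational lesioning

Lesioning a canonical network removes all of its nodes from every matrix
and deletes every mask edge incident to a removed node — within-network
and between-network connections alike. Strength after lesioning is
recomputed as the mean over the *surviving* edges, not rescaled to the
original edge count. Lesioning is idempotent and commutative, and the edge
count obeys |lesioned| = |mask| − |incident edges| exactly.

The Steiger comparison requires a common sample, so both correlations are
computed on the same listwise-complete participant set (outcome, both
strengths, covariates); n is shared and reported. The predictor–predictor
term r_kh is the rank (Spearman) correlation between the whole-brain and
lesioned strength scores, keeping all three correlations in the formula on
the same scale. If a lesion leaves the mask unchanged the two scores are
identical; the comparison is degenerate and reported as Z = 0, p = 1. A
lesion that empties the mask yields a row with explicit NaN fields, never
a silently dropped network.

## Synthetic cohort generator

The generator emulates the statistical shape of a resting-state aging
cohort, not its physiology. Defaults describe the cohort the analyses are
sized for: 324 enrolled participants, 268 nodes, 134 positive + 134
negative signal edges, coverage/motion exclusion fractions of 5/324 and
30/324, six missing-prone nodes, motion confound 0.48, and a planted
strength–biomarker rank correlation of 0.4 (a value chosen to be reliably
detectable at n ≈ 300; observed effect sizes in real cohorts can be
substantially smaller, and the planted value is a free simulation
parameter, not an empirical claim).

Mechanics, in draw order (one `numpy.random.default_rng(seed)` stream;
identical configs are byte-identical on disk):

1. **Copula.** (behavior, motion, biomarker) latents are trivariate
   standard normal. The behavior–biomarker entry converts the target
   Spearman ρ to the latent Pearson scale via r = 2·sin(πρ/6) (exact for
   bivariate normals). The motion–biomarker entry is solved in closed form
   so that the behavior–biomarker correlation is identical marginally and
   partially given motion — making the planted target mean the same thing
   to a plain and a motion-adjusted estimator. Because the strength score
   retains residual edge noise `edge_noise_sd/√K` over K signal edges, the
   latent couplings are pre-inflated by the analytic attenuation factor
   `effect/√(effect² + noise²/K)` so the *strength-level* correlations
   land on target. Infeasible combinations (non-PSD matrix, or attenuation
   compensation pushing a latent correlation past 1) raise an error naming
   the offending parameters.
2. **Edges.** Each edge has a participant-constant baseline
   ~N(0.30, 0.15), plus N(0, 0.10) participant noise; signal edges add
   ±effect_size·behavior (default 0.08 z-units per SD). These magnitudes
   put per-edge correlations near 0.6 — strong enough that consensus
   recovery is a property of the algorithm, not luck.
3. **QC.** Coverage failures are an exact random subset. Motion failures
   are exact by construction: coverage-passing participants are ranked on
   the motion latent and placed at lognormal plotting-position quantiles
   (log-SD 0.45) whose location parameter is solved so exactly the
   configured count exceeds 0.15 mm. The mapping is monotone in the
   latent, so the planted motion confound survives.
4. **Missing nodes.** Each missing-prone node is absent from exactly three
   QC-passing participants (so the ≥3 rule fires even after participant
   exclusion); assignments are recorded in the ground truth.
5. **Phenotypes.** Biomarker = exp(skew·latent) (positively skewed,
   monotone, rank structure preserved); three cognitive composites are
   negatively coupled to behavior (r ≈ −0.35); observed behavior is the
   latent plus N(0, 0.2) measurement noise; diagnostic labels follow
   biomarker rank in shares ≈ 0.52/0.38/0.10.

Time-series mode (n_timepoints > 0) back-transforms each planted z-matrix
to correlations, projects to the nearest positive-definite correlation
matrix (eigenvalue clipping), and draws multivariate-normal series, adding
~1/√T sampling noise to the recovered connectivity.

**What the simulations do not emulate:** BOLD autocorrelation, scanner and
site effects, spatially structured (distance- or network-dependent)
connectivity, realistic biomarker assay floors/ceilings, or any
physiological coupling between motion and disease. Passing tests therefore
establish the correctness and calibration of the *pipeline*, not the
effect sizes to expect from real data.

## Numerical choices

- Correlation clip before atanh: 1e−7 (see above). No clipping inside
  Steiger's Z.
- Edge identity is the unordered pair (i, j), i < j, of 0-based node ids,
  stable under node removal; every file format documents this.
- Partial correlations use `pinv` of the rank-correlation matrix; ranks
  use average ties.
- Fold regressions use `numpy.polyfit` degree 1 (single predictor).
- Per-edge p-values use the exact t transform of r with df = n − 2,
  vectorized over all edges.

## Validation problem sizes

The shipped tests and acceptance script size their simulations to
establish each property with adequate Monte-Carlo resolution while staying
quick: null calibration of edge selection uses 200 pure-noise cohorts
(38,000 edge tests); Steiger type-I calibration uses 2,000 trivariate
replicates at n = 150 (binomial 95% CI half-width ≈ 0.0096 around 0.05);
planted-correlation recovery uses 100 replicates at n = 300 on 40-node
cohorts (truth-mask scoring isolates the generator-estimator contract from
mask-selection noise); the end-to-end run uses the full default 324 × 268
conditions.

## Known limitations

- Leave-one-out is the only cross-validation scheme; k-fold would require
  a consensus rule other than all-folds intersection.
- The consensus mask admits noise edges whose full-sample correlation is
  comfortably below the threshold; at default conditions this dilutes the
  strength–outcome correlation by a few hundredths relative to the true
  mask.
- Under the permutation null, leave-one-out prediction correlations have
  a small negative bias (≈ −0.08 at n = 40), a known property of LOO
  regression, so "≈ 0" checks must tolerate it.
- Steiger's Z with rank-based inputs is asymptotic; below n ≈ 50 its
  calibration has not been verified here.
- Real-atlas analyses require a user-supplied node→network lookup; the
  built-in atlas is a block partition for simulation only.
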