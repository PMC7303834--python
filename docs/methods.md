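# Methods

## Setting and model

A distributed data network consists of k data partners, each holding the
complete record (outcomes and covariates) for its own patients, and one
analysis center trusted with summary statistics but never with rows. The
package fits three regression families over such a network:

* linear regression of a continuous outcome,
* logistic regression of a binary outcome,
* Cox proportional hazards regression of a right-censored event time,

each with an identical covariate schema at every site ("harmonized"
analytical datasets). The estimand and every reported quantity are defined
to be *exactly* those of the corresponding pooled individual-level analysis;
the distributed computation is an exact rearrangement of the pooled one, not
an approximation (the one deliberate approximation — privacy binning of
predicted values — affects only the ROC/calibration diagnostics, never the
estimates).

## Protocol

The center drives a master-worker loop. One round = one *computation
directive* (instruction token, iteration index, current parameter vector,
model digest) broadcast to all partners, followed by one *payload* per
partner (aggregate blocks only) returned to the center. Three instruction
tokens exist: `compute_intermediates`, `compute_diagnostics`, `stop`.

* **Linear**: round 0 returns {n, XᵀX, Xᵀy, yᵀy, Σy}; the center solves the
  normal equations via Cholesky (never an explicit inverse for the solve)
  and computes SEs. Round 1 (`compute_diagnostics` with the final β)
  returns each site's residual sum of squares, from which the fit
  statistics are computed — the residual-round SSE is used there because
  the direct Σ(y−Xβ)² form avoids the catastrophic cancellation of
  yᵀy − βᵀXᵀy; the closed form is still used for σ̂² inside the round-0
  covariance. Exactly two rounds, always.
* **Logistic**: rounds r = 0,1,... evaluate score/information/log-likelihood
  at the current β (β₀ = 0), and the center applies the IRLS/Newton update.
  Convergence is declared when max_j |β′_j − β_j| < ε (default ε = 0.01,
  chosen for transparency and site-independence; the cap is 25 iterations).
  One final diagnostics round evaluates everything at the converged β —
  SEs come from the information at the *final* β — and carries the privacy
  bins.
* **Cox**: round 0 collects each site's distinct event times with tie
  counts; the union (the global event grid) is echoed back inside every
  subsequent directive so risk-set sums are evaluated at all global event
  times, including foreign ones. Newton rounds and a diagnostics round then
  mirror the logistic flow. Sharing the grid discloses the network's event
  times with multiplicities — a deliberate, documented leak far weaker than
  any row-level disclosure.

The file transport realizes each round as JSON documents plus zero-byte
trigger files in per-node inbox/outbox folders, written payload-first so a
trigger guarantees a complete file. Folder monitoring is plain polling
(default 20 ms) for portability; collection timeouts default to 120 s. Four
step categories are timestamped per node and round — download, compute,
upload, transfer — and summarized as mean (SE) per node class. The
in-process driver (`run_inprocess`) executes the same sessions and partner
computations without files; the two paths produce bit-identical models, a
property the tests assert.

## Numerical design: partition invariance at double precision

The only place the distributed computation could diverge from the pooled one
is floating-point summation order: a pooled pass adds n terms in one
sequence, the network adds per-site partial sums. Plain float64 partials
reproduce the pooled result only to ~1e-10 relative on fit statistics of
magnitude 1e4, which would not support a 1e-12 equivalence claim.

Every additive payload block is therefore accumulated with an error-free
two-sum reduction and carried as a double-double (hi, lo) pair; cross-site
aggregation adds the pairs. The aggregate equals the exact real-arithmetic
sum to O(eps²) ≈ 1e-31 relative — independent of grouping — so distributed
and pooled collapse to the same rounded double except with vanishing
probability, and everything downstream (solves, SEs, fit statistics,
survival curves) is bit-identical. Per-row products (outer products,
weights) are ordinary float64 and identical on both paths by construction.
The observed distributed-vs-pooled differences in the test suite are exactly
0 or a few times 1e-17.

Other numerical choices:

* Near-singularity is judged on the diagonally normalized (correlation-form)
  matrix, making the check invariant to covariate units; a scaled reciprocal
  condition estimate below 1e-10 raises a collinearity /
  non-identifiability error naming the implicated columns.
* No step-halving or line search in the Newton iterations: divergence (e.g.
  monotone likelihood from a perfectly separating covariate) surfaces
  through the 25-iteration cap with an explicit non-convergence warning,
  never silently.
* An exact linear fit (SSE ≤ 1e-14·SST) reports R² = 1 and flags the
  information criteria as undefined.
* The survival median is read off the step function without interpolation;
  if S never reaches 0.5 the median is reported as undefined.
* Ties between an event and a censoring at the same time keep the censored
  subject in the risk set at that time.

## Fit statistics

SAS-style conventions, so distributed and pooled values are comparable term
by term: linear AIC = n ln(SSE/n) + 2p, Schwarz BIC = n ln(SSE/n) + p ln n,
Sawa BIC = n ln(SSE/n) + 2(p+2)q − 2q² with q = nσ̂²/SSE; σ̂² inside q is
SSE/n by default with a `sawa_variance="unbiased"` switch for SSE/(n−p).
Logistic: −2logL, AIC = −2logL + 2p, SC = −2logL + p ln n. Cox: −2logL,
AIC = −2logL + 2p, SBC = −2logL + p ln D with D the total event count. p
counts all design columns including the intercept where present.

## Privacy-binned diagnostics

Site-local predicted probabilities are sorted ascending (stable, ties by
row order) and grouped in runs of `roc_bin_size` = 6; the final partial bin
keeps its true size. Each bin reports only (mean prediction, event count,
nonevent count, size). The center merges all sites' bins, collapsing equal
means into one operating point, and traces the ROC with trapezoidal AUC —
with bins of 1 this reduces exactly to the all-pairs concordance with ties
counted ½. The Hosmer–Lemeshow statistic partitions the merged bins into 10
risk groups at cumulative-count boundaries nearest n·k/10, takes expected
events from bin mean predictions (individual predictions never reach the
center), and uses Σ(O−E)²/(E(1−E/n_g)) on groups−2 df. Binning costs
discrimination accuracy on the order of 1e-5 absolute AUC at n ≈ 5000
(measured by the acceptance script), at the price that runs of 6 records are
the finest granularity disclosed.

## Synthetic cohort generator

The generator emulates a three-partner bariatric-surgery follow-up study so
every protocol stage is testable without any external data. Defaults are the
study conditions: site sizes (1706, 2728, 1018); exposure ~ Bernoulli(0.18);
age ~ Uniform(18, 79); baseline BMI ~ Normal(45, 7) truncated at ≥ 35;
utilization counts Poisson (ambulatory 10, other ambulatory 5, emergency 0.8,
inpatient 0.3, nonacute stays 0.05, comorbidity score 1.2, measurement-gap
days 30); 6-level race (reference white), binary sex (77% female), 6 surgery
years (reference 2010), and the partner site itself as an ordinary 3-level
covariate (reference 1) — 23 design columns, 24 with intercept.

All three outcomes coexist on one covariate draw: a continuous change in
BMI (Gaussian noise, SD 2), a binary ≥20%-weight-loss indicator from a
logistic model (≈75% event rate), and a time to ≥20% loss from a
proportional-hazards Weibull model (shape 1.2, scale 146 days — tuned once
so roughly three quarters of subjects have the event by day 365), rounded
**up** to whole days and administratively censored at day 365. Day rounding
is deliberate: it produces heavy within- and cross-site ties (well over 10%
of events share a time at n ≥ 2000), which is the hardest path for the
Efron correction. Per-site substreams derive deterministically from the
master seed, so cohorts are byte-reproducible.

What the generator does **not** emulate: claims-data realism (enrollment
spans, code lists, informative censoring), missing data, measurement error,
or confounding calibrated to any real study. Passing tests therefore
demonstrate *protocol correctness and pooled-equivalence* on realistic
scales and degeneracy patterns — not clinical validity of any estimate.

## Verification surface and problem sizes

Two oracle tiers: (a) the internal pooled fit — the same engine run on the
concatenated rows as one site, sharing every convention — is the target of
the ≤1e-12 equivalence tests; (b) independent library fits (statsmodels
OLS/Logit, lifelines Efron Cox, scikit-survival Breslow Cox) at tight
convergence are the target of 1e-8 estimate comparisons. The default
stopping rule (ε = 0.01) leaves ~1e-4 distance to the exact MLE, so
tier-(b) comparisons run both sides at ε = 1e-12; tier-(a) comparisons
always use identical settings on both sides, making the stopping iterate
itself part of the estimand.

Test problem sizes: the full three-partner study (n = 5452) for end-to-end
equivalence and diagnostics; n = 1000 for the partition-invariance sweep
(k ∈ {1,2,3,5} × three partition schemes × three families); n = 800
tie-free rows for Efron≡Breslow; n = 50,000 single-site for parameter
recovery (every coefficient within 3 SEs of truth); n ≈ 400 for the
file-protocol bit-identity and privacy-audit runs. File-based Cox runs use
the smaller cohorts because the S₂ blocks on a ~365-point event grid make
per-iteration payloads tens of MB of JSON at n ≈ 5000; large-n equivalence
runs use the in-process driver, whose bit-identity with the file protocol
is asserted directly.

## Known limitations

* No weighted, offset, ridge/Firth, robust-variance, stratified,
  time-varying or left-truncated variants.
* The Cox baseline survival uses the Breslow estimator irrespective of the
  tie method (with the tie method's β); an Efron-specific product-limit
  baseline would differ slightly in heavily tied data.
* The transfer layer is a local-folder stand-in with a pluggable transport
  interface; there is no authentication or transport encryption, and the
  intermediate statistics themselves are not encrypted or perturbed —
  extreme cells (e.g. an indicator identifying one patient) can still leak
  information through aggregates.
* Plain Newton iterations assume a well-posed MLE; separation and monotone
  likelihood are detected, reported and refused rather than regularized.
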