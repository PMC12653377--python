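# Methods

`cdpath` turns a binary response matrix (N examinees × J items) and a
Q-matrix (J items × K attributes) into three linked results: per-examinee
knowledge states under a mixed cognitive diagnostic model (CDM), a
first-order learning-pathway network with a dominant path, and an
ability-scaled, tiered learning progression. This note records the models,
the numerical choices, and what the synthetic cohorts do and do not
emulate.

## Latent class space

A knowledge state is a binary mastery vector α = (α₁, …, α_K). States are
rendered as 0/1 strings with attribute 1 leftmost, and the class space
enumerates all 2^K states in ascending order of the string read as a
binary number (attribute 1 = most significant bit). This single ordering
defines posterior columns, mixing-weight indices, and every tie-break that
refers to "the lower class index".

## Item response functions

Each item j responds only to its required attributes (its Q-matrix row),
of size K*_j. Six families are implemented on the reduced profiles:

| family | form | free parameters |
|---|---|---|
| G-DINA | identity link, all 2^{K*} subset effects | 2^{K*} |
| DINA | g + (1−s−g)·∏ α_k | 2 |
| DINO | g + (1−s−g)·(1−∏(1−α_k)) | 2 |
| ACDM | P = λ₀ + Σ λ_k α_k | K*+1 |
| LLM | logit P = λ₀ + Σ λ_k α_k | K*+1 |
| RRUM | log P = λ₀ + Σ λ_k α_k | K*+1 |

RRUM uses the log-link GLM convention (log P = intercept + Σ effect_k·α_k);
the classical π*·∏ r^(1−α) form is an affine reparameterisation of it.
Parameter validity requires every implied probability in [0, 1], checked by
enumerating the reduced profiles. Monotonicity is *not* imposed — only
[0, 1] validity — since nothing in the method requires it. The saturated
log-linear parameterisation (LCDM) is fit-equivalent to saturated G-DINA
and is not implemented as a separate family.

## EM estimation

The marginal likelihood is a 2^K-component mixture; estimation is EM on
the expected complete-data log-likelihood:

- **E-step.** Posterior over classes per examinee, computed on the set of
  *distinct response patterns* (cost scales with patterns, not N).
  Probabilities are floored at ε = 1e-10 inside logs so boundary
  parameters never produce −∞.
- **M-step.** Mixing weights π are mean posteriors. Saturated items update
  in closed form (posterior-weighted proportion correct per reduced
  profile), DINA/DINO collapse to two groups and are also closed form, and
  the additive families take damped Fisher-scoring steps on the link scale
  with main effects projected to be nonnegative — in ACDM/LLM/RRUM,
  mastering an attribute may not lower the success probability, which is
  those families' standard interpretation and what prevents attribute
  labels from drifting to a permuted mode during long EM runs. A step is
  accepted only when the implied probabilities stay inside (1e-4, 1−1e-4)
  and the expected log-likelihood does not decrease, making the algorithm
  a generalized EM with a monotone trace.
- **Initialization.** Item success probabilities ramp linearly from 0.2 to
  0.8 in the number of mastered required attributes, with seeded uniform
  jitter (±0.05); π starts uniform. The seed argument controls only this
  jitter.
- **Convergence.** Maximum absolute change of any item probability or
  mixing proportion < 1e-4, capped at 1000 iterations; hitting the cap
  returns `converged=False` with a warning rather than an error. With 2^7
  classes the mixing weights can converge slowly, so long fits are normal
  for saturated models on large cohorts.

Number of free parameters: Σ_j (item free parameters) + (2^K − 1).

## Classification, fit and reliability

MAP classification assigns each examinee the state maximizing the
posterior; exact ties go to the lower class index and are logged.
Marginal per-attribute mastery is the posterior-weighted sum of profile
bits.

Deviance = −2·loglik, AIC = deviance + 2·p, BIC = deviance + p·ln N. Item
RMSEA_j = sqrt(Σ_c π̂_c (P_j(α_c) − P̃_jc)²), with P̃_jc the
posterior-weighted observed proportion correct on item j in class c
(empty classes contribute zero); the overall index is the mean over
items. Cronbach's α uses sample variances (ddof = 1) of the raw scores.

Attribute classification reliability is simulation-based: simulees are
drawn from π̂, responses from the fitted IRFs, and re-classified by MAP
with the same parameters; reliability_k is the agreement rate between
generating and recovered mastery of attribute k, averaged over
replications. A posterior-correlation estimator would be a defensible
alternative; MAP agreement was chosen because the pipeline's downstream
statistics (state tallies, pathway counts) consume MAP states.

## Wald model selection

For every multi-attribute item the saturated G-DINA fit is tested against
each reduced family. Restrictions are linear in a link transform f(p) of
the reduced-profile success probabilities: equality of all
non-distinguished profiles for DINA/DINO (df = 2^{K*} − 2), and vanishing
interaction coefficients of the saturated decomposition on the
identity/logit/log scale for ACDM/LLM/RRUM (df = 2^{K*} − K* − 1). The
statistic is W = (C f)' (C Σ_f C')⁻¹ (C f) ~ χ²_df, with Σ_f by the delta
method from Σ_p, and Σ_p the inverse of the item-block outer-product
(empirical) information with posterior-weighted group membership. A
sandwich correction is not applied; the covariance estimator is a
documented, configurable choice. Singular matrices fall back to
pseudo-inverses with warnings.

The mixed model assembled from the selected families is refitted by EM
*warm-started from the saturated solution* (item probabilities projected
onto each selected family's link scale, mixing weights carried over). A
fresh random start can converge to a label-switched mode of nearly equal
likelihood; the warm start keeps the refit in the saturated fit's
labeling and roughly halves its iteration count.

Selection rules per item: (1) admit reduced families with p > α
(default 0.05); (2) keep the admitted family with the highest p;
(3) optionally prefer DINA/DINO among the admitted when parsimony is
prioritised; (4) retain saturated G-DINA when nothing is admitted.
Single-attribute items always receive the saturated model. Exact p ties
break by fixed precedence RRUM < LLM < ACDM < DINO < DINA (most
constrained wins) and are logged. With items measuring 3+ attributes and
n ≤ 1000, a warning notes that Wald type-I error may be inflated.
Calibration at the suite's conditions (true ACDM item, K* = 2, N = 3000,
200 replicates) gives rejection rates of 0.045–0.08 at nominal 0.05.

## Pathway construction

MAP states are tallied; the k most frequent (default 17) are retained,
with rank-boundary ties going to the lower state index, and coverage is
their share of the cohort. Edges connect retained states s → t when
s ⊂ t and they differ in exactly one attribute (first-order transitions);
levels are mastery counts, so every edge climbs one level. The dominant
path maximizes the *sum of node counts* from the all-zero to the all-one
state (dynamic program over the level-layered DAG; ties resolved to the
lexicographically smallest path and logged). Sum-of-counts is the
aggregate that reproduces a segment-by-segment "more students on this
branch" comparison whenever one branch dominates statewise;
bottleneck-min and greedy-next-state are noted alternatives and the
criterion is a single documented function, easy to swap.

## Progression

Rare states (everything outside the retained set) are absorbed by a
single nearest-centroid pass with the retained states as fixed centers —
squared Euclidean distance on 0/1 vectors equals Hamming distance; ties
prefer the higher-count center, then the lexicographically smaller one.
Full Lloyd iterations would move the centers and are deliberately not
run: the centers *are* the dominant states.

Ability is scaled by a unidimensional 2PL fitted with marginal maximum
likelihood EM: 61 fixed quadrature nodes on [−6, 6] under a standard
normal prior (which also identifies the latent scale), slope–intercept
Newton updates per item with step clipping, and EAP ability per examinee.
EAP is used because it is finite for perfect and zero scores, which occur
in any large cohort. Constant items are dropped with a warning. Each
examinee's EAP θ is averaged within clusters (per-student θ first, then
the cluster mean).

Tier boundaries: none are canonically defined, so `set_levels` takes
explicit boundaries or defaults to weighted-quantile (equal-count) cuts
of the cluster means, with the boundaries echoed in the output. The
mapping of tiers to curriculum proficiency labels is interpretive, not
computational, and is out of scope.

## Synthetic cohorts

The real cohort (a provincial high-stakes English reading assessment,
N = 361,967) is confidential, so the generator emulates its structure:

- **Instrument.** The published 20-item × 8-attribute Q-matrix is built
  in; the 3-item rule removes A8, leaving K = 7 and attribute item counts
  (5, 3, 5, 4, 5, 9, 10).
- **Population.** A higher-order model: one latent continuum η ~ N(0,1);
  attribute k mastered when a uniform draw falls below
  logistic(a_k(η − τ_k)). Thresholds are calibrated by root-finding so
  the marginal mastery rates match targets. Two pairs of the published
  rates are nearly tied (A2/A7 at .582/.587; A4/A5 at .364/.363) — ties
  that small are resolvable only at the full cohort size, so the default
  targets spread them apart (each within 0.02 of its published value)
  along the published acquisition order A6, A2, A7, A3, A5, A4, A1.
  Discrimination a = 7 for all attributes concentrates the cohort on the
  nested chain while still producing ~45–60 observed states and top-17
  coverage near 95% at N = 20,000, the same regime as the real cohort's
  79 states and 97%.
- **Items.** Strongly discriminating: success probability from ~0.04–0.08
  (no required attribute) to 0.92–0.96 (all mastered), the quality of a
  well-constructed high-stakes exam. Each item's discrimination is split
  across its attributes with weight inversely proportional to the
  *square* of the attribute's item count: frequently measured attributes
  also own the single-attribute anchor items, so linear compensation
  would leave an anchor-less attribute like A2 (three multi-attribute
  items only) undiagnosable — MAP would shrink its states into more
  prevalent neighbours. The generating family plan is saturated G-DINA
  for most items with LLM (items 11, 14) and RRUM (item 13) mixed in.
  Under these conditions per-attribute MAP accuracy lands at 0.90–0.99,
  consistent with the 0.76–0.97 reliabilities operational diagnostic
  assessments report.
- **Recovery scenarios.** DINA parameter-recovery cohorts use
  g, s ~ U(0.05, 0.2) with an anchored random Q-matrix; the 2PL recovery
  harness draws a ~ U(0.8, 2), b ~ U(−2, 2).

What the generator does *not* emulate: response dependence beyond the
single latent continuum, missing responses, speededness, item drift, and
the full 79-state diversity of the real cohort. A passing end-to-end test
shows the pipeline recovers structure the generator builds in; it cannot
certify that the real assessment satisfies those assumptions.

## Problem sizes in the test suite

The suite runs the stated study conditions at desk scale: DINA recovery
at K = 5, J = 20, N = 2000 over 10 cohorts; Wald type-I calibration over
200 cohorts of N = 3000; 2PL recovery at N = 2000, J = 20; the end-to-end
pathway run at N = 20,000. Exhaustive lattice oracles go up to K = 4.

## Known limitations

- The saturated G-DINA M-step does not impose monotonicity; on small
  samples individual items can fit non-monotone profiles.
- The Wald covariance uses item-block empirical information; cross-item
  and mixing-weight covariance blocks are ignored, which can tilt type-I
  error a point or two around the nominal level.
- With 2^7 classes the EM mixing weights converge slowly; fits that stop
  at the iteration cap are flagged, not failed.
- MAP state frequencies are shrunk toward prevalent states when an
  attribute is weakly measured; this is a property of MAP classification
  itself and the reason the generator compensates anchor-less attributes.
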