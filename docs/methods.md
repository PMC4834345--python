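# Methods

This note documents the statistical model behind macanet, the choices
made where the design was genuinely open, and what the validation suite
does and does not establish.

## The inference problem

All data come from one social group observed exhaustively, so the
"sample" is a single network: tie weights share actors, and metric
values share ties. The package therefore never uses sampling-theory
p-values. Every test is a **node-label permutation test**: the network
(and hence each individual's metric value) is held fixed while the
attribute rows — gender, age, matriline, hierarchy, jointly — are
randomly reassigned to individuals. The null hypothesis is that any
individual could carry any attribute profile. Permuting attribute rows
jointly is algebraically identical to permuting the metric vector over
individuals, which is how the engine implements it (the design matrix
pseudoinverse is computed once and reused across permutations).

p-values use the add-one convention
p = (1 + #{null ≥ observed}) / (1 + n_perm): ties count against
rejection, the minimum attainable p is 1/(n_perm+1), and p is never 0.
Two-sided p doubles the smaller tail and caps at 1. The default
n_perm = 10 000.

One numerical subtlety is load-bearing: the observed statistic is
computed through the *same* vectorized floating-point path as the
permutation null (the identity permutation rides along as row 0 of the
permutation stack). Without this, a constant response — which occurs in
practice, see "degenerate statistics" below — differs from its own
permutations by last-ulp BLAS rounding noise and the test rejects
spuriously instead of returning p = 1.

## Metrics

Strengths (out/in/total) are row/column sums of the raw directed count
matrix. Eigenvector centrality and the weighted clustering coefficient
are computed on the symmetrized matrix W = M + Mᵀ, matching the default
behavior of the classic desktop SNA tools this protocol mirrors; whether
symmetrization is appropriate for a given question is a substantive
choice, and the directed strengths are always available alongside.
Eigenvector centrality is the Perron vector of W, obtained by power
iteration (relative tolerance 1e-10) with a positive diagonal shift so
bipartite-like spectra (±λ of equal magnitude) cannot oscillate; the
vector is sign-normalized nonnegative and scaled to unit Euclidean norm.
In disconnected networks nodes outside the dominant component score ~0.
Clustering uses the Barrat et al. weighted form
C_i = [1/(s_i(k_i−1))] Σ_{j,h} ((w_ij+w_ih)/2) a_ij a_ih a_jh, chosen
because it weights neighborhood density by tie strength as the protocol
describes; nodes with fewer than two neighbors get C_i = 0 rather than
NaN so regressions never drop rows silently. The formulation sits behind
a single function boundary so an alternative triangle weighting could be
slotted in.

## Dominance

David's Score is computed from raw dyadic win proportions P_ij by
default (every directed agonistic act counts as a win for the actor; a
re-polarization hook for specific behaviors such as avoidance is the
caller's responsibility upstream). The chance-corrected D_ij variant is
available by flag; the two converge as dyadic sample sizes grow, and
both are exposed because the original analysis does not say which was
used. The regression covariate is the ordinal rank of DS (n = most
dominant), not raw DS, so that positive coefficients read "the higher
the rank, the more ...". ΣDS = 0 holds to 1e-12 by construction.

**A circularity to be aware of:** when the hierarchy covariate is
estimated from the same agonistic matrix whose metrics are being
modeled, rank is mechanically coupled to the metrics (an individual that
receives many acts loses many dyads, hence scores low). The agonistic
indegree ~ hierarchy association is therefore partly structural, in this
package as in the protocol it implements. The calibration harness
imposes its global null *after* rank estimation (one extra node-label
permutation of the analyzed attribute table) precisely so that this
mechanical coupling is not mistaken for miscalibration of the test.

## Individual-level models

The protocol's individual-level models are fixed-effects OLS: the
field-study analyses this mirrors used a GLM-with-bootstrap procedure
with no stated random-effect structure, so none is modeled here. Two designs per metric: main effects
(intercept + gender + age + matriline + hierarchy, gender coded F=1/M=0)
and gender interaction (intercept + six gender-specific slopes, no
shared main effects, matching the Males\*Age / Females\*Age table
layout). Rows with missing matriline are dropped from both designs
(both contain matriline) and the count is reported. Standard errors are
bootstrap-of-cases (resampling individuals with replacement,
default 1000); estimates are plain OLS and the permutation machinery
affects only p-values. A term is flagged significant when p < α = 0.05
**and** |estimate| > 0.009; the effect floor reproduces the protocol's
explicit minimum-effect filter, is a plain parameter, and terms
suppressed by the floor alone are marked so the filter's bite is
visible. Matriline enters as its ordinal integer code (larger = higher
matriline).

## Group level

The categorical statistic is mean(between-group ordered dyad weights) −
mean(within-group), zero-weight dyads included: excluding them would
conflate tie formation with tie strength (switchable). Negative values
indicate homophily (within-group ties heavier than between-group ties). Moran's I uses raw directed
weights with no row standardization — the analytic anchors I = +1 (two
disjoint reciprocal dyads, attribute constant within dyads) and I = −1
(one reciprocal pair, distinct values) hold exactly for the raw form,
and the permutation-null mean is −1/(n−1). I is invariant to affine
transforms of the attribute and to global weight rescaling. Matriline
and hierarchy homophily are tested with Moran's I on their numeric codes
(they are graded, not nominal, in this pipeline); the categorical test remains
available for any categorical column. Per-gender variants re-run the
test on the induced single-gender submatrix; structurally degenerate
combinations (e.g. gender homophily within one gender) are reported as
NaN rows with a note, keeping the 24-row report shape stable.

## Synthetic troop generator

The generator emulates the study conditions: 52 individuals
(25 F / 27 M), integer ages uniform on 1–25, 8 matrilines partitioned
over the females with ≥2 members each, males attached to their mother's
matriline, and 9 individuals (8 M, 1 F) whose matriline is masked as
missing in the *observed* table while the generator retains the truth.
Latent dominance implements matrilineal rank inheritance with youngest
ascendancy: each female scores matriline_code + spread · f where f
decreases with age among sisters (strictly younger ⇒ strictly higher),
and males occupy an independent uniform stratum over the same range.
The band width (`matriline_spread`, default 4.5) deliberately lets
adjacent matrilines interleave: real dominance orders are
matriline-structured but not block-partitioned, and with strictly
non-overlapping blocks the female rank covariate is so collinear with
matriline that conditional rank effects are unrecoverable by any
analysis at this sample size.

Counts are independent Poisson per ordered dyad with the log-linear
rate given in `synthetic_data`'s module docstring. Baselines are
calibrated so mean grand totals match the observed study scale (5867
agonistic, 1281 grooming events; per-seed totals vary ±10–12% with the
troop's age profile). Planted effects cover female-female grooming,
same-gender agonism, age homophily, matriline homophily, age-related
activity decline (applied to giver and receiver, so indegree declines
with age as well as outdegree), rank-directed agonism (dominants give
more, receive less), grooming directed at high-ranking females, and
matriline-graded agonistic activity. The default effect sizes are a
frozen, versioned preset (presets.py, version 2026.1), tuned once by
grid search until the qualitative direction structure of the headline
findings is recovered in ≥90% of troops, then fixed. A practical finding
from that tuning: *larger* planted rank effects reduce sign recovery,
because exponential rates make the response so convex in rank that a
linear model's coefficient split across collinear covariates becomes
leverage-dominated; moderate effects are both more realistic and more
recoverable. A Gamma–Poisson overdispersion hook exists
(`dispersion`) but defaults to pure Poisson: no dispersion estimate
exists to tune it against. The generator does not model dyadic
reciprocity correlation, observation error, bout durations, or
demographic turnover — passing tests therefore show the *analysis
machinery* is sound under the assumed data-generating process, not that
the process matches any particular field system.

## Degenerate statistics under the homogeneous null

With every planted effect at zero the dyadic rates are homogeneous and
at study-scale totals (~2.2 expected agonistic acts per directed dyad)
the null agonistic network is complete with probability ≈ 1. On a
complete graph the clustering coefficient is identically 1: the
statistic is constant, carries no information, and its permutation test
returns p = 1 under the tie convention. The type-I calibration suite
therefore checks such tests for conservativeness (rejection rate ≤ α;
observed 0) and checks the binomial envelope around α only for tests
whose statistic actually varies; degeneracy is detected from the data
(zero range of the metric), not assumed. All 98 non-degenerate tests
calibrate within a family-wise 95% envelope (Šidák-adjusted per-test
level — ~100 simultaneous plain 95% intervals would each fail 5% of the
time by construction).

## Determinism

One master seed drives everything. Per-stage seeds derive from
SHA-256("stage-name|master") mod 2³¹, so adding a stage never perturbs
earlier stages' draws, and two runs with the same seed produce
byte-identical reports (verified down to file bytes in the tests).

## Problem sizes used by the validation suite

Oracle-equivalence checks run on 50 random ≤10-node digraphs;
exact-enumeration agreement at n = 5–6 (Moran) and n = 7 (coefficients;
the 5-term design requires n ≥ terms + 2); type-I calibration on 1000
zero-effect 52-individual troops at 200 permutations per test;
direction recovery on 100 field-study troops; the determinism check runs
the full 52-individual pipeline twice at 200 permutations. These sizes
keep the full suite at a few minutes on one core while leaving every
estimate's Monte-Carlo error well inside the asserted envelopes.

## Known limitations

- Fixed-effects OLS stands in for the ambiguous "GLMM"; no random-effect
  structure is modeled.
- Eigenvector and clustering symmetrize the directed matrix; directed
  variants are not offered.
- The categorical homophily statistic mixes tie formation and strength
  (zero dyads included by design; switchable).
- Moran's I on ordinal codes (matriline, rank) treats them as interval
  scales.
- No multiple-testing correction across the 20 model tables or the
  homophily battery, by design: each table answers its own question.
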