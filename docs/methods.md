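# Methods

## The model

`condlab` analyses two-condition conditioned-response data under the
standard paired-design normal model: each participant i contributes a
difference score d_i = cs1_i − cs2_i, assumed i.i.d. normal with mean
μ_d and standard deviation σ_d. The standardised effect size is
δ = μ_d/σ_d. Two hypotheses are compared:

* H0: δ = 0 (no CR difference between the stimuli);
* H1: δ ~ Cauchy(0, r) — the Jeffreys–Zellner–Siow (JZS) default prior
  on the effect size.

The Bayes factor is the ratio of the marginal likelihood of the observed
t statistic under the two hypotheses. Because t is a sufficient summary
for δ in this model, BF10 depends on the data only through (t, ν, N):

BF10 = ∫ f_ν(t; δ√N) Cauchy(δ; 0, r) dδ / f_ν(t; 0),

with f_ν(·; ncp) the noncentral Student-t density, ν the degrees of
freedom and N the effective sample size. For the paired design
ν = n − 1, N = n. With a two-level group column the analysed quantity is
the between-group contrast of difference scores, tested with a classical
pooled-variance two-sample t (ν = n1 + n2 − 2) and N = n1·n2/(n1 + n2),
so the frequentist ν and the Bayesian effective-N algebra refer to the
same design. BF01 = 1/BF10 exactly (computed, never re-integrated), and
posterior odds = prior odds × BF10.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| r | Cauchy scale on δ (dimensionless) | 0.707 | the common software default for the JZS test; the literal printed value is used rather than √2/2 (difference ~1e−4 in BF) |
| prior_odds | P(H1)/P(H0) before data | 1 | equal prior plausibility, the usual reporting convention |
| alpha | significance level for the report's labels | .05 | conventional; Bonferroni-style values can be passed per call |
| sensitivity grid | scales at which BF10 is re-evaluated | 0.1–2.0, step 0.05, plus {0.707, 1.0, 1.414} | covers the narrow-to-ultrawide range discussed in the field; the canonical trio is always present and highlighted |

## Numerical evaluation

The δ-integral is compactified by δ = r·tan(θ), under which the Cauchy
prior becomes the uniform measure dθ/π on (−π/2, π/2), and evaluated with
adaptive quadrature (relative tolerance 1e−10, reported per call in
`quad_error`; failure to converge raises, never a silent NaN). Two
features need explicit resolution: the Cauchy core of width r at δ = 0
and the likelihood peak of width ~1/√N at the MLE δ̂ = t/√N. When r is
very small the peak sits in the far prior tail, compressed against
θ = π/2, so the outer region |δ| > 10r is integrated in log|δ| space,
where the 1/δ² prior tail is a smooth exponential. scipy's noncentral-t
density can return NaN or raise at astronomically large noncentrality;
those points are treated as the exact zero the true density has
underflowed to.

Every call also evaluates an independent second formulation — the Cauchy
written as a normal scale mixture, δ | g ~ N(0, g) with
g ~ inverse-gamma(1/2, r²/2), integrated over g in log space so that both
the prior bump (g ≈ r²) and the likelihood bump (g ≈ δ̂²) are O(1)-wide
features. The two routes must agree to 1e−6 relative; disagreement is an
error. In testing, worst-case disagreement across t ∈ [−5, 5],
n ∈ {5, …, 200}, r ∈ [1e−6, 100] is ~1e−11.

Degenerate inputs fail loudly: zero-variance difference scores (or zero
pooled variance) make the t statistic undefined and raise; group columns
with ≠ 2 levels, or a level with fewer than two rows, are rejected at
table construction. Missing data are handled by listwise deletion with a
logged count of dropped rows — standard paired-test practice that keeps
the cs1/cs2 vectors aligned.

## Design choices

* **Primary formulation** is the δ-integral (numerically tame, a single
  compactification); the g-mixture form is retained as the built-in
  cross-check rather than an alternative backend.
* **Pooled-variance (not Welch) two-sample test**, so that ν, N and the
  pooled-t reference distribution are mutually consistent between the
  frequentist and Bayesian halves of the report.
* **Two-sided tests only**; the prior is symmetric, BF10(t) = BF10(−t),
  and directional (one-sided) priors are out of scope.
* **Sign conventions**: differences are always CS1 − CS2; group levels
  are ordered by first appearance in the file, fixing the sign of the
  between-group t.
* **Evidence vocabulary**: the full Jeffreys band table — anecdotal
  (1–3], substantial (3–10], strong (10–30], very strong (30–100],
  decisive (>100) — applied to whichever of BF10/BF01 exceeds 1. A BF
  in the 3–10 band is labelled "substantial" here even though it is
  sometimes called "strong" informally; Wetzels-style wording is an
  alternative vocabulary, not implemented.
* **Rounding is presentation-only**: results objects and the JSON export
  carry full float precision; the report rounds t, d, BF to 2 decimals
  and p to 3 (floored at "p < .001").
* **Interpretation is opt-in** and explicitly flagged as a report based
  on the numerical values that researchers are free to question or
  ignore.

## The sensitivity curve near its peak

For fixed (t, ν, N), BF10 as a function of r rises from 1 (at r → 0 the
alternative collapses onto the null) to a single interior maximum near
the scale best matched to the observed effect, then declines — wider
priors spend mass on large effects the data do not support. For the
acquisition-sized example (t = 2.92, n = 40) the exact maximum sits at
r ≈ 0.37, so on the default 0.05-step grid the curve declines strictly
from r = 0.35 onward; at plot resolution the decline appears to start
just above r ≈ 0.3. `direction_stable` flags only whether BF10 stays on
one side of 1 over the whole grid; no numeric "robust/not robust"
threshold is imposed beyond that.

## The synthetic-data generator

`simulate_conditioning` draws each participant's (cs1, cs2) pair from a
bivariate normal with means (μ1, μ2), common sd σ and correlation ρ; the
implied paired effect size is δ = (μ1 − μ2)/(σ√(2(1 − ρ))). Defaults
(n = 40, σ = 1, ρ = 0.5) mirror a typical single-group startle study of
the size analysed in the worked examples. The generator matches the
normal-theory assumptions of the tests it feeds — deliberately, since
the tests are the object under study. It does **not** emulate the
skewness, zero-inflation (non-responders), habituation or trial-level
structure of real psychophysiological data, so passing calibration tests
here demonstrates correctness of the statistical machinery under its own
assumptions, not robustness to real-data pathologies. Randomness uses
numpy's PCG64 (`default_rng`), fixed across platforms; batch replicates
derive per-replicate seeds from `SeedSequence(base_seed, spawn_key=(i,))`
so any single replicate can be regenerated in isolation.

## Problem sizes used in the test suite

Frequentist agreement with the closed-form reference uses 1,000 random
small tables; type-I calibration uses 5,000 null tables of n = 30
(empirical rejection rate compared with .05 within 3 binomial standard
errors); evidence-for-null consistency uses 200 replicates at n = 500;
the formulation-equivalence grid covers t ∈ {−5, …, 5}, n ∈ {5, 20, 40,
200}, r ∈ {0.5, 0.707, 1, 1.414}. These sizes make the full suite run in
under a minute while leaving the statistical bounds comfortably
non-trivial.

## Known limitations

* Only two stimuli and up to two groups; no ANOVA/multi-stimulus or
  repeated-measures extensions, no individual-differences modelling.
* Input is one row per participant; trial-level averaging is the user's
  preprocessing step.
* No posterior distribution or credible interval for δ — the package
  reports Bayes factors and odds only.
* No informed/meta-analytic prior presets; the Cauchy scale is the only
  prior knob exposed.
* The acquisition-phase sample size n = 40 used in the worked examples is
  inferred from the companion test's printed 39 degrees of freedom on the
  same sample.
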