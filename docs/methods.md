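# Methods

## The calibration problem

A multiplexed assay of variant effect (MAVE) reports a continuous score
per variant measuring some function relative to wild type. Clinical
variant classification under the ACMG/AMP framework instead consumes
discrete lines of evidence with a strength (supporting / moderate /
strong / very strong) and a direction (pathogenic / benign). `mavecal`
maps a gene's assay scores onto that scale: it learns, per gene or
domain, which score ranges carry which evidence strength, together with
the gene-specific prior probability of pathogenicity, and quantifies the
uncertainty of those score thresholds by bootstrap.

## Model

Scores are oriented so that **lower scores indicate functional
abnormality** (inputs in the opposite orientation are negated on read).
Four labeled samples are modeled: ClinVar P/LP controls (`P`), ClinVar
B/LB controls (`B`), a gnomAD reference sample (`G`) and, when the assay
reports them, synonymous variants (`S`). Every sample shares one pair of
skew-normal components — functionally abnormal `SN(s; θ_a)` and
functionally normal `SN(s; θ_n)` — and differs only in its mixing weight:

    p_i(s) = w_i · SN(s; θ_a) + (1 − w_i) · SN(s; θ_n),  i ∈ {P, B, G, S}.

The skew-normal family `SN(μ, ω, λ)` (location, scale, skew) was chosen
because assay score distributions are routinely asymmetric, and because
the family admits a tractable EM via its half-normal constructive
representation `X = μ + Δ·T + Γ^{1/2}·U` with `Δ = ωλ/√(1+λ²)`,
`Γ = ω² − Δ²`.

Two structural assumptions carry all the clinical content:

1. **Assay validity**: pathogenic variants are more often functionally
   abnormal than benign ones, `w_P > w_B`.
2. **Monotone density ratio**: `SN(s; θ_a)/SN(s; θ_n)` is non-increasing
   in `s` over the observed score range. Together with (1) this makes the
   local positive likelihood ratio

       lr+(s) = p_P(s) / p_B(s)

   non-increasing, so a more abnormal score can never yield weaker
   pathogenic evidence.

The reference sample is itself a pathogenic/benign mixture of the same
two clinical score distributions, which identifies the prior:

    P(Y=1) = (w_G − w_B) / (w_P − w_B).

An estimate outside the open interval (0, 1), or a fit with
`w_P ≤ w_B`, is flagged invalid and excluded downstream.

## Evidence point system

Evidence strengths live on a log-LR+ point scale: supporting / moderate /
strong / very strong are ±1/±2/±4/±8 points and a combination worth `n`
points has `LR+ = c^(n/8)`. Given a prior, `c` is the smallest constant
for which every combination in the combining-rule set pushes the
posterior

    P(Y=1 | e) = LR+·π / ((LR+ − 1)·π + 1)

past its target: 0.99 for pathogenic combinations, 0.90 for likely
pathogenic. The solver brackets and bisects the monotone constraint
system (relative precision 1e-6; < 1 ms).

**Rule-set choice.** The default rule set is the classical ACMG/AMP
combining table with one deliberate placement: the "two strong lines ⇒
pathogenic" combination is carried at the 0.90 tier rather than 0.99.
The canonical solutions of this point system — c ≈ 350 at prior 0.1 and
c ≈ 1124 at prior 0.044 — put two strong lines at posterior ≈ 0.975;
requiring 0.99 of an 8-point combination would instead force c ≈ 891 at
prior 0.1 and break the scale. With this placement the binding constraint
is the 6-point likely-pathogenic tier, giving the closed form
`c = (9·(1−π)/π)^{4/3}`. The rule set is plain data
(`EvidenceCombination` tuples, loadable from YAML) so VCEP-specific
variants can be swapped in. Benign-side combinations do not constrain
`c`; benign floors are `c^(−points/8)`. The intermediate ±3 level is
included by default since the point scale makes it well defined.

## EM with the monotone-ratio constraint

The E-step computes each observation's abnormal responsibility with its
own sample's weight, plus the conditional moments `E[T|s]`, `E[T²|s]` of
the half-normal latent variable (inverse-Mills terms computed through
`erfcx`, stable arbitrarily far into the tails). The M-step updates each
component's `(μ, Δ, Γ)` by pooling responsibilities across all samples —
the location update uses the old `Δ`, `Δ` the new location, `Γ` both new
values; iterated to a fixed point these coordinate updates maximize the
expected complete-data log-likelihood (verified against a numerical
maximizer in the test suite) — and each sample's weight as its mean
responsibility. Mixture log-densities use log-sum-exp throughout.

After each component update the density-ratio constraint is re-imposed:
the ratio is checked on a 512-point grid spanning the observed score
range padded by 5% on each side (padding guards edge crossings), and on a
violation a 50-step binary search along the segment between the last
feasible parameter vector and the proposal keeps the largest feasible
step. The full `(μ, Δ, Γ)` vector of the updated component is
interpolated (the skew is implied by `Δ/√Γ`, so it participates in the
projection). A clipped update is kept only if it does not lower the
observed-data log-likelihood; otherwise it is reverted, which preserves
monotone ascent (unclipped block updates ascend by standard EM theory).

**Initialization.** K-means (K=2, 10 inits, seeded) on the pooled
observations; per-cluster Gaussian fits give scales; skews are drawn from
U(−0.25, 0.25) (the skew direction empirically does not change during
EM, so varied small initial skews diversify the restarts); the component
with the lower location is labeled abnormal and keeps that identity. The
initial location is set by moment matching,
`μ = cluster mean − ω·δ·√(2/π)` with `δ = λ/√(1+λ²)`: the skew-normal
likelihood is nearly flat along the mean-preserving location/skew ridge
(the Fisher information in `λ` is singular at `λ = 0`), so the cluster
mean — not the location — is what the data pin down, and anchoring the
implied mean keeps the fitted location from inheriting the arbitrary
initialization skew. Initial sample weights are the per-sample fractions
of observations in the abnormal cluster, kept off the absorbing
boundaries (clipped to [0.05, 0.95]). If the initial pair violates the
ratio constraint, the component locations are moved apart in steps of 5%
of the score range until it holds.

**Restarts and convergence.** `fit` runs `n_restarts` independent
restarts (default 100; restart `r` seeded `seed + r`) and keeps the
highest-likelihood model. EM stops when the relative log-likelihood
change drops below 1e-6 or at 500 iterations. A component with vanishing
pooled responsibility (all weights at a boundary) is frozen rather than
updated, making degenerate single-component configurations exact fixed
points. `Γ` is floored at 1e-12 times the pooled variance.

## Thresholds, bootstrap, and evidence assignment

For a fitted model and its `(prior, c)`, the threshold of pathogenic
level `+x` is the largest score whose lr+ still meets `c^(x/8)`, found by
bisection (1e-8 score tolerance) on the monotone log-lr+ curve over the
padded observed range; benign level `−x` symmetrically uses the smallest
score with `lr+ ≤ c^(−x/8)`. Levels whose floor is never met are absent.

Uncertainty: each bootstrap iteration (default 5000; iteration `i` seeded
`seed + i`) independently resamples each labeled set with replacement —
keeping the sets disjoint by construction — refits the mixture,
re-estimates the prior, re-solves `c` for that prior and recomputes
thresholds. Iterations with invalid priors are excluded from aggregation
but counted. The reported threshold per level is the 5th percentile
across iterations on the pathogenic side and the 95th on the benign side
(the conservative tail of each direction; we read the percentile choice
as per-direction), and a level is reported only when at least 95% of the
valid iterations reach it. The reach rule is evaluated against
valid-prior iterations only, consistent with the exclusion rule.

Per-variant evidence is the strongest pathogenic level whose threshold
the score meets, else the strongest benign level, else 0 (indeterminate).
Variants used in fitting are assigned out-of-bag: the mode over the
assignments of all valid iterations whose resampled set did not include
the variant, with ties broken toward 0 and a residual ±tie toward the
benign side (conservative).

## Diagnostics

Fit quality per sample is the normalized p=2 distance between the
empirical CDF and the fitted mixture CDF, both evaluated at all unique
observed scores of that sample:

    d(F, G) = ‖F − G‖₂ / (‖F‖₂ + ‖G‖₂)  ∈  [0, 1].

This normalization satisfies every property required of the distance
(range, p=2, evaluation at unique scores); it is isolated in
`normalized_vector_distance` so an alternative normalization can be
swapped in one place. On the reference and synonymous samples — larger
and less subject to ascertainment bias than the clinical controls — a
median distance below ≈ 0.2 across bootstrap fits is the working
accept-the-fit signal; distances on P/LP and B/LB are reported but are
noisier.

Evidence directions against ClinVar classes are summarized by a 2×3
contingency table dichotomized positive-vs-rest, reporting the positive
likelihood ratio `(TP/P)/(FP/N)` and diagnostic odds ratio
`TP·TN/(FN·FP)`; zero denominators raise an explicit undefined-result
signal with an optional 0.5 continuity correction.

## Synthetic data

The generator draws each sample from the shared component pair with its
configured weight — exactly the model's data-generating process — and
writes a truth sidecar (component indicators, weights, implied prior) as
a separate file so the pipeline cannot consume it. Defaults define the
reference conditions used throughout the tests: components
`SN(−3, 1, 0.2)` and `SN(0, 1, −0.2)` (a well-separated assay, roughly
3σ), `w_P = 0.9`, `w_B = 0.05`, `w_S = 0.02`, `w_G` set by a target prior
of 0.1 (giving 0.135), 2000 variants per sample. A fixture suite adds an
overlapping-pathogenic regime (`w_P = 0.5`, emulating an assay blind to
part of the disease mechanism), a tiny-B/LB regime (8 benign controls,
matching the smallest published control sets), and a three-sample
no-synonymous regime.

What the generator does **not** emulate: replicate-level measurement
error, ascertainment bias in the clinical control sets, scores from
mechanisms the mixture cannot represent (e.g. gain- plus loss-of-function
in one gene), splice-driven outliers, or non-skew-normal score shapes.
Passing recovery tests therefore demonstrates correctness of the
estimator under its own assumptions, not robustness to real-data
violations of them; the CDF-distance diagnostic is the tool for judging
the latter on real assays.

## Numerical and scale choices

- Constraint grid: 512 points, 5% padding; monotonicity slack 1e-12 in
  the enforcement check (tests allow 1e-9).
- Binary search: 50 bisections; threshold root-finding: 1e-8 in score.
- c-solver: bisection to 1e-6 relative precision.
- Test problem sizes: recovery uses 20 generator replicates at
  2000/sample with 10 restarts; fit-quality uses 50 bootstrap refits of
  one dataset; bootstrap-behavior tests use a few hundred observations.
  These sizes make the suite a desk-scale experiment while keeping
  Monte-Carlo error well inside the asserted tolerances.
- The reduced bootstrap mode (e.g. 200 iterations, 10 restarts) is the
  documented testing default; 5000 × 100 is the full analysis scale.

## Known limitations

- Location and skew of a component are only weakly separated by the
  likelihood near `λ = 0`; reported locations are accurate to ~0.15 score
  units under the reference conditions, while component *means* are much
  tighter. Downstream quantities (lr+, thresholds, prior) depend on the
  densities, not the parameterization, and are unaffected by the ridge.
- A single abnormal component cannot represent genes with coexisting
  gain- and loss-of-function mechanisms; a three-component extension is
  out of scope.
- The prior estimate degrades when `w_P − w_B` is small (a weak assay):
  the bootstrap then excludes many iterations and widens percentile
  thresholds, which is the intended conservative behavior.
- Dataset-specific normalizations (e.g. multi-promoter medians) are left
  to upstream preprocessing; the reader accepts precomputed splice-effect
  scores and documents, rather than resolves, the protein-level
  aggregation ambiguity for assays described only at the protein level.
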