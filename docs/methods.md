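# Methods

## Model

Let `Q` be a finite item set and `L = {ℓ0 < ℓ1 < … < ℓn}` a finite chain of
response levels, coded internally as `0…n`. A state is a mapping
`K : Q → L`; a polytomous structure `𝒦` is a nonempty subset of `L^Q`, with
the pointwise partial order `K1 ⊑ K2 iff K1(q) ≤ K2(q)` for all `q`. A
respondent's latent state is drawn from a distribution `π` on `𝒦`; given the
state, responses are locally independent, with
`P(R_q = j | K_q = i) = ε_q(i, j)` collected in a row-stochastic `|L|×|L|`
error matrix per item. Marginal pattern probabilities are the mixture over
states; the model has `|Q||L|(|L|−1) + |𝒦| − 1` free parameters. The
two-level case reduces exactly to the basic local independence model with
careless-error and lucky-guess rates.

Probabilities are treated as lying in the open interval `(0, 1)`: estimation
applies a floor of `1e-12` to `ε` entries and `π` before renormalizing,
which avoids `log 0` while approximating the open-interval constraint.
Per-pattern conditional probabilities are accumulated in the log domain, so
long domains cannot underflow. Likelihoods are computed on aggregated
distinct patterns with frequencies.

## Monotonicity conditions

For a level metric (or general dissimilarity) `δ`, a pair function `f` is
`δ`-monotone when `δ(i,j) < δ(i,k) ⟺ f(i,j) > f(i,k)` for all level
triples; ties on either side falsify the biconditional and are reported as
violations. Half-monotonicity restricts the test to same-side triples,
implemented as `{i ≤ min(j,k)} ∪ {max(j,k) < i}` — one bound reflexive, one
strict. This is a deliberate reading of an ambiguous boundary convention:
with both bounds reflexive a 4-level chain has 56 such triples and with both
strict 28, while either one-strict variant yields the canonical count of 44
out of 64; the variant written above (reflexive on the side at or above
`i`, strict on the side below) is implemented.

Checkers accept partial pair functions (triples with undefined values are
skipped), and a transposed accessor turns every row checker into a column
checker. Level-metric construction enforces symmetry, zero diagonal and
positive off-diagonals, but *not* the triangle inequality or the
order-respecting condition: useful dissimilarities violate them, so both are
checkable reports rather than invariants. Modality (strict diagonal row
maximum) coincides with Hamming-monotonicity; the overall-error condition
(`ε(i,i)` exceeds the sum of the row's other entries) implies a diagonal
above 1/2.

Half-monotone rows are reparameterized by decay rates: for row `i`,
`υ_{ij} = ε(i,j)/ε(i,j+1)` for `j < i` and `ω_{ij} = ε(i,j)/ε(i,j−1)` for
`j > i` — each rate steps one column further from the diagonal, and the row
is half-monotone iff all its rates lie in `(0, 1)`. The forward map builds
the row outward from an unnormalized diagonal of 1 and normalizes; the
diagonal then equals `(1 + Σ of the off-diagonal products)^{-1}`. Forward
and inverse maps are exact inverses on positive rows (verified numerically
to `1e-12`).

## EM estimation

The unconstrained M-step is the complete-data maximizer of the latent-class
likelihood (posterior-weighted count ratios for `ε`, posterior-weighted
frequencies for `π`); it reduces to the classical dichotomous EM. The
default stopping rule is an absolute log-likelihood change below `1e-6`
(library default) with an iteration cap of 2,000.

The *exactly uniform* start `ε = 1/|L|`, `π = 1/|𝒦|` is a saddle point of
the EM map: uniform rows make `P(R|K)` independent of `K`, so the posterior
equals the prior and every update reproduces the same point. The default
initialization therefore keeps `π` uniform but tilts each error row slightly
toward its diagonal, `ε(i,j) = (1 + κ·1[i=j]) / (|L| + κ)` with `κ = 0.5`.
This is deterministic, breaks the saddle in the direction that aligns latent
levels with the observed coding, and is symmetric over items and levels.
Random restarts draw error rows and `π` from flat Dirichlet distributions,
seeded.

The constrained EM keeps every row inside the half-monotone family by
updating the decay rates: each item row's expected complete-data
log-likelihood `Σ_j c_ij log ε_j(rates)` is maximized by L-BFGS-B on
logit-transformed rates, started at the previous iterate, and a proposal is
accepted only when it improves the row objective. This generalized-EM
contract preserves the monotone log-likelihood guarantee (slack `1e-8` for
float noise) without closed-form constrained updates, which do not exist for
this family.

The empirical identifiability probe fits the model repeatedly from random
starts, keeps the fits within a log-likelihood window (default `1e-3`,
configurable) of the best, and reports the maximum across-fit standard
deviation over all parameters; values below `1e-3` are conventionally read
as consistent with identifiability.

## Minimum-discrepancy estimation

MD assumes a pattern can only be generated by the states at minimum
distance from it, the distance being the per-item sum of a level metric
(Hamming or Manhattan). The per-item additive form is the natural
generalization of the dichotomous symmetric-difference distance and is the
only additive choice consistent with the level metrics above. Each pattern's
frequency is spread *uniformly* over its tied minimum-distance states (the
direct generalization of the dichotomous method's uniform conditional);
estimates are then the same closed-form count ratios as the EM M-step with
the posterior replaced by this assignment. Error rows whose latent level
receives no mass carry no information; they fall back to the uniform row and
are flagged with a warning.

## Structure extraction

The ordinal k-median alternates (a) assigning each observed pattern to its
nearest centroid under the Manhattan sum, ties to the lowest-index centroid,
and (b) replacing each centroid by the component-wise weighted *lower*
median of its assigned patterns. Both steps are coordinate-wise minimizers,
so the within-cluster discrepancy never increases and the algorithm reaches
a fixed point (cap 100 iterations by default). Empty clusters are dropped;
duplicate final centroids are merged.

Candidates are scored on a validation split by two asymmetric
discrepancies: the frequency-weighted mean over respondents of the distance
to the nearest state, and the unweighted mean over states of the distance to
the nearest *distinct* observed pattern — matching the index sets of the two
defining sums (respondent-averaged vs. state-averaged). The selected
structure minimizes the larger of the two (minimax), with ties broken by
smaller structure, then input order.

## Simulation study and synthetic data

The generator emulates a Likert-type questionnaire setting: 10 items, 4
levels, a random structure of 1,000 states drawn uniformly without
replacement from `L^Q` minus the extremes and always containing the bottom
(all-0) and top (all-max) states, and a uniform state distribution. True
diagonals are uniform on `[m, 1)` with `m ∈ {.75, .85, .95}` (defaults to
`.95`); off-diagonal values are uniform draws normalized to `1 − diagonal`,
so the overall-error condition always holds. The monotone scenario re-orders
the same off-diagonal values within each side of the diagonal to decrease
with level distance, so paired scenarios share identical diagonals and
off-diagonal multisets per row. One structure, one `π`, and one true `ε` set
are held fixed across replications — bias and the across-replication SD of
each estimate (the reported "SE") presuppose a fixed truth. Replication
seeds are spawned from the master seed, so replications are independent and
could be distributed.

What the generator does *not* emulate: respondent heterogeneity beyond the
state mixture (no per-person error rates), item wording effects, missing
responses, or any dependence between items given the state. Passing
recovery checks therefore demonstrates correctness of the estimators under
the model's own assumptions, not robustness to their violation.

### Scaled replication sizes

The package's desk-scale replication of the recovery study (in
`tests/test_acceptance.py`) uses the full structural design — 1,000 states,
10 items, 4 levels, `m = .95`, N = 2,000 — with 20 replications per scenario
instead of 100, and an EM tolerance of `1e-4` for study runs (`1e-6` stays
the library default). Twenty replications are sufficient for the sign-level
bias patterns and order-of-magnitude SE checks the study design targets;
per-parameter SEs are noisier than at 100 replications, which the test
tolerances reflect. The qualitative findings replicated are: unconstrained
EM unbiased in both scenarios; constrained EM biased exactly when the truth
violates row monotonicity (inflated one level from the diagonal, deflated
far from it); Manhattan-MD over-estimating at level distance 1 and
under-estimating at distance ≥ 2, with the bias largely vanishing under a
monotone truth; Hamming-MD compressing toward the middle (over-estimation
of small true values, under-estimation of large ones) in both scenarios.

## Numerical choices and degenerate inputs

- Probability floor `1e-12`; row/distribution sums validated to `1e-10`.
- Monotonicity conditions use strict inequalities exactly; equal values are
  violations.
- k-median ties: lowest-index centroid; even-count medians: lower median.
- Random structure generation uses rejection sampling on a seeded stream
  (never materializing `L^Q`) and switches to enumeration when the
  requested size exceeds half the product space.
- Exhaustive pattern enumeration refuses above a configurable cap
  (default 2·10⁶ rows).
- `em_fit` on a single-state structure reduces to observed response
  proportions; MD on noiseless data returns empirical frequencies and
  degenerate diagonals.

## Known limitations

- Constrained M-steps are numerical (bounded quasi-Newton per row); they
  are accepted only when improving, so convergence can be slower than the
  unconstrained EM near the boundary of the monotone family.
- No analytic standard errors; the nonparametric bootstrap is provided for
  EM-type fits, and none exists for MD estimates.
- Identifiability is probed empirically only; no Jacobian-rank analysis.
- Structures read from files are not required to contain the bottom and top
  states (only the random generator forces them).
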