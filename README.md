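# polikst

Probabilistic knowledge space theory for **polytomous** items: a latent-class
framework for questionnaires and tests whose items are scored on an ordinal
scale (e.g. a 0–3 Likert scale) rather than right/wrong.

## Who this is for

Psychometricians and applied statisticians who model item-response data
combinatorially: instead of a continuous latent trait, each respondent
occupies a *state* `K : Q → L` assigning a response level to every item, and
only the states of a *structure* `𝒦 ⊆ L^Q` are admissible. The dichotomous
case (`|L| = 2`) is classical knowledge space theory with the basic local
independence model (BLIM); this package implements its polytomous
generalization (PoLIM) together with the estimation and structure-building
machinery around it.

## The model

Each respondent's state `K` is drawn from a distribution `π` on `𝒦`. Given
the state, item responses are conditionally independent, governed by one
row-stochastic error matrix `E_q` per item with entries
`ε_q(i, j) = P(R_q = j | K_q = i)`:

    P(R | K) = ∏_q ε_q(K(q), R(q)),        P(R) = Σ_{K ∈ 𝒦} P(R | K) π_K

with `|Q||L|(|L|−1) + |𝒦| − 1` free parameters. For `|L| = 2` the
off-diagonals of `E_q` are the careless-error and lucky-guess rates
`β_q = ε_q(1,0)`, `η_q = ε_q(0,1)` of the BLIM.

The package covers:

- **Monotonicity theory** for the error matrices: modality (the true level
  is modal), overall error (diagonal > sum of the row's off-diagonals),
  and δ-(half-)monotonicity under a level metric — Hamming, the discrete
  Manhattan metric, or any order-respecting metric — with exhaustive
  witness-reporting checkers, row and column variants.
- **A constrained reparameterization**: half-monotone rows are encoded by
  overrate/underrate decay rates `ω, υ ∈ (0,1)` (each off-diagonal entry is
  its inner neighbour times a rate), turning inequality constraints into box
  constraints.
- **Estimation**: unconstrained EM, constrained (generalized) EM over the
  decay rates, and closed-form minimum-discrepancy (MD) estimation under
  Hamming or Manhattan pattern–state distances; an empirical
  identifiability probe by multistart EM.
- **Structure extraction**: ordinal k-median clustering of observed
  patterns (component-wise medians as centroids) with minimax selection on
  the two asymmetric data↔structure discrepancies.
- **A parameter-recovery simulation study** replicating the published
  design: random 1,000-state structures over 10 items and 4 levels, error
  matrices with diagonal floor `m ∈ {.75, .85, .95}`, paired scenarios with
  and without row monotonicity, and bias/SE reporting per parameter class.

## Worked example

`examples/02_monotonicity.py` builds an error-matrix row from its decay
rates and runs the checkers:

```text
row for latent level 2 (x157): [  2.  10. 100.  30.  15.]
modality:            True
overall error row 2: True (all rows: False)
half-monotone:       True
fully monotone:      False (e.g. eps(2,4)=0.0955 > eps(2,1)=0.0637)
restricted (same-side) triples on a 4-chain: 44 of 64
recovered rates: 0.20000000000000004 0.1 0.3 0.5
```

The rates `υ = (2/10, 1/10)`, `ω = (3/10, 5/10)` generate the row
`(2, 10, 100, 30, 15)/157`: probabilities decay away from the true level on
each side (half-monotonicity) even though the row is not fully monotone
(`ε(2,4) > ε(2,1)` compares across sides). `epsilon_to_rates` inverts the
construction exactly.

`examples/03_fitting_em_vs_md.py` fits a simulated sample (15 states, 5
items, 3 levels, N = 3,000):

```text
method                max |eps err|  max |pi err|       loglik
EM (unconstrained)           0.0913        0.0094    -12181.50
EM (constrained)             0.0816        0.0165    -12317.16
MD (Manhattan)               0.1698        0.0315    -12458.81
MD (Hamming)                 0.0684        0.0142    -12249.99
```

EM maximizes the likelihood; MD trades likelihood for a closed form based on
minimum-distance states. The other examples cover model basics, structure
extraction, and a miniature recovery study.

A thin CLI mirrors the library: `polikst simulate-structure | simulate-data
| fit-em | fit-md | check-monotonicity | extract | recovery-study`
(see `polikst --help`).

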