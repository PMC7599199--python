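"""Build a small polytomous model and evaluate its probabilities.

A 3-item questionnaire on a 0-2 scale, five admissible belief states, a
state distribution, and per-item error matrices; prints a conditional and a
marginal pattern probability, the total probability over all 27 patterns,
and the model's free-parameter count.
"""

import numpy as np

from polikst import (
    Domain,
    LevelSet,
    PolimParameters,
    PolytomousStructure,
    conditional_pattern_prob,
    count_free_parameters,
    enumerate_patterns,
    marginal_pattern_prob,
    simulate_responses,
)

structure = PolytomousStructure(
    Domain(("calm", "tense", "worried")),
    LevelSet((0, 1, 2)),
    [(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 1), (2, 2, 2)],
)

# 80% of the mass on the true level, the rest split over the other levels
eps = np.tile(0.7 * np.eye(3) + 0.1, (3, 1, 1))
pi = np.array([0.25, 0.20, 0.25, 0.20, 0.10])
params = PolimParameters(structure, eps, pi)

R, K = (1, 1, 1), (1, 1, 0)
print(f"P(R={R} | K={K}) = {conditional_pattern_prob(R, K, params):.6f}")
print(f"P(R={R})         = {marginal_pattern_prob(R, params):.6f}")

total = sum(marginal_pattern_prob(r, params)
            for r in enumerate_patterns(structure.domain, structure.levels))
print(f"sum of P(R) over all 3^3 patterns = {total:.12f}  (must be 1)")

print(f"free parameters: {count_free_parameters(structure)} "
      "(= |Q||L|(|L|-1) + |K| - 1)")

data, latent = simulate_responses(params, 1000, seed=1)
print(f"simulated N=1000; {data.n_patterns} distinct response patterns")
# The conditional probability multiplies one error-matrix entry per item;
# the marginal mixes it over the five states weighted by pi.
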