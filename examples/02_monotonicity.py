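"""Monotonicity conditions on an item's error matrix.

Builds the worked half-monotone row from its overrate/underrate decay
rates, then runs the row checkers: modality, overall error, full and half
monotonicity under the discrete Manhattan metric.
"""

import numpy as np

from polikst import (
    RateParameters,
    check_modality,
    check_overall_error,
    epsilon_to_rates,
    is_delta_half_monotone,
    is_delta_monotone,
    manhattan_metric,
    rates_to_epsilon,
    restricted_triples,
)

# five ordered levels; row 2 is pinned by four decay rates
rates = RateParameters.from_flat("item", np.full(20, 0.5), 5)
rates.upsilon[2, 0], rates.upsilon[2, 1] = 2 / 10, 1 / 10
rates.omega[2, 3], rates.omega[2, 4] = 3 / 10, 5 / 10

E = rates_to_epsilon(rates)
print("row for latent level 2 (x157):", np.round(E.probs[2] * 157, 6))
# (2, 10, 100, 30, 15)/157 -- the probability decays away from the diagonal
# on each side, at the given rates.

metric = manhattan_metric(5)
print("modality:           ", check_modality(E))
row2 = E.probs[2]
print("overall error row 2:", row2[2] > row2.sum() - row2[2],
      "(all rows:", str(check_overall_error(E)) + ")")
half, _ = is_delta_half_monotone(E.probs, metric)
full, violations = is_delta_monotone(E.probs, metric)
print("half-monotone:      ", half)
print("fully monotone:     ", full,
      f"(e.g. eps(2,4)={E.probs[2,4]:.4f} > eps(2,1)={E.probs[2,1]:.4f})")

print(f"restricted (same-side) triples on a 4-chain: "
      f"{len(restricted_triples(4))} of 64")

back = epsilon_to_rates(E)
print("recovered rates:", back.upsilon[2, 0], back.upsilon[2, 1],
      back.omega[2, 3], back.omega[2, 4])
# Half-monotonicity only constrains comparisons on one side of the true
# level, which is exactly what the decay-rate parameterization encodes.
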