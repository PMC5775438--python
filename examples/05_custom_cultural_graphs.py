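"""Beyond two cultural states: custom cultural transition graphs.

Two bundled builders: a one-way chain (states that can only move forward,
like proposed unidirectional morphological change) and a pure/mixed/pure
three-state graph.  Any composition-dependent kernel can be plugged into the
same exact solver.
"""

import numpy as np

from coculture import (
    build_custom_model,
    mixed_chain,
    solve_fixation_probabilities,
    unidirectional_chain,
)

N = 40
labels = ("archaic", "transitional", "innovative")

# Specialists are adapted to the final state of a one-way cultural drift:
# disadvantaged early, advantaged once culture arrives.
advantage = np.tile([-0.1, 0.0, 0.1], (N + 1, 1))
kernel = unidirectional_chain(3, rate=0.01)
model = build_custom_model(N, labels, advantage, kernel)
eps = solve_fixation_probabilities(model)
print("One-way cultural chain, specialist adapted to the final state:")
for j, lab in enumerate(labels):
    print(f"  start in {lab:>12}: fixation probability of 1 mutant = {eps[1, j]:.5f}")
print(f"  (neutral drift would give 1/N = {1/N:.5f})")
print()

# Mixed-state graph with composition dependence: more specialists pull the
# culture toward the 100% state.
kernel3 = mixed_chain(0.0, 0.0, rate_fn=lambda i: (0.02 * (1 + i / N), 0.02))
model3 = build_custom_model(N, ("0%", "50%", "100%"), np.tile([-0.1, 0.0, 0.1], (N + 1, 1)), kernel3)
eps3 = solve_fixation_probabilities(model3)
print("Pure/mixed/pure graph, forward rate rising with specialist count:")
for j, lab in enumerate(("0%", "50%", "100%")):
    print(f"  start in {lab:>4}: fixation probability = {eps3[1, j]:.5f}")
print()
print("Starting nearer the specialist-favoured state raises the invader's")
print("chances; the solver handles any row-stochastic, level-dependent kernel.")
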