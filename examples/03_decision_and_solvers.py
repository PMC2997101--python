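"""Compare the solver stack on one instance and ask a decision question.

Builds a noisy two-group planted graph just above the exact-enumeration
comfort zone, runs greedy and the memetic algorithm, then answers a
threshold (Yes/No) question with the greedy-localisation procedure on a
smaller instance where enumeration can certify the answer.
"""

from ahcut import (
    DecisionTarget,
    MemeticConfig,
    enumerate_optimum,
    evolve,
    fpt_decide,
    greedy_partition,
)
from ahcut.synthetic import planted_partition_graph

graph, truth = planted_partition_graph(
    (12, 12), d_within=1.0, d_between=10.0, noise=0.3, rng_seed=5
)
greedy, _ = greedy_partition(graph)
best, log = evolve(graph, MemeticConfig(max_generations=50, rng_seed=5))
print(f"n={graph.n}: greedy value {greedy.value:,.1f}, "
      f"memetic value {best.value:,.1f} after {len(log)} generations "
      f"({log[-1]['restarts']} diversity restarts)")
recovered = {frozenset(best.members(1)), frozenset(best.members(2))} == {
    frozenset(l for l, g in truth.items() if g == 0),
    frozenset(l for l, g in truth.items() if g == 1)}
print(f"memetic split matches the planted groups: {recovered}")

# Decision question on an enumerable instance: is there a split of value >= k/l?
small, _ = planted_partition_graph((2, 2), 1.0, 10.0)
opt = enumerate_optimum(small).best_value  # 80
for k, l in [(80, 1), (161, 2)]:
    yes, certificate = fpt_decide(small, DecisionTarget(k, l))
    print(f"value >= {k}/{l} = {k / l}: {'Yes' if yes else 'No'}"
          + (f" (certificate value {certificate.value:.1f})" if yes else ""))
# 80/1 is answered Yes with the planted split as certificate; 161/2 = 80.5
# exceeds the optimum, so the answer is No.
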