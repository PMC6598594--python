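"""Build a phenotype Markov chain from attractors via perturbation.

Attractors are merged by their signature-gene pattern into phenotype
states.  Each state is then perturbed (5% flip probability, escalating
until the system leaves the basin) and the recorded destinations define a
transition matrix; raw frequencies are divided by the phenotype distance
and mean simulation length, then rows are renormalized.
"""

import numpy as np

from phenoflow import attractor_campaign, build_matrix, merge_attractors, transition_campaign
from phenoflow.bn_dynamics import state_to_bits
from phenoflow.synthetic import planted_attractor_network

net, _ = planted_attractor_network(k_basins=2, seed=0)
signature = net.node_order[:4]  # first loop + one node of the second

rng = np.random.default_rng(2)
camp = attractor_campaign(net, 2000, max_iter=100, rng=rng)
states = merge_attractors(camp.attractors, signature, net)
print(f"{len(camp.attractors)} attractors merge into {len(states)} phenotype states:")
for s in states:
    print(f"  state {s.state_id}: pattern {state_to_bits(s.pattern)}, "
          f"basin weight {s.basin_weight}")

records = transition_campaign(net, states, signature, 400, max_iter=100, rng=rng)
dtmc = build_matrix(records, states, signature)
print("\ntransition matrix (rows = source phenotype):")
print(np.round(dtmc.P, 3))
print(f"row sums: {dtmc.P.sum(axis=1)}")
print("-> probabilities favor nearby phenotypes and short simulations;")
print("   every row sums to one, so population mass is conserved.")
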