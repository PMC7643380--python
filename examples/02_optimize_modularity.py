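"""Maximize multilayer modularity and inspect the temporal communities.

Generates one synthetic subject with seven planted resting-state networks
over four occasions and runs the generalized Louvain optimizer repeatedly.
"""

import numpy as np

import longnet as ln

cfg = ln.small_test_config(n_subjects=1, seed=4)
subject = ln.generate_cohort(cfg).subjects[0]

ensemble = ln.repeated_optimization(subject.network, n_reps=20, base_seed=7)
res = ensemble.results[0]

print(f"network: N={subject.network.n_nodes}, L={subject.network.n_layers}")
print(f"mean Q over {ensemble.n_reps} optimizations: {ensemble.mean_Q:.4f}")
print(f"modules in the first run: {ln.count_modules(res.partition)}")
q_check = ln.evaluate_Q(subject.network, res.partition, res.params)
print(f"optimizer Q {res.Q:.10f} vs. direct formula evaluation {q_check:.10f}")

truth_flex = ln.node_flexibility(subject.truth).mean()
est_flex = np.mean([ln.node_flexibility(p).mean() for p in ensemble.partitions])
print(f"ground-truth global flexibility: {truth_flex:.3f}; recovered: {est_flex:.3f}")
print("a clearly positive Q with seven modules reflects the planted community")
print("structure; the recovered flexibility tracks the generator's switching rate.")
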