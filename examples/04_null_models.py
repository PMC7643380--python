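"""Compare real metric distributions against temporal and nodal nulls.

A small cohort is compared to nodal nulls (recruitment should collapse
when edges are rewired) using Welch's t test and Cohen's d.
"""

import numpy as np

import longnet as ln

cfg = ln.small_test_config(n_subjects=10, seed=21)
cohort = ln.generate_cohort(cfg)

real, null = [], []
for i, rec in enumerate(cohort.subjects):
    labels = rec.network.network_label_array()
    ens = ln.repeated_optimization(rec.network, n_reps=5, base_seed=100 + i)
    real.append(ln.summarize(ens, rec.network.node_labels, labels).global_means["recruitment"])
    msets = ln.null_ensemble(rec.network, "nodal", n_null=3, n_reps=5, base_seed=200 + i)
    null.append(np.mean([m.global_means["recruitment"] for m in msets]))

comp = ln.compare_to_null(np.array(real), np.array(null), metric="recruitment")
print(f"global recruitment: real {np.mean(real):.3f} vs. nodal null {np.mean(null):.3f}")
print(f"Welch t({comp.df:.1f}) = {comp.t:.1f}, p = {comp.p:.2e}, "
      f"d = {comp.d:.2f} ({ln.interpret_d(comp.d)})")
print("a large positive effect means the planted community structure is far")
print("from random: regions co-occur with their own network much more than")
print("in weight-preserving rewired layers.")
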