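"""Temporal community metrics for one subject.

Computes flexibility, promiscuity, cohesion strength, disjointedness and
recruitment, aggregated from nodes to the seven predefined networks.
"""

import longnet as ln

cfg = ln.small_test_config(n_subjects=1, seed=11)
subject = ln.generate_cohort(cfg).subjects[0]
labels = subject.network.network_label_array()

ensemble = ln.repeated_optimization(subject.network, n_reps=20, base_seed=3)
ms = ln.summarize(ensemble, subject.network.node_labels, labels)

print("global metrics (ensemble-averaged):")
for name, value in ms.global_means.items():
    print(f"  {name:18s} {value:8.4f}")
print(f"  {'Q_mean':18s} {ms.Q_mean:8.4f}")
print("\nper-network flexibility:")
print(ms.per_network["flexibility"].round(4).to_string())
print("\nflexibility is the fraction of occasion-to-occasion transitions at")
print("which a region changes community; recruitment is how consistently a")
print("region co-occurs with its own resting-state network across time.")
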