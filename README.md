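# longnet

Longitudinal reconfiguration of brain functional networks, analyzed as a
multilayer temporal community-detection problem.

`longnet` is for researchers studying how the modular organization of the
functional connectome changes over years-long follow-up: each measurement
occasion contributes one weighted connectivity layer, the layers are
coupled in time, and community structure is estimated for all occasions
simultaneously. The package covers the full pipeline:

1. **Connectome construction** — Pearson correlation of ROI time series,
   Fisher r-to-z transform, removal of negative weights (optionally keeping
   only FDR-significant edges), assembly into per-subject multilayer
   networks over the seven canonical resting-state networks (FPCN, DMN,
   DAN, SVAN, LIMB, SM, VIS).
2. **Multilayer modularity** — maximization of

   Q = (1/2μ) Σ_{ijlr} [(A_ijl − γ P_ijl) δ_lr + δ_ij ω_jlr] δ(g_il, g_jr)

   with the Newman–Girvan intralayer null P_ijl = k_il k_jl / 2m_l and
   ordinal interlayer coupling ω between a node and itself in adjacent
   layers, via a generalized Louvain optimizer (supporting the `move` and
   `moverandw` move rules), averaged over many stochastic restarts.
3. **Temporal metrics** — node/network/global flexibility, promiscuity,
   cohesion strength, disjointedness, the module allegiance matrix, and
   network recruitment.
4. **Null models** — temporal (layer-order shuffling) and nodal
   (within-layer weight rewiring) nulls, compared with Welch's t and
   Cohen's d.
5. **Cohort statistics** — metric ~ age regressions with partial η²,
   metric intercorrelations with age-partialled variants, per-subject
   cognitive change slopes, and change–change brain–cognition
   correlations.
6. **Synthetic cohorts** — a generator that plants known community
   structure, age-dependent switching, and cognitive decline, retaining
   the ground truth so every stage is testable end to end.

## Worked example

```bash
python examples/04_null_models.py
```

```
global recruitment: real 0.621 vs. nodal null 0.266
Welch t(10.2) = 21.3, p = 8.96e-10, d = 9.54 (large)
```

Regions of a simulated cohort co-occur with their own resting-state
network in 62% of (layer, optimization) instances, versus 27% after the
layer weights are rewired — a very large effect, showing the detected
communities reflect planted structure rather than chance. The other
examples (`examples/01` – `05`) walk through layer construction,
optimization, metrics, and the cohort statistics; `examples/05` recovers a
positive age → flexibility coefficient and a strong negative
modularity–flexibility correlation from a simulated aging cohort.

The same stages are available as a thin CLI for file-based workflows:

```bash
longnet simulate --subjects 10 --nodes 56 --seed 1 --out-dir cohort/
longnet optimize cohort/sub000.mlnet --reps 100 --seed 42 --out sub000.partitions
longnet metrics sub000.partitions --network-map cohort/network_map.csv --out sub000.metrics.csv
```

All outputs are plain text and byte-identical across re-runs with the same
seed.

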