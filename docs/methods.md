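# Methods

## Model

A subject observed at L measurement occasions is represented as a
multilayer network: one N×N nonnegative, symmetric, zero-diagonal weighted
graph per occasion over a fixed node set, with interlayer edges of weight
ω linking each node to itself in adjacent layers (ordinal coupling; no
categorical or longer-range coupling is implemented). A partition assigns
every (node, layer) copy a community id that is global across layers, and
is scored by the multilayer modularity

Q = (1/2μ) Σ_{ijlr} [(A_ijl − γ·P_ijl)·δ_lr + δ_ij·ω_jlr]·δ(g_il, g_jr),

with P_ijl = k_il·k_jl/(2m_l), k_il the strength of node i in layer l,
2m_l the total weight of layer l, ω_jlr = ω for |l−r| = 1 and 0 otherwise,
and 2μ = Σ_jl (k_jl + c_jl) where c_jl is node j's total interlayer
coupling strength in layer l. One description of this quality function in
circulation defines m as the *average* edge weight; this package follows
the standard Newman–Girvan convention in which 2m_l is the *total* layer
weight, which is the normalization the widely used generalized-Louvain
implementations apply. An all-zero layer makes 2m_l undefined and is
rejected.

### Layer construction

ROI time series are correlated pairwise (Pearson), Fisher r-to-z
transformed, and negative values and the diagonal are set to zero, giving
positive weighted networks. Correlations of magnitude 1 are clipped to
1 − 1e−7 before atanh so weights stay finite for the optimizer. An
optional thresholded mode retains only edges significant under
Benjamini–Hochberg FDR control (the field-default FDR procedure) at a
configurable α, with p-values from the exact t transform of r; the
correction runs over the N(N−1)/2 unique pairs of one subject's matrix
(per-subject correction — pooling across subjects would need the whole
cohort in memory and is not what a subject-level pipeline implies).
Layers are joined by node label, not position; a subject missing any
occasion is rejected rather than imputed.

### Optimization

The optimizer is a Louvain-style agglomerative scheme on the supra graph
of N·L node-layer copies: local-move sweeps in freshly shuffled node
order, followed by aggregation of communities into super-nodes, repeated
until no move improves Q. Under the `move` rule the best strictly
improving move is taken (RNG tie-break); under `moverandw` (the default)
one of the strictly improving moves is chosen with probability
proportional to its gain, which mitigates known pathologies of the
deterministic rule under ordinal coupling. Every accepted move strictly
increases Q (threshold 1e−12 on the gain, so floating-point noise cannot
cycle); a sweep cap of 1000 guards against non-termination. Q is tracked
incrementally from the accepted gains, and the test suite verifies it
against an independent evaluation of the formula to 1e−10. Community ids
are canonicalized by order of first appearance scanning nodes, then
layers, making partitions comparable bit-for-bit. Because the algorithm
is stochastic, results are reported as ensembles of seeded restarts
(default 100; reduced sizes are used in the test suite, see below), with
Q averaged over the ensemble.

Defaults γ = 1, ω = 1 are the conventional operating point: γ scales the
intralayer null term (larger γ, more and smaller modules), ω the
interlayer coupling (larger ω, more temporally persistent modules). Both
monotonicity properties are exercised in the tests.

### Temporal metrics

For each optimization run: flexibility is a node's number of
consecutive-layer community changes over L−1; promiscuity is the number
of distinct communities the node visits divided by K, the number of
distinct communities in that partition (K could alternatively be defined
over the whole ensemble; the per-partition reading is the default and the
alternative is a documented extension point); cohesion counts, for each
node pair, transitions at which both move from a common community to a
common different community, with cohesion strength the row sum of that
matrix (an unbounded raw count); disjointedness counts a node's switches
that no other node shares — same (source, target) pair at the same
transition — over L−1. Under these definitions a community split or merge
yields positive cohesion and zero disjointedness for every participating
node. The allegiance matrix is the fraction of (layer, run) instances in
which two nodes share a community; recruitment is a node's mean
allegiance to same-network peers, self excluded (nodes in singleton
networks are flagged missing and excluded from aggregates). Run-level
metrics are averaged across the ensemble, then aggregated node → network
→ global by unweighted means; network-level flexibility is the mean of
member-node flexibilities (not a recomputation on the subnetwork).

### Null models

The temporal null permutes the order of a subject's layers uniformly at
random (identity permutation allowed; with L = 4 there are only 24
orderings, so separate seeds may coincide). The nodal null permutes each
layer's upper-triangle weights over node pairs independently per layer,
then symmetrizes: the layer's weight multiset, density and total weight
are preserved exactly while community structure is destroyed. A
strength-sequence-preserving rewiring (configuration-model style) is a
possible stricter alternative; the simpler pair-permutation null is the
implemented choice. Per subject, metric values are averaged across the
null realizations before the group comparison, so the real and null
samples are paired in length; comparisons use Welch's two-sample t with
Satterthwaite degrees of freedom, Cohen's d = |Δmean|/pooled SD
(small/medium/large at 0.2/0.5/0.8), and Bonferroni-adjusted significance
α/n over the family of metrics compared.

### Cohort statistics

Each metric is regressed (OLS) on grand-mean-centered age at baseline
plus gender (1 = female), education (numeric 1–3), and mean framewise
displacement; partial η² per predictor is SS_effect/(SS_effect + SS_res)
from the type-III decomposition (equal to t²/(t² + df_res) for these 1-df
terms, an identity the tests verify against squared partial correlation).
Metric intercorrelations (mean Q, global recruitment, global flexibility)
are Pearson r with Fisher-z confidence intervals, plus age-partialled
versions via residual-on-residual correlation.

Per-subject cognitive change is the OLS slope of the score on time in
years (occasions at 0, 1, 2, 4). The retest/practice effect — a jump
common to all follow-ups — is estimated at cohort level by pooled OLS on
time + retest indicator and removed before the subject fits. This
two-stage estimate replaces a random-slope mixed model deliberately: the
slopes serve only as correlation inputs, and the transparent version has
no convergence or boundary issues; an optional empirical-Bayes shrinkage
mode (weights from the between-subject slope variance net of sampling
variance) is provided for noisy designs. Change–change associations are
Pearson correlations between slopes and flexibility measures, with
age-partialled variants.

## Synthetic cohorts

The generator emulates the target study conditions: 150 subjects, 200
regions split into the seven networks with the Schaefer-200/Yeo-7 block
sizes (30, 45, 23, 22, 12, 37, 31; proportionally scaled for other N,
equal blocks in tests), 4 occasions at years 0, 1, 2, 4; baseline ages
truncated-normal on [64, 83] with mean 69.8 (scale 4 years, location
solved so the truncated mean is exact). Layer-one communities are exactly
the seven networks; each transition flags nodes to switch with
probability clip(p₀ + β_age·(age − mean age), 0, 1), defaults p₀ = 0.2
and β_age = 0.004/year, and executes each community's flagged group
either cohesively (all move to one common target; probability 0.75 by
default) or as independent lone moves. Weights are drawn directly on the
Fisher-z scale as block means (0.5 within, 0.1 between communities —
values typical of z-transformed cortical functional connectivity) plus
Gaussian noise (SD 0.1) clipped at zero, matching the positive-network
assumption; clipping, not resampling, keeps the generator fast and the
zero inflation mirrors thresholded real matrices. An optional mode emits
latent block-factor ROI time series instead, so the correlation stage is
exercised end to end. Cognitive T-scores use intercept 50, mean slope
−0.5 points/year, age steepening −0.05 points/year², subject slope SD 1,
retest bump +1.8 at follow-ups, and unit residual noise. All randomness
descends from one seed sequence (cohort → subject → stage), so cohorts
are bit-reproducible and any subject can be regenerated alone.

The generator writes ground-truth partitions for every subject, and the
metric definitions invert the generative events: truth-based flexibility
equals the switching probability in expectation, cohesive events produce
cohesion without disjointedness, and lone events the reverse — the
generator and the metrics module are mutual oracles in the tests. What
passing on these cohorts shows is that the pipeline's computations are
correct and sensitive under the designed signal; it does not certify
performance on real BOLD-derived matrices, whose noise is neither
Gaussian, independent, nor stationary.

## Problem sizes and numerical choices

The test and acceptance workloads use reduced sizes chosen to keep the
statistical checks well-powered while remaining quick on one CPU:
cohort-level checks run 30 subjects × 56 nodes × 4 layers with 10
optimizer restarts and 5–10 nulls per subject; the age-recovery check
uses 150 subjects at 56 nodes with 10 restarts; exhaustive-enumeration
checks use 6 nodes × 2 layers (≈ 7×10⁵ partitions into ≤ 4 blocks).
Degenerate inputs are rejected loudly rather than repaired: zero-variance
time series (named node), all-zero layers, asymmetric matrices,
rank-deficient designs (named columns), zero-variance Welch samples, and
subjects with under three occasions (flagged missing). Ties in the
deterministic move rule are broken by the run's seeded RNG; all file
output uses 17-significant-digit floats so re-runs are byte-identical.

## Known limitations

- Negative-edge-aware modularity variants are out of scope; negative
  correlations are discarded by construction.
- Only ordinal, uniform interlayer coupling is supported (no multi-aspect
  networks, no layer-specific γ_l).
- The nodal null preserves the weight multiset but not node strength
  sequences.
- Change slopes are two-stage OLS estimates, not mixed-model BLUPs; with
  strongly unbalanced designs the shrinkage mode is advisable.
- The generator's noise model is i.i.d. Gaussian on edge weights;
  realistic scanner/motion artifacts are not simulated.
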