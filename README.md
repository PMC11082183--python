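# phosphonet

Signaling-network dissection and kinase/phosphatase activity inference from
sparse, censored phosphoproteomic matrices.

## The problem

Bottom-up phosphoproteomics measures the abundance of phosphopeptides across
dozens to hundreds of samples, but 20–80% of the entries are missing — and
much of that missingness is *informative*: peptides below the instrument's
limit of detection (LOD) are absent exactly because their abundance is low
(missing-not-at-random, MNAR). phosphonet reconstructs, de novo, which
kinases and phosphatases (KP-enzymes) regulate which phosphosites, and then
uses those networks to read out per-sample enzyme *activity* — the quantity
drug-response and resistance studies actually care about, and one that no
single phosphopeptide measures directly.

Intended users: computational biologists analyzing phosphoproteomic cohorts
(clinical tumor panels, drug-perturbation time courses) who need
context-specific kinase→substrate networks and per-sample activity scores
without relying on generic interaction databases.

## The method

**hpMI — hybrid-partitioning mutual information.** For a candidate pair of
rank vectors (enzyme proxy peptide KP, substrate S), the sample space is
split into four quadrants by observed/missing status. Jointly observed
points are scored with the adaptive-partitioning MI estimator (recursive
midpoint splits of the rank plane accepted while a χ² heterogeneity
statistic over the four sub-cells exceeds χ²₃,0.05 = 7.815); the quadrant
structure itself is scored as a discrete 2×2 system, so co-censoring of an
enzyme and its substrate counts as evidence of dependence:

    hpMI(X;Y) = I(Bx; By)  +  (n11/N) · MI_adaptive(X, Y | both observed)

where Bx, By are the observed/missing indicators and n11 the jointly
observed count. With no missing values this reduces exactly to adaptive-
partition MI. Significance is controlled family-wise: the candidate matrix
is row-permuted (values and missingness together), and the MI threshold is
the Šidák per-test quantile (1 − FWER)^(1/#candidates) of the permutation
null, tail-extrapolated when needed.

**Network dissection.** hpMI is recomputed over N = 200 bootstrap
resamplings of the runs; sub-threshold edges are dropped per bootstrap and
indirect edges pruned by the Data Processing Inequality — for a triangle
KP→KP′, KP′→S, KP→S, the last edge is removed when its MI is the strict
minimum. The signal-transduction variant (stDPI) only assesses triangles
whose intermediary is a kinase, because a phosphatase intermediary inverts
the sign of the putative indirect effect; stDPI is paired with the signed
candidate mode (kinase edges require ρ > 0, phosphatase edges ρ < 0 on
complete pairs). Edges significant under a Poisson model of bootstrap
support (BH-corrected p < 0.05) form the consensus network.

**Signalons and activity.** Each regulator's consensus targets form its
*signalon*: weights w = MI / max(MI) (optionally × normalized priors), modes
of regulation in [−1, 1] from a three-Gaussian mixture over Spearman ρ, and
trimming by the cumulative squared normalized weight Σ(w/w₁)² with a hard
cap of 500 targets. Per-sample differential signatures (row-min + low-noise
imputation, z vs a reference set, symmetric rank quantiles) are scored by an
analytic weighted-rank enrichment:

    NES = Σᵢ wᵢ·xᵢ / sqrt(Σᵢ wᵢ²),   xᵢ ~ N(0,1) under the null

which is z-scaled by construction (verified by KS calibration). Crosstalk
between signalons sharing substrates is corrected by down-weighting the
shared targets of the weaker regulator via CDE = log₁₀(pB) − log₁₀(pA) and
the crosstalk index CI = 20. A second, activity-level network is dissected
from the phosphostate-level activity matrix (regular DPI), and the two
levels are integrated per regulator and sample with Stouffer's method,
(z_PL + z_AL)/√2.

A first-class synthetic-data module generates censored matrices from known
signed enzyme→substrate networks (linear-Gaussian structural model, MNAR
censoring at a per-feature LOD quantile, enzyme cascades, feed-forward
motifs, drug-perturbation time series), so every claim above is testable
without downloads.

## Worked example

```python
from phosphonet import (CandidateSpec, SimConfig, dissect,
                        hierarchical_measure, recovery_report, simulate)

cfg = SimConfig(n_kinases=5, n_phosphatases=3, n_substrates=320,
                targets_per_enzyme=40, n_samples=150, lod_quantile=0.4,
                chain_depth=2, seed=3)
matrix, truth = simulate(cfg)
spec = CandidateSpec(mode="signed-enzyme-list",
                     kinases=set(truth.kinases),
                     phosphatases=set(truth.phosphatases))
network = dissect(matrix, spec, dpi="stdpi", n_boot=200, seed=1)
print(recovery_report(network, truth))
result = hierarchical_measure(matrix, network, spec,
                              matrix.run_index, matrix.run_index,
                              seed=2, n_boot=100)
print(recovery_report(network, truth,
                      activity=result.integrated.nes)["median_activity_spearman"])
```

Output (examples/01 and 03 print the same numbers):

```
consensus edges: 270 (planted direct edges: 364)
precision 0.95, recall 0.71, indirect edges wrongly included 4.17%
median Spearman(true activity, integrated NES): 0.91
```

precision/recall score the consensus edge list against the planted direct
edges; the Spearman value says the integrated per-sample NES tracks each
enzyme's latent activity almost monotonically. The `examples/` directory
holds four narrative scripts: network dissection, the hpMI-vs-dMI/iMI
comparison under 80% censoring, hierarchical activity inference, and an
inhibitor time course with adaptive rebound.

A thin CLI mirrors the library:
`phosphonet simulate | import | dissect | measure | evaluate` (see
`phosphonet --help`).

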