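# Methods

This note documents the models, estimators and numerical conventions the
package implements, the choices made where the design was genuinely open,
and what the synthetic benchmarks do and do not establish.

## Input model and preprocessing

The long-format PVM table (one row per peptide × run, with
gene/protein/site identifiers and log2 intensities) is collapsed to a
site × run matrix. When several peptide precursors cover one phosphosite,
the most consistently detected precursor (highest count of observed runs)
is kept; ties are broken by the higher median intensity. A multiply
phosphorylated precursor contributes one row per site sharing its
intensity vector. Missing entries stay NaN throughout — they are never
imputed before MI estimation, because censoring below the limit of
detection is informative.

Quantile normalization is missingness-aware: within each run group, each
run's observed values are mapped through their ranks onto the across-run
average empirical quantile function; ties share averaged reference
quantiles, missing entries are untouched, and groups with a single run are
skipped with a warning. Centering is row-wise (mean 0 over observed
entries). The alternative — column centering — would remove run-level
offsets that quantile normalization already equalizes, while row centering
puts every site on a common differential scale; row-wise was chosen and is
the convention all downstream steps assume.

Protein-abundance normalization subtracts the matching protein row
(`GENE:ACC:PA`) in log2 space where both values are observed. Where the
protein value is missing the phosphopeptide value is retained unnormalized:
propagating missingness would destroy already-sparse rows, and a missing
protein estimate carries no evidence that the peptide value is wrong.

## hpMI

Adaptive-partition MI follows the recursive midpoint-splitting scheme on
the rank plane: a cell is split into four sub-cells while the χ² statistic
of the sub-cell counts against uniformity exceeds 7.815 (χ², 3 df,
α = 0.05); cells with ≤ 2 points or unit rank width are leaves. Cell
probabilities use rank widths, so marginals are exactly uniform. A
`max_depth` argument forces a fixed 2^d × 2^d grid instead, which makes the
final partition explicit; on such grids the estimator coincides with the
plug-in discrete MI of the grid's contingency table (tested to 1e-9).

For censored pairs, hpMI is the exact chain-rule decomposition

    I(X;Y) = I(Bx;By) + P(both observed) · I(X;Y | both observed)

estimated as the plug-in MI of the 2×2 observed/missing table plus the
(n11/N)-weighted adaptive MI of the jointly observed points re-ranked among
themselves (the quadrant-1 term is dropped below 4 joint points). This is
one specific resolution of "combine and normalize the four quadrants"; it
was chosen because it reduces *exactly* to adaptive MI under completeness,
is symmetric, non-negative, and additive on the probability scale. The
convention is isolated in `_mi_core.hpmi_ranks` so it can be swapped.

Ranks are computed per row over observed entries; ties (bootstrap-
duplicated runs) are broken by a seeded RNG so bootstrap replicates are
reproducible. MI is in nats everywhere.

Comparison estimators: dMI is adaptive MI over jointly observed points only
(zero below 8 points); iMI imputes each row as row-minimum plus uniform
noise spanning the gap between the two lowest observed values, then applies
adaptive MI to the completed vectors.

**Significance.** The null permutes each row of the rank matrix, values and
missingness together, preserving marginal missingness rates while breaking
all coupling. The family-wise threshold is the null quantile at the Šidák
per-test tail 1 − (1 − FWER)^(1/n_candidates); when the permutation sample
cannot resolve that tail directly, an exponential tail is fit to the top 1%
of null MI values and extrapolated. Brute-force permutation at FWER 0.05
over ~10⁵ candidates is otherwise unreachable. The threshold is computed
once on the full matrix and reused across bootstraps.

## Network dissection

Candidates are enzyme rows × target rows (same-gene pairs excluded; an
enzyme's own sites co-vary through shared peptides), or a supplied
reference edge list with priors. 200 bootstrap resamplings of the runs are
drawn with per-bootstrap RNG streams derived from (seed, bootstrap index),
so results are independent of execution order. Per bootstrap, edges below
the MI threshold are dropped and the selected DPI variant applied:
for each triangle R1→R2, R2→T, R1→T the last edge is removed when its MI is
the strict minimum (a configurable tolerance relaxes strictness). stDPI
assesses only kinase-intermediary triangles. Pruning decisions are
evaluated simultaneously on the unmodified weights.

stDPI is inseparable from the sign model it encodes: kinase edges must
correlate positively, phosphatase edges negatively (checked on complete
pairs at consensus time, `signed-enzyme-list` mode). Phosphatase-routed
indirect paths always inverting sign is exactly why their triangles are
exempt from pruning — the sign filter already excludes them. Benchmarks
therefore run stDPI in signed mode and plain DPI/noDPI without a sign
model, each variant under its own stated assumptions.

**Consensus.** Edge support across bootstraps is tested against
Poisson(λ) with λ = (total edge occurrences) / (number of candidate
pairs) — the marginal support rate of the candidate family, with
never-detected candidates counting as zero. The often-used alternative,
λ = mean support over *detected* edges, degenerates on small networks in
which nearly every detected edge is real (every edge then sits at its own
mean and nothing is significant); the candidate-family rate behaves
identically on large sparse problems and remains calibrated on small ones.
Upper-tail p-values are BH-corrected; adjusted p < 0.05 retained.

Protein-level dissection aggregates each regulator protein's sites into one
row (observed-only mean; missing only where all sites are missing), keeping
substrates at site resolution.

## Signalons

Weights are MI normalized by the network-wide maximum, multiplied by
per-regulator max-normalized priors when supplied (a zero prior drops the
target), and finally rescaled per regulator so the top weight is 1. Modes
of regulation come from a three-component 1-D Gaussian mixture over
Spearman ρ (components relabeled by sorted means; mode =
P(activated|ρ) − P(repressed|ρ)). The mixture is fit on the pooled
network-wide ρ distribution: kinase and phosphatase edges give it the
bimodal separation it needs, whereas per-regulator fits on unimodal ρ sets
are unstable and can flip signs. Two guards apply: fewer than 10 fitting
points, or fitted extreme components that do not straddle zero, fall back
to the linear ramp sign(ρ)·min(1, |ρ|/0.5).

Trimming accumulates s_k = Σ_{i≤k} (w_i/w₁)² over weight-sorted targets and
keeps the smallest k with s_k ≥ T (default T = 50, the regulon-pruning
heritage convention), capped at 500 targets; the published description
leaves open whether T is a stopping threshold or a derived constant, and
the stopping-threshold reading is implemented. Signalons with fewer than
M = 5 targets are excluded from inference.

Cross-dataset optimization scores each candidate signalon on a signature
ensemble and keeps, per regulator, the candidate with the highest median
|NES| — incorrect signalons can only dilute enrichment, so the maximum
identifies the best-supported variant. Redundant signalons of one peptide
are removed greedily by activity correlation (drop the signalon with the
largest mean absolute correlation until no pair exceeds C = 0.5), the
caret `findCorrelation` contract.

## Activity inference

Signatures: missing entries are imputed as row minimum plus uniform noise
spanning the gap between the two lowest observed row values (rows with < 2
observed values get zero range, with a warning); each feature's two-sample
z statistic of test vs reference is mapped to symmetric normal quantiles by
rank. Null ensembles resample pseudo-test sets from the reference.

The enrichment statistic per target blends the signed rank quantile t2
(weight = mode) with the magnitude rank quantile t1 (weight = 1 − |mode|,
signed by the mode), normalized by sqrt(mode² + (1−|mode|)²) to unit null
variance; NES = Σ w·x / sqrt(Σ w²). Signing the one-tailed component by the
mode makes the statistic exactly antisymmetric under mode negation (targets
with mode exactly 0 contribute nothing — sign-free evidence cannot inform a
signed activity call). Calibration is verified empirically: permuted-
signalon NES passes a KS test against N(0,1).

Crosstalk correction, per sample: among significant regulators (two-tailed
p < α = 0.05, log-p computed via `norm.logsf` so extreme z never overflow),
every pair with shared targets defines CDE = log₁₀(pB) − log₁₀(pA) ≥ 0 (A
the stronger). The shared targets' weights in the weaker signalon are
multiplied by m = 1 − 10^(−CDE·NT/CI), NT being the number of pairs that
signalon participates in and CI = 20; B's NES is recomputed from the
down-weighted signalon, A's is untouched. The anchors are m(0) = 0 (equal
significance ⇒ the shared evidence is fully ambiguous and contributes
nothing to the weaker regulator) and m → 1 as the significance gap grows
(a hugely stronger A does not need B's shared targets to explain its own
signal, and B's residual significance is increasingly its own); CI scales
the penalty and NT divides it so many simultaneous pairs do not
over-penalize multiplicatively. The exact functional form mapping the
penalized quantity onto target weights is not published; this choice is
isolated in `crosstalk_correct` and validated by the directional
simulation (the weaker regulator's |NES| shrinks, the stronger one's is
bit-identical).

Hierarchical inference: phosphostate-level (PL) activities for all runs →
activity-level (AL) network dissected from the PL activity matrix with
regular DPI (at the functional level the stDPI sign constraints no longer
apply) → AL activities → per regulator-sample integration
z = (z_PL + z_AL)/√2, falling back to the available level. Equal Stouffer
weights are used; nothing in the two-level design motivates
unequal-variance weighting.

## Synthetic data

A linear-Gaussian structural model: latent enzyme activities are standard
normal per sample (chain children regress on their parent with coupling
`chain_rho`, sign + for kinase parents, − for phosphatase parents); each
enzyme's proxy phosphopeptide correlates with its activity at
`proxy_rho` = 0.95; substrates regress on their parent activity so that the
proxy-substrate Spearman ≈ `effect_rho`. Defaults: `effect_rho` = 0.6 (the
middle of the well-correlated regime, ρ > 0.5, typical of genuine
enzyme-substrate pairs), `noise_sd` = 0.5 as the measurement floor (an
error is raised, with the attainable bound, if the requested effect cannot
coexist with the noise floor), `lod_quantile` = 0.4, i.e. 40% MNAR
missingness, the middle of the 20–80% range seen in practice. Chain
feed-forward motifs (`feedforward_frac` = 0.25 of a child's substrates also
receiving a direct parent term at 0.4× the main effect) place true direct
edges inside enzyme-enzyme-substrate triangles. Values are shifted to
log2-intensity scale (feature baselines ~ N(22, 1.5)) and censored below
the per-feature `lod_quantile` empirical quantile, making missingness
value-dependent by construction. Optional two-batch mean shifts exercise
grouped normalization. Since the estimators are rank-based, monotone-linear
structure suffices; an exponential link (`link="exp"`) stresses estimators
beyond linear correlation.

Perturbation series: enzymes operate `basal_activity` = 2 population-SDs
above zero; inhibiting a target scales its total activity (basal +
deviation) by (1 − inhibition), so full inhibition pins it 2 SDs below its
operating point — without a basal level, pure variance scaling would be
invisible to mean-based differential signatures. Control and perturbed
series share every innovation draw (exact counterfactual pairing) and the
control-derived LODs; an adaptation spec rebounds the activity linearly
back to baseline as an adaptive-resistance surrogate.

What the generator does *not* emulate: peptide-level technical artifacts
(retention-time drift, TMT ratio compression, fractionation effects),
non-stationary network rewiring within a cohort, and combinatorial
multi-site regulation. Passing benchmarks therefore demonstrate correctness
of the inference machinery under the method's own statistical assumptions,
not performance on any particular real instrument or cohort.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` size their simulations as
follows (all on one CPU, suite ≈ 3 min, script ≈ 2 min): null calibration
with 1000 pairs at n = 200 and 50% censoring; estimator comparison with 60
planted pairs × 20 replicates at 80% censoring and ρ ≈ 0.3; cascade
A→B→C at n = 250 with direct-edge ρ ≈ 0.9 and 60 bootstraps; precision
ordering over 10 replicate 8-enzyme/64-substrate cascade networks with
tight chains (`chain_rho` = 0.95, so indirect edges rank among direct ones
and the noDPI penalty is visible) at 100 bootstraps; NES calibration with
1000 permuted 40-target signalons over 2000 features; crosstalk with 200
replicates of the two-regulator shared-target design; end-to-end recovery
over 150-sample cohorts with 8 enzymes × 40 targets at 40% censoring
(20 replicates in the suite, 12 in the acceptance script).

## Known limitations

- The hpMI quadrant combination is one defensible convention among several;
  absolute MI values are not comparable across conventions (thresholds are
  always derived from the matching permutation null, which is what matters).
- Mode-of-regulation fitting assumes the pooled ρ distribution separates
  activated and repressed edges; networks with a single enzyme class and
  homogeneous ρ fall back to the ramp, which saturates at |ρ| = 0.5.
- Crosstalk correction operates pairwise; a regulator whose every target is
  shared with several stronger regulators can be over-penalized.
- The AL network needs enough regulators with PL activities (≥ 3) and
  enough samples; below that the pipeline degrades gracefully to PL-only.
- Protein-level dissection aggregates regulator sites by observed-only
  means, which blurs site-specific (e.g. inhibitory-site) signals; use
  site-level networks when site resolution matters.
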