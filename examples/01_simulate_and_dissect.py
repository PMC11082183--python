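"""Simulate a censored phosphoproteomic cohort and dissect its network.

Generates 150 samples driven by 5 kinases and 3 phosphatases (40% of each
feature censored below its limit of detection), reconstructs the
enzyme -> substrate network with hpMI + stDPI + Poisson consensus, and
scores it against the planted ground truth.
"""

import numpy as np

from phosphonet import CandidateSpec, SimConfig, dissect, recovery_report, simulate

cfg = SimConfig(n_kinases=5, n_phosphatases=3, n_substrates=320,
                targets_per_enzyme=40, n_samples=150, lod_quantile=0.4,
                chain_depth=2, seed=3)
matrix, truth = simulate(cfg)
print(f"matrix: {matrix.n_sites} features x {matrix.n_runs} runs, "
      f"{(~matrix.mask).mean():.0%} missing")

spec = CandidateSpec(mode="signed-enzyme-list",
                     kinases=set(truth.kinases),
                     phosphatases=set(truth.phosphatases))
network = dissect(matrix, spec, dpi="stdpi", n_boot=200, seed=1)
report = recovery_report(network, truth)
print(f"consensus edges: {report['n_predicted']} "
      f"(planted direct edges: {report['n_true']})")
print(f"precision {report['precision']:.2f}, recall {report['recall']:.2f}, "
      f"indirect edges wrongly included {report['indirect_included']:.2%}")
# precision near 1 means almost every reported edge is a planted direct
# interaction; the indirect-inclusion rate shows stDPI suppressing the
# cascade shortcuts (enzyme -> grand-substrate) the chains plant.
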