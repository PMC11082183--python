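"""Why hpMI: dependence detection under heavy value-dependent missingness.

Plants weakly correlated pairs (Spearman ~ 0.3), censors 80% of each
vector below its limit of detection, and counts how many pairs each MI
estimator recovers at the same family-wise threshold: hpMI (treats the
observed/missing pattern as informative), dMI (complete cases only) and
iMI (low-intensity imputation).
"""

import math

import numpy as np

from phosphonet._mi_core import batch_mi
from phosphonet.mi import impute_row_min_noise, null_mi_values, rank_rows

n, npairs, rho, n_rep = 200, 60, 0.31, 5


def censor(v):
    out = v.copy()
    out[out < np.quantile(out, 0.8)] = np.nan
    return out


totals = {"hpMI": 0, "dMI": 0, "iMI": 0}
for rep in range(n_rep):
    rng = np.random.default_rng(rep)
    rows = []
    for _ in range(npairs):
        a = rng.standard_normal(n)
        y = rho * a + math.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        rows.extend([censor(a), censor(y)])
    V = np.vstack(rows)
    ia = np.arange(0, 2 * npairs, 2, dtype=np.int64)
    ib = ia + 1
    null_rows = np.vstack([censor(v) for v in rng.standard_normal((80, n))])

    for name, method, R, nulls_src in [
        ("hpMI", 0, rank_rows(V), null_rows),
        ("dMI", 1, rank_rows(V), null_rows),
        ("iMI", 0, rank_rows(impute_row_min_noise(V, rng)),
         impute_row_min_noise(null_rows, rng)),
    ]:
        nulls = null_mi_values(nulls_src, n_perm=3, seed=rep,
                               estimator="hpmi" if method == 0 else "dmi")
        p = 1 - 0.95 ** (1 / npairs)
        u = np.quantile(nulls, 0.99)
        exc = nulls[nulls > u] - u
        thr = u + np.log((exc.size / nulls.size) / p) * exc.mean()
        out = np.empty(npairs)
        batch_mi(R, ia, ib, method, out)
        totals[name] += int((out >= thr).sum())

for name, count in totals.items():
    print(f"{name:>4}: {count:3d} / {npairs * n_rep} planted pairs recovered")
# hpMI recovers far more because correlated low-abundance pairs censor
# together, and that co-missingness is itself evidence of dependence that
# complete-case analysis discards and imputation blurs.
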