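"""Per-sample kinase/phosphatase activity inference from signalons.

A differential signature (rank-based z-scores of one sample against a
reference set, after row-min + low-noise imputation of censored values) is
scored against each regulator's signalon by an analytic weighted-rank
enrichment statistic, yielding a normalized enrichment score (NES) that is
approximately N(0,1) under the null. Positive NES = activated enzyme.

The hierarchical pipeline infers phosphostate-level (PL) activities, dissects
a second, activity-level (AL) network from the PL activity matrix with
regular DPI, infers AL activities, and integrates both levels per
regulator-sample with Stouffer's method. Pleiotropy between signalons with
shared substrates is handled by the crosstalk correction (CDE penalty).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mi import impute_row_min_noise
from .network import CandidateSpec, Interaction, dissect
from .pvm import PhosphoMatrix
from .signalon import Signalon, signalons_from_network

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "ActivityMatrix",
    "make_signature",
    "make_signatures",
    "make_null_signatures",
    "enrichment_nes",
    "empirical_null_nes",
    "activity_matrix",
    "crosstalk_correct",
    "stouffer",
    "hierarchical_measure",
    "HierarchicalResult",
]


@dataclass
class Signature:
    """Per-sample differential scores on a symmetric rank-quantile scale.

    ``null_ensemble`` (optional) holds B reference-resampled null
    signatures over the same feature space.
    """

    scores: np.ndarray
    features: list[str]
    sample: str = ""
    null_ensemble: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size != len(self.features):
            raise ValueError("scores and features must align")
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature ids must be unique")


@dataclass
class ActivityMatrix:
    """Regulators x samples normalized enrichment scores with two-tailed p-values."""

    nes: pd.DataFrame
    pvalues: pd.DataFrame
    level: str = "phosphostate"

    @property
    def regulators(self) -> list[str]:
        return list(self.nes.index)

    @property
    def samples(self) -> list[str]:
        return list(self.nes.columns)

    def write(self, path, pvalue_path=None) -> None:
        self.nes.to_csv(path, sep="\t")
        if pvalue_path is not None:
            self.pvalues.to_csv(pvalue_path, sep="\t")


def _quantile_scale(z: np.ndarray) -> np.ndarray:
    """Map scores to symmetric normal quantiles via their ranks."""
    n = z.size
    r = stats.rankdata(z, method="average")
    return stats.norm.ppf(r / (n + 1))


def _zscores(values: np.ndarray, test_idx, ref_idx) -> np.ndarray:
    ref = values[:, ref_idx]
    tst = values[:, test_idx]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    n_t, n_r = len(test_idx), len(ref_idx)
    return (tst.mean(axis=1) - mu) / (sd * math.sqrt(1.0 / n_t + 1.0 / n_r))


def make_signature(
    m: PhosphoMatrix,
    test_runs: Sequence[str],
    reference_runs: Sequence[str],
    noise_seed: int = 0,
    null_size: int = 0,
) -> Signature:
    """Differential signature of ``test_runs`` against ``reference_runs``.

    Missing entries are imputed as row minimum plus uniform noise whose
    range is the gap between the two lowest observed values of the row
    (breaking ties from identical imputed values); the per-feature z
    statistic of test vs reference is then mapped to symmetric normal
    quantiles by rank.
    """
    if not len(reference_runs):
        raise ValueError("reference run set must be nonempty")
    rng = np.random.default_rng(noise_seed)
    imputed = impute_row_min_noise(m.values, rng)
    col = {r: j for j, r in enumerate(m.run_index)}
    test_idx = [col[r] for r in test_runs]
    ref_idx = [col[r] for r in reference_runs]
    scores = _quantile_scale(_zscores(imputed, test_idx, ref_idx))
    nulls = None
    if null_size:
        nulls = make_null_signatures(imputed, ref_idx, len(test_idx), null_size,
                                     seed=noise_seed + 1)
    return Signature(scores, list(m.site_index),
                     sample=",".join(map(str, test_runs)), null_ensemble=nulls)


def make_null_signatures(
    imputed_values: np.ndarray,
    ref_idx: Sequence[int],
    n_test: int,
    size: int,
    seed: int = 0,
) -> np.ndarray:
    """Null signature ensemble from reference-resampled pseudo-test sets."""
    rng = np.random.default_rng(seed)
    ref_idx = np.asarray(ref_idx)
    out = np.empty((size, imputed_values.shape[0]))
    replace = n_test >= ref_idx.size
    for b in range(size):
        pick = rng.choice(ref_idx, size=n_test, replace=replace)
        out[b] = _quantile_scale(_zscores(imputed_values, pick, ref_idx))
    return out


def _target_stat(scores: np.ndarray, idx: np.ndarray, modes: np.ndarray) -> np.ndarray:
    """Per-target unit-variance enrichment statistic.

    Blends the signed rank-quantile (two-tailed, weight = mode) with the
    magnitude rank-quantile (one-tailed, weight = 1 - |mode|, signed by the
    mode) and rescales to unit null variance. Exactly antisymmetric under
    mode negation.
    """
    n = scores.size
    t2 = stats.norm.ppf(stats.rankdata(scores, method="average")[idx] / (n + 1))
    t1 = stats.norm.ppf(stats.rankdata(np.abs(scores), method="average")[idx] / (n + 1))
    num = modes * t2 + (1.0 - np.abs(modes)) * np.sign(modes) * t1
    denom = np.sqrt(modes ** 2 + (1.0 - np.abs(modes)) ** 2)
    return np.where(denom > 0, num / denom, 0.0)


def enrichment_nes(sig: Signature, s: Signalon, min_targets: int = 5) -> float:
    """Analytic rank-based NES of one signalon in one signature.

    Weighted sum of per-target statistics scaled by sqrt(sum w^2), a
    z-score under the independence null. Returns NaN (regulator skipped)
    when fewer than ``min_targets`` signalon targets are in the signature's
    feature space.
    """
    pos = {f: i for i, f in enumerate(sig.features)}
    keep = [k for k, t in enumerate(s.targets) if t in pos]
    if len(keep) < min_targets:
        logger.info("regulator %s skipped: %d targets in feature space", s.regulator, len(keep))
        return float("nan")
    idx = np.array([pos[s.targets[k]] for k in keep])
    w = s.weights[keep]
    x = _target_stat(sig.scores, idx, s.modes[keep])
    return float(np.sum(w * x) / math.sqrt(np.sum(w ** 2)))


def empirical_null_nes(nes: float, null_nes: np.ndarray) -> tuple[float, float]:
    """Rescale an NES against its regulator-specific null NES distribution.

    Returns (calibrated z, two-tailed empirical p). The p-value is floored
    at 2/(B+1), the resolution of a B-sized null.
    """
    null_nes = np.asarray(null_nes, dtype=float)
    B = null_nes.size
    if B < 100:
        logger.warning("null ensemble of size %d; p-values floored at %.3g", B, 2 / (B + 1))
    mu, sd = null_nes.mean(), null_nes.std(ddof=1)
    z = (nes - mu) / sd if sd > 0 else 0.0
    lo = int(np.sum(null_nes <= nes))
    hi = int(np.sum(null_nes >= nes))
    p = min(1.0, 2.0 * (1 + min(lo, hi)) / (B + 1))
    return float(z), float(p)


def _nes_pvalues(nes: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(2.0 * stats.norm.sf(np.abs(nes.to_numpy())),
                        index=nes.index, columns=nes.columns)


def activity_matrix(
    m: PhosphoMatrix,
    signalons: Mapping[str, Signalon],
    test_runs: Sequence[str],
    reference_runs: Sequence[str],
    seed: int = 0,
    null_size: int = 0,
    min_targets: int = 5,
    level: str = "phosphostate",
) -> tuple[ActivityMatrix, list[Signature]]:
    """NES of every signalon in every per-sample signature.

    Each run in ``test_runs`` is scored individually against the reference
    set. With ``null_size`` > 0, NES values are additionally calibrated
    against a reference-resampled null ensemble (empirical two-tailed p).
    """
    rng = np.random.default_rng(seed)
    imputed = impute_row_min_noise(m.values, rng)
    col = {r: j for j, r in enumerate(m.run_index)}
    ref_idx = [col[r] for r in reference_runs]
    regs = list(signalons)
    sigs: list[Signature] = []
    nes = np.full((len(regs), len(test_runs)), np.nan)
    for j, run in enumerate(test_runs):
        scores = _quantile_scale(_zscores(imputed, [col[run]], ref_idx))
        sig = Signature(scores, list(m.site_index), sample=str(run))
        sigs.append(sig)
        for i, reg in enumerate(regs):
            nes[i, j] = enrichment_nes(sig, signalons[reg], min_targets=min_targets)
    nes_df = pd.DataFrame(nes, index=regs, columns=list(test_runs))
    if null_size:
        nulls = make_null_signatures(imputed, ref_idx, 1, null_size, seed=seed + 1)
        pvals = pd.DataFrame(np.nan, index=regs, columns=list(test_runs))
        for i, reg in enumerate(regs):
            null_nes = np.array([
                enrichment_nes(Signature(nulls[b], list(m.site_index)),
                               signalons[reg], min_targets=min_targets)
                for b in range(null_size)
            ])
            null_nes = null_nes[np.isfinite(null_nes)]
            if null_nes.size < 10:
                continue
            for j in range(len(test_runs)):
                z, p = empirical_null_nes(nes[i, j], null_nes)
                nes_df.iloc[i, j] = z
                pvals.iloc[i, j] = p
        return ActivityMatrix(nes_df, pvals, level=level), sigs
    return ActivityMatrix(nes_df, _nes_pvalues(nes_df), level=level), sigs


def _log10_two_tailed(z: float) -> float:
    # log10 of the two-tailed normal p, safe against underflow
    return (math.log(2.0) + stats.norm.logsf(abs(z))) / math.log(10.0)


def crosstalk_correct(
    am: ActivityMatrix,
    signalons: Mapping[str, Signalon],
    signatures: Sequence[Signature],
    ci: float = 20.0,
    alpha: float = 0.05,
    min_targets: int = 5,
) -> ActivityMatrix:
    """Down-weight substrates shared between co-significant signalons.

    Per sample, for every pair of significant regulators with shared
    targets, the stronger (A) keeps its NES while the weaker (B) has the
    shared targets' weights multiplied by 1 - 10^(-CDE * NT / CI), where
    CDE = log10(pB) - log10(pA) and NT is the number of pairs B
    participates in; equal significance (CDE = 0) nullifies the shared
    contribution. B's NES is then recomputed from the down-weighted
    signalon.
    """
    regs = am.regulators
    tsets = {r: set(signalons[r].targets) for r in regs if r in signalons}
    nes_out = am.nes.copy()
    log_alpha = math.log10(alpha)
    for j, sample in enumerate(am.samples):
        sig = signatures[j]
        lp = {}
        for r in regs:
            z = am.nes.at[r, sample]
            if np.isfinite(z):
                lp[r] = _log10_two_tailed(float(z))
        signif = [r for r in lp if lp[r] < log_alpha and r in tsets]
        pairs = []
        for a in range(len(signif)):
            for b in range(a + 1, len(signif)):
                ra, rb = signif[a], signif[b]
                if tsets[ra] & tsets[rb]:
                    pairs.append((ra, rb))
        if not pairs:
            continue
        nt = {r: 0 for r in signif}
        for ra, rb in pairs:
            nt[ra] += 1
            nt[rb] += 1
        mult: dict[str, np.ndarray] = {}
        for ra, rb in pairs:
            # A = stronger (smaller log10 p)
            if lp[rb] < lp[ra]:
                ra, rb = rb, ra
            cde = lp[rb] - lp[ra]
            factor = 1.0 - 10.0 ** (-cde * nt[rb] / ci)
            s = signalons[rb]
            shared = np.array([t in tsets[ra] for t in s.targets])
            if rb not in mult:
                mult[rb] = np.ones(len(s))
            mult[rb][shared] *= factor
        for rb, f in mult.items():
            s = signalons[rb]
            w = s.weights * f
            keep = w > 0
            if keep.sum() < 1 or np.sum(w ** 2) == 0:
                nes_out.at[rb, sample] = 0.0
                continue
            corrected = Signalon(s.regulator, [t for t, k in zip(s.targets, keep) if k],
                                 w[keep] / w[keep].max(), s.modes[keep],
                                 level=s.level, source=s.source)
            nes_out.at[rb, sample] = enrichment_nes(sig, corrected, min_targets=1)
    return ActivityMatrix(nes_out, _nes_pvalues(nes_out), level=am.level)


def stouffer(z_values: Sequence[float]) -> float:
    """Stouffer combination of z-scores with equal weights."""
    z = np.asarray([v for v in z_values if np.isfinite(v)], dtype=float)
    if z.size == 0:
        return float("nan")
    return float(z.sum() / math.sqrt(z.size))


@dataclass
class HierarchicalResult:
    """Phosphostate-level, activity-level and Stouffer-integrated activities."""

    integrated: ActivityMatrix
    phosphostate: ActivityMatrix
    activity_level: ActivityMatrix | None
    al_network: list[Interaction] = field(default_factory=list)


def hierarchical_measure(
    m: PhosphoMatrix,
    pl_net: Sequence[Interaction],
    spec: CandidateSpec,
    test_runs: Sequence[str],
    reference_runs: Sequence[str],
    seed: int = 0,
    min_targets: int = 5,
    n_boot: int = 200,
    n_perm_al: int = 50,
    fwer: float = 0.05,
    crosstalk: bool = False,
    t_target: float = 50.0,
) -> HierarchicalResult:
    """Two-level activity inference with Stouffer integration.

    Step 1 infers phosphostate-level (PL) activities from the PL consensus
    network. Step 2 dissects an activity-level (AL) network from the PL
    activity matrix of all runs, using regular DPI (the AL pass abstracts
    the network to a functional representation, where the stDPI sign
    constraints no longer apply). Step 3 infers AL activities; step 4
    integrates z_PL and z_AL per regulator-sample as (z_PL + z_AL)/sqrt(2),
    falling back to the single available level.
    """
    pl_signalons = signalons_from_network(pl_net, min_targets=min_targets,
                                          t_target=t_target, seed=seed)
    all_runs = list(test_runs) + [r for r in reference_runs if r not in set(test_runs)]
    pl_all, sigs_all = activity_matrix(m, pl_signalons, all_runs, reference_runs,
                                       seed=seed, min_targets=min_targets)
    pl_am = ActivityMatrix(pl_all.nes[list(test_runs)],
                           pl_all.pvalues[list(test_runs)], level="phosphostate")
    if crosstalk:
        sig_by_run = {s.sample: s for s in sigs_all}
        pl_am = crosstalk_correct(pl_am, pl_signalons,
                                  [sig_by_run[str(r)] for r in test_runs],
                                  min_targets=min_targets)

    al_am = None
    al_net: list[Interaction] = []
    finite = pl_all.nes.dropna(how="any")
    if finite.shape[0] >= 3:
        al_matrix = PhosphoMatrix(finite.to_numpy(), list(finite.index),
                                  list(finite.columns))
        try:
            al_net = dissect(al_matrix, spec, level="site", dpi="dpi",
                             n_boot=n_boot, fwer=fwer, n_perm=n_perm_al, seed=seed + 1)
        except ValueError:
            al_net = []
    if al_net:
        al_signalons = signalons_from_network(
            al_net, min_targets=min(min_targets, 2), t_target=t_target,
            level="activity", seed=seed)
        if al_signalons:
            al_all, _ = activity_matrix(al_matrix, al_signalons, list(test_runs),
                                        list(finite.columns), seed=seed + 2,
                                        min_targets=min(min_targets, 2),
                                        level="activity")
            al_am = al_all

    if al_am is None:
        logger.info("activity-level network empty; returning phosphostate-only result")
        return HierarchicalResult(pl_am, pl_am, None, [])

    regs = sorted(set(pl_am.regulators) | set(al_am.regulators))
    z = np.full((len(regs), len(test_runs)), np.nan)
    for i, reg in enumerate(regs):
        for j, run in enumerate(test_runs):
            parts = []
            if reg in pl_am.nes.index and np.isfinite(pl_am.nes.at[reg, run]):
                parts.append(float(pl_am.nes.at[reg, run]))
            if reg in al_am.nes.index and np.isfinite(al_am.nes.at[reg, run]):
                parts.append(float(al_am.nes.at[reg, run]))
            if parts:
                z[i, j] = stouffer(parts)
    nes_df = pd.DataFrame(z, index=regs, columns=list(test_runs))
    integrated = ActivityMatrix(nes_df, _nes_pvalues(nes_df), level="integrated")
    return HierarchicalResult(integrated, pl_am, al_am, al_net)
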