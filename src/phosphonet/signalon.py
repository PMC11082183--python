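"""Signalons: per-regulator substrate sets with weights and regulation signs.

A signalon is the signaling analog of a transcriptional regulon: the set of
phosphosites (or proteins) inferred to be regulated by one kinase or
phosphatase, each target carrying a probabilistic weight (MI normalized by
the network-wide maximum, optionally multiplied by reference priors) and a
mode of regulation in [-1, 1] (activated vs repressed, from a
three-Gaussian mixture over Spearman correlations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .network import Interaction

logger = logging.getLogger(__name__)

__all__ = [
    "Signalon",
    "mode_of_regulation",
    "weights",
    "trim",
    "signalons_from_network",
    "optimize",
    "deduplicate",
    "write_signalons",
    "read_signalons",
]


@dataclass
class Signalon:
    """One regulator's target set.

    ``level`` is ``phosphostate`` or ``activity``; ``source`` tags the
    dataset the signalon was dissected from.
    """

    regulator: str
    targets: list[str]
    weights: np.ndarray
    modes: np.ndarray
    level: str = "phosphostate"
    source: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        if not (len(self.targets) == self.weights.size == self.modes.size):
            raise ValueError("targets, weights and modes must align")
        if self.weights.size and (self.weights.min() < 0 or self.weights.max() > 1):
            raise ValueError("weights must lie in [0, 1]")
        if self.modes.size and (np.abs(self.modes) > 1 + 1e-12).any():
            raise ValueError("modes must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.targets)


def _ramp_mode(rhos: np.ndarray) -> np.ndarray:
    return np.sign(rhos) * np.minimum(1.0, np.abs(rhos) / 0.5)


def mode_of_regulation(rhos, fit_rhos=None, seed: int = 0) -> np.ndarray:
    """Mode of regulation in [-1, 1] from per-target Spearman correlations.

    A three-component 1-D Gaussian mixture (repressed / non-monotone /
    activated, components relabeled by sorted means) is fit to ``fit_rhos``
    (defaults to ``rhos``; passing the pooled network-wide correlations
    stabilizes the fit for regulators whose own rho values are unimodal);
    the mode is P(activated | rho) - P(repressed | rho). With fewer than 10
    fitting points, or when the fitted extreme components do not straddle
    zero (a degenerate, unimodal fit), a linear ramp
    sign(rho) * min(1, |rho| / 0.5) is used instead, which keeps small
    signalons usable.
    """
    rhos = np.asarray(rhos, dtype=float)
    fit = rhos if fit_rhos is None else np.asarray(fit_rhos, dtype=float)
    fit = fit[np.isfinite(fit)]
    if fit.size < 10 or np.unique(fit).size < 3:
        return _ramp_mode(rhos)
    gm = GaussianMixture(
        n_components=3,
        means_init=np.array([[-0.5], [0.0], [0.5]]),
        random_state=int(seed),
        max_iter=500,
        reg_covar=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(fit[:, None])
        means = gm.means_.ravel()
        order = np.argsort(means)
        if not (means[order[0]] < 0.0 < means[order[2]]):
            return _ramp_mode(rhos)
        post = gm.predict_proba(np.where(np.isfinite(rhos), rhos, 0.0)[:, None])
    return post[:, order[2]] - post[:, order[0]]


def weights(mis, network_max_mi: float | None = None, priors=None) -> np.ndarray:
    """Probabilistic target weights: MI / max(MI over the entire network).

    Priors, when present, are first normalized by the per-regulator maximum
    prior and then multiplied in; a zero prior drops the target.
    """
    mis = np.asarray(mis, dtype=float)
    if network_max_mi is None:
        network_max_mi = float(mis.max()) if mis.size else 0.0
    if network_max_mi <= 0:
        raise ValueError("all MI values are zero; cannot weight targets")
    w = mis / network_max_mi
    if priors is not None:
        priors = np.asarray(priors, dtype=float)
        pmax = priors.max()
        if pmax > 0:
            w = w * (priors / pmax)
        else:
            w = w * 0.0
    return w


def trim(target_weights, n_max: int = 500, t_target: float = 50.0) -> int:
    """Number of leading targets kept by cumulative squared-weight trimming.

    With weights sorted descending, accumulate s_k = sum_{i<=k}
    (w_i / w_1)^2 and keep the smallest k with s_k >= t_target, capped at
    ``n_max``; if the threshold is never reached all targets are kept (up
    to the cap).
    """
    if t_target <= 0:
        raise ValueError("t_target must be positive")
    w = np.asarray(target_weights, dtype=float)
    if w.size == 0:
        return 0
    if np.any(np.diff(w) > 1e-12):
        raise ValueError("weights must be sorted in descending order")
    s = np.cumsum((w / w[0]) ** 2)
    reached = np.nonzero(s >= t_target)[0]
    k = int(reached[0]) + 1 if reached.size else w.size
    return min(k, n_max, w.size)


def signalons_from_network(
    interactions: Iterable[Interaction],
    min_targets: int = 5,
    n_max: int = 500,
    t_target: float = 50.0,
    level: str = "phosphostate",
    source: str = "",
    seed: int = 0,
) -> dict[str, Signalon]:
    """Build one signalon per regulator from a consensus interaction set.

    Weights normalize MI by the network-wide maximum (times normalized
    priors when present), modes come from the mixture fit over the
    regulator's Spearman correlations, targets are trimmed by
    :func:`trim`, and regulators with fewer than ``min_targets`` surviving
    targets are excluded.
    """
    by_reg: dict[str, list[Interaction]] = {}
    max_mi = 0.0
    for it in interactions:
        by_reg.setdefault(it.regulator, []).append(it)
        if np.isfinite(it.mi):
            max_mi = max(max_mi, it.mi)
    pooled_rhos = np.array([it.rho for its in by_reg.values() for it in its])
    out: dict[str, Signalon] = {}
    for reg, its in by_reg.items():
        mis = np.array([it.mi for it in its])
        priors = None
        if any(it.prior is not None for it in its):
            priors = np.array([it.prior if it.prior is not None else 0.0 for it in its])
        w = weights(mis, network_max_mi=max_mi, priors=priors)
        keep = w > 0
        its = [it for it, k in zip(its, keep) if k]
        w = w[keep]
        if not its:
            continue
        rhos = np.array([it.rho for it in its])
        modes = mode_of_regulation(rhos, fit_rhos=pooled_rhos, seed=seed)
        order = np.argsort(-w, kind="stable")
        w = w[order]
        modes = modes[order]
        targets = [its[i].target for i in order]
        k = trim(w, n_max=n_max, t_target=t_target)
        if k < min_targets:
            logger.info("regulator %s excluded: %d targets < minimum %d", reg, k, min_targets)
            continue
        w = w[:k] / w[:k].max()  # per-regulator normalization: top weight = 1
        out[reg] = Signalon(reg, targets[:k], w, modes[:k], level=level, source=source)
    return out


def optimize(
    candidates: Mapping[str, Sequence[Signalon]],
    signatures: Sequence,
    min_targets: int = 5,
) -> dict[str, Signalon]:
    """Select, per regulator, the candidate signalon with the highest
    differential activity (max median |NES| across the signature ensemble).

    Incorrect signalons can only dilute the enrichment score, so the
    candidate scoring highest is the best-supported representation of the
    regulator. Candidates smaller than ``min_targets`` are skipped; a
    regulator with no usable candidate is excluded.
    """
    from .activity import enrichment_nes  # local import to avoid a cycle

    out: dict[str, Signalon] = {}
    for reg, cands in candidates.items():
        best, best_score = None, -np.inf
        for s in cands:
            if len(s) < min_targets:
                continue
            nes = [enrichment_nes(sig, s) for sig in signatures]
            nes = [v for v in nes if np.isfinite(v)]
            if not nes:
                continue
            score = float(np.median(np.abs(nes)))
            if score > best_score:
                best, best_score = s, score
        if best is None:
            logger.info("regulator %s excluded: no candidate signalon usable", reg)
            continue
        out[reg] = best
    return out


def deduplicate(
    signalons: Sequence[Signalon],
    activity: np.ndarray | None = None,
    cutoff: float = 0.5,
    corr: np.ndarray | None = None,
) -> list[Signalon]:
    """Drop redundant signalons of one phosphopeptide by activity correlation.

    Greedy rule (the caret ``findCorrelation`` contract): while any pair of
    activity profiles exceeds ``cutoff`` in absolute correlation, remove
    the signalon with the largest mean absolute correlation to the others.
    ``activity`` is (n_signalons, n_samples), row-aligned with
    ``signalons``; alternatively a precomputed absolute correlation matrix
    can be supplied via ``corr``.
    """
    alive = list(range(len(signalons)))
    if len(alive) < 2:
        return list(signalons)
    if corr is None:
        if activity is None:
            raise ValueError("either activity or corr is required")
        activity = np.asarray(activity, dtype=float)
        if activity.shape[0] != len(signalons):
            raise ValueError("activity rows must align with signalons")
        corr = np.abs(np.corrcoef(activity))
    else:
        corr = np.abs(np.asarray(corr, dtype=float))
    while len(alive) > 1:
        sub = corr[np.ix_(alive, alive)]
        np.fill_diagonal(sub, 0.0)
        if sub.max() <= cutoff:
            break
        mean_abs = sub.sum(axis=1) / (len(alive) - 1)
        drop = alive[int(np.argmax(mean_abs))]
        alive.remove(drop)
    return [signalons[i] for i in alive]


def write_signalons(signalons: Mapping[str, Signalon] | Sequence[Signalon], path) -> None:
    """Round-trippable TSV: regulator, level, source, target, weight, mode."""
    items = signalons.values() if isinstance(signalons, Mapping) else signalons
    rows = []
    for s in items:
        for t, w, m in zip(s.targets, s.weights, s.modes):
            rows.append((s.regulator, s.level, s.source, t, w, m))
    pd.DataFrame(rows, columns=["regulator", "level", "source", "target",
                                "weight", "mode"]).to_csv(path, sep="\t", index=False)


def read_signalons(path) -> dict[str, Signalon]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"regulator": str, "level": str, "source": str,
                            "target": str})
    out: dict[str, Signalon] = {}
    for (reg, level, source), g in df.groupby(["regulator", "level", "source"], sort=False):
        out[str(reg)] = Signalon(
            str(reg), [str(t) for t in g["target"]],
            g["weight"].to_numpy(float), g["mode"].to_numpy(float),
            level=str(level), source=str(source),
        )
    return out
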