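"""Ground-truth signaling networks and censored phosphoproteomic matrices.

The generator emulates the statistical structure the dissection method
assumes: latent kinase/phosphatase activities drive substrate phosphosite
log2 intensities through a linear-Gaussian structural model with signed
monotone effects (kinases +, phosphatases -); enzyme chains plant known
indirect regulator/target pairs; feed-forward motifs plant direct edges
inside enzyme-enzyme-substrate triangles; and observations below a
per-feature limit of detection are censored to missing, producing
value-dependent (MNAR) missingness. A monotone-nonlinear link is available
to stress rank-based estimators beyond linear correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .pvm import PhosphoMatrix

__all__ = ["SimConfig", "GroundTruth", "simulate", "simulate_perturbation",
           "PerturbationSeries"]


@dataclass
class SimConfig:
    """Synthetic study design.

    ``effect_rho`` is the expected correlation between an enzyme's observed
    proxy phosphopeptide and its direct substrates; ``proxy_rho`` the
    correlation between the proxy peptide and the latent activity;
    ``chain_depth`` enzymes per chain (1 = no chains); ``lod_quantile`` the
    per-feature censoring level; ``feedforward_frac`` the fraction of a
    chain child's substrates also directly regulated by its parent.
    """

    n_kinases: int = 5
    n_phosphatases: int = 3
    n_substrates: int = 80
    targets_per_enzyme: int = 10
    effect_rho: float = 0.6
    chain_depth: int = 1
    n_samples: int = 150
    noise_sd: float = 0.5
    lod_quantile: float = 0.4
    batch_shift_sd: float = 0.0
    seed: int = 0
    proxy_rho: float = 0.95
    feedforward_frac: float = 0.25
    chain_rho: float | None = None  # enzyme-enzyme activity coupling; default from effect_rho
    basal_activity: float = 2.0  # enzyme operating point (in population-SD units)
    link: Literal["linear", "exp"] = "linear"

    def __post_init__(self) -> None:
        if not (0.0 < self.effect_rho < 1.0):
            raise ValueError("effect_rho must be in (0, 1)")
        if not (0.0 <= self.lod_quantile < 1.0):
            raise ValueError("lod_quantile must be in [0, 1)")
        if self.n_kinases + self.n_phosphatases < 1:
            raise ValueError("need at least one enzyme")
        for name in ("n_substrates", "targets_per_enzyme", "n_samples", "chain_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        n_enz = self.n_kinases + self.n_phosphatases
        if self.n_substrates < n_enz * self.targets_per_enzyme:
            raise ValueError(
                f"n_substrates={self.n_substrates} cannot host "
                f"{n_enz} enzymes x {self.targets_per_enzyme} targets")
        r = self.effect_rho / self.proxy_rho
        bound = self.proxy_rho * math.sqrt(max(0.0, 1.0 - self.noise_sd ** 2))
        if r ** 2 > 1.0 - self.noise_sd ** 2 + 1e-12:
            raise ValueError(
                f"effect_rho={self.effect_rho} infeasible with "
                f"noise_sd={self.noise_sd}; attainable bound is {bound:.3f}")


@dataclass
class GroundTruth:
    """Planted edges (direct/indirect, signed), latent activities and LODs.

    ``edges`` columns: regulator (proxy row id), target (row id), sign
    (+1 kinase / -1 phosphatase effect), kind (direct | indirect).
    ``activities``: enzymes (proxy row id) x runs latent activity.
    """

    edges: pd.DataFrame
    activities: pd.DataFrame
    lod: pd.Series
    kinases: list[str] = field(default_factory=list)
    phosphatases: list[str] = field(default_factory=list)

    def direct_edges(self) -> set[tuple[str, str]]:
        d = self.edges[self.edges["kind"] == "direct"]
        return set(zip(d["regulator"], d["target"]))

    def indirect_edges(self) -> set[tuple[str, str]]:
        d = self.edges[self.edges["kind"] == "indirect"]
        return set(zip(d["regulator"], d["target"]))


def _site_id(name: str) -> str:
    return f"{name}:{name}:S1"


@dataclass
class _Design:
    """Structural layout drawn once per config seed."""

    enzymes: list[str]            # interleaved kinase/phosphatase order
    signs: dict[str, float]
    parent: dict[str, str | None]
    alpha: float
    targets: dict[str, list[str]]
    ff_targets: dict[str, list[str]]  # child -> substrates co-driven by its parent
    substrates: list[str]
    baselines: np.ndarray


def _design(cfg: SimConfig, rng: np.random.Generator) -> _Design:
    kin = [f"KIN{i + 1}" for i in range(cfg.n_kinases)]
    pho = [f"PHO{i + 1}" for i in range(cfg.n_phosphatases)]
    enzymes: list[str] = []
    i = j = 0
    while i < len(kin) or j < len(pho):
        if i < len(kin):
            enzymes.append(kin[i]); i += 1
        if j < len(pho):
            enzymes.append(pho[j]); j += 1
    signs = {e: (1.0 if e.startswith("KIN") else -1.0) for e in enzymes}
    parent: dict[str, str | None] = {e: None for e in enzymes}
    if cfg.chain_depth >= 2:
        for start in range(0, len(enzymes) - cfg.chain_depth + 1, cfg.chain_depth):
            chain = enzymes[start:start + cfg.chain_depth]
            for a, b in zip(chain, chain[1:]):
                parent[b] = a
    alpha = (cfg.chain_rho if cfg.chain_rho is not None
             else min(0.99, cfg.effect_rho / cfg.proxy_rho ** 2))
    subs = [f"SUB{i + 1:03d}" for i in range(cfg.n_substrates)]
    targets: dict[str, list[str]] = {}
    k = 0
    for e in enzymes:
        targets[e] = subs[k:k + cfg.targets_per_enzyme]
        k += cfg.targets_per_enzyme
    ff_targets = {}
    for e in enzymes:
        if parent[e] is not None:
            n_ff = int(round(cfg.feedforward_frac * len(targets[e])))
            ff_targets[e] = targets[e][:n_ff]
        else:
            ff_targets[e] = []
    n_rows = len(enzymes) + len(subs)
    baselines = rng.normal(22.0, 1.5, n_rows)
    return _Design(enzymes, signs, parent, alpha, targets, ff_targets, subs, baselines)


def _activities(cfg: SimConfig, d: _Design, eps: dict[str, np.ndarray],
                inhibit: dict[str, float] | None = None) -> dict[str, np.ndarray]:
    """Latent activities as deviations from each enzyme's basal operating point.

    Inhibiting an enzyme scales its *total* activity (basal + deviation) by
    (1 - inhibition), so the stored deviation becomes
    (1 - inh) * a - inh * basal: full inhibition pins the enzyme
    ``basal_activity`` population-SDs below its operating point, which is
    what a differential signature against vehicle controls can detect.
    """
    act: dict[str, np.ndarray] = {}
    for e in d.enzymes:  # chain parents precede children in this order
        p = d.parent[e]
        if p is None:
            a = eps[e]
        else:
            a = d.signs[p] * d.alpha * act[p] + math.sqrt(1 - d.alpha ** 2) * eps[e]
        if inhibit and e in inhibit:
            inh = inhibit[e]
            a = (1.0 - inh) * a - inh * cfg.basal_activity
        act[e] = a
    return act


def _assemble(cfg: SimConfig, d: _Design, act: dict[str, np.ndarray],
              noise: dict[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """Latent activities + innovations -> uncensored value matrix (z-space + baselines)."""
    r = cfg.effect_rho / cfg.proxy_rho
    g = 0.4 * r
    rows: list[np.ndarray] = []
    ids: list[str] = []
    for e in d.enzymes:
        x = cfg.proxy_rho * act[e] + math.sqrt(1 - cfg.proxy_rho ** 2) * noise[_site_id(e)]
        rows.append(x)
        ids.append(_site_id(e))
    owner = {}
    for e in d.enzymes:
        for s in d.targets[e]:
            owner[s] = e
    for s in d.substrates:
        sid = f"{s}:{s}:S1"
        e = owner.get(s)
        if e is None:
            rows.append(noise[sid])
        else:
            p = d.parent[e]
            sig = d.signs[e] * r * act[e]
            var_sig = r ** 2
            if p is not None and s in d.ff_targets[e]:
                sig = sig + d.signs[p] * g * act[p]
                var_sig = r ** 2 + g ** 2 + 2 * r * g * d.signs[e] * d.signs[p] * d.signs[p] * d.alpha
            sigma2 = 1.0 - var_sig
            if sigma2 < cfg.noise_sd ** 2 - 1e-9:
                raise ValueError(
                    f"effect_rho={cfg.effect_rho} with feed-forward motifs "
                    f"leaves residual sd {math.sqrt(max(sigma2, 0)):.3f} < noise_sd")
            rows.append(sig + math.sqrt(max(sigma2, 0.0)) * noise[sid])
        ids.append(sid)
    values = np.vstack(rows)
    if cfg.link == "exp":
        values = np.expm1(values * 0.5)  # monotone-nonlinear link, preserves ranks
    values = values + d.baselines[:, None]
    return values, ids


def _innovations(cfg: SimConfig, d: _Design, rng: np.random.Generator):
    eps = {e: rng.standard_normal(cfg.n_samples) for e in d.enzymes}
    noise = {}
    for e in d.enzymes:
        noise[_site_id(e)] = rng.standard_normal(cfg.n_samples)
    for s in d.substrates:
        noise[f"{s}:{s}:S1"] = rng.standard_normal(cfg.n_samples)
    return eps, noise


def _truth_edges(cfg: SimConfig, d: _Design) -> pd.DataFrame:
    rows = []
    for e in d.enzymes:
        reg = _site_id(e)
        for s in d.targets[e]:
            rows.append((reg, f"{s}:{s}:S1", d.signs[e], "direct"))
        p = d.parent[e]
        if p is not None:
            preg = _site_id(p)
            rows.append((preg, reg, d.signs[p], "direct"))
            for s in d.ff_targets[e]:
                rows.append((preg, f"{s}:{s}:S1", d.signs[p], "direct"))
            for s in d.targets[e]:
                if s not in d.ff_targets[e]:
                    rows.append((preg, f"{s}:{s}:S1",
                                 d.signs[p] * d.signs[e], "indirect"))
            # deeper ancestors reach this enzyme only indirectly
            anc = d.parent[p]
            while anc is not None:
                rows.append((_site_id(anc), reg, d.signs[anc], "indirect"))
                anc = d.parent[anc]
    return pd.DataFrame(rows, columns=["regulator", "target", "sign", "kind"])


def _censor(values: np.ndarray, lod_quantile: float) -> tuple[np.ndarray, np.ndarray]:
    if lod_quantile <= 0:
        return values.copy(), np.full(values.shape[0], -np.inf)
    lod = np.quantile(values, lod_quantile, axis=1)
    out = values.copy()
    out[values < lod[:, None]] = np.nan
    return out, lod


def simulate(cfg: SimConfig) -> tuple[PhosphoMatrix, GroundTruth]:
    """Generate one censored phosphoproteomic matrix with known ground truth.

    Deterministic for a fixed ``cfg.seed``. Each feature is censored below
    its own ``lod_quantile`` empirical quantile, so missingness is
    value-dependent (MNAR) and the per-feature missing fraction equals the
    configured censoring level.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    d = _design(cfg, rng)
    eps, noise = _innovations(cfg, d, rng)
    act = _activities(cfg, d, eps)
    values, ids = _assemble(cfg, d, act, noise)
    runs = [f"run{j + 1:03d}" for j in range(cfg.n_samples)]
    run_groups = None
    if cfg.batch_shift_sd > 0:
        half = cfg.n_samples // 2
        shifts = rng.normal(0.0, cfg.batch_shift_sd, (values.shape[0], 2))
        values[:, :half] += shifts[:, [0]]
        values[:, half:] += shifts[:, [1]]
        run_groups = {r: ("batch1" if j < half else "batch2") for j, r in enumerate(runs)}
    censored, lod = _censor(values, cfg.lod_quantile)
    m = PhosphoMatrix(censored, ids, runs, run_groups)
    truth = GroundTruth(
        edges=_truth_edges(cfg, d),
        activities=pd.DataFrame({_site_id(e): act[e] for e in d.enzymes},
                                index=runs).T,
        lod=pd.Series(lod, index=ids),
        kinases=[e for e in d.enzymes if d.signs[e] > 0],
        phosphatases=[e for e in d.enzymes if d.signs[e] < 0],
    )
    return m, truth


@dataclass
class PerturbationSeries:
    """Matched perturbed / vehicle-control time series with latent truth."""

    perturbed: list[PhosphoMatrix]
    control: list[PhosphoMatrix]
    activities_perturbed: list[pd.DataFrame]
    activities_control: list[pd.DataFrame]
    timepoints: list[int]
    truth: GroundTruth


def simulate_perturbation(
    cfg: SimConfig,
    target: str,
    inhibition: float,
    timepoints: int,
    adaptation: dict | None = None,
) -> PerturbationSeries:
    """Drug-perturbation surrogate: inhibit one regulator across timepoints.

    The target enzyme's activity is multiplied by (1 - inhibition) at every
    timepoint; an ``adaptation`` spec ``{"start": t, "full_by": T-1}``
    rebounds the activity linearly back to baseline (an adaptive-resistance
    surrogate). Control and perturbed series share all innovation draws, so
    they differ only through the intervention, and share the control-derived
    limits of detection.
    """
    if not (0.0 <= inhibition <= 1.0):
        raise ValueError("inhibition must be in [0, 1]")
    rng0 = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    d = _design(cfg, rng0)
    enzyme = target.split(":")[0]
    if enzyme not in d.enzymes:
        raise ValueError(f"unknown target regulator {target!r}")
    pert, ctrl, act_p, act_c = [], [], [], []
    tps = list(range(timepoints))
    for t in tps:
        eff = inhibition
        if adaptation is not None and t >= adaptation["start"]:
            full_by = adaptation.get("full_by", timepoints - 1)
            span = max(full_by - adaptation["start"] + 1, 1)
            eff = inhibition * max(0.0, 1.0 - (t - adaptation["start"] + 1) / span)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000 + t]))
        eps, noise = _innovations(cfg, d, rng)
        a_c = _activities(cfg, d, eps)
        a_p = _activities(cfg, d, eps, inhibit={enzyme: eff})
        v_c, ids = _assemble(cfg, d, a_c, noise)
        v_p, _ = _assemble(cfg, d, a_p, noise)
        runs = [f"t{t}_rep{j + 1:02d}" for j in range(cfg.n_samples)]
        c_cens, lod = _censor(v_c, cfg.lod_quantile)
        p_cens = v_p.copy()
        p_cens[v_p < np.asarray(lod)[:, None]] = np.nan
        ctrl.append(PhosphoMatrix(c_cens, ids, runs))
        pert.append(PhosphoMatrix(p_cens, ids, [f"{r}_drug" for r in runs]))
        act_c.append(pd.DataFrame({_site_id(e): a_c[e] for e in d.enzymes}, index=runs).T)
        act_p.append(pd.DataFrame({_site_id(e): a_p[e] for e in d.enzymes}, index=runs).T)
    base_m, truth = simulate(cfg)
    return PerturbationSeries(pert, ctrl, act_p, act_c, tps, truth)
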