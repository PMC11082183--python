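"""Bootstrapped dissection of kinase/phosphatase -> substrate networks.

Pipeline: a family-wise MI significance threshold is estimated once on the
full matrix from a permutation null; hpMI is then recomputed over candidate
enzyme->substrate pairs for each of N bootstrap resamplings of the runs,
sub-threshold edges are dropped, indirect edges are pruned by the Data
Processing Inequality (DPI) or its signal-transduction variant (stDPI,
which only assesses triangles whose intermediary is a kinase), and edges
are kept when their bootstrap support is significant under a Poisson model
(Benjamini-Hochberg corrected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._mi_core import batch_mi
from .mi import null_mi_threshold, rank_rows, spearman_complete
from .pvm import PhosphoMatrix, aggregate_to_protein

__all__ = [
    "CandidateSpec",
    "Interaction",
    "node_class",
    "candidate_pairs",
    "bootstrap_network",
    "dpi_prune",
    "consensus",
    "dissect",
    "write_network",
    "read_network",
]

DpiMode = Literal["none", "dpi", "stdpi"]


@dataclass
class CandidateSpec:
    """Which regulator->target pairs the dissection may consider.

    ``mode``: ``enzyme-list`` (all enzyme x substrate combinations),
    ``signed-enzyme-list`` (additionally requires positive Spearman
    correlation for kinase edges and negative for phosphatase edges), or
    ``reference-network`` (candidates restricted to a supplied edge list
    with optional priors in [0, 1]).
    """

    mode: str = "enzyme-list"
    kinases: set[str] = field(default_factory=set)
    phosphatases: set[str] = field(default_factory=set)
    substrate_whitelist: set[str] | None = None
    reference_edges: list[tuple[str, str, float]] | None = None

    def __post_init__(self) -> None:
        self.kinases = set(self.kinases)
        self.phosphatases = set(self.phosphatases)
        overlap = self.kinases & self.phosphatases
        if overlap:
            raise ValueError(f"ids listed as both kinase and phosphatase: {sorted(overlap)}")
        if self.reference_edges:
            for r, t, p in self.reference_edges:
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"prior for {r}->{t} outside [0,1]: {p}")


@dataclass
class Interaction:
    regulator: str
    target: str
    mi: float
    support: int
    pvalue: float
    rho: float
    prior: float | None = None


def _gene_of(node_id: str) -> str:
    return node_id.split(":")[0]


def node_class(spec: CandidateSpec, node_id: str) -> str:
    """Classify a matrix row as kinase / phosphatase / substrate by id or gene prefix."""
    g = _gene_of(node_id)
    if node_id in spec.kinases or g in spec.kinases:
        return "kinase"
    if node_id in spec.phosphatases or g in spec.phosphatases:
        return "phosphatase"
    return "substrate"


def candidate_pairs(m: PhosphoMatrix, spec: CandidateSpec):
    """Index arrays (regulator rows, target rows) of candidate edges.

    Same-gene pairs are excluded (an enzyme's own phosphosites trivially
    co-vary through shared peptides). In reference-network mode candidates
    are the supplied edges present in the matrix.
    """
    pos = {s: i for i, s in enumerate(m.site_index)}
    if spec.mode == "reference-network":
        if not spec.reference_edges:
            raise ValueError("reference-network mode requires reference_edges")
        ia, ib, priors = [], [], []
        for r, t, p in spec.reference_edges:
            if r in pos and t in pos and _gene_of(r) != _gene_of(t):
                ia.append(pos[r]); ib.append(pos[t]); priors.append(p)
        if not ia:
            raise ValueError("no reference edges overlap the matrix")
        return np.asarray(ia, np.int64), np.asarray(ib, np.int64), np.asarray(priors)

    reg_rows = [i for i, s in enumerate(m.site_index)
                if node_class(spec, s) != "substrate"]
    if spec.substrate_whitelist is not None:
        wl = set(spec.substrate_whitelist)
        tgt_rows = [i for i, s in enumerate(m.site_index)
                    if s in wl or _gene_of(s) in wl or node_class(spec, s) != "substrate"]
    else:
        tgt_rows = list(range(m.n_sites))
    ia, ib = [], []
    for i in reg_rows:
        gi = _gene_of(m.site_index[i])
        for j in tgt_rows:
            if _gene_of(m.site_index[j]) != gi:
                ia.append(i); ib.append(j)
    if not ia:
        raise ValueError("candidate specification yields zero pairs")
    return np.asarray(ia, np.int64), np.asarray(ib, np.int64), None


def dpi_prune(
    edges: dict[tuple[str, str], float],
    classes: dict[str, str],
    mode: DpiMode = "stdpi",
    tolerance: float = 0.0,
) -> dict[tuple[str, str], float]:
    """Remove indirect edges by the (signal-transduction) Data Processing Inequality.

    For every triangle R1->R2, R2->T, R1->T, the edge R1->T is removed when
    its MI is the strict minimum of the three (within ``tolerance``). Under
    ``stdpi`` a triangle is only assessed when the intermediary R2 is a
    kinase; phosphatase-intermediary triangles would invert the sign of the
    putative indirect effect and are never pruned.
    """
    if mode == "none":
        return dict(edges)
    out_adj: dict[str, list[str]] = {}
    for (r, t) in edges:
        if r not in classes or t not in classes:
            raise ValueError(f"node without a class in edge {r}->{t}")
        out_adj.setdefault(r, []).append(t)
    doomed: set[tuple[str, str]] = set()
    for r1, targets in out_adj.items():
        tset = set(targets)
        for r2 in targets:
            if r2 not in out_adj:
                continue
            if mode == "stdpi" and classes.get(r2) != "kinase":
                continue
            mi_12 = edges[(r1, r2)]
            for t in out_adj[r2]:
                if t == r1 or t not in tset:
                    continue
                mi_1t = edges[(r1, t)]
                mi_2t = edges[(r2, t)]
                if mi_1t < min(mi_12, mi_2t) * (1.0 - tolerance):
                    doomed.add((r1, t))
    return {e: w for e, w in edges.items() if e not in doomed}


def bootstrap_network(
    m: PhosphoMatrix,
    spec: CandidateSpec,
    n_boot: int = 200,
    dpi: DpiMode = "stdpi",
    fwer: float = 0.05,
    n_perm: int = 10,
    seed: int = 0,
    threshold: float | None = None,
    tolerance: float = 0.0,
) -> tuple[list[dict[tuple[str, str], float]], float]:
    """Per-bootstrap surviving edge sets (and the MI threshold used).

    Each bootstrap resamples runs with replacement, recomputes hpMI for all
    candidate pairs (ties from duplicated runs broken by a seeded RNG),
    drops edges below the full-data FWER threshold and applies the selected
    DPI variant. Per-bootstrap RNG streams are derived from (seed, b), so
    results are reproducible and independent of execution order.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    ia, ib, _ = candidate_pairs(m, spec)
    if threshold is None:
        # small candidate families need more permutation rounds to resolve
        # the Sidak tail; extra rounds are cheap exactly when pairs are few
        n_perm_eff = max(n_perm, -(-2500 // ia.size))
        threshold = null_mi_threshold(
            m, fwer=fwer, n_perm=n_perm_eff, pairs=(ia, ib),
            n_candidates=ia.size, seed=seed,
        )
    classes = {s: node_class(spec, s) for s in m.site_index}
    sites = m.site_index
    edge_sets: list[dict[tuple[str, str], float]] = []
    out = np.empty(ia.size)
    for b in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        cols = rng.integers(0, m.n_runs, m.n_runs)
        R = rank_rows(m.values[:, cols], rng=rng)
        batch_mi(R, ia, ib, 0, out)
        keep = out >= threshold
        edges = {(sites[ia[k]], sites[ib[k]]): float(out[k])
                 for k in np.nonzero(keep)[0]}
        if dpi != "none":
            edges = dpi_prune(edges, classes, mode=dpi, tolerance=tolerance)
        edge_sets.append(edges)
    return edge_sets, float(threshold)


def consensus(
    edge_sets: Sequence[dict[tuple[str, str], float]],
    n_boot: int | None = None,
    alpha: float = 0.05,
    full_mi: dict[tuple[str, str], float] | None = None,
    rho: dict[tuple[str, str], float] | None = None,
    priors: dict[tuple[str, str], float] | None = None,
    spec: CandidateSpec | None = None,
    n_candidates: int | None = None,
) -> list[Interaction]:
    """Poisson-consensus significant edges across bootstrap runs.

    Edge support k is tested against Poisson(lambda) with lambda the mean
    support over the candidate family (total edge occurrences across
    bootstraps divided by ``n_candidates``; edges never detected count as
    zero support). When ``n_candidates`` is not given the mean is taken
    over the edges ever detected. Upper-tail p-values are BH corrected and
    edges with adjusted p < alpha retained. In signed-enzyme-list mode,
    kinase edges additionally require rho > 0 and phosphatase edges
    rho < 0 on complete pairs.
    """
    if len(edge_sets) < 2:
        raise ValueError("need at least two bootstrap edge sets")
    if n_boot is None:
        n_boot = len(edge_sets)
    support: dict[tuple[str, str], int] = {}
    for es in edge_sets:
        for e in es:
            support[e] = support.get(e, 0) + 1
    if not support:
        warnings.warn("no edges detected in any bootstrap; empty network")
        return []
    denom = n_candidates if n_candidates else len(support)
    lam = sum(support.values()) / denom
    edges = sorted(support)
    pvals = np.array([stats.poisson.sf(support[e] - 1, lam) for e in edges])
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    padj = stats.false_discovery_control(pvals, method="bh")
    result: list[Interaction] = []
    for e, p_raw, p_adj in zip(edges, pvals, padj):
        if p_adj >= alpha:
            continue
        r, t = e
        rho_e = rho.get(e, float("nan")) if rho else float("nan")
        if spec is not None and spec.mode == "signed-enzyme-list":
            cls = node_class(spec, r)
            if cls == "kinase" and not (rho_e > 0):
                continue
            if cls == "phosphatase" and not (rho_e < 0):
                continue
        result.append(Interaction(
            regulator=r, target=t,
            mi=full_mi.get(e, float("nan")) if full_mi else float("nan"),
            support=support[e], pvalue=float(p_adj), rho=rho_e,
            prior=priors.get(e) if priors else None,
        ))
    return result


def _full_data_stats(m: PhosphoMatrix, ia, ib, priors_arr):
    """Full-data hpMI, Spearman rho and priors for every candidate pair."""
    R = rank_rows(m.values)
    out = np.empty(ia.size)
    batch_mi(R, ia, ib, 0, out)
    sites = m.site_index
    full_mi, rho, priors = {}, {}, {}
    for k in range(ia.size):
        e = (sites[ia[k]], sites[ib[k]])
        full_mi[e] = float(out[k])
        rho[e] = spearman_complete(m.values[ia[k]], m.values[ib[k]])
        if priors_arr is not None:
            priors[e] = float(priors_arr[k])
    return full_mi, rho, (priors if priors_arr is not None else None)


def dissect(
    m: PhosphoMatrix,
    spec: CandidateSpec,
    level: Literal["site", "protein"] = "site",
    dpi: DpiMode = "stdpi",
    n_boot: int = 200,
    fwer: float = 0.05,
    n_perm: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    tolerance: float = 0.0,
) -> list[Interaction]:
    """Full dissection pipeline: threshold -> bootstrap -> DPI -> consensus.

    ``level='protein'`` first combines the phosphosites of each regulator
    protein into one aggregated row (observed-only mean), keeping substrate
    rows at site resolution. Deterministic for a fixed seed.
    """
    if level == "protein":
        reg_rows = [i for i, s in enumerate(m.site_index)
                    if node_class(spec, s) != "substrate"]
        sub_rows = [i for i in range(m.n_sites) if i not in set(reg_rows)]
        agg = aggregate_to_protein(
            PhosphoMatrix(m.values[reg_rows], [m.site_index[i] for i in reg_rows],
                          list(m.run_index)))
        values = np.vstack([agg.values, m.values[sub_rows]])
        sites = list(agg.site_index) + [m.site_index[i] for i in sub_rows]
        m = PhosphoMatrix(values, sites, list(m.run_index),
                          dict(m.run_groups) if m.run_groups else None)
    ia, ib, priors_arr = candidate_pairs(m, spec)
    edge_sets, threshold = bootstrap_network(
        m, spec, n_boot=n_boot, dpi=dpi, fwer=fwer, n_perm=n_perm,
        seed=seed, tolerance=tolerance,
    )
    full_mi, rho, priors = _full_data_stats(m, ia, ib, priors_arr)
    return consensus(edge_sets, n_boot=n_boot, alpha=alpha, full_mi=full_mi,
                     rho=rho, priors=priors, spec=spec, n_candidates=ia.size)


NETWORK_COLUMNS = ["regulator", "target", "mi", "support", "pvalue", "rho", "prior"]


def network_frame(interactions: Iterable[Interaction]) -> pd.DataFrame:
    rows = [(i.regulator, i.target, i.mi, i.support, i.pvalue, i.rho,
             i.prior if i.prior is not None else np.nan)
            for i in interactions]
    return pd.DataFrame(rows, columns=NETWORK_COLUMNS)


def write_network(interactions: Iterable[Interaction], path) -> None:
    """Tab-separated edge list export (the ARACNe-style interchange layout)."""
    network_frame(interactions).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_network(path) -> list[Interaction]:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    return [
        Interaction(str(r.regulator), str(r.target), float(r.mi), int(r.support),
                    float(r.pvalue), float(r.rho),
                    None if pd.isna(r.prior) else float(r.prior))
        for r in df.itertuples()
    ]
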