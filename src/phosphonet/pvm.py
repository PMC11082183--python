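"""PVM-format phosphoproteomic input handling.

The PVM (Proteomic VESPA-style input Matrix) is a long-format table with one
row per detected peptide x run. :func:`load_pvm` collapses it to a sparse
phosphosite x run log2-intensity matrix (:class:`PhosphoMatrix`) with an
explicit missingness mask, choosing one peptide precursor per phosphosite.

Missing values are carried as NaN throughout; they are never silently
imputed here because downstream mutual-information estimation treats
censoring below the limit of detection as informative.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column names of the long-format PVM table, in canonical order.
PVM_COLUMNS = [
    "gene_id",
    "protein_id",
    "peptide_id",
    "site_id",
    "modified_peptide_sequence",
    "peptide_sequence",
    "phosphosite",
    "run_id",
    "peptide_intensity",
]

_SITE_RE = re.compile(r"^[STY]\d+$")


class PvmValidationError(ValueError):
    """Raised when a PVM record violates the format contract."""


@dataclass
class PhosphoMatrix:
    """Sites x runs log2-abundance matrix with explicit missingness.

    Parameters
    ----------
    values
        ``(n_sites, n_runs)`` float array; missing entries are NaN.
    site_index
        Ordered unique site identifiers (``GENE:ACCESSION:SITE``).
    run_index
        Ordered unique run identifiers.
    run_groups
        Optional mapping run_id -> group label for batch-wise normalization.
    """

    values: np.ndarray
    site_index: list[str]
    run_index: list[str]
    run_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.site_index = list(self.site_index)
        self.run_index = list(self.run_index)
        if self.values.shape != (len(self.site_index), len(self.run_index)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.site_index)} sites x {len(self.run_index)} runs"
            )
        if len(set(self.site_index)) != len(self.site_index):
            raise ValueError("site_index entries must be unique")
        if len(set(self.run_index)) != len(self.run_index):
            raise ValueError("run_index entries must be unique")

    @property
    def mask(self) -> np.ndarray:
        """Boolean observed mask (True where a value was measured)."""
        return np.isfinite(self.values)

    @property
    def n_sites(self) -> int:
        return len(self.site_index)

    @property
    def n_runs(self) -> int:
        return len(self.run_index)

    def completeness(self) -> np.ndarray:
        """Per-site fraction of observed runs."""
        return self.mask.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_index, columns=self.run_index)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, run_groups=None) -> "PhosphoMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), run_groups)

    def copy(self) -> "PhosphoMatrix":
        return PhosphoMatrix(
            self.values.copy(), list(self.site_index), list(self.run_index),
            dict(self.run_groups) if self.run_groups else None,
        )


def _as_pvm_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    missing = [c for c in PVM_COLUMNS if c not in df.columns]
    if missing:
        raise PvmValidationError(f"PVM input lacks required columns: {missing}")
    return df[PVM_COLUMNS]


def validate_pvm(df: pd.DataFrame) -> None:
    """Check PVM invariants, raising :class:`PvmValidationError` on the first offender.

    Checks: ``site_id == gene_id:protein_id:phosphosite``, the phosphosite
    pattern (``[STY]<pos>`` or ``PA`` for protein abundance), and finiteness
    of reported intensities.
    """
    expected = (
        df["gene_id"].astype(str) + ":" + df["protein_id"].astype(str)
        + ":" + df["phosphosite"].astype(str)
    )
    bad = df.index[expected != df["site_id"].astype(str)]
    if len(bad):
        rec = df.loc[bad[0]]
        raise PvmValidationError(
            f"site_id {rec['site_id']!r} does not equal "
            f"gene_id:protein_id:phosphosite for record {bad[0]}"
        )
    ok = df["phosphosite"].astype(str).map(lambda s: s == "PA" or bool(_SITE_RE.match(s)))
    bad = df.index[~ok]
    if len(bad):
        rec = df.loc[bad[0]]
        raise PvmValidationError(
            f"phosphosite {rec['phosphosite']!r} in record {bad[0]} "
            "does not match [STY]<position> or 'PA'"
        )
    vals = pd.to_numeric(df["peptide_intensity"], errors="coerce")
    present = df["peptide_intensity"].notna()
    bad = df.index[present & ~np.isfinite(vals.to_numpy(dtype=float))]
    if len(bad):
        raise PvmValidationError(f"non-finite peptide_intensity in record {bad[0]}")


def load_pvm(records, run_order: Sequence[str] | None = None,
             id_map: Mapping[str, str] | None = None) -> PhosphoMatrix:
    """Collapse long-format PVM records to a site x run matrix.

    When a phosphosite is covered by several peptide precursors, the most
    consistently detected precursor (highest number of runs with an observed
    intensity) is used; ties are broken by the higher median intensity.
    A multiply phosphorylated precursor contributes one row per site, all
    sharing its intensity vector.

    Identifiers are case-sensitive and never remapped silently; an explicit
    ``id_map`` (e.g. parsed from a UniProtKB FASTA header table) remaps
    gene/protein identifiers and rebuilds ``site_id`` accordingly. Off by
    default.
    """
    df = _as_pvm_frame(records)
    if df.empty:
        raise PvmValidationError("empty PVM input")
    if id_map is not None:
        df = df.assign(
            gene_id=df["gene_id"].map(lambda g: id_map.get(g, g)),
            protein_id=df["protein_id"].map(lambda p: id_map.get(p, p)),
        )
        df = df.assign(site_id=df["gene_id"] + ":" + df["protein_id"]
                       + ":" + df["phosphosite"])
    validate_pvm(df)
    df = df.assign(peptide_intensity=pd.to_numeric(df["peptide_intensity"]))

    runs = list(run_order) if run_order is not None else list(pd.unique(df["run_id"]))
    run_pos = {r: i for i, r in enumerate(runs)}

    # pick one precursor per site: detection count, then median intensity
    stats = (
        df.dropna(subset=["peptide_intensity"])
        .groupby(["site_id", "peptide_id"])["peptide_intensity"]
        .agg(n_runs=lambda s: s.size, med="median")
        .reset_index()
    )
    stats = stats.sort_values(
        ["site_id", "n_runs", "med", "peptide_id"], ascending=[True, False, False, True]
    )
    chosen = stats.drop_duplicates("site_id").set_index("site_id")["peptide_id"]

    sites = list(pd.unique(df["site_id"]))
    values = np.full((len(sites), len(runs)), np.nan)
    sel = df.merge(
        chosen.rename("chosen"), left_on="site_id", right_index=True, how="inner"
    )
    sel = sel[sel["peptide_id"] == sel["chosen"]]
    site_pos = {s: i for i, s in enumerate(sites)}
    rows = sel["site_id"].map(site_pos).to_numpy()
    cols = sel["run_id"].map(run_pos).to_numpy()
    keep = pd.notna(cols)
    values[rows[keep], cols[keep].astype(int)] = sel["peptide_intensity"].to_numpy()[keep]

    kept_sites = [s for s in sites if s in set(chosen.index)]
    idx = [site_pos[s] for s in kept_sites]
    return PhosphoMatrix(values[idx], kept_sites, runs)


def read_pvm(path) -> pd.DataFrame:
    """Read a tab-separated PVM file."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in PVM_COLUMNS[:-1]})
    return _as_pvm_frame(df)


def write_pvm(df: pd.DataFrame, path) -> None:
    _as_pvm_frame(df).to_csv(path, sep="\t", index=False)


def matrix_to_pvm(m: PhosphoMatrix, peptide_prefix: str = "pep") -> pd.DataFrame:
    """Serialize a matrix back to minimal long-format PVM records (observed cells only)."""
    rows = []
    for i, sid in enumerate(m.site_index):
        gene, acc, site = sid.split(":")
        for j, run in enumerate(m.run_index):
            v = m.values[i, j]
            if np.isfinite(v):
                rows.append((gene, acc, f"{peptide_prefix}_{sid}", sid,
                             f"{peptide_prefix}_{sid}", f"{peptide_prefix}_{sid}",
                             site, run, v))
    return pd.DataFrame(rows, columns=PVM_COLUMNS)


def write_matrix(m: PhosphoMatrix, path) -> None:
    """Wide TSV export: first column ``site_id``, one column per run, missing = empty."""
    df = m.to_frame()
    df.index.name = "site_id"
    df.to_csv(path, sep="\t", na_rep="")


def read_matrix(path, run_groups=None) -> PhosphoMatrix:
    df = pd.read_csv(path, sep="\t", index_col="site_id")
    return PhosphoMatrix.from_frame(df, run_groups)


def quantile_normalize(m: PhosphoMatrix, by_group: bool = False) -> PhosphoMatrix:
    """Missingness-aware quantile normalization followed by row centering.

    Within each run group (one global group unless ``by_group``), observed
    values of every run are mapped onto a common reference distribution (the
    across-run average empirical quantile function, evaluated on a common
    grid). Missing entries stay missing. Each site row is then centered to
    mean 0 over its observed entries.
    """
    out = m.copy()
    if by_group:
        if not m.run_groups:
            raise ValueError("by_group=True requires run_groups on the matrix")
        groups: dict[str, list[int]] = {}
        for j, run in enumerate(m.run_index):
            groups.setdefault(m.run_groups[run], []).append(j)
    else:
        groups = {"all": list(range(m.n_runs))}

    for gname, cols in groups.items():
        if len(cols) < 2:
            warnings.warn(f"run group {gname!r} has a single run; skipped")
            continue
        sorted_per_run = []
        for j in cols:
            v = m.values[:, j]
            obs = np.sort(v[np.isfinite(v)])
            if obs.size:
                sorted_per_run.append(obs)
        if not sorted_per_run:
            continue
        grid_n = max(len(s) for s in sorted_per_run)
        grid = (np.arange(grid_n) + 0.5) / grid_n
        ref = np.zeros(grid_n)
        for s in sorted_per_run:
            q = (np.arange(len(s)) + 0.5) / len(s)
            ref += np.interp(grid, q, s)
        ref /= len(sorted_per_run)
        for j in cols:
            v = out.values[:, j]
            fin = np.isfinite(v)
            n_obs = int(fin.sum())
            if n_obs == 0:
                continue
            # average ranks for ties -> averaged reference quantiles
            from scipy.stats import rankdata
            r = rankdata(v[fin], method="average")
            q = (r - 0.5) / n_obs
            out.values[fin, j] = np.interp(q, grid, ref)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing rows
        row_mean = np.nanmean(np.where(out.mask, out.values, np.nan), axis=1)
    out.values = out.values - np.nan_to_num(row_mean)[:, None]
    return out


def _protein_key(site_id: str) -> str:
    gene, acc = site_id.split(":")[:2]
    return f"{gene}:{acc}"


def protein_normalize(phospho: PhosphoMatrix, protein: PhosphoMatrix) -> PhosphoMatrix:
    """Subtract protein-level log2 abundance from each matching phosphosite row.

    Protein rows are keyed ``GENE:ACCESSION:PA``. Where the protein value is
    missing (or the protein row absent entirely) the phosphopeptide value is
    retained unnormalized, so already-sparse rows are not destroyed.
    """
    shared = [r for r in phospho.run_index if r in set(protein.run_index)]
    if not shared:
        raise ValueError("phospho and protein matrices share no runs")
    prot_rows = {_protein_key(s): i for i, s in enumerate(protein.site_index)}
    ph_col = [phospho.run_index.index(r) for r in shared]
    pr_col = [protein.run_index.index(r) for r in shared]
    out = phospho.copy()
    n_without = 0
    for i, sid in enumerate(phospho.site_index):
        pi = prot_rows.get(_protein_key(sid))
        if pi is None:
            n_without += 1
            continue
        pv = protein.values[pi, pr_col]
        cur = out.values[i, ph_col]
        both = np.isfinite(cur) & np.isfinite(pv)
        cur[both] -= pv[both]
        out.values[i, ph_col] = cur
    if n_without:
        logger.info("protein_normalize: %d sites had no protein row", n_without)
    return out


def aggregate_to_protein(m: PhosphoMatrix) -> PhosphoMatrix:
    """Combine all phosphosites of one protein into a single row (observed-only mean).

    The aggregated row id is ``GENE:ACCESSION:PA``. An entry is missing only
    when every site of the protein is missing in that run, so per-row
    completeness never decreases.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(m.site_index):
        key = _protein_key(sid)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    values = np.full((len(order), m.n_runs), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k, key in enumerate(order):
            values[k] = np.nanmean(m.values[groups[key]], axis=0)
    return PhosphoMatrix(values, [f"{k}:PA" for k in order], list(m.run_index),
                         dict(m.run_groups) if m.run_groups else None)
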