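import numpy as np
import pandas as pd
import pytest

from phosphonet.pvm import PVM_COLUMNS, PhosphoMatrix


def pvm_record(gene, acc, site, run, intensity, peptide="pep1"):
    return dict(
        gene_id=gene,
        protein_id=acc,
        peptide_id=peptide,
        site_id=f"{gene}:{acc}:{site}",
        modified_peptide_sequence=f"{peptide}_mod",
        peptide_sequence=peptide,
        phosphosite=site,
        run_id=run,
        peptide_intensity=intensity,
    )


@pytest.fixture
def small_matrix():
    """4 sites x 6 runs with structured missingness."""
    values = np.array([
        [10.0, 11.0, 12.0, 13.0, 14.0, 15.0],
        [20.0, np.nan, 22.0, np.nan, 24.0, 25.0],
        [np.nan, np.nan, np.nan, np.nan, np.nan, np.nan],
        [5.0, 4.0, 3.0, 2.0, 1.0, 0.0],
    ])
    sites = ["EGFR:P00533:S229", "EGFR:P00533:S233", "AKT1:P31749:S473",
             "MTOR:P42345:S2448"]
    runs = [f"r{i}" for i in range(6)]
    return PhosphoMatrix(values, sites, runs)


def mnar_censor(v, frac):
    """Censor the lowest `frac` quantile of a vector to NaN."""
    out = np.asarray(v, dtype=float).copy()
    thr = np.quantile(out, frac)
    out[out < thr] = np.nan
    return out
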