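import numpy as np
import pandas as pd
import pytest

from phosphonet.pvm import (
    PhosphoMatrix, PvmValidationError, aggregate_to_protein, load_pvm,
    matrix_to_pvm, protein_normalize, quantile_normalize, read_matrix,
    write_matrix,
)

from conftest import pvm_record


class TestLoadPvm:
    def test_most_consistent_precursor_wins(self):
        # precursor A observed in 4 runs, precursor B in 2 -> A kept
        recs = []
        for run in ["r1", "r2", "r3", "r4"]:
            recs.append(pvm_record("EGFR", "P00533", "S229", run, 10.0, peptide="pepA"))
        for run in ["r1", "r2"]:
            recs.append(pvm_record("EGFR", "P00533", "S229", run, 99.0, peptide="pepB"))
        m = load_pvm(recs)
        assert m.site_index == ["EGFR:P00533:S229"]
        np.testing.assert_allclose(m.values[0], [10.0, 10.0, 10.0, 10.0])

    def test_detection_tie_broken_by_median_intensity(self):
        recs = [pvm_record("EGFR", "P00533", "S229", r, 10.0, peptide="lo") for r in "ab"]
        recs += [pvm_record("EGFR", "P00533", "S229", r, 20.0, peptide="hi") for r in "ab"]
        m = load_pvm(recs)
        np.testing.assert_allclose(m.values[0], [20.0, 20.0])

    def test_multisite_peptide_yields_row_per_site(self):
        # a doubly phosphorylated peptide covering S229 and S233
        recs = []
        for run, v in [("r1", 8.0), ("r2", 9.0)]:
            recs.append(pvm_record("EGFR", "P00533", "S229", run, v, peptide="pepD"))
            recs.append(pvm_record("EGFR", "P00533", "S233", run, v, peptide="pepD"))
        m = load_pvm(recs)
        assert m.n_sites == 2
        np.testing.assert_allclose(m.values[0], m.values[1])

    def test_bad_phosphosite_rejected(self):
        rec = pvm_record("EGFR", "P00533", "X99", "r1", 10.0)
        with pytest.raises(PvmValidationError, match="X99"):
            load_pvm([rec])

    def test_inconsistent_site_id_rejected(self):
        rec = pvm_record("EGFR", "P00533", "S229", "r1", 10.0)
        rec["site_id"] = "EGFR:WRONG:S229"
        with pytest.raises(PvmValidationError, match="site_id"):
            load_pvm([rec])

    def test_empty_input_rejected(self):
        with pytest.raises(PvmValidationError):
            load_pvm([])

    def test_explicit_id_map_rebuilds_site_ids(self):
        recs = [pvm_record("EGFR_HUMAN", "P00533", "S229", "r1", 10.0)]
        recs[0]["site_id"] = "EGFR_HUMAN:P00533:S229"
        m = load_pvm(recs, id_map={"EGFR_HUMAN": "EGFR"})
        assert m.site_index == ["EGFR:P00533:S229"]

    def test_idempotent_on_own_output(self, small_matrix):
        pvm1 = matrix_to_pvm(small_matrix)
        m1 = load_pvm(pvm1)
        m2 = load_pvm(matrix_to_pvm(m1))
        assert m1.site_index == m2.site_index
        np.testing.assert_array_equal(np.nan_to_num(m1.values), np.nan_to_num(m2.values))


class TestQuantileNormalize:
    def test_identical_rank_orders_become_identical(self):
        values = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0], [4.0, 40.0]])
        m = PhosphoMatrix(values, [f"G{i}:A{i}:S1" for i in range(4)], ["r1", "r2"])
        out = quantile_normalize(m)
        # after row-centering both runs of each row must agree exactly
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1], atol=1e-9)

    def test_rows_centered_and_missing_preserved(self, small_matrix):
        out = quantile_normalize(small_matrix)
        assert np.array_equal(out.mask, small_matrix.mask)
        for i in range(out.n_sites):
            obs = out.values[i][out.mask[i]]
            if obs.size:
                assert abs(obs.mean()) < 1e-9

    def test_all_missing_row_unchanged(self, small_matrix):
        out = quantile_normalize(small_matrix)
        assert not out.mask[2].any()

    def test_preserves_within_run_rank_order(self, small_matrix):
        out = quantile_normalize(small_matrix)
        # undo centering so within-run comparisons are valid
        with np.errstate(all="ignore"):
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                row_mean = np.nanmean(small_matrix.values, axis=1)
        restored = out.values + np.nan_to_num(row_mean)[:, None]
        for j in range(out.n_runs):
            obs = small_matrix.mask[:, j]
            before = small_matrix.values[obs, j]
            after = restored[obs, j]
            assert np.array_equal(np.argsort(before), np.argsort(after))

    def test_single_run_group_skipped_with_warning(self, small_matrix):
        small_matrix.run_groups = {r: ("a" if i else "solo")
                                   for i, r in enumerate(small_matrix.run_index)}
        with pytest.warns(UserWarning, match="single run"):
            quantile_normalize(small_matrix, by_group=True)


class TestProteinNormalize:
    def make_protein(self, values, runs):
        return PhosphoMatrix(np.asarray(values, float), ["EGFR:P00533:PA"], runs)

    def test_log_ratio(self, small_matrix):
        prot = self.make_protein([[18.0] * 6], small_matrix.run_index)
        out = protein_normalize(small_matrix, prot)
        assert out.values[0, 0] == pytest.approx(10.0 - 18.0)

    def test_missing_protein_value_keeps_phospho(self, small_matrix):
        prot = self.make_protein([[np.nan] * 6], small_matrix.run_index)
        out = protein_normalize(small_matrix, prot)
        np.testing.assert_array_equal(np.nan_to_num(out.values),
                                      np.nan_to_num(small_matrix.values))

    def test_site_without_protein_row_passes_through(self, small_matrix):
        prot = self.make_protein([[18.0] * 6], small_matrix.run_index)
        out = protein_normalize(small_matrix, prot)
        np.testing.assert_allclose(out.values[3], small_matrix.values[3])

    def test_no_shared_runs_rejected(self, small_matrix):
        prot = self.make_protein([[18.0]], ["other_run"])
        with pytest.raises(ValueError, match="no runs"):
            protein_normalize(small_matrix, prot)


class TestAggregateToProtein:
    def test_observed_only_mean(self, small_matrix):
        out = aggregate_to_protein(small_matrix)
        assert out.site_index[0] == "EGFR:P00533:PA"
        # run r1: sites at 11.0 and NaN -> 11.0; run r0: (10+20)/2
        assert out.values[0, 0] == pytest.approx(15.0)
        assert out.values[0, 1] == pytest.approx(11.0)

    def test_single_site_is_identity(self, small_matrix):
        out = aggregate_to_protein(small_matrix)
        np.testing.assert_allclose(out.values[2], small_matrix.values[3])

    def test_completeness_never_decreases(self, small_matrix):
        out = aggregate_to_protein(small_matrix)
        before = {s: c for s, c in zip(small_matrix.site_index,
                                       small_matrix.completeness())}
        for k, key in enumerate(out.site_index):
            prefix = ":".join(key.split(":")[:2])
            members = [before[s] for s in before if s.startswith(prefix + ":")]
            assert out.completeness()[k] >= max(members) - 1e-12


def test_matrix_tsv_roundtrip(tmp_path, small_matrix):
    path = tmp_path / "m.tsv"
    write_matrix(small_matrix, path)
    back = read_matrix(path)
    assert back.site_index == small_matrix.site_index
    assert back.run_index == small_matrix.run_index
    np.testing.assert_allclose(np.nan_to_num(back.values),
                               np.nan_to_num(small_matrix.values))
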