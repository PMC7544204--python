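import numpy as np
import pandas as pd
import pytest

import capscreen
from capscreen.ingest import (
    DesignError,
    ExperimentDesign,
    IntensityMatrix,
    ProteinRecord,
    ProteinGroupsError,
    filter_records,
    merge_homologs,
    read_design,
    read_protein_groups,
)
from capscreen.synthetic import SyntheticConfig, generate_screen, write_protein_groups

from .conftest import make_matrix


class TestDesign:
    def test_minimal_valid_design(self, toy_design):
        assert toy_design.testable_conditions() == [("NCBP1", "7")]
        assert toy_design.case_experiments("NCBP1", "7") == ["e1", "e2"]

    def test_duplicate_experiment_id_rejected(self, toy_design):
        table = toy_design.table.copy()
        table.loc[1, "experiment_id"] = "e1"
        with pytest.raises(DesignError, match="duplicate"):
            ExperimentDesign(table)

    def test_single_control_replicate_rejected(self, toy_design):
        with pytest.raises(DesignError, match="control replicates"):
            ExperimentDesign(toy_design.table.iloc[:3])

    def test_missing_column_rejected(self, toy_design):
        with pytest.raises(DesignError, match="vessel"):
            ExperimentDesign(toy_design.table.drop(columns=["vessel"]))

    def test_ncbp_registry_has_57_case_runs(self):
        """The packaged screen registry reproduces the per-target case-IP
        totals: 23 + 22 + 12 = 57 dimensions before MDS reduction."""
        design = read_design(capscreen.ncbp_design_path())
        counts = design.n_case_runs()
        assert counts == {"NCBP1": 23, "NCBP2": 22, "NCBP3": 12}
        assert sum(counts.values()) == 57


class TestReadProteinGroups:
    @pytest.fixture
    def written(self, tmp_path, toy_design):
        cfg = SyntheticConfig(
            targets=(capscreen.TargetSpec("NCBP1", ("7",), 2, 2),),
            n_background=40,
            n_interactors=3,
            seed=5,
        )
        design, frame, truth = generate_screen(cfg)
        paths = write_protein_groups(design, frame, truth, tmp_path)
        return design, frame, paths

    def test_zero_intensity_becomes_missing(self, written):
        design, frame, paths = written
        records, lfq, ibaq = read_protein_groups(paths["protein_groups"], design)
        col = f"LFQ intensity {design.experiment_ids[0]}"
        zero_rows = frame.index[frame[col] == 0]
        assert len(zero_rows) > 0
        ids = frame.loc[zero_rows, "Majority protein IDs"]
        assert lfq.mask.loc[ids, design.experiment_ids[0]].all()

    def test_round_trip_exact(self, written):
        design, frame, paths = written
        records, lfq, ibaq = read_protein_groups(paths["protein_groups"], design)
        for layer, prefix in ((lfq, "LFQ intensity "), (ibaq, "iBAQ ")):
            for e in design.experiment_ids:
                raw = frame[prefix + e].to_numpy(dtype=float)
                expected = np.where(raw > 0, raw, np.nan)
                np.testing.assert_array_equal(layer.values[e].to_numpy(), expected)

    def test_semicolon_peptide_counts_and_flags(self, tmp_path, toy_design):
        table = pd.DataFrame(
            {
                "Majority protein IDs": ["P1;P2", "P3"],
                "Gene names": ["A", "B"],
                "Peptide counts (razor + unique)": ["5;1", "3"],
                "Reverse": ["", "+"],
                "Potential contaminant": ["", ""],
                **{f"LFQ intensity {e}": [10.0, 20.0] for e in toy_design.experiment_ids},
                **{f"iBAQ {e}": [1.0, 2.0] for e in toy_design.experiment_ids},
            }
        )
        path = tmp_path / "pg.txt"
        table.to_csv(path, sep="\t", index=False)
        records, lfq, _ = read_protein_groups(path, toy_design)
        assert records[0].protein_id == "P1"
        assert records[0].peptide_counts == (5, 1)
        assert records[1].is_reverse
        assert lfq.proteins == ["P1", "P3"]

    def test_missing_intensity_column_errors(self, tmp_path, toy_design):
        table = pd.DataFrame(
            {
                "Majority protein IDs": ["P1"],
                "Gene names": ["A"],
                "Peptide counts (razor + unique)": ["5"],
                "Reverse": [""],
                "Potential contaminant": [""],
                "LFQ intensity e1": [10.0],
                "iBAQ e1": [1.0],
            }
        )
        path = tmp_path / "pg.txt"
        table.to_csv(path, sep="\t", index=False)
        with pytest.raises(ProteinGroupsError, match="e2"):
            read_protein_groups(path, toy_design)


def _record(pid, counts, reverse=False, contaminant=False):
    return ProteinRecord(pid, pid, tuple(counts), reverse, contaminant)


class TestFilterRecords:
    @pytest.mark.parametrize(
        "record, kept",
        [
            (_record("P1", [2, 1]), True),  # max over members reaches 2
            (_record("P2", [1]), False),
            (_record("P3", [30], contaminant=True), False),  # flag dominates
            (_record("P4", [30], reverse=True), False),
        ],
    )
    def test_retention_rule(self, record, kept):
        m = make_matrix(pd.DataFrame({"e1": [5.0]}, index=[record.protein_id]), scale="linear")
        records, mats, dropped = filter_records([record], [m])
        assert (len(records) == 1) is kept
        assert (record.protein_id in mats[0].proteins) is kept

    def test_drop_log_and_alignment(self):
        records = [_record("P1", [3]), _record("P2", [1]), _record("P3", [9], reverse=True)]
        vals = pd.DataFrame({"e1": [1.0, 2.0, 3.0]}, index=["P1", "P2", "P3"])
        kept, (m,), dropped = filter_records(records, [make_matrix(vals, scale="linear")])
        assert [r.protein_id for r in kept] == ["P1"]
        assert dropped == {"reverse": 1, "contaminant": 0, "low_peptides": 1}
        assert float(m.values.loc["P1", "e1"]) == 1.0


class TestMergeHomologs:
    def mat(self, data):
        return make_matrix(pd.DataFrame(data).T, scale="linear")

    def test_sum_and_missing_conventions(self):
        m = self.mat(
            {
                "MAGOH": [100.0, np.nan, np.nan],
                "MAGOHB": [50.0, 50.0, np.nan],
                "OTHER": [7.0, 7.0, 7.0],
            }
        )
        (merged,) = merge_homologs([m])
        row = merged.values.loc["MAGOH*"]
        assert row.iloc[0] == 150.0  # both present: summed
        assert row.iloc[1] == 50.0  # one absent: treated as zero
        assert np.isnan(row.iloc[2])  # all absent: stays missing
        assert "MAGOH" not in merged.proteins

    def test_total_signal_conserved(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(
            rng.lognormal(3, 1, size=(6, 4)),
            index=["MAGOH", "MAGOHB", "A", "B", "C", "D"],
        )
        vals.iloc[0, 1] = np.nan
        m = make_matrix(vals, scale="linear")
        (merged,) = merge_homologs([m])
        np.testing.assert_allclose(
            merged.values.sum(axis=0, skipna=True).to_numpy(),
            vals.sum(axis=0, skipna=True).to_numpy(),
        )

    def test_absent_member_warns_and_merges_present(self):
        m = self.mat({"MAGOH": [10.0], "X": [1.0]})
        with pytest.warns(UserWarning, match="absent"):
            (merged,) = merge_homologs([m])
        assert merged.values.loc["MAGOH*"].iloc[0] == 10.0


class TestIntensityMatrix:
    def test_linear_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            make_matrix(pd.DataFrame({"e1": [-1.0]}), scale="linear")

    def test_mask_tracks_nan(self):
        m = make_matrix(pd.DataFrame({"e1": [1.0, np.nan]}), scale="linear")
        assert m.mask["e1"].tolist() == [False, True]
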