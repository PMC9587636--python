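"""Parsing of screen description files and assembly of the cell table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sopra import screen_io
from sopra.screen_io import (
    ContentType,
    FlagRecord,
    PlateListEntry,
    ScreenFormatError,
    WellAnnotation,
)


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestPlateList:
    def test_two_entries_in_file_order(self, tmp_path):
        p = _write(tmp_path / "PlateList.txt",
                   "Plate\tReplicate\tFilename\nP1\t1\ta.txt\nP2\t1\tb.txt\n")
        entries = screen_io.read_plate_list(p)
        assert entries == [
            PlateListEntry("P1", 1, "a.txt"),
            PlateListEntry("P2", 1, "b.txt"),
        ]

    def test_empty_body_gives_empty_list(self, tmp_path):
        p = _write(tmp_path / "PlateList.txt", "Plate\tReplicate\tFilename\n")
        assert screen_io.read_plate_list(p) == []

    def test_duplicate_plate_replicate_rejected(self, tmp_path):
        p = _write(tmp_path / "PlateList.txt",
                   "Plate\tReplicate\tFilename\nP1\t1\ta.txt\nP1\t1\tb.txt\n")
        with pytest.raises(ScreenFormatError, match="duplicate"):
            screen_io.read_plate_list(p)

    def test_non_integer_replicate_rejected(self, tmp_path):
        p = _write(tmp_path / "PlateList.txt",
                   "Plate\tReplicate\tFilename\nP1\tx\ta.txt\n")
        with pytest.raises(ScreenFormatError):
            screen_io.read_plate_list(p)


class TestPlateConf:
    def test_content_labels_map_to_types(self, tmp_path):
        p = _write(
            tmp_path / "conf.txt",
            "Plate\tWell\tContent\tRNA.ID\tGeneSymbol\n"
            "P1\t1\tAllStars\tAS1\t\n"
            "P1\t2\tsample\tSI00012345\tCDK1\n",
        )
        anns = screen_io.read_plate_conf(p, ["P1"])
        assert anns[0].content_type is ContentType.NEUTRAL_CONTROL
        assert anns[0].rna_id == "AS1"
        assert anns[1].content_type is ContentType.SAMPLE
        assert anns[1].gene_symbol == "CDK1"

    def test_plate_missing_from_conf_rejected(self, tmp_path):
        p = _write(tmp_path / "conf.txt",
                   "Plate\tWell\tContent\nP1\t1\tAllStars\n")
        with pytest.raises(ScreenFormatError, match="P2"):
            screen_io.read_plate_conf(p, ["P1", "P2"])

    def test_unknown_content_label_rejected(self, tmp_path):
        p = _write(tmp_path / "conf.txt",
                   "Plate\tWell\tContent\nP1\t1\tmystery\n")
        with pytest.raises(ScreenFormatError, match="mystery"):
            screen_io.read_plate_conf(p, ["P1"])

    def test_plate_without_neutral_controls_rejected(self, tmp_path):
        p = _write(tmp_path / "conf.txt",
                   "Plate\tWell\tContent\nP1\t1\tsample\n")
        with pytest.raises(ScreenFormatError, match="neutral"):
            screen_io.read_plate_conf(p, ["P1"])


class TestSingleCellFile:
    def test_all_numeric_rows_kept(self, tmp_path):
        p = _write(tmp_path / "sc.txt",
                   "Well\tArea\n1\t10.5\n1\t11.0\n2\t9.0\n")
        rows, report = screen_io.read_single_cell_file(p, ["Area"])
        assert len(rows) == 3 and report.n_dropped == 0
        assert rows["Area"].tolist() == [10.5, 11.0, 9.0]

    def test_non_numeric_row_dropped_and_reported(self, tmp_path):
        p = _write(tmp_path / "sc.txt",
                   "Well\tArea\n1\t10.5\n1\tNaN\n2\t9.0\n")
        rows, report = screen_io.read_single_cell_file(p, ["Area"])
        assert len(rows) == 2
        assert report.n_rows == 3 and report.n_dropped == 1 and report.n_kept == 2

    def test_missing_feature_column_rejected(self, tmp_path):
        p = _write(tmp_path / "sc.txt", "Well\tIntensity\n1\t5\n")
        with pytest.raises(ScreenFormatError, match="Area"):
            screen_io.read_single_cell_file(p, ["Area"])

    def test_comma_decimal_mode(self, tmp_path):
        p = _write(tmp_path / "sc.txt", "Well\tArea\n1\t10,5\n")
        rows, _ = screen_io.read_single_cell_file(p, ["Area"], decimal=",")
        assert rows["Area"].iloc[0] == 10.5


@pytest.fixture()
def assembled_inputs():
    entries = [PlateListEntry("P1", 1, "p1.txt")]
    annotations = [
        WellAnnotation("P1", 1, ContentType.NEUTRAL_CONTROL, "AS1", None),
        WellAnnotation("P1", 2, ContentType.SAMPLE, "SI1", "CDK1"),
    ]
    raw = {("P1", 1): pd.DataFrame({"well": [1, 1, 2], "Area": [1.0, 2.0, 3.0]})}
    return entries, annotations, raw


class TestAssemble:
    def test_flagged_well_excluded(self, assembled_inputs):
        entries, annotations, raw = assembled_inputs
        flags = [FlagRecord("P1", 1, "contaminated")]
        table = screen_io.assemble_cell_table(entries, annotations, flags, raw)
        assert set(table["well"]) == {2}

    def test_no_flags_keeps_all_rows(self, assembled_inputs):
        entries, annotations, raw = assembled_inputs
        table = screen_io.assemble_cell_table(entries, annotations, [], raw)
        assert len(table) == 3
        counts = table.groupby("well").size()
        assert counts[1] == 2 and counts[2] == 1

    def test_all_flagged_gives_empty_table_with_warning(self, assembled_inputs):
        entries, annotations, raw = assembled_inputs
        flags = [FlagRecord("P1", 1), FlagRecord("P1", 2)]
        with pytest.warns(UserWarning, match="empty"):
            table = screen_io.assemble_cell_table(entries, annotations, flags, raw)
        assert table.empty

    def test_unannotated_well_rejected(self, assembled_inputs):
        entries, annotations, raw = assembled_inputs
        raw[("P1", 1)].loc[0, "well"] = 99
        with pytest.raises(ScreenFormatError, match="annotation"):
            screen_io.assemble_cell_table(entries, annotations, [], raw)


class TestAllDataTable:
    def _profiles(self):
        return pd.DataFrame(
            {
                "plate": "P1", "replicate": 1, "well": 1, "content": "sample",
                "rna_id": "SI1", "gene": "CDK1", "feature": "Area",
                "bin": range(1, 8),
                "count": [3, 5, 8, 13, 8, 5, 3],
                "rel_freq": np.linspace(0.05, 0.3, 7),
                "value": np.log2(np.linspace(0.5, 2.0, 7)),
                "scale": "log2",
            }
        )

    def test_one_row_per_bin(self, tmp_path):
        path = tmp_path / "AllDataTable.txt"
        screen_io.write_all_data_table(self._profiles(), path)
        assert len(path.read_text().splitlines()) == 8  # header + 7 bins

    def test_round_trip_is_lossless(self, tmp_path):
        path = tmp_path / "AllDataTable.txt"
        original = self._profiles()
        screen_io.write_all_data_table(original, path)
        back = screen_io.read_all_data_table(path)
        np.testing.assert_array_equal(back["value"].to_numpy(), original["value"].to_numpy())
        np.testing.assert_array_equal(back["rel_freq"].to_numpy(), original["rel_freq"].to_numpy())

    def test_empty_profile_list_gives_header_only(self, tmp_path):
        path = tmp_path / "AllDataTable.txt"
        screen_io.write_all_data_table(self._profiles().iloc[:0], path)
        assert len(path.read_text().splitlines()) == 1


class TestLoadScreen:
    def test_generated_screen_round_trips(self, tmp_path, tiny_config, tiny_cells):
        from sopra.simulate import FEATURES, generate_screen

        generate_screen(tiny_config, tmp_path)
        cells = screen_io.load_screen(tmp_path, FEATURES)
        assert len(cells) == len(tiny_cells)
        np.testing.assert_allclose(
            np.sort(cells["Area"].to_numpy()), np.sort(tiny_cells["Area"].to_numpy())
        )

    def test_object_counts_match_minus_flagged(self, tmp_path, tiny_config):
        import dataclasses

        from sopra.simulate import FEATURES, generate_screen

        cfg = dataclasses.replace(tiny_config, n_flagged=2)
        generate_screen(cfg, tmp_path)
        flags = screen_io.read_screen_log(tmp_path / "ScreenLog.txt")
        assert len(flags) == 2
        cells = screen_io.load_screen(tmp_path, FEATURES)
        flagged = {(f.plate_id, f.well_index) for f in flags}
        present = set(zip(cells["plate"], cells["well"]))
        assert not (flagged & present)


def test_well_name_conversion():
    assert screen_io.well_name_to_index("A01", n_cols=24) == 1
    assert screen_io.well_name_to_index("B01", n_cols=24) == 25
    assert screen_io.well_name_to_index("P24", n_cols=24) == 384
    assert screen_io.well_name_to_index("A12", n_cols=12) == 12
    with pytest.raises(ScreenFormatError):
        screen_io.well_name_to_index("A99", n_cols=12)
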