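"""Cq table parsing, replicate collapsing and detectability filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_cq_table, make_pair_sheet
from hemomir.cq_data import (
    CqTable,
    SampleSheet,
    collapse_replicates,
    detection_mask,
    filter_detectable,
    read_cq_table,
    read_sample_sheet,
    write_cq_table,
    write_sample_sheet,
)
from hemomir.errors import (
    ConfigurationError,
    DesignError,
    FormatError,
    ValidationError,
)
from hemomir.synth import generate_paired_study


class TestParsing:
    def test_undetermined_maps_to_undetected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("mir_id\tA\tB\nmiR-1\t24.5\tUndetermined\nmiR-2\t30\t31\n")
        t = read_cq_table(p)
        assert np.isnan(t.frame.loc["miR-1", ("B", "1")])
        assert t.frame.loc["miR-2", ("A", "1")] == 30.0

    def test_out_of_range_cq_is_validation_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("mir_id\tA\nmiR-1\t41.2\n")
        with pytest.raises(ValidationError, match="41.2"):
            read_cq_table(p)

    def test_duplicate_assays_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("mir_id\tA\nmiR-1\t24\nmiR-1\t25\n")
        with pytest.raises(FormatError, match="miR-1"):
            read_cq_table(p)

    def test_unparsable_cell_is_format_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("mir_id\tA\nmiR-1\toops\n")
        with pytest.raises(FormatError, match="oops"):
            read_cq_table(p)

    def test_replicate_headers_split_on_colon(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("mir_id\tA:run1\tA:run2\nmiR-1\t24\t25\n")
        t = read_cq_table(p)
        assert t.replicates_of("A") == ["run1", "run2"]

    def test_roundtrip_of_synthetic_study(self, tmp_path):
        study = generate_paired_study(seed=11, n_mirs=25)
        path = tmp_path / "cq.tsv"
        write_cq_table(study.cq_table, path)
        back = read_cq_table(path)
        assert back.mir_ids == study.cq_table.mir_ids
        a = study.cq_table.frame.to_numpy()
        b = back.frame.to_numpy()
        # values survive the %.6g serialization
        np.testing.assert_allclose(a, b, rtol=1e-5, equal_nan=True)


class TestCollapse:
    def test_mean_of_detected_replicates(self):
        t = make_cq_table({("A", "1"): [24.0], ("A", "2"): [25.0]}, ["m1"])
        c = collapse_replicates(t)
        assert c.frame.loc["m1", ("A", "1")] == pytest.approx(24.5)

    def test_all_undetected_stays_undetected(self):
        t = make_cq_table({("A", "1"): [None], ("A", "2"): [None]}, ["m1"])
        assert np.isnan(collapse_replicates(t).frame.to_numpy()).all()

    def test_mixed_replicates_default_undetected(self):
        t = make_cq_table({("A", "1"): [33.0], ("A", "2"): [None]}, ["m1"])
        assert np.isnan(collapse_replicates(t).frame.to_numpy()).all()

    def test_mixed_replicates_detected_only_policy(self):
        t = make_cq_table({("A", "1"): [33.0], ("A", "2"): [None]}, ["m1"])
        c = collapse_replicates(t, policy="detected_only")
        assert c.frame.loc["m1", ("A", "1")] == pytest.approx(33.0)

    def test_collapse_is_idempotent(self):
        t = make_cq_table(
            {("A", "1"): [24.0, None], ("A", "2"): [25.0, 30.0], ("B", "1"): [22.0, 29.0]},
            ["m1", "m2"],
        )
        once = collapse_replicates(t)
        assert once.is_collapsed
        twice = collapse_replicates(once)
        assert once == twice

    def test_unknown_policy(self):
        t = make_cq_table({("A", "1"): [24.0]}, ["m1"])
        with pytest.raises(ConfigurationError):
            collapse_replicates(t, policy="median")


class TestDetection:
    def test_strict_boundary(self):
        t = make_cq_table({("A", "1"): [34.99, 35.00, None]}, ["m1", "m2", "m3"])
        mask = detection_mask(t)
        assert mask["A"].tolist() == [True, False, False]

    def test_counts_match_bruteforce_on_synthetic_table(self):
        rng = np.random.default_rng(5)
        mirs = [f"m{i}" for i in range(20)]
        cols = {}
        for s in "ABCDEF":
            vals = rng.uniform(20, 40, size=20)
            vals[rng.random(20) < 0.2] = np.nan
            cols[(s, "1")] = vals.tolist()
        t = make_cq_table(cols, mirs)
        mask = detection_mask(t)
        for s in "ABCDEF":
            manual = sum(
                1
                for v in cols[(s, "1")]
                if v is not None and not np.isnan(v) and v < 35.0
            )
            assert int(mask[s].sum()) == manual

    @given(st.floats(25.0, 40.0))
    def test_monotone_in_threshold(self, cutoff):
        rng = np.random.default_rng(0)
        t = make_cq_table(
            {("A", "1"): rng.uniform(20, 40, 30).tolist()}, [f"m{i}" for i in range(30)]
        )
        assert int(detection_mask(t, cutoff).sum().sum()) <= int(
            detection_mask(t, 40.0).sum().sum()
        )

    def test_requires_collapsed(self):
        t = make_cq_table({("A", "1"): [24.0], ("A", "2"): [24.0]}, ["m1"])
        with pytest.raises(ValidationError):
            detection_mask(t)


class TestFilterDetectable:
    def make_table(self):
        rng = np.random.default_rng(9)
        mirs = [f"m{i}" for i in range(10)]
        cols = {}
        for s in "ABCDEF":
            vals = rng.uniform(25, 39, size=10)
            cols[(s, "1")] = vals.tolist()
        return make_cq_table(cols, mirs)

    def test_matches_enumeration_oracle(self):
        t = self.make_table()
        kept = filter_detectable(t, 4, list("ABCDEF")).mir_ids
        mask = detection_mask(t)
        expected = [
            m for m in t.mir_ids if int(mask.loc[m, list("ABCDEF")].sum()) >= 4
        ]
        assert kept == expected

    def test_kept_when_detected_in_four_of_six(self):
        cols = {(s, "1"): [30.0 if i < 4 else 36.0] for i, s in enumerate("ABCDEF")}
        t = make_cq_table(cols, ["m1"])
        assert filter_detectable(t, 4, list("ABCDEF")).mir_ids == ["m1"]

    def test_global_exclusion_of_never_detected(self):
        cols = {(s, "1"): [36.0] for s in "ABCDEF"}
        t = make_cq_table(cols, ["m1"])
        assert filter_detectable(t, 0, list("ABCDEF")).mir_ids == []

    def test_idempotent(self):
        t = self.make_table()
        once = filter_detectable(t, 3, list("ABCDEF"))
        twice = filter_detectable(once, 3, list("ABCDEF"))
        assert once == twice

    def test_threshold_exceeding_subset_size(self):
        t = self.make_table()
        with pytest.raises(ConfigurationError):
            filter_detectable(t, 7, list("ABCDEF"))


class TestSampleSheet:
    def test_pair_integrity_enforced(self):
        rows = pd.DataFrame(
            [
                dict(sample_id="a", subject_id="s", condition="hemolyzed",
                     pair_id="P1", a414=0.4, rbc_fraction=np.nan),
                dict(sample_id="b", subject_id="s", condition="hemolyzed",
                     pair_id="P1", a414=0.3, rbc_fraction=np.nan),
            ]
        )
        with pytest.raises(DesignError, match="P1"):
            SampleSheet(rows)

    def test_dilution_requires_fraction(self):
        rows = pd.DataFrame(
            [dict(sample_id="d", subject_id="s", condition="dilution",
                  pair_id="", a414=0.2, rbc_fraction=np.nan)]
        )
        with pytest.raises(ValidationError, match="rbc_fraction"):
            SampleSheet(rows)

    def test_fraction_only_on_dilution(self):
        rows = pd.DataFrame(
            [dict(sample_id="r", subject_id="s", condition="rbc",
                  pair_id="", a414=np.nan, rbc_fraction=0.1)]
        )
        with pytest.raises(ValidationError):
            SampleSheet(rows)

    def test_pair_degrees(self):
        sheet = make_pair_sheet({"P1": (0.143, 0.574), "P2": (0.127, 0.242)})
        deg = sheet.pair_degrees()
        assert deg["P1"] == pytest.approx(4.01, abs=0.02)
        assert deg["P2"] == pytest.approx(1.90, abs=0.02)

    def test_roundtrip(self, tmp_path):
        sheet = make_pair_sheet({"P1": (0.14, 0.41)})
        p = tmp_path / "sheet.tsv"
        write_sample_sheet(sheet, p)
        back = read_sample_sheet(p)
        pd.testing.assert_frame_equal(back.frame, sheet.frame)
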