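"""Channel gating, LEV proximity annotation, and the per-frame debris filter."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from liqbio.core import CHANNELS, LEV_CLASSES, RareEventClass
from liqbio.gating import (
    annotate_lev_proximity,
    classify_table,
    filter_lev_frames,
)
from liqbio.synthetic import EventMixtureSpec, generate_event_table


def _table_from_mixture(n=400, seed=21, rare_fraction=0.3):
    spec = EventMixtureSpec.default(rare_fraction=rare_fraction)
    table = generate_event_table(n, spec, seed=seed)
    return spec, table


class TestClassifyTable:
    def test_calls_equal_threshold_comparison_exactly(self):
        spec, table = _table_from_mixture()
        cutoffs = spec.cutoffs()
        out = classify_table(table, cutoffs)
        for c in CHANNELS:
            expected = table[f"median_{c}"] > cutoffs[c]
            if c == "dapi":
                expected &= table["kind"] == "nucleated"
            np.testing.assert_array_equal(out[f"{c}_call"].to_numpy(),
                                          expected.to_numpy())

    def test_gating_recovers_truth_labels(self):
        spec, table = _table_from_mixture()
        out = classify_table(table, spec.cutoffs())
        rare = out[~out["true_class"].isin(["WBC", "artifact"])]
        accuracy = (rare["event_class"] == rare["true_class"]).mean()
        # the populations are ~3.9 log-SD apart: misgating is possible but rare
        assert accuracy >= 0.99

    def test_wbc_maps_to_cd_only_signature(self):
        # common WBCs share the CD45/CD31-only channel signature: the table
        # gates them into that category; only truth labels separate the two
        spec, table = _table_from_mixture()
        out = classify_table(table, spec.cutoffs())
        wbc = out[out["true_class"] == "WBC"]
        assert (wbc["event_class"] == RareEventClass.CD_ONLY.value).mean() > 0.98

    def test_elongated_anucleated_marked_artifact(self):
        spec, table = _table_from_mixture(rare_fraction=0.2)
        row = table.iloc[[0]].copy()
        row["kind"] = "anucleated"
        row["cell_eccentricity"] = 0.97
        row["nuclear_area_um2"] = 0.0
        out = classify_table(row, spec.cutoffs())
        assert out["event_class"].iloc[0] == RareEventClass.ARTIFACT.value

    def test_without_frame_columns_filter_passes_everything(self):
        spec, table = _table_from_mixture(n=50)
        out = classify_table(table, spec.cutoffs())
        assert out["passed_frame_filter"].all()


class TestProximity:
    def test_inclusive_boundary(self):
        nuclei = [(0.0, 0.0)]
        assert annotate_lev_proximity((10.0, 0.0), nuclei, 10.0) == \
            "cell_proximal"
        assert annotate_lev_proximity((10.001, 0.0), nuclei, 10.0) == \
            "free_floating"

    def test_no_nuclei_means_free_floating(self):
        assert annotate_lev_proximity((5.0, 5.0), [], 10.0) == "free_floating"

    def test_nearest_nucleus_decides(self):
        nuclei = [(100.0, 100.0), (12.0, 0.0)]
        assert annotate_lev_proximity((3.0, 0.0), nuclei, 10.0) == \
            "cell_proximal"

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            annotate_lev_proximity((0, 0), [(1, 1)], 0.0)


def _lev_frame_table():
    lev = RareEventClass.LEV_CK.value
    rows = []
    for i in range(5):  # frame 0: 5 LEVs (over the cap)
        rows.append({"frame": 0, "event_class": lev, "median_ck": 100.0 + i})
    for i in range(2):  # frame 1: under the cap
        rows.append({"frame": 1, "event_class": lev, "median_ck": 50.0})
    rows.append({"frame": 0, "event_class": "epi.CTC", "median_ck": 900.0})
    return pd.DataFrame(rows)


class TestFrameFilter:
    def test_drop_mode_removes_whole_frame(self):
        out = filter_lev_frames(_lev_frame_table(), max_per_frame=3)
        lev_frames = out[out["event_class"] == RareEventClass.LEV_CK.value]
        assert set(lev_frames["frame"]) == {1}
        # non-LEV rows always pass
        assert (out["event_class"] == "epi.CTC").sum() == 1

    def test_cap_mode_keeps_brightest(self):
        out = filter_lev_frames(_lev_frame_table(), max_per_frame=3,
                                mode="cap")
        kept = out[(out["frame"] == 0)
                   & (out["event_class"] == RareEventClass.LEV_CK.value)]
        assert len(kept) == 3
        assert sorted(kept["median_ck"]) == [102.0, 103.0, 104.0]

    def test_idempotent(self):
        once = filter_lev_frames(_lev_frame_table(), max_per_frame=3)
        twice = filter_lev_frames(once, max_per_frame=3)
        pd.testing.assert_frame_equal(once, twice)

    def test_never_increases_counts(self):
        table = _lev_frame_table()
        out = filter_lev_frames(table, max_per_frame=3)
        assert len(out) <= len(table)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            filter_lev_frames(_lev_frame_table(), mode="trim")


class TestFrameIntegration:
    def test_debris_frames_contribute_no_levs(self, frame_run):
        _, truth, classified, _ = frame_run
        lev_names = {c.value for c in LEV_CLASSES}
        debris_frames = set(truth.loc[truth["is_debris_frame"], "frame"])
        levs = classified[classified["event_class"].isin(lev_names)]
        failed = set(levs.loc[~levs["passed_frame_filter"], "frame"])
        assert debris_frames <= failed

    def test_clean_frames_keep_their_levs(self, frame_run):
        _, truth, classified, _ = frame_run
        lev_names = {c.value for c in LEV_CLASSES}
        levs = classified[classified["event_class"].isin(lev_names)]
        for f, sub in levs.groupby("frame"):
            if len(sub) <= 3:
                assert sub["passed_frame_filter"].all()

    def test_proximity_annotation_matches_truth(self, frame_run):
        _, truth, classified, matched = frame_run
        lev_names = {c.value for c in LEV_CLASSES}
        lev_truth = matched[matched["true_class"].isin(lev_names)
                            & matched["matched_event_id"].notna()]
        by_id = classified.set_index("event_id")
        for _, row in lev_truth.iterrows():
            det = by_id.loc[int(row["matched_event_id"])]
            expected = "cell_proximal" if row["lev_proximal"] \
                else "free_floating"
            assert det["lev_proximity"] == expected
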