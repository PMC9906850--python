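"""Quality filters, night segmentation, period/age labels, inclusion rules."""

import io
from datetime import date

import numpy as np
import pandas as pd
import pytest

from owlmove import preprocess, simulate
from owlmove.preprocess import (
    SchemaError,
    apply_inclusion_rules,
    assign_age_class,
    assign_period,
    filter_fixes,
    read_fixes,
    segment_nights,
)

HEADER = "tag_id,time_utc_ms,x_m,y_m,std_m\n"


def _fixes(rows):
    return read_fixes(io.StringIO(HEADER + "\n".join(rows)))


class TestReadFixes:
    def test_empty_file_with_header_is_ok(self):
        df = _fixes([])
        assert len(df) == 0

    def test_duplicate_timestamps_collapsed_to_first(self):
        df = _fixes(["1,1000,0,0,5", "1,1000,9,9,5", "1,2000,1,1,5"])
        assert len(df) == 2
        assert df.loc[df["time_utc_ms"] == 1000, "x_m"].iloc[0] == 0

    def test_sort_invariance(self):
        rows = ["1,3000,3,3,5", "1,1000,1,1,5", "1,2000,2,2,5"]
        a = _fixes(rows)
        b = _fixes(sorted(rows))
        pd.testing.assert_frame_equal(a, b)

    def test_missing_column_raises_schema_error(self):
        with pytest.raises(SchemaError, match="std_m"):
            read_fixes(io.StringIO("tag_id,time_utc_ms,x_m,y_m\n1,1,0,0\n"))


class TestFilters:
    def test_accuracy_threshold_toy_counts(self):
        # stds 10, 60, 20, 49, 51 -> only 10, 20, 49 survive the 50 m rule
        df = _fixes(
            [f"1,{i * 100_000},0,0,{s}" for i, s in enumerate([10, 60, 20, 49, 51])]
        )
        out, counts = filter_fixes(df)
        assert len(out) == 3
        assert counts["removed_std"] == 2

    def test_overspeed_pair_drops_later_fix(self):
        # 200 m in 10 s = 20 m/s > 15 m/s
        df = _fixes(["1,0,0,0,5", "1,10000,200,0,5"])
        out, counts = filter_fixes(df)
        assert list(out["x_m"]) == [0.0]
        assert counts["removed_speed"] == 1

    def test_clean_track_unchanged_and_idempotent(self, small_track):
        df = small_track[["tag_id", "time_utc_ms", "x_m", "y_m", "std_m"]]
        once, _ = filter_fixes(df)
        pd.testing.assert_frame_equal(once, df.reset_index(drop=True))
        twice, counts = filter_fixes(once)
        pd.testing.assert_frame_equal(twice, once)
        assert counts == {"removed_std": 0, "removed_speed": 0}

    def test_planted_artifact_recall_and_false_removal(self):
        cfg = simulate.SimConfig(n_individuals=3, nights_per_individual=4, seed=21)
        fixes, _ = simulate.simulate_tracks(cfg)
        raw = fixes[["tag_id", "time_utc_ms", "x_m", "y_m", "std_m"]]
        out, _ = filter_fixes(raw)
        kept = pd.MultiIndex.from_frame(out[["tag_id", "time_utc_ms"]])
        all_ix = pd.MultiIndex.from_frame(fixes[["tag_id", "time_utc_ms"]])
        kept_mask = all_ix.isin(kept)
        planted = (fixes["artifact_std"] | fixes["artifact_speed"]).to_numpy()
        recall = 1 - kept_mask[planted].mean()
        false_removal = 1 - kept_mask[~planted].mean()
        assert recall >= 0.99
        assert false_removal <= 0.01


class TestNightSegmentation:
    @staticmethod
    def _ms(d, h, m=0):
        from datetime import datetime, timezone

        local = datetime(2021, 3, d, h, m)
        utc = local.timestamp() - 2 * 3600  # naive arithmetic, fixed offset
        return int(
            (datetime(2021, 3, d, h, m, tzinfo=timezone.utc).timestamp() - 2 * 3600)
            * 1000
        )

    def test_window_boundaries(self):
        rows = [
            f"1,{self._ms(10, 16, 59)},0,0,5",   # before the window
            f"1,{self._ms(10, 17, 0)},0,0,5",    # opening boundary: included
            f"1,{self._ms(11, 5, 59)},0,0,5",    # included, previous evening
            f"1,{self._ms(11, 6, 0)},0,0,5",     # closing boundary: excluded
        ]
        df = _fixes(rows)
        out, n_day = segment_nights(df, utc_offset_h=2)
        assert n_day == 2
        assert set(out["night_date"]) == {date(2021, 3, 10)}
        assert len(out) == 2

    def test_continuous_day_keeps_exactly_the_window(self):
        t0 = self._ms(10, 0, 0)
        t = t0 + np.arange(24 * 3600 // 8) * 8000
        df = pd.DataFrame(
            {"tag_id": 1, "time_utc_ms": t, "x_m": 0.0, "y_m": 0.0, "std_m": 5.0}
        )
        out, _ = segment_nights(df, utc_offset_h=2)
        assert len(out) == 13 * 3600 // 8  # 5850


class TestLabels:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (date(2021, 3, 15), ("P1", 2021)),
            (date(2021, 6, 1), ("P2", 2021)),
            (date(2021, 1, 10), ("P3", 2020)),
            (date(2021, 10, 2), ("P3", 2021)),
        ],
    )
    def test_period_assignment(self, d, expected):
        assert assign_period(d) == expected

    def test_age_class_around_first_birthday(self):
        hatch = date(2020, 4, 1)
        assert assign_age_class(hatch, date(2021, 3, 31)) == "juvenile"
        assert assign_age_class(hatch, date(2021, 4, 2)) == "adult"

    def test_fallback_class_and_unknown_age(self):
        assert assign_age_class(None, date(2021, 1, 1), "adult") == "adult"
        with pytest.raises(ValueError, match="unknown age"):
            assign_age_class(None, date(2021, 1, 1))


def _night_df(n_fixes_by_night):
    """individual-night fix frames with given sizes, all in one period."""
    frames = []
    for (ind, nd), n in n_fixes_by_night.items():
        frames.append(
            pd.DataFrame(
                {
                    "individual": ind,
                    "tag_id": 1,
                    "night_date": nd,
                    "time_utc_ms": np.arange(n) * 8000,
                    "x_m": 0.0,
                    "y_m": 0.0,
                    "std_m": 5.0,
                    "period": "P1",
                    "period_year": 2021,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestInclusionRules:
    def test_min_fixes_is_strict(self):
        df = _night_df({("a", date(2021, 2, 1)): 1000, ("a", date(2021, 2, 2)): 1001})
        out, rep = apply_inclusion_rules(df, min_fixes=1000, min_nights=1)
        assert set(out["night_date"]) == {date(2021, 2, 2)}
        assert rep.nights_below_min_fixes == 1

    def test_cell_below_min_nights_dropped(self):
        nights = {("a", date(2021, 2, d)): 1500 for d in range(1, 25)}  # 24 nights
        nights.update({("b", date(2021, 2, d)): 1500 for d in range(1, 26)})  # 25
        df = _night_df(nights)
        out, rep = apply_inclusion_rules(df, min_fixes=1000, min_nights=25)
        assert set(out["individual"]) == {"b"}
        assert rep.cells_below_min_nights == 1

    def test_empty_exclusion_windows_are_noop(self):
        df = _night_df({("a", date(2021, 2, 1)): 1200})
        out1, _ = apply_inclusion_rules(df, min_nights=1)
        out2, _ = apply_inclusion_rules(df, min_nights=1, exclusion_windows=pd.DataFrame(columns=["individual", "start", "end"]))
        pd.testing.assert_frame_equal(out1, out2)

    def test_exclusion_window_drops_overlapping_nights(self):
        df = _night_df({("a", date(2021, 2, 1)): 1200, ("a", date(2021, 2, 5)): 1200})
        win = pd.DataFrame(
            [{"individual": "a", "start": date(2021, 2, 4), "end": date(2021, 2, 6)}]
        )
        out, rep = apply_inclusion_rules(df, min_nights=1, exclusion_windows=win)
        assert set(out["night_date"]) == {date(2021, 2, 1)}
        assert rep.nights_excluded_window == 1

    def test_report_reconciles_counts(self):
        nights = {("a", date(2021, 2, d)): (900 if d % 2 else 1500) for d in range(1, 11)}
        df = _night_df(nights)
        out, rep = apply_inclusion_rules(df, min_fixes=1000, min_nights=3)
        assert rep.nights_output == rep.nights_input - rep.nights_excluded_window \
            - rep.nights_below_min_fixes - rep.nights_in_dropped_cells
        assert rep.n_output_fixes == len(out)
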