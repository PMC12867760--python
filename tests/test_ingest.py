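"""Raw-log parsing, per-second downsampling and forward fill."""

import random
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd
import pytest

from cagetrack.ingest import (
    RawDetection,
    SessionConfig,
    dedupe_first_wins,
    forward_fill,
    parse_raw_log,
    parse_raw_log_frame,
    preprocess,
    read_processed_csv,
    to_epoch,
    truncate_to_seconds,
    write_processed_csv,
)

S0 = to_epoch(datetime(2023, 1, 10, 8, 0, 0))


def write_log(tmp_path, text, name="raw.txt"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParsing:
    def test_tab_delimited_line(self, tmp_path):
        p = write_log(tmp_path, "2023-01-10 08:00:00.41\t13\tTAG_A\n")
        (d,) = parse_raw_log(p)
        assert d.antenna_id == 13
        assert d.tag_id == "TAG_A"
        assert d.timestamp == datetime(2023, 1, 10, 8, 0, 0, 410000)
        assert d.line_no == 1

    def test_space_delimited_and_t_separator(self, tmp_path):
        p = write_log(
            tmp_path,
            "2023-01-10 08:00:00.41 13 TAG_A\n2023-01-10T08:00:01 14 TAG_B\n",
        )
        dets = parse_raw_log(p)
        assert [(d.antenna_id, d.tag_id) for d in dets] == [(13, "TAG_A"), (14, "TAG_B")]

    def test_empty_file(self, tmp_path):
        p = write_log(tmp_path, "")
        assert parse_raw_log(p) == []
        assert parse_raw_log_frame(p).empty

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        p = write_log(tmp_path, "# header\n\n2023-01-10 08:00:00\t1\tA\n")
        assert len(parse_raw_log(p)) == 1

    def test_out_of_range_antenna_rejected(self, tmp_path, caplog):
        p = write_log(tmp_path, "2023-01-10 08:00:00\t97\tA\n2023-01-10 08:00:01\t96\tA\n")
        with caplog.at_level("WARNING"):
            dets = parse_raw_log(p)
        assert len(dets) == 1 and dets[0].antenna_id == 96
        assert "rejected" in caplog.text

    def test_strict_mode_aborts_with_line_number(self, tmp_path):
        p = write_log(tmp_path, "2023-01-10 08:00:00\t1\tA\nnot a line\n")
        with pytest.raises(ValueError, match=":2"):
            parse_raw_log(p, strict=True)
        with pytest.raises(ValueError, match=":2"):
            parse_raw_log_frame(p, strict=True)

    def test_frame_parser_matches_record_parser(self, tmp_path):
        text = (
            "# log\n"
            "2023-01-10 08:00:00.41\t13\tA\n"
            "2023-01-10 08:00:00.52 27 B\n"
            "garbage line here extra\n"
            "2023-01-10 08:00:01\t96\tA\n"
        )
        p = write_log(tmp_path, text)
        dets = parse_raw_log(p)
        frame = parse_raw_log_frame(p)
        assert len(frame) == len(dets) == 3
        for d, row in zip(dets, frame.itertuples(index=False)):
            assert d.antenna_id == row.antenna_id
            assert d.tag_id == row.tag_id
            assert pd.Timestamp(d.timestamp) == row.timestamp
            assert d.line_no == row.line_no


class TestTruncateAndDedupe:
    def det(self, us, antenna=1, tag="A", line_no=1, sec=0):
        ts = datetime(2023, 1, 10, 8, 0, sec, us)
        return RawDetection(ts, antenna, tag, line_no)

    def test_truncation_is_floor_not_round(self):
        out = truncate_to_seconds([self.det(410000), self.det(990000, line_no=2)])
        assert all(d.timestamp == datetime(2023, 1, 10, 8, 0, 0) for d in out)

    def test_truncation_idempotent_on_integral(self):
        d = self.det(0)
        assert truncate_to_seconds([d]) == [d]

    def test_first_detection_wins_by_line_order(self):
        dets = truncate_to_seconds(
            [self.det(100000, antenna=13, line_no=1), self.det(200000, antenna=14, line_no=2)]
        )
        out = dedupe_first_wins(dets)
        assert len(out) == 1 and out[0].antenna_id == 13

    def test_different_tags_same_second_all_kept(self):
        dets = truncate_to_seconds(
            [self.det(0, tag="A", line_no=1), self.det(0, tag="B", antenna=2, line_no=2)]
        )
        assert len(dedupe_first_wins(dets)) == 2

    def test_dedupe_identity_and_idempotence(self):
        dets = truncate_to_seconds(
            [self.det(0, sec=0, line_no=1), self.det(0, sec=1, line_no=2)]
        )
        once = dedupe_first_wins(dets)
        assert once == dets
        assert dedupe_first_wins(once) == once


class TestForwardFill:
    def cfg(self, **kw):
        kw.setdefault("session_start", datetime(2023, 1, 10, 8, 0, 0))
        kw.setdefault("session_hours", 72.0)
        return SessionConfig(**kw)

    def det_at(self, sec_offset, antenna, tag="A", line_no=1):
        ts = datetime(2023, 1, 10, 8, 0, 0) + timedelta(seconds=sec_offset)
        return RawDetection(ts, antenna, tag, line_no)

    def test_gap_filled_with_preceding_position(self):
        traj = forward_fill(
            [self.det_at(100, 1, line_no=1), self.det_at(103, 2, line_no=2)], self.cfg()
        )
        assert list(traj["second"] - S0) == [100, 101, 102, 103]
        assert list(traj["x"]) == [1, 1, 1, 2]
        assert list(traj["observed"]) == [True, False, False, True]

    def test_no_gaps_all_observed(self):
        dets = [self.det_at(i, 1, line_no=i + 1) for i in range(5)]
        traj = forward_fill(dets, self.cfg())
        assert traj["observed"].all()

    def test_single_detection_fills_to_session_end(self):
        cfg = self.cfg(session_hours=105 / 3600, fill_to_session_end=True)
        traj = forward_fill([self.det_at(100, 7)], cfg)
        # oracle: last-observation-carried-forward over seconds 100..104
        assert list(traj["second"] - S0) == [100, 101, 102, 103, 104]
        assert (traj["antenna_id"] == 7).all()
        assert list(traj["observed"]) == [True] + [False] * 4

    def test_no_backfill_before_first_detection(self):
        traj = forward_fill([self.det_at(50, 1)], self.cfg())
        assert traj["second"].min() - S0 == 50

    def test_max_fill_gap_caps_carry_forward(self):
        cfg = self.cfg(max_fill_gap=2)
        traj = forward_fill(
            [self.det_at(0, 1, line_no=1), self.det_at(10, 2, line_no=2)], cfg
        )
        offs = sorted(traj["second"] - S0)
        assert offs == [0, 1, 2, 10]

    def test_drop_tags_excluded(self):
        dets = [self.det_at(0, 1, tag="A", line_no=1), self.det_at(0, 2, tag="B", line_no=2)]
        traj = forward_fill(dets, self.cfg(drop_tags=("B",)))
        assert set(traj["tag_id"]) == {"A"}

    def test_expected_tag_never_seen_warns_and_omits(self, caplog):
        with caplog.at_level("WARNING"):
            traj = forward_fill(
                [self.det_at(0, 1, tag="A")], self.cfg(expected_tags=["A", "GHOST"])
            )
        assert set(traj["tag_id"]) == {"A"}
        assert "GHOST" in caplog.text

    def test_row_count_identity_per_tag(self):
        dets = [self.det_at(o, 1, line_no=i + 1) for i, o in enumerate([5, 9, 30])]
        traj = forward_fill(dets, self.cfg())
        assert len(traj) == 30 - 5 + 1

    def test_forward_fill_idempotent_on_own_output(self):
        dets = [self.det_at(100, 1, line_no=1), self.det_at(103, 2, line_no=2)]
        traj = forward_fill(dets, self.cfg())
        redone = forward_fill(
            traj.assign(
                timestamp=pd.to_datetime(traj["second"], unit="s"),
                line_no=np.arange(len(traj)),
            ),
            self.cfg(),
        )
        pd.testing.assert_frame_equal(
            traj[["tag_id", "second", "antenna_id", "x", "y"]],
            redone[["tag_id", "second", "antenna_id", "x", "y"]],
        )


class TestPipeline:
    def cfg(self, **kw):
        kw.setdefault("session_start", datetime(2023, 1, 10, 8, 0, 0))
        return SessionConfig(**kw)

    def test_order_insensitive_to_cross_tag_interleaving(self, tmp_path):
        rng = random.Random(5)
        lines_a = [f"2023-01-10 08:00:{s:02d}.10\t{s + 1}\tA" for s in range(0, 40, 3)]
        lines_b = [f"2023-01-10 08:00:{s:02d}.20\t{s + 2}\tB" for s in range(0, 40, 4)]
        merged = lines_a + lines_b

        def run(lines):
            p = tmp_path / "log.txt"
            p.write_text("\n".join(lines) + "\n")
            return preprocess(p, self.cfg())

        base = run(sorted(merged))
        # shuffle across tags, preserving per-tag order
        shuffled = []
        ia = ib = 0
        order = [0] * len(lines_a) + [1] * len(lines_b)
        rng.shuffle(order)
        for which in order:
            if which == 0 and ia < len(lines_a):
                shuffled.append(lines_a[ia]); ia += 1
            elif ib < len(lines_b):
                shuffled.append(lines_b[ib]); ib += 1
            else:
                shuffled.append(lines_a[ia]); ia += 1
        other = run(shuffled)
        key = ["tag_id", "second"]
        pd.testing.assert_frame_equal(
            base.sort_values(key).reset_index(drop=True),
            other.sort_values(key).reset_index(drop=True),
        )

    def test_non_monotonic_timestamps_warn(self, tmp_path, caplog):
        p = tmp_path / "log.txt"
        p.write_text(
            "2023-01-10 08:00:05\t1\tA\n2023-01-10 08:00:01\t2\tA\n"
        )
        with caplog.at_level("WARNING"):
            traj = preprocess(p, self.cfg())
        assert "non-monotonic" in caplog.text
        assert traj["second"].min() - S0 == 1

    def test_processed_csv_round_trip_exact(self, tmp_path, small_cohort):
        traj = small_cohort.ground_truth
        out = tmp_path / "traj.csv"
        write_processed_csv(traj, out)
        back = read_processed_csv(out)
        pd.testing.assert_frame_equal(traj.reset_index(drop=True), back)

    def test_processed_csv_iso_timestamp_round_trip(self, tmp_path):
        traj = forward_fill(
            [RawDetection(datetime(2023, 1, 10, 8, 0, 0), 5, "A", 1)], self.cfg()
        )
        out = tmp_path / "traj.csv"
        write_processed_csv(traj, out, iso_timestamps=True)
        back = read_processed_csv(out)
        pd.testing.assert_frame_equal(traj.reset_index(drop=True), back)


class TestSessionConfig:
    def test_lights_must_differ(self):
        with pytest.raises(ValueError):
            SessionConfig(
                session_start=datetime(2023, 1, 10, 8),
                lights_on=time(8),
                lights_off=time(8),
            )

    def test_light_mask_12_12_cycle(self):
        cfg = SessionConfig(session_start=datetime(2023, 1, 10, 8))
        secs = np.array(
            [to_epoch(datetime(2023, 1, 10, h)) for h in (8, 12, 19, 20, 23, 7)]
        )
        assert list(cfg.light_mask(secs)) == [True, True, True, False, False, False]
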