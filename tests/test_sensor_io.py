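"""Stream ingestion, fusion and diary labeling."""

import numpy as np
import pandas as pd
import pytest

from actitime import Activity
from conftest import make_fused_frame

from actitime.sensor_io import (
    AnnotationIntervals,
    SensorFormatError,
    SensorStream,
    StreamValidationError,
    label_samples,
    parse_annotations,
    read_sensor_stream,
    synchronize,
)

T0 = pd.Timestamp("2024-03-04 08:00:00")


def write_sensor_csv(path, epochs, steps=None, z=False):
    """epochs: list of second offsets; steps: {minute offset: count}."""
    steps = steps or {}
    lines = ["timestamp,x,y" + (",z" if z else "") + ",steps"]
    for s in epochs:
        t = T0 + pd.Timedelta(seconds=s)
        zcol = ",0.3" if z else ""
        stepval = str(steps[s]) if s in steps else ""
        lines.append(f"{t.isoformat()},0.1,0.2{zcol},{stepval}")
    path.write_text("\n".join(lines) + "\n")
    return path


def make_stream(site, sec_range, step_value=0, z=False):
    """Stream covering [start, stop) seconds with steps on every minute."""
    start, stop = sec_range
    epochs = pd.date_range(
        T0 + pd.Timedelta(seconds=start),
        T0 + pd.Timedelta(seconds=stop),
        freq="5s",
        inclusive="left",
    )
    cols = {"x": np.full(len(epochs), 1.0), "y": np.full(len(epochs), 2.0)}
    if z:
        cols["z"] = np.full(len(epochs), 3.0)
    accel = pd.DataFrame(cols, index=pd.DatetimeIndex(epochs, name="epoch_start"))
    minutes = pd.DatetimeIndex(sorted(set(epochs.floor("60s"))), name="minute_start")
    steps = pd.Series(step_value, index=minutes, dtype=int, name="steps")
    return SensorStream(site=site, axes="triaxial" if z else "biaxial", accel=accel, steps=steps)


class TestReadSensorStream:
    def test_minimal_file(self, tmp_path):
        p = write_sensor_csv(tmp_path / "arm.csv", [0, 5, 10], steps={0: 12})
        stream = read_sensor_stream(p, "arm")
        assert len(stream.accel) == 3
        assert len(stream.steps) == 1
        assert stream.steps.iloc[0] == 12

    def test_axes_inferred_from_z_column(self, tmp_path):
        bi = read_sensor_stream(write_sensor_csv(tmp_path / "b.csv", [0, 5]), "arm")
        tri = read_sensor_stream(write_sensor_csv(tmp_path / "t.csv", [0, 5], z=True), "arm")
        assert bi.axes == "biaxial"
        assert tri.axes == "triaxial"
        assert "z" not in bi.accel.columns
        assert "z" in tri.accel.columns

    def test_gap_accepted_and_fusion_skips_missing_epoch(self, tmp_path):
        arm = read_sensor_stream(
            write_sensor_csv(tmp_path / "a.csv", [0, 10], steps={0: 0}), "arm"
        )
        thigh = make_stream("thigh", (0, 60))
        fused = synchronize(arm, thigh)
        assert list(fused.index) == [T0, T0 + pd.Timedelta(seconds=10)]

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("timestamp,x,y,steps\n2024-03-04T08:00:00,0.1,oops,\n")
        with pytest.raises(SensorFormatError, match="line 2"):
            read_sensor_stream(p, "arm")

    def test_non_monotone_rejected(self, tmp_path):
        p = write_sensor_csv(tmp_path / "m.csv", [5, 0])
        with pytest.raises(StreamValidationError, match="non-monotone|duplicate"):
            read_sensor_stream(p, "arm")

    def test_duplicate_epoch_rejected(self, tmp_path):
        p = write_sensor_csv(tmp_path / "d.csv", [0, 0])
        with pytest.raises(StreamValidationError):
            read_sensor_stream(p, "arm")

    def test_off_grid_epoch_rejected(self, tmp_path):
        p = write_sensor_csv(tmp_path / "g.csv", [0, 3])
        with pytest.raises(StreamValidationError, match="5-s grid"):
            read_sensor_stream(p, "arm")

    def test_separate_steps_file(self, tmp_path):
        p = write_sensor_csv(tmp_path / "a.csv", [0, 5])
        sp = tmp_path / "steps.csv"
        sp.write_text(f"minute_start,steps\n{T0.isoformat()},42\n")
        stream = read_sensor_stream(p, "arm", steps_path=sp)
        assert stream.steps.iloc[0] == 42


class TestSynchronize:
    def test_intersection_of_time_ranges(self):
        arm = make_stream("arm", (0, 100))
        thigh = make_stream("thigh", (20, 120))
        fused = synchronize(arm, thigh)
        assert len(fused) == 16
        assert fused.index[0] == T0 + pd.Timedelta(seconds=20)
        assert fused.index[-1] == T0 + pd.Timedelta(seconds=95)

    def test_identical_grids(self):
        arm = make_stream("arm", (0, 300))
        thigh = make_stream("thigh", (0, 300))
        assert len(synchronize(arm, thigh)) == 60

    def test_step_broadcast_to_all_epochs_of_minute(self):
        arm = make_stream("arm", (0, 120))
        arm.steps.iloc[:] = [0, 36]
        thigh = make_stream("thigh", (0, 120))
        fused = synchronize(arm, thigh)
        minute2 = fused[fused.index >= T0 + pd.Timedelta(seconds=60)]
        assert len(minute2) == 12
        assert (minute2["arm_steps"] == 36).all()
        assert (fused.loc[fused.index < T0 + pd.Timedelta(seconds=60), "arm_steps"] == 0).all()

    def test_empty_intersection_is_error(self):
        arm = make_stream("arm", (0, 60))
        thigh = make_stream("thigh", (3600, 3660))
        with pytest.raises(ValueError, match="intersection"):
            synchronize(arm, thigh)

    def test_mixed_axes_is_error(self):
        arm = make_stream("arm", (0, 60), z=True)
        thigh = make_stream("thigh", (0, 60))
        with pytest.raises(ValueError, match="mixed axes"):
            synchronize(arm, thigh)


class TestParseAnnotations:
    def test_single_entry(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("activity,start,end\nsitting,2024-03-04T09:00:00,2024-03-04T10:30:00\n")
        iv = parse_annotations(p)
        assert len(iv) == 1
        assert iv.total_seconds()[Activity.SITTING] == 5400

    def test_abutting_entries_accepted(self):
        iv = AnnotationIntervals.from_records(
            [
                ("walking", T0, T0 + pd.Timedelta(seconds=60)),
                ("sitting", T0 + pd.Timedelta(seconds=60), T0 + pd.Timedelta(seconds=120)),
            ]
        )
        assert len(iv) == 2

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            AnnotationIntervals.from_records(
                [
                    ("walking", T0, T0 + pd.Timedelta(minutes=10)),
                    ("sitting", T0 + pd.Timedelta(minutes=5), T0 + pd.Timedelta(minutes=20)),
                ]
            )

    def test_unknown_activity_lists_legal_names(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("activity,start,end\njogging,2024-03-04T09:00:00,2024-03-04T09:10:00\n")
        with pytest.raises(ValueError, match="dynamic_standing"):
            parse_annotations(p)

    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError, match="<= start"):
            AnnotationIntervals.from_records([("sitting", T0, T0)])


class TestLabelSamples:
    def interval(self, label, start_s, end_s):
        return (
            label,
            T0 + pd.Timedelta(seconds=start_s),
            T0 + pd.Timedelta(seconds=end_s),
        )

    def test_full_coverage(self):
        samples = make_fused_frame(24)
        iv = AnnotationIntervals.from_records([self.interval("sitting", 0, 120)])
        labeled = label_samples(samples, iv)
        assert len(labeled) == 24
        assert (labeled["label"] == Activity.SITTING).all()

    def test_window_containment_at_boundary(self):
        samples = make_fused_frame(24)  # epochs 0..115
        iv = AnnotationIntervals.from_records(
            [self.interval("walking", 0, 60), self.interval("sitting", 60, 120)]
        )
        labeled = label_samples(samples, iv)
        at55 = labeled.loc[T0 + pd.Timedelta(seconds=55), "label"]
        at60 = labeled.loc[T0 + pd.Timedelta(seconds=60), "label"]
        assert at55 == Activity.WALKING  # window [55, 60) inside first interval
        assert at60 == Activity.SITTING

    def test_guard_band_excludes_boundary_epochs(self):
        samples = make_fused_frame(24)
        iv = AnnotationIntervals.from_records(
            [self.interval("walking", 0, 60), self.interval("sitting", 60, 120)]
        )
        labeled = label_samples(samples, iv, drop_transitions=True, guard_s=5)
        excluded = {T0 + pd.Timedelta(seconds=s) for s in (55, 60)}
        assert excluded.isdisjoint(set(labeled.index))
        # epochs clear of every boundary's guard band survive
        assert T0 + pd.Timedelta(seconds=50) in labeled.index
        assert T0 + pd.Timedelta(seconds=65) in labeled.index

    def test_partial_window_unlabeled_and_scoring_mode_retains(self):
        samples = make_fused_frame(24)
        iv = AnnotationIntervals.from_records([self.interval("sitting", 0, 63)])
        train = label_samples(samples, iv)
        score = label_samples(samples, iv, keep_unlabeled=True)
        assert len(train) == 12  # windows fully inside [0, 63): epochs 0..55
        assert len(score) == 24
        assert score["label"].isna().sum() == 12

    def test_label_conservation(self):
        """Labeled count x 5 s equals annotated time covered by whole windows."""
        samples = make_fused_frame(120)  # 10 min
        iv = AnnotationIntervals.from_records(
            [
                self.interval("walking", 0, 120),
                self.interval("running", 120, 240),
                self.interval("sitting", 240, 600),
            ]
        )
        labeled = label_samples(samples, iv)
        for act, sec in iv.total_seconds().items():
            assert (labeled["label"] == act).sum() * 5 == sec

    def test_interval_order_irrelevant(self):
        samples = make_fused_frame(48)
        recs = [
            self.interval("sitting", 120, 240),
            self.interval("walking", 0, 120),
        ]
        a = label_samples(samples, AnnotationIntervals.from_records(recs))
        b = label_samples(samples, AnnotationIntervals.from_records(recs[::-1]))
        assert (a["label"] == b["label"]).all()
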