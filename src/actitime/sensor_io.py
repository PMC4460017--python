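"""Reading, validating, synchronizing and labeling raw sensor streams.

Each body site (upper arm, thigh) produces one stream: acceleration means
on an exact 5-second grid plus step counts accumulated per minute.  The
two sites are fused into one sample per 5-s epoch of their common time
range, with the minute's step count broadcast to all twelve epochs of that
minute.  Ground truth comes from an annotation diary (researcher log in a
confined protocol, participant diary in free living) as labeled
``[start, end)`` intervals with 1-second precision.

File formats
------------
Sensor CSV (one per site): header ``timestamp,x,y[,z],steps``.
``timestamp`` is ISO-8601 and must fall on the 5-s grid; ``x,y,z`` are
floating-point epoch means; ``steps`` is an integer populated only on
minute-start rows (blank elsewhere).  A separate step file with header
``minute_start,steps`` is also accepted.

Diary CSV: header ``activity,start,end`` with ISO-8601 times and activity
names from the five-category vocabulary.

Fused samples are represented as a :class:`pandas.DataFrame` indexed by
``epoch_start`` with columns ``arm_x, arm_y[, arm_z], arm_steps,
thigh_x, thigh_y[, thigh_z], thigh_steps`` and, once labeled, ``label``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from actitime.activities import Activity

logger = logging.getLogger(__name__)

EPOCH_S = 5
MINUTE_S = 60

SITES = ("arm", "thigh")


class SensorFormatError(ValueError):
    """A sensor or diary file violates the documented schema."""


class StreamValidationError(ValueError):
    """A parsed stream violates a grid/monotonicity invariant."""


def _parse_timestamps(raw: pd.Series, path: Path, column: str) -> pd.Series:
    ts = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
        raise SensorFormatError(
            f"{path}: line {line}: cannot parse {column} value {raw[bad.idxmax()]!r}"
        )
    return ts


def _parse_floats(raw: pd.Series, path: Path, column: str) -> pd.Series:
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna()
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise SensorFormatError(
            f"{path}: line {line}: non-numeric {column} value {raw[bad.idxmax()]!r}"
        )
    if vals.isna().any():
        line = int(vals.isna().idxmax()) + 2
        raise SensorFormatError(f"{path}: line {line}: missing {column} value")
    if not np.isfinite(vals.to_numpy()).all():
        raise SensorFormatError(f"{path}: column {column} contains non-finite values")
    return vals.astype(float)


def _seconds(ts: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Timestamps as integer epoch seconds (raises on sub-second parts)."""
    ns = pd.DatetimeIndex(ts).asi8
    if (ns % 1_000_000_000).any():
        raise StreamValidationError("timestamps must have whole-second precision")
    return ns // 1_000_000_000


@dataclass
class SensorStream:
    """One body site's acceleration epochs and per-minute step counts.

    ``accel`` is indexed by ``epoch_start`` (5-s grid) with columns
    ``x, y`` and, for triaxial devices, ``z``.  ``steps`` is indexed by
    ``minute_start`` (60-s grid) with non-negative integer values.
    """

    site: str
    axes: str  # 'biaxial' | 'triaxial'
    accel: pd.DataFrame
    steps: pd.Series

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.axes not in ("biaxial", "triaxial"):
            raise ValueError(f"axes must be biaxial or triaxial, got {self.axes!r}")
        expected = ["x", "y"] + (["z"] if self.axes == "triaxial" else [])
        if list(self.accel.columns) != expected:
            raise StreamValidationError(
                f"{self.site}: accel columns {list(self.accel.columns)} != {expected}"
            )
        self._validate_grids()

    def _validate_grids(self) -> None:
        idx = self.accel.index
        if len(idx) == 0:
            raise StreamValidationError(f"{self.site}: empty acceleration stream")
        sec = _seconds(idx)
        if (np.diff(sec) <= 0).any():
            pos = int(np.argmax(np.diff(sec) <= 0)) + 1
            raise StreamValidationError(
                f"{self.site}: non-monotone or duplicate epoch at {idx[pos]}"
            )
        if (sec % EPOCH_S).any():
            off = idx[sec % EPOCH_S != 0][0]
            raise StreamValidationError(f"{self.site}: epoch {off} off the 5-s grid")
        gaps = np.flatnonzero(np.diff(sec) != EPOCH_S)
        for g in gaps[:5]:
            logger.warning(
                "%s: gap of %d s after epoch %s", self.site, sec[g + 1] - sec[g], idx[g]
            )
        if len(self.steps):
            msec = _seconds(self.steps.index)
            if (msec % MINUTE_S).any():
                raise StreamValidationError(f"{self.site}: step minute off 60-s grid")
            if self.steps.index.has_duplicates or not self.steps.index.is_monotonic_increasing:
                raise StreamValidationError(f"{self.site}: step minutes not strictly increasing")
            if (self.steps < 0).any():
                raise StreamValidationError(f"{self.site}: negative step count")

    @property
    def start(self) -> pd.Timestamp:
        return self.accel.index[0]

    @property
    def end(self) -> pd.Timestamp:
        """End of the last 5-s window (exclusive)."""
        return self.accel.index[-1] + pd.Timedelta(seconds=EPOCH_S)


def read_sensor_stream(
    path: Union[str, Path],
    site: str,
    steps_path: Union[str, Path, None] = None,
) -> SensorStream:
    """Read one site's sensor CSV into a validated :class:`SensorStream`.

    The device type is inferred from the presence of a ``z`` column
    (``biaxial`` without, ``triaxial`` with).  Step counts are taken from
    the ``steps`` column (populated on minute-start rows) or, if
    ``steps_path`` is given, from a separate ``minute_start,steps`` file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    required = {"timestamp", "x", "y"}
    if not required.issubset(raw.columns):
        raise SensorFormatError(
            f"{path}: header must contain timestamp,x,y[,z][,steps]; got {list(raw.columns)}"
        )
    ts = _parse_timestamps(raw["timestamp"], path, "timestamp")
    axes = "triaxial" if "z" in raw.columns else "biaxial"
    cols = {"x": _parse_floats(raw["x"], path, "x"), "y": _parse_floats(raw["y"], path, "y")}
    if axes == "triaxial":
        cols["z"] = _parse_floats(raw["z"], path, "z")
    accel = pd.DataFrame(cols)
    accel.index = pd.DatetimeIndex(ts, name="epoch_start")

    if steps_path is not None:
        sraw = pd.read_csv(Path(steps_path), dtype=str, skipinitialspace=True)
        if not {"minute_start", "steps"}.issubset(sraw.columns):
            raise SensorFormatError(f"{steps_path}: header must be minute_start,steps")
        mts = _parse_timestamps(sraw["minute_start"], Path(steps_path), "minute_start")
        steps = pd.Series(
            pd.to_numeric(sraw["steps"]).astype(int).to_numpy(),
            index=pd.DatetimeIndex(mts, name="minute_start"),
            name="steps",
        )
    elif "steps" in raw.columns:
        mask = raw["steps"].notna() & (raw["steps"].str.strip() != "")
        vals = pd.to_numeric(raw.loc[mask, "steps"], errors="coerce")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise SensorFormatError(f"{path}: line {line}: non-integer steps value")
        steps = pd.Series(
            vals.astype(int).to_numpy(),
            index=pd.DatetimeIndex(ts[mask], name="minute_start"),
            name="steps",
        )
    else:
        steps = pd.Series(
            [], index=pd.DatetimeIndex([], name="minute_start"), dtype=int, name="steps"
        )
    return SensorStream(site=site, axes=axes, accel=accel, steps=steps)


def _broadcast_steps(stream: SensorStream, epochs: pd.DatetimeIndex) -> pd.Series:
    """Step count of the enclosing minute for each epoch (NaN when absent)."""
    minutes = epochs.floor("60s")
    looked = stream.steps.reindex(minutes)
    looked.index = epochs
    return looked


def synchronize(arm: SensorStream, thigh: SensorStream) -> pd.DataFrame:
    """Fuse two per-site streams into one sample per shared 5-s epoch.

    Produces a row for each epoch present in *both* acceleration streams
    whose enclosing minute has a step reading at both sites; the minute's
    steps/min value is broadcast unchanged to its twelve 5-s epochs.

    Raises if the time ranges do not intersect, or if one stream is
    biaxial and the other triaxial (drop the z axis first with
    :func:`actitime.features.drop_axis`).
    """
    if arm.site == thigh.site:
        raise ValueError("need one arm and one thigh stream")
    if arm.axes != thigh.axes:
        raise ValueError(
            "mixed axes (one biaxial, one triaxial); drop the z axis from the "
            "triaxial stream before fusing"
        )
    common = arm.accel.index.intersection(thigh.accel.index)
    if len(common) == 0:
        raise ValueError("streams share no 5-s epochs (empty time intersection)")
    parts = {}
    for stream in (arm, thigh):
        acc = stream.accel.loc[common]
        part = acc.add_prefix(f"{stream.site}_")
        part[f"{stream.site}_steps"] = _broadcast_steps(stream, common)
        parts[stream.site] = part
    fused = pd.concat([parts["arm"], parts["thigh"]], axis=1)
    missing = fused.filter(like="_steps").isna().any(axis=1)
    if missing.any():
        logger.warning(
            "dropping %d fused epochs with no step reading for their minute",
            int(missing.sum()),
        )
        fused = fused.loc[~missing]
    if fused.empty:
        raise ValueError("no fused epochs with step data at both sites")
    fused[["arm_steps", "thigh_steps"]] = fused[["arm_steps", "thigh_steps"]].astype(float)
    fused.index.name = "epoch_start"
    return fused


@dataclass
class AnnotationIntervals:
    """Ground-truth labeled ``[start, end)`` time intervals.

    Entries are kept sorted by start, must not overlap, and carry
    whole-second timestamps.
    """

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["label", "start", "end"])
    )

    def __post_init__(self) -> None:
        df = self.entries.reset_index(drop=True)
        if len(df) == 0:
            self.entries = df
            return
        df["label"] = [Activity(l) for l in df["label"]]
        df["start"] = pd.DatetimeIndex(df["start"])
        df["end"] = pd.DatetimeIndex(df["end"])
        _seconds(df["start"])
        _seconds(df["end"])
        if (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise ValueError(f"interval end {bad['end']} <= start {bad['start']}")
        df = df.sort_values("start", kind="stable").reset_index(drop=True)
        overlap = df["start"].iloc[1:].to_numpy() < df["end"].iloc[:-1].to_numpy()
        if overlap.any():
            i = int(np.argmax(overlap))
            raise ValueError(
                f"overlapping intervals: {df['label'][i]} [{df['start'][i]}, {df['end'][i]}) "
                f"and {df['label'][i + 1]} [{df['start'][i + 1]}, {df['end'][i + 1]})"
            )
        self.entries = df

    def __len__(self) -> int:
        return len(self.entries)

    def total_seconds(self) -> dict[Activity, float]:
        """Total annotated seconds per activity."""
        if len(self.entries) == 0:
            return {}
        dur = (self.entries["end"] - self.entries["start"]).dt.total_seconds()
        out: dict[Activity, float] = {}
        for label, d in zip(self.entries["label"], dur):
            out[label] = out.get(label, 0.0) + float(d)
        return out

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[Union[Activity, str], object, object]]
    ) -> "AnnotationIntervals":
        rows = [
            {"label": Activity(l) if isinstance(l, Activity) else Activity.from_name(str(l)),
             "start": pd.Timestamp(s), "end": pd.Timestamp(e)}
            for l, s, e in records
        ]
        return cls(pd.DataFrame(rows, columns=["label", "start", "end"]))

    def to_csv(self, path: Union[str, Path]) -> None:
        out = self.entries.copy()
        out["activity"] = [l.value for l in out["label"]]
        out[["activity", "start", "end"]].to_csv(path, index=False)


def parse_annotations(path: Union[str, Path]) -> AnnotationIntervals:
    """Read a diary CSV (``activity,start,end``) into validated intervals."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if not {"activity", "start", "end"}.issubset(raw.columns):
        raise SensorFormatError(f"{path}: header must be activity,start,end")
    labels = [Activity.from_name(a) for a in raw["activity"]]
    start = _parse_timestamps(raw["start"], path, "start")
    end = _parse_timestamps(raw["end"], path, "end")
    return AnnotationIntervals(
        pd.DataFrame({"label": labels, "start": start, "end": end})
    )


def label_samples(
    samples: pd.DataFrame,
    intervals: AnnotationIntervals,
    drop_transitions: bool = False,
    guard_s: float = 0.0,
    keep_unlabeled: bool = False,
) -> pd.DataFrame:
    """Attach diary labels to fused samples by window containment.

    A sample is labeled with the interval that contains its full 5-s
    window ``[epoch_start, epoch_start + 5)``; windows straddling a
    boundary stay unlabeled.  With ``drop_transitions``, samples whose
    window is not fully inside one interval, or overlaps the open guard
    band ``(boundary - guard_s, boundary + guard_s)`` around any interval
    boundary, are removed — an automated surrogate for hand-pruning the
    activity transitions from a training set.  Unlabeled samples are
    dropped unless ``keep_unlabeled`` (scoring mode) is set.
    """
    if guard_s < 0:
        raise ValueError("guard_s must be >= 0")
    ent = intervals.entries
    t0 = samples.index.to_numpy()
    t1 = t0 + np.timedelta64(EPOCH_S, "s")
    label = np.full(len(samples), None, dtype=object)
    if len(ent):
        starts = ent["start"].to_numpy()
        ends = ent["end"].to_numpy()
        # intervals are sorted and disjoint: candidate is the last start <= t0
        pos = np.searchsorted(starts, t0, side="right") - 1
        ok = pos >= 0
        inside = np.zeros(len(samples), dtype=bool)
        inside[ok] = (t1[ok] <= ends[pos[ok]])
        label[inside] = ent["label"].to_numpy()[pos[inside]]
    out = samples.copy()
    out["label"] = label
    keep = np.ones(len(out), dtype=bool)
    if drop_transitions:
        keep &= out["label"].notna().to_numpy()
        if guard_s > 0 and len(ent):
            bounds = np.unique(
                np.concatenate([ent["start"].to_numpy(), ent["end"].to_numpy()])
            )
            g = np.timedelta64(int(round(guard_s * 1_000_000)), "us")
            for b in bounds:
                keep &= ~((t0 < b + g) & (t1 > b - g))
    elif not keep_unlabeled:
        keep &= out["label"].notna().to_numpy()
    return out.loc[keep]


def write_fused(samples: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write fused samples (optionally labeled) to CSV."""
    out = samples.copy()
    if "label" in out.columns:
        out["label"] = [l.value if isinstance(l, Activity) else "" for l in out["label"]]
    out.index.name = "timestamp"
    out.to_csv(path)


def read_fused(path: Union[str, Path]) -> pd.DataFrame:
    """Read fused samples written by :func:`write_fused`."""
    df = pd.read_csv(path, index_col="timestamp", parse_dates=True)
    df.index.name = "epoch_start"
    if "label" in df.columns:
        df["label"] = [
            Activity(l) if isinstance(l, str) and l else None for l in df["label"]
        ]
    return df
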