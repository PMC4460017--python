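"""Synthetic dual-site sensor sessions with ground-truth diaries.

Two protocols are emulated.  The confined-environment (CE) protocol is a
supervised session of 22 two-minute activity bouts — predetermined
variants of the five categories — performed either in a fixed canonical
order or in a seeded random permutation.  The free-living (UE) protocol
is a 24-hour diary of alternating bouts whose per-activity time totals
match configurable target shares (defaults: 37% lying, 45% sitting, 12%
dynamic standing, 5% walking, 1% running — a typical mostly-sedentary
day).

Signals are generated at the devices' native resolutions: acceleration
means on a 5-s grid drawn from per-activity, per-site normal profiles,
and step counts accumulated per minute drawn from per-activity integer
step-rate ranges.  Both sites see the same underlying gait, so their
per-minute step counts agree up to a small independent jitter.  The
step-rate ranges encode the operational definitions of the categories:
dynamic standing stays strictly below 30 steps/min, walking above it,
running well above walking.

The default acceleration profiles are invented constants (the device
units are arbitrary) chosen so the five classes are separable in the
arm/thigh x-y plane; the z axis carries no class information by default,
and a ``standing_walk_overlap`` dial slides the dynamic-standing profile
toward walking to create a known-hard regime that confuses exactly that
class pair.  No biomechanical realism (gait harmonics, gravity
orientation drift) is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from actitime.activities import Activity
from actitime.sensor_io import (
    EPOCH_S,
    MINUTE_S,
    AnnotationIntervals,
    SensorStream,
)


@dataclass(frozen=True)
class ActivityProfile:
    """Signal distribution for one activity.

    ``accel_mean``/``accel_sd`` map site -> (x, y, z) normal parameters in
    device units.  ``step_range`` is the inclusive integer range of the
    underlying gait rate (steps/min); each site reports that rate plus an
    independent jitter of at most ``step_site_jitter`` (no jitter when the
    rate is exactly zero, so resting minutes count exactly 0 steps).
    """

    activity: Activity
    accel_mean: dict[str, tuple[float, float, float]]
    accel_sd: dict[str, tuple[float, float, float]]
    step_range: tuple[int, int]
    step_site_jitter: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.step_range
        if lo < 0 or hi < lo:
            raise ValueError(f"bad step range {self.step_range}")
        for site in ("arm", "thigh"):
            if any(s < 0 for s in self.accel_sd[site]):
                raise ValueError("negative acceleration SD")

    def max_steps(self) -> int:
        return self.step_range[1] + (self.step_site_jitter if self.step_range[1] > 0 else 0)

    def min_steps(self) -> int:
        return max(0, self.step_range[0] - (self.step_site_jitter if self.step_range[0] > 0 else 0))


def _mk_profile(activity, arm_xy, thigh_xy, sd, step_range, z_mean=8.0, z_sd=2.0,
                step_site_jitter=2):
    return ActivityProfile(
        activity=activity,
        accel_mean={
            "arm": (arm_xy[0], arm_xy[1], z_mean),
            "thigh": (thigh_xy[0], thigh_xy[1], z_mean),
        },
        accel_sd={"arm": (sd, sd, z_sd), "thigh": (sd, sd, z_sd)},
        step_range=step_range,
        step_site_jitter=step_site_jitter,
    )


def default_profiles(
    standing_walk_overlap: float = 0.0,
) -> dict[Activity, ActivityProfile]:
    """The documented default signal profiles.

    Arm/thigh x-y means (device units) separate the five classes;
    ``standing_walk_overlap`` in [0, 1] linearly interpolates the
    dynamic-standing acceleration means toward walking's (1 = identical),
    degrading exactly the walking/dynamic-standing distinction that rests
    on the step-count threshold.  The z axis has the same distribution
    for every activity, so six- and eight-feature classifiers see the
    same class-relevant information.
    """
    if not 0.0 <= standing_walk_overlap <= 1.0:
        raise ValueError("standing_walk_overlap must be in [0, 1]")
    walk_arm, walk_thigh = (14.0, 10.0), (10.0, 12.0)
    dyn_arm, dyn_thigh = (10.0, 14.0), (4.0, 17.0)
    o = standing_walk_overlap
    dyn_arm = tuple((1 - o) * a + o * w for a, w in zip(dyn_arm, walk_arm))
    dyn_thigh = tuple((1 - o) * a + o * w for a, w in zip(dyn_thigh, walk_thigh))
    # The overlap dial also pulls both step-rate ranges toward the
    # 30 steps/min boundary: at o=1 incidental stepping reaches 29/min and
    # slow walking straddles the threshold (27-36/min), so the threshold
    # rule zeroes a share of walking minutes and jitter pushes standing
    # minutes above it — blurring exactly this class pair, the way short-
    # distance walking below 30 steps/min is ambiguous by definition.
    dyn_steps = (0, 27 + int(round(2 * o)))
    walk_steps = (62 - int(round(35 * o)), 118 - int(round(82 * o)))
    # Per-site jitter shrinks with the overlap so near-threshold minutes
    # are zeroed consistently at both sites rather than split across them.
    jitter = int(round(2 * (1 - o)))
    return {
        Activity.LYING_DOWN: _mk_profile(
            Activity.LYING_DOWN, (2.0, 3.0), (2.0, 3.0), 2.0, (0, 0)
        ),
        Activity.SITTING: _mk_profile(
            Activity.SITTING, (4.0, 16.0), (16.0, 5.0), 2.0, (0, 0)
        ),
        Activity.DYNAMIC_STANDING: _mk_profile(
            Activity.DYNAMIC_STANDING, dyn_arm, dyn_thigh, 2.5, dyn_steps,
            step_site_jitter=jitter,
        ),
        Activity.WALKING: _mk_profile(
            Activity.WALKING, walk_arm, walk_thigh, 3.0, walk_steps,
            step_site_jitter=jitter,
        ),
        Activity.RUNNING: _mk_profile(
            Activity.RUNNING, (24.0, 18.0), (20.0, 22.0), 4.0, (142, 178)
        ),
    }


#: Canonical CE protocol: 22 two-minute bouts of activity variants
#: (4 lying, 5 sitting, 5 dynamic standing, 5 walking, 3 running).
CE_BOUT_SEQUENCE: tuple[Activity, ...] = (
    Activity.LYING_DOWN,
    Activity.SITTING,
    Activity.DYNAMIC_STANDING,
    Activity.WALKING,
    Activity.RUNNING,
    Activity.SITTING,
    Activity.LYING_DOWN,
    Activity.WALKING,
    Activity.DYNAMIC_STANDING,
    Activity.SITTING,
    Activity.RUNNING,
    Activity.WALKING,
    Activity.LYING_DOWN,
    Activity.DYNAMIC_STANDING,
    Activity.SITTING,
    Activity.WALKING,
    Activity.DYNAMIC_STANDING,
    Activity.RUNNING,
    Activity.LYING_DOWN,
    Activity.SITTING,
    Activity.WALKING,
    Activity.DYNAMIC_STANDING,
)

DEFAULT_UE_FRACTIONS: dict[Activity, float] = {
    Activity.LYING_DOWN: 0.37,
    Activity.SITTING: 0.45,
    Activity.DYNAMIC_STANDING: 0.12,
    Activity.WALKING: 0.05,
    Activity.RUNNING: 0.01,
}


@dataclass
class SessionConfig:
    """Everything that determines one simulated recording session."""

    mode: str  # 'ce_ordered' | 'ce_random' | 'ue_diary'
    seed: int = 0
    bout_minutes: int = 2
    ue_bout_minutes: int = 10
    total_hours: float = 24.0
    axes: str = "triaxial"
    start: pd.Timestamp = pd.Timestamp("2024-03-04 08:00:00")
    profiles: Optional[dict[Activity, ActivityProfile]] = None
    ue_time_fractions: dict[Activity, float] = field(
        default_factory=lambda: dict(DEFAULT_UE_FRACTIONS)
    )
    unannotated_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("ce_ordered", "ce_random", "ue_diary"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.bout_minutes <= 0 or self.ue_bout_minutes <= 0:
            raise ValueError("bout lengths must be positive")
        if self.axes not in ("biaxial", "triaxial"):
            raise ValueError("axes must be biaxial or triaxial")
        if abs(sum(self.ue_time_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("ue_time_fractions must sum to 1")
        if not 0.0 <= self.unannotated_fraction < 1.0:
            raise ValueError("unannotated_fraction must be in [0, 1)")

    def resolved_profiles(self) -> dict[Activity, ActivityProfile]:
        return self.profiles if self.profiles is not None else default_profiles()


def _ue_bout_sequence(config: SessionConfig, rng: np.random.Generator) -> list[Activity]:
    """Bout list whose per-class totals match the target shares.

    Bout counts are apportioned by largest remainder over a uniform
    ``ue_bout_minutes`` grid, then shuffled into a seeded order.
    """
    total_bouts = int(round(config.total_hours * 60 / config.ue_bout_minutes))
    acts = list(config.ue_time_fractions)
    quotas = np.array([config.ue_time_fractions[a] * total_bouts for a in acts])
    counts = np.floor(quotas).astype(int)
    short = total_bouts - counts.sum()
    for i in np.argsort(-(quotas - counts))[:short]:
        counts[i] += 1
    bouts = [a for a, c in zip(acts, counts) for _ in range(int(c))]
    order = rng.permutation(len(bouts))
    return [bouts[i] for i in order]


def make_schedule(config: SessionConfig) -> AnnotationIntervals:
    """Build the session's ground-truth activity schedule.

    ``ce_ordered`` uses the canonical 22-bout sequence; ``ce_random`` a
    seeded permutation of the same bouts; ``ue_diary`` an alternating
    bout sequence matching the configured time shares to within one bout.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 0])))
    if config.mode == "ce_ordered":
        bouts = list(CE_BOUT_SEQUENCE)
        bout_s = config.bout_minutes * MINUTE_S
    elif config.mode == "ce_random":
        order = rng.permutation(len(CE_BOUT_SEQUENCE))
        bouts = [CE_BOUT_SEQUENCE[i] for i in order]
        bout_s = config.bout_minutes * MINUTE_S
    else:
        bouts = _ue_bout_sequence(config, rng)
        bout_s = config.ue_bout_minutes * MINUTE_S
    records = []
    t = config.start
    step = pd.Timedelta(seconds=bout_s)
    for activity in bouts:
        records.append((activity, t, t + step))
        t += step
    return AnnotationIntervals.from_records(records)


def _minute_activities(schedule: AnnotationIntervals) -> pd.Series:
    """Activity occupying the majority of each minute of the schedule span."""
    ent = schedule.entries
    start, end = ent["start"].iloc[0], ent["end"].iloc[-1]
    minutes = pd.date_range(start, end, freq="60s", inclusive="left")
    labels = []
    for m in minutes:
        m_end = m + pd.Timedelta(seconds=MINUTE_S)
        overlap = (
            (ent["end"].clip(upper=m_end) - ent["start"].clip(lower=m)).dt.total_seconds()
        ).clip(lower=0)
        labels.append(ent["label"].iloc[int(overlap.idxmax())])
    return pd.Series(labels, index=minutes)


def simulate_session(
    config: SessionConfig,
) -> tuple[SensorStream, SensorStream, AnnotationIntervals]:
    """Generate (arm, thigh, truth) for one session, reproducibly.

    Acceleration epochs are drawn from the active bout's profile; step
    counts per minute come from one gait-rate draw shared by both sites
    plus independent per-site jitter.  With a positive
    ``unannotated_fraction`` a seeded subset of bouts is withheld from
    the returned diary (the signal is still generated), exercising the
    unscored-time path.
    """
    profiles = config.resolved_profiles()
    schedule = make_schedule(config)
    ss = np.random.SeedSequence([config.seed, 1])
    rng_steps, rng_arm, rng_thigh, rng_diary = (
        np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(4)
    )

    minute_act = _minute_activities(schedule)
    axes = ["x", "y"] + (["z"] if config.axes == "triaxial" else [])

    steps: dict[str, list[int]] = {"arm": [], "thigh": []}
    for act in minute_act:
        prof = profiles[act]
        lo, hi = prof.step_range
        base = int(rng_steps.integers(lo, hi + 1))
        for site, rng in (("arm", rng_arm), ("thigh", rng_thigh)):
            if base == 0:
                steps[site].append(0)
            else:
                j = int(rng.integers(-prof.step_site_jitter, prof.step_site_jitter + 1))
                steps[site].append(max(0, base + j))

    ent = schedule.entries
    start, end = ent["start"].iloc[0], ent["end"].iloc[-1]
    epochs = pd.date_range(start, end, freq=f"{EPOCH_S}s", inclusive="left")
    epoch_act = minute_act.reindex(epochs.floor("60s")).to_numpy()

    streams = {}
    for site, rng in (("arm", rng_arm), ("thigh", rng_thigh)):
        cols = {}
        means = np.array(
            [[profiles[a].accel_mean[site][i] for i in range(3)] for a in epoch_act]
        )
        sds = np.array(
            [[profiles[a].accel_sd[site][i] for i in range(3)] for a in epoch_act]
        )
        draws = rng.normal(means, sds)
        for i, ax in enumerate(["x", "y", "z"]):
            if ax in axes:
                cols[ax] = draws[:, i]
        accel = pd.DataFrame(cols, index=pd.DatetimeIndex(epochs, name="epoch_start"))
        step_series = pd.Series(
            steps[site],
            index=pd.DatetimeIndex(minute_act.index, name="minute_start"),
            name="steps",
            dtype=int,
        )
        streams[site] = SensorStream(
            site=site, axes=config.axes, accel=accel, steps=step_series
        )

    truth = schedule
    if config.unannotated_fraction > 0:
        n = len(ent)
        n_drop = int(round(config.unannotated_fraction * n))
        drop = set(rng_diary.choice(n, size=n_drop, replace=False).tolist())
        keep = ent.loc[[i for i in range(n) if i not in drop]]
        truth = AnnotationIntervals(keep.reset_index(drop=True))
    return streams["arm"], streams["thigh"], truth


def write_session_csv(
    arm: SensorStream,
    thigh: SensorStream,
    truth: AnnotationIntervals,
    out_dir: Union[str, Path],
) -> dict[str, Path]:
    """Write arm.csv, thigh.csv and diary.csv in the ingestion schemas."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for stream in (arm, thigh):
        df = stream.accel.copy()
        step_col = stream.steps.reindex(df.index)
        df["steps"] = [
            "" if pd.isna(v) else str(int(v)) for v in step_col
        ]
        df.index.name = "timestamp"
        p = out_dir / f"{stream.site}.csv"
        df.to_csv(p)
        paths[stream.site] = p
    p = out_dir / "diary.csv"
    truth.to_csv(p)
    paths["diary"] = p
    return paths
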