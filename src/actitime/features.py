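"""Feature vectors and the step-count threshold rule.

Each 5-s fused sample yields a six- or eight-dimensional raw feature
vector: the per-epoch mean accelerations of both sites (x, y and — for
triaxial devices — z) plus both sites' steps/min, broadcast from the
enclosing minute.  Before classification, a step-count threshold zeroes
step counts below 30/min so that incidental stepping during dynamic
standing does not masquerade as locomotion; counts at or above the
threshold pass through unchanged.  No derived time- or frequency-domain
features are computed, and no standardization is applied by default — the
classifier's cost/gamma settings refer to raw feature units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

#: Fixed feature orders.  The eight-feature set interleaves z after y so
#: each site's block stays contiguous: accelerations first, steps last.
SIX_FEATURES = ("arm_x", "arm_y", "arm_steps", "thigh_x", "thigh_y", "thigh_steps")
EIGHT_FEATURES = (
    "arm_x", "arm_y", "arm_z", "arm_steps",
    "thigh_x", "thigh_y", "thigh_z", "thigh_steps",
)


@dataclass(frozen=True)
class FeatureSet:
    """The six- (biaxial) or eight-feature (triaxial) vector layout."""

    kind: str  # 'six' | 'eight'

    def __post_init__(self) -> None:
        if self.kind not in ("six", "eight"):
            raise ValueError(f"kind must be 'six' or 'eight', got {self.kind!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return SIX_FEATURES if self.kind == "six" else EIGHT_FEATURES

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class ThresholdRule:
    """Zero step counts below (or at) a per-minute threshold.

    The default is strict: counts strictly below 30 steps/min become 0,
    a count of exactly 30 is kept.  Set ``comparison='le'`` for the
    inclusive reading.
    """

    threshold_steps_per_min: int = 30
    comparison: str = "lt"  # 'lt' | 'le'

    def __post_init__(self) -> None:
        if self.threshold_steps_per_min < 0:
            raise ValueError("threshold must be >= 0")
        if self.comparison not in ("lt", "le"):
            raise ValueError("comparison must be 'lt' or 'le'")

    def zeroed(self, steps: np.ndarray) -> np.ndarray:
        if self.comparison == "lt":
            mask = steps < self.threshold_steps_per_min
        else:
            mask = steps <= self.threshold_steps_per_min
        return np.where(mask, 0.0, steps)


def apply_step_threshold(
    samples: pd.DataFrame, rule: ThresholdRule = ThresholdRule()
) -> pd.DataFrame:
    """Apply the step threshold to both sites' step columns.

    Acceleration columns are untouched; the operation is idempotent.
    """
    out = samples.copy()
    for col in ("arm_steps", "thigh_steps"):
        if col not in out.columns:
            raise ValueError(f"samples lack column {col!r}")
        out[col] = rule.zeroed(out[col].to_numpy(dtype=float))
    return out


def samples_axes(samples: pd.DataFrame) -> str:
    """'triaxial' when both sites carry a z column, else 'biaxial'."""
    has_z = {"arm_z", "thigh_z"}.issubset(samples.columns)
    return "triaxial" if has_z else "biaxial"


def extract_features(
    samples: pd.DataFrame, fset: FeatureSet
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Fused samples -> (n, 6 or 8) feature matrix plus labels if present.

    Raises when eight features are requested from biaxial samples.
    Returns ``(X, y)`` with ``y`` an object array of :class:`Activity`
    (or ``None`` when the samples carry no label column).
    """
    if fset.kind == "eight" and samples_axes(samples) != "triaxial":
        raise ValueError("eight features require triaxial samples (no z columns)")
    missing = [c for c in fset.names if c not in samples.columns]
    if missing:
        raise ValueError(f"samples lack feature columns {missing}")
    X = samples[list(fset.names)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    y = None
    if "label" in samples.columns:
        y = samples["label"].to_numpy(dtype=object)
    return X, y


def drop_axis(samples: pd.DataFrame, axis: str = "z") -> pd.DataFrame:
    """Remove the z axis from both sites, turning triaxial samples biaxial.

    All other columns are returned bit-identical.  Only ``axis='z'`` is
    supported; calling on already-biaxial samples is an error.
    """
    if axis != "z":
        raise ValueError(f"only the z axis can be dropped, got {axis!r}")
    if samples_axes(samples) != "triaxial":
        raise ValueError("samples are already biaxial")
    return samples.drop(columns=["arm_z", "thigh_z"])


def drop_stream_axis(stream, axis: str = "z"):
    """Stream-level counterpart of :func:`drop_axis` for a SensorStream."""
    from actitime.sensor_io import SensorStream

    if axis != "z":
        raise ValueError(f"only the z axis can be dropped, got {axis!r}")
    if stream.axes != "triaxial":
        raise ValueError("stream is already biaxial")
    return SensorStream(
        site=stream.site,
        axes="biaxial",
        accel=stream.accel.drop(columns=["z"]),
        steps=stream.steps,
    )
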