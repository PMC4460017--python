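"""The five activity categories and their canonical ordering.

The canonical order (walking, sitting, running, lying down, dynamic
standing) fixes the row/column layout of every confusion matrix and the
category distances used by the weighted-kappa statistics, so it is defined
once here and imported everywhere else.
"""

from __future__ import annotations

import enum


class Activity(str, enum.Enum):
    """One of the five recognized activity categories.

    ``dynamic standing`` is standing with possible upper-body movement and
    incidental stepping below 30 steps/min; walking below that step rate is
    classed here by definition, walking above it as ``walking``.
    """

    WALKING = "walking"
    SITTING = "sitting"
    RUNNING = "running"
    LYING_DOWN = "lying_down"
    DYNAMIC_STANDING = "dynamic_standing"

    @property
    def index(self) -> int:
        """Position in the canonical confusion-matrix order."""
        return CANONICAL_ORDER.index(self)

    @classmethod
    def from_name(cls, name: str) -> "Activity":
        try:
            return cls(name.strip().lower())
        except ValueError:
            legal = ", ".join(a.value for a in cls)
            raise ValueError(
                f"unknown activity {name!r}; legal names are: {legal}"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Row/column order of all confusion matrices and weighted-kappa distances.
CANONICAL_ORDER: tuple[Activity, ...] = (
    Activity.WALKING,
    Activity.SITTING,
    Activity.RUNNING,
    Activity.LYING_DOWN,
    Activity.DYNAMIC_STANDING,
)
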