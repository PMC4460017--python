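"""Published pooled confusion matrices shipped as reference fixtures.

The dual-site arm/thigh classification study that this package
re-implements reports two pooled 5x5 confusion matrices of real x
classified 5-s epochs: one for the supervised confined-environment (CE)
sessions and one for the 24-h free-living (UE) sessions.  They are
shipped as CSV data files (25 integer cells each, canonical class order)
so the agreement statistics derived from them can be recomputed and
regression-tested without any device data.
"""

from __future__ import annotations

from importlib import resources

from actitime.metrics import ConfusionMatrix

_FILES = {"ce": "ce_confusion.csv", "ue": "ue_confusion.csv"}


def load_reference_matrix(session: str) -> ConfusionMatrix:
    """Load the pooled CE or UE reference confusion matrix."""
    key = session.lower()
    if key not in _FILES:
        raise ValueError(f"session must be 'ce' or 'ue', got {session!r}")
    ref = resources.files("actitime.data").joinpath(_FILES[key])
    with resources.as_file(ref) as path:
        return ConfusionMatrix.from_csv(path)
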