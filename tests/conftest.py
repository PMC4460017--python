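import numpy as np
import pandas as pd
import pytest

from actitime import (
    Activity,
    FeatureSet,
    SessionConfig,
    label_samples,
    synchronize,
    simulate_session,
)
from actitime.classify import fit_on_samples, predict_on_samples
from actitime.reference import load_reference_matrix


@pytest.fixture(scope="session")
def ce_matrix():
    return load_reference_matrix("ce")


@pytest.fixture(scope="session")
def ue_matrix():
    return load_reference_matrix("ue")


def run_held_out_day(
    train_seed: int,
    test_seed: int,
    feature_kind: str = "six",
    profiles=None,
    axes: str = "triaxial",
):
    """Train on an ordered CE day, classify a random-order CE day.

    Returns (real labels, predicted labels) for the held-out day.
    """
    cfg_tr = SessionConfig(mode="ce_ordered", seed=train_seed, axes=axes, profiles=profiles)
    arm, thigh, truth = simulate_session(cfg_tr)
    fused = synchronize(arm, thigh)
    labeled = label_samples(fused, truth, drop_transitions=True, guard_s=5)
    model = fit_on_samples(labeled, FeatureSet(feature_kind))

    cfg_te = SessionConfig(mode="ce_random", seed=test_seed, axes=axes, profiles=profiles)
    arm2, thigh2, truth2 = simulate_session(cfg_te)
    fused2 = synchronize(arm2, thigh2)
    scored = label_samples(fused2, truth2)
    pred = predict_on_samples(model, scored)
    return list(scored["label"]), list(pred)


@pytest.fixture(scope="session")
def held_out_run():
    """One default-profile held-out-day run shared across tests."""
    return run_held_out_day(train_seed=1, test_seed=2)


def make_fused_frame(
    n: int,
    arm_steps: float = 0.0,
    thigh_steps: float = 0.0,
    triaxial: bool = False,
    label: Activity | None = None,
    start: str = "2024-03-04 08:00:00",
    seed: int = 0,
) -> pd.DataFrame:
    """Small synthetic fused-sample frame on the 5-s grid."""
    rng = np.random.default_rng(seed)
    idx = pd.date_range(start, periods=n, freq="5s", name="epoch_start")
    cols = {
        "arm_x": rng.normal(5, 1, n),
        "arm_y": rng.normal(5, 1, n),
        "arm_steps": np.full(n, float(arm_steps)),
        "thigh_x": rng.normal(5, 1, n),
        "thigh_y": rng.normal(5, 1, n),
        "thigh_steps": np.full(n, float(thigh_steps)),
    }
    if triaxial:
        cols["arm_z"] = rng.normal(5, 1, n)
        cols["thigh_z"] = rng.normal(5, 1, n)
    df = pd.DataFrame(cols, index=idx)
    order = ["arm_x", "arm_y"] + (["arm_z"] if triaxial else []) + ["arm_steps"]
    order += ["thigh_x", "thigh_y"] + (["thigh_z"] if triaxial else []) + ["thigh_steps"]
    df = df[order]
    if label is not None:
        df["label"] = label
    return df
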