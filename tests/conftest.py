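import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ergorula.engine import score_frames
from ergorula.io import (
    read_body_stream,
    read_hand_stream,
    read_labels,
    write_scores,
)
from ergorula.preprocess import drop_null_rows, fuse, resample_stream
from ergorula.skeleton import Stream
from ergorula.synth import demo_session, make_session
from ergorula.wrist import calibrate

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


def run_pipeline(paths):
    """Preprocess + calibrate + score a written session; returns
    (kept fused frames, results)."""
    body = read_body_stream(paths["body"])
    hand = read_hand_stream(paths["hand"])
    labels = read_labels(paths["labels"])
    fused = fuse(resample_stream(body), resample_stream(hand), labels)
    kept, _ = drop_null_rows(fused)
    hand20 = Stream(
        np.array([f.timestamp for f in kept]),
        np.stack([f.hands.coords for f in kept]),
        "hand", kept[0].hands.registry, 20.0,
    )
    calibration = calibrate(hand20)
    return kept, score_frames(kept, calibration)


@pytest.fixture(scope="session")
def session_paths(tmp_path_factory):
    """A written five-activity synthetic session (noise-free)."""
    outdir = tmp_path_factory.mktemp("session")
    return make_session(demo_session(), outdir, seed=7)


@pytest.fixture(scope="session")
def scored_session(session_paths, tmp_path_factory):
    """(fused frames, results, wide score table, labels, ground truth)."""
    kept, results = run_pipeline(session_paths)
    out = tmp_path_factory.mktemp("scores") / "scores.csv"
    scores_df = write_scores(out, results)
    labels = read_labels(session_paths["labels"])
    truth = pd.read_csv(session_paths["ground_truth"])
    return kept, results, scores_df, labels, truth
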