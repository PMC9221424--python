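"""Shared fixtures: one small rendered-frame run reused across tests."""

from __future__ import annotations

import warnings

import pytest

from liqbio.detection import candidates_to_table, detect_events
from liqbio.evaluate import match_to_truth
from liqbio.gating import classify_table
from liqbio.synthetic import EventMixtureSpec, generate_frames

# Fixed seed for the shared imaging fixture; any seed should do, this one is
# not special (see the seed-parameterized sweep in test_detection.py).
FRAME_SEED = 12345


@pytest.fixture(scope="session")
def default_mixture() -> EventMixtureSpec:
    return EventMixtureSpec.default()


@pytest.fixture(scope="session")
def frame_run():
    """Rendered frames -> detection -> gating -> truth matching, computed once.

    Returns (frames, truth, classified, matched).
    """
    mixture = EventMixtureSpec.default()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        frames, truth = generate_frames(
            6, 50, mixture, seed=FRAME_SEED, n_debris_frames=2)
        candidates = []
        for frame in frames:
            candidates.extend(detect_events(frame))
        classified = classify_table(
            candidates_to_table(candidates), mixture.cutoffs())
    matched = match_to_truth(truth, classified)
    return frames, truth, classified, matched
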