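"""Shared fixtures: synthetic ground-truth models and crosslink sets."""

import numpy as np
import pytest

from kinfold.synthetic_data import (
    ToyDimerSpec,
    build_toy_dimer,
    simulate_crosslinks,
)

KIF5B_FRAGMENT_BOUNDS = [(1, 540), (401, 690), (691, 820), (821, 963)]
# same 4-fragment pattern widened so that every consecutive pair shares a
# stitchable region (the printed pattern only overlaps between the first two
# fragments; the later cuts abut), for stitching-only assembly tests
OVERLAPPING_BOUNDS = [(1, 540), (401, 690), (631, 820), (761, 963)]


@pytest.fixture(scope="session")
def folded_spec() -> ToyDimerSpec:
    return ToyDimerSpec(conformation="folded", seed=11)


@pytest.fixture(scope="session")
def folded_model(folded_spec):
    return build_toy_dimer(folded_spec)


@pytest.fixture(scope="session")
def extended_model():
    return build_toy_dimer(ToyDimerSpec(conformation="extended", seed=11))


@pytest.fixture(scope="session")
def folded_links(folded_model):
    """All detectable crosslinks of the folded toy, no false positives."""
    return simulate_crosslinks(folded_model, detection_prob=1.0, fp_rate=0.0, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def ideal_helix(n: int, rise: float = 1.5, radius: float = 2.3) -> np.ndarray:
    """CA trace of an ideal straight alpha-helix along +z."""
    i = np.arange(1, n + 1)
    twist = np.deg2rad(100.0)
    return np.stack(
        [radius * np.cos(twist * i), radius * np.sin(twist * i), rise * i], axis=1
    )


def bend_trace(trace: np.ndarray, at: int, angle_deg: float) -> np.ndarray:
    """Rotate the part of a trace after index ``at`` about y by ``angle_deg``."""
    out = np.array(trace, dtype=float)
    th = np.deg2rad(angle_deg)
    rot = np.array(
        [
            [np.cos(th), 0.0, np.sin(th)],
            [0.0, 1.0, 0.0],
            [-np.sin(th), 0.0, np.cos(th)],
        ]
    )
    pivot = out[at - 1]
    out[at:] = (out[at:] - pivot) @ rot.T + pivot
    return out
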