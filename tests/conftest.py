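"""Shared fixtures: synthetic walkers and the evaluation cohort.

Walker renders are session-scoped because they are by far the most expensive
objects in the suite; every test that needs a walking pass shares them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import gaitsil as gs
from gaitsil.synthetic_walker import _BASE_PRESETS


def extract_quiet(seq, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gs.extract_features(seq, **kw)


@pytest.fixture(scope="session")
def nm_walker():
    """Symmetric normal-gait walker (base preset, no jitter)."""
    return gs.generate_walker(_BASE_PRESETS["NM"], label="NM")


@pytest.fixture(scope="session")
def nm_features(nm_walker):
    seq, _ = nm_walker
    return extract_quiet(seq)


@pytest.fixture(scope="session")
def rl_walker():
    return gs.generate_walker(_BASE_PRESETS["RL"], label="RL")


@pytest.fixture(scope="session")
def rl_features(rl_walker):
    seq, _ = rl_walker
    return extract_quiet(seq)


@pytest.fixture(scope="session")
def fb_features():
    seq, _ = gs.generate_walker(_BASE_PRESETS["FB"], label="FB")
    return extract_quiet(seq)


@pytest.fixture(scope="session")
def cohort():
    """Synthetic evaluation cohort: 10 subjects x 2 sequences x 4 classes."""
    return gs.generate_cohort(n_subjects=10, sequences_per_subject=2, seed=1)


@pytest.fixture(scope="session")
def cohort_features(cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gs.extract_feature_table(cohort)


@pytest.fixture(scope="session")
def recovery_walkers():
    """Long passes (16 steps) for parameter-recovery checks.

    Longer walks shrink the structural small-sample bias of the speed
    estimator (total measured distance spans one fewer step than the
    first-to-last-contact duration).
    """
    from dataclasses import replace

    out = []
    for label in ("NM", "RL"):
        params = replace(_BASE_PRESETS[label], n_steps=16)
        out.append((label, *gs.generate_walker(params, label=label)))
    return out


def make_sequence(frames, fps=30.0, **kw):
    return gs.SilhouetteSequence(np.asarray(frames, dtype=np.uint8), fps=fps, **kw)
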