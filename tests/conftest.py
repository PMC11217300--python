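"""Shared fixtures.

The trained-model fixtures are session-scoped: detector, labeller and grader
are each trained once on phantom data and reused by the unit and acceptance
tests that need them.
"""

from __future__ import annotations

import numpy as np
import pytest

from spinegrader import zoo
from spinegrader.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    spec = PhantomSpec(n_vertebrae=6, lowest_level="L5", noise_sd=0.0, seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(n_vertebrae=6, lowest_level="L5", noise_sd=0.02, seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def trained_detector():
    """Tiny VFR net trained on 300 phantom slices for 10 epochs."""
    return zoo.train_detector(seed=101)


@pytest.fixture(scope="session")
def trained_labeller():
    """Appearance + context pair trained on phantoms across the ladder."""
    return zoo.train_labeller(seed=202)


@pytest.fixture(scope="session")
def trained_graders():
    """(CAST, encoder-only baseline, train studies, test studies)."""
    return zoo.train_graders(seed=303)


@pytest.fixture(scope="session")
def trained_bundle(trained_detector, trained_labeller, trained_graders):
    """Full pipeline bundle assembled from the session-trained stages."""
    from spinegrader.pipeline import ModelBundle
    appearance, context = trained_labeller
    grader, _, _, _ = trained_graders
    return ModelBundle(detector=trained_detector, appearance=appearance,
                       context=context, grader=grader)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
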