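"""Shared fixtures: synthetic datasets at the default study conditions."""

from __future__ import annotations

import numpy as np
import pytest

from voltfp.extremes import clean_dataset
from voltfp.io import Voltammogram, default_potentials
from voltfp.synthetic import (DEFAULT_OUTLIER_FLAGS, DatasetSpec,
                              generate_dataset, make_tissue_profiles)

SEED = 0


def brute_force_extremes(y):
    """Neighbour-comparison oracle with the 0 -> rising tie rule.

    A sample p (0 < p < n-1) is an extreme iff rising(p) != rising(p+1)
    with rising(m) := y[m] >= y[m-1]; it is a maximum iff rising(p).
    This is the rule the difference / signum / difference chain encodes.
    """
    y = np.asarray(y, dtype=float)
    pos, kinds = [], []
    for p in range(1, len(y) - 1):
        a = y[p] >= y[p - 1]
        b = y[p + 1] >= y[p]
        if a != b:
            pos.append(p)
            kinds.append("max" if a else "min")
    return np.array(pos, dtype=int), kinds


def as_curve(y, tissue="synthetic", subject=1, replicate=1):
    """Wrap a plain signal in a Voltammogram on the default grid."""
    y = np.asarray(y, dtype=float)
    pots = default_potentials(len(y)) if len(y) != 518 else default_potentials()
    return Voltammogram(pots, y, tissue, subject, replicate)


@pytest.fixture(scope="session")
def profiles():
    return make_tissue_profiles(SEED)


@pytest.fixture(scope="session")
def default_dataset(profiles):
    spec = DatasetSpec(outlier_flags=list(DEFAULT_OUTLIER_FLAGS), seed=SEED)
    return generate_dataset(spec, profiles)


@pytest.fixture(scope="session")
def cleaned_dataset(default_dataset):
    cleaned, flagged = clean_dataset(default_dataset,
                                     manual_flags=list(DEFAULT_OUTLIER_FLAGS))
    assert len(flagged) == 8
    return cleaned


@pytest.fixture(scope="session")
def zero_noise_dataset(profiles):
    spec = DatasetSpec(seed=SEED, noise_sd=0.0, family_noise_frac=0.0,
                       shape_noise_sd=0.0)
    return generate_dataset(spec, profiles)
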