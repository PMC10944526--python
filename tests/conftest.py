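"""Shared fixtures: synthetic phantoms and the seeded test cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import plusquant as pq

COHORT_SEED = 11


@pytest.fixture(scope="session")
def easy_cohort():
    """Seeded 40-image well-separated cohort (Plus vs non-Plus phantoms)."""
    spec = pq.easy_cohort_spec(n_per_class=20, shape=(512, 512), seed=COHORT_SEED)
    masks, discs, labels, truth = pq.make_cohort(spec)
    return {"masks": masks, "discs": discs, "labels": labels, "truth": truth}


@pytest.fixture(scope="session")
def easy_cohort_features(easy_cohort):
    """Feature table extracted from the easy cohort (the slow step, shared)."""
    feats, segments = pq.cohort_features(
        easy_cohort["masks"], easy_cohort["discs"], pq.RunConfig(), seed=COHORT_SEED
    )
    feats = feats.join(easy_cohort["labels"])
    return {"features": feats, "segments": segments}


@pytest.fixture
def straight_path():
    """200-px horizontal centerline."""
    coords = np.column_stack([np.full(200, 50, dtype=int), np.arange(20, 220)])
    return pq.CenterlinePath(coords)


@pytest.fixture
def three_rater_table():
    """Two-session three-rater label table over 12 images, no noise on session 1."""
    ref = pd.Series(
        [pq.PLUS] * 6 + [pq.NONPLUS] * 6, index=[f"im{i:02d}" for i in range(12)]
    )
    return pq.make_rater_table(ref, {"E1": 0.0, "E2": 0.0, "E3": 0.0}, sessions=2, seed=0), ref


def rasterized_segment(family: str, params: dict, width: int = 11, shape=(512, 512)):
    """Rasterize a phantom and trace its (single) centerline path."""
    spec = pq.SyntheticVesselSpec(family, params, width=width)
    mask, truth = pq.rasterize_vessel(spec, shape)
    skel = pq.prune_spurs(pq.skeletonize_mask(mask))
    paths = pq.extract_segments(skel)
    assert len(paths) >= 1
    return mask, paths[0], truth
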