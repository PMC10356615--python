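"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spirart.model import FeatureMasks, ImageMeta
from spirart.morphometrics import artery_features, default_thresholds
from spirart.simulate import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact cohort exercising every pipeline input."""
    spec = SimulationSpec(
        n_subjects=8,
        images_per_subject=1,
        cells_per_image=300,
        n_genes=60,
        n_trending_delta=15,
        n_trending_ga=8,
        fov_size=320,
        planted_pathways={"PLANTED_EARLY": (12, 2.0, 0.1)},
        seed=11,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def morpho_cohort():
    """Medium cohort with extracted morphometric features, for the
    trajectory stage (kept session-scoped: artery rasterization plus
    feature extraction dominates the suite's runtime)."""
    spec = SimulationSpec(
        n_subjects=30,
        images_per_subject=1,
        cells_per_image=60,
        n_genes=10,
        n_trending_delta=4,
        n_trending_ga=2,
        planted_pathways={},
        fov_size=350,
        arteries_per_image=(1, 2),
        seed=7,
    )
    ds = simulate_dataset(spec)
    rows = []
    thr = default_thresholds()
    for (img, aid), crop in ds.artery_crops.items():
        f = artery_features(
            crop["mask"], crop["centre"], crop["rasters"], 10, 100, thr, thr
        )
        f["image_id"], f["artery_id"] = img, aid
        rows.append(f)
    feats = pd.DataFrame(rows).merge(ds.arteries, on=["image_id", "artery_id"])
    return ds, feats


@pytest.fixture()
def flat_masks():
    """A trivially all-decidua image mask (no features) for cell placement."""
    size = 300
    return FeatureMasks(
        image_id="flat",
        artery=np.zeros((size, size), dtype=np.int32),
        gland=np.zeros((size, size), dtype=bool),
        vessel=np.zeros((size, size), dtype=bool),
        cell_column=np.zeros((size, size), dtype=bool),
        decidua=np.ones((size, size), dtype=bool),
    )


@pytest.fixture()
def flat_image():
    return ImageMeta("flat", "S0", 90, 300)


def uniform_cells(n: int, size: float, lineages, rng) -> pd.DataFrame:
    """Complete-spatial-randomness cell table for null calibrations."""
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "image_id": "img",
            "x": rng.uniform(0, size, n),
            "y": rng.uniform(0, size, n),
            "area": np.full(n, 100.0),
            "lineage": rng.choice(lineages, n),
            "compartment": "decidua",
        }
    )
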