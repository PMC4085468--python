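"""Shared fixtures: configs, small embryos, and a session-scoped model."""

from __future__ import annotations

import numpy as np
import pytest

from lineagetrace import classify, simulate
from lineagetrace.model import Detection, Lineage, TrackingConfig


@pytest.fixture
def tcfg() -> TrackingConfig:
    return TrackingConfig()


@pytest.fixture
def chain_lineage() -> Lineage:
    """Five detections chained 1:1 over five frames."""
    lin = Lineage(
        Detection(id=i, t=i, x=float(i), y=0.0, z=0.0, radius=1.0, intensity=10.0)
        for i in range(1, 6))
    for i in range(1, 5):
        lin.add_link(i, i + 1)
    return lin


@pytest.fixture
def division_lineage() -> Lineage:
    """A parent track that divides at t=2 into two child tracks."""
    dets = [
        Detection(id=1, t=1, x=0.0, y=0.0, z=0.0, radius=1.0, intensity=10.0),
        Detection(id=2, t=2, x=0.0, y=0.0, z=0.0, radius=1.0, intensity=10.0),
        Detection(id=3, t=3, x=-1.0, y=0.0, z=0.0, radius=0.8, intensity=5.0),
        Detection(id=4, t=3, x=1.0, y=0.0, z=0.0, radius=0.8, intensity=5.0),
        Detection(id=5, t=4, x=-1.2, y=0.0, z=0.0, radius=0.8, intensity=5.0),
        Detection(id=6, t=4, x=1.2, y=0.0, z=0.0, radius=0.8, intensity=5.0),
    ]
    lin = Lineage(dets)
    lin.add_link(1, 2)
    lin.add_link(2, 3)
    lin.add_link(2, 4)
    lin.add_link(3, 5)
    lin.add_link(4, 6)
    return lin


@pytest.fixture(scope="session")
def trained_model() -> classify.NBModel:
    """A classifier trained on simulator neighborhoods (reused everywhere)."""
    feats, labels = simulate.make_training_set(250, seed=1)
    return classify.fit(feats, labels)


@pytest.fixture(scope="session")
def clean_embryo() -> simulate.SyntheticEmbryo:
    """Mid-sized error-free embryo with a few division rounds."""
    cfg = simulate.SimConfig(n_start_cells=2, n_frames=60, cell_cycle_mean=18.0,
                             cell_cycle_sd=1.5, rng_seed=5)
    embryo = simulate.generate_embryo(cfg)
    simulate.inject_errors(embryo, cfg)
    return embryo


def random_frame(rng: np.random.Generator, n: int, t: int, start_id: int = 1,
                 box: float = 20.0) -> list[Detection]:
    """n random detections in a cube, ids start_id.. ."""
    pts = rng.uniform(-box, box, size=(n, 3))
    return [
        Detection(id=start_id + i, t=t, x=float(p[0]), y=float(p[1]), z=float(p[2]),
                  radius=float(rng.uniform(0.5, 2.0)),
                  intensity=float(rng.uniform(1.0, 100.0)))
        for i, p in enumerate(pts)
    ]
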