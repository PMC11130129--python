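"""Shared fixtures: scaled-down study conditions and a trained network.

Sections are rendered at 384x384 px and 0.884 µm/px — the same tissue
geometry as the full-scale defaults, at a quarter of the pixel count — so
whole pipeline runs stay fast while adipocytes (40-80 µm) remain large
relative to every mask-pipeline kernel.
"""

from __future__ import annotations

import numpy as np
import pytest

import imfquant as q
from imfquant.segment import (calibrate_threshold_on_sections, extract_tiles,
                              train_segnet_ensemble)


@pytest.fixture(scope="session")
def render_params() -> q.RenderParams:
    return q.RenderParams(canvas=(384, 384), um_per_px=0.884)


@pytest.fixture(scope="session")
def segnet_cfg() -> q.SegnetConfig:
    return q.SegnetConfig(depth=3, channels=(8, 16, 32), tile=144, epochs=35,
                          lr=5e-3, batch_size=8, seed=0, pos_weight=3.0,
                          downsample=3)


def _clean_spec(name: str, target: float) -> q.SectionSpec:
    return q.SectionSpec(name, "CT", "nPCA", "none", 0, 0, target)


@pytest.fixture(scope="session")
def training_sections(render_params) -> list[q.SyntheticSection]:
    """20 clean sections: 12 for tile training, 8 for threshold calibration."""
    rng = np.random.default_rng(0)
    return [
        q.render_section(_clean_spec(f"T{i:02d}", float(rng.uniform(1, 14))),
                         render_params, seed=100 + i)
        for i in range(20)
    ]


@pytest.fixture(scope="session")
def eval_sections(render_params) -> list[q.SyntheticSection]:
    """Held-out clean sections spanning the study's fat range."""
    return [
        q.render_section(
            _clean_spec(f"E{i:02d}", float(np.random.default_rng(500 + i).uniform(2, 12))),
            render_params, seed=700 + i)
        for i in range(20)
    ]


@pytest.fixture(scope="session")
def crack_sections(render_params) -> list[q.SyntheticSection]:
    """Held-out sections bearing crack artifacts inside the tissue."""
    return [
        q.render_section(
            q.SectionSpec(f"A{i:02d}", "CT", "nPCA", "none", 0, 0,
                          float(np.random.default_rng(900 + i).uniform(3, 10)),
                          crack=True),
            render_params, seed=900 + i)
        for i in range(10)
    ]


@pytest.fixture(scope="session")
def trained_model(training_sections, segnet_cfg):
    """Two-member ensemble trained on tiles, threshold calibrated on
    held-out whole sections through the tiled inference path."""
    tiles = extract_tiles(training_sections[:12], 220, segnet_cfg.tile, seed=1)
    ensemble = train_segnet_ensemble(tiles, segnet_cfg, n_members=2)
    calibrate_threshold_on_sections(ensemble, training_sections[12:], segnet_cfg)
    return ensemble


@pytest.fixture(scope="session")
def clean_section(render_params) -> q.SyntheticSection:
    """One artifact-free section at a control-like fat level."""
    return q.render_section(_clean_spec("C00", 5.7), render_params, seed=42)
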