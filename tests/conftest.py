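"""Shared fixtures: small synthetic fields and screen configs."""

from __future__ import annotations

import numpy as np
import pytest

from netquant.nucleus_segmentation import SegmentationParams, flag_apoptotic, segment_nuclei
from netquant.synth_fields import generate_field, preset


@pytest.fixture(scope="session")
def unstim_field():
    """One unstimulated field (50 condensed nuclei) plus its truth."""
    params = preset("unstim_0", n_cells=50, seed=11)
    return generate_field(params, shape=(512, 512))


@pytest.fixture(scope="session")
def pma240_field():
    """One 4-h PMA field: 60% decondensed nuclei, filaments in the DNA channel."""
    params = preset("pma_240", n_cells=60, seed=13)
    return generate_field(params, shape=(640, 640))


def segment_and_flag(field, params: SegmentationParams | None = None):
    labels, records = segment_nuclei(field, params)
    return labels, flag_apoptotic(labels, field, params, records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def mini_screen_config(**overrides) -> dict:
    """A small but statistically well-powered screen fixture for fast tests."""
    cfg = {
        "doses_molar": [1e-9, 1e-8, 1e-7, 1e-6],
        "image_shape": [512, 512],
        "fields_per_well": 1,
        "n_cells": 45,
        "pma_base_fraction": 0.40,
        "effect_span": 0.45,
        "stimulated_intensity_drop": 200.0,
        "baseline_apoptotic_fraction": 0.02,
        "confounder_apoptotic_fraction": 0.45,
        "timepoint_min": 180,
        "seed": 0,
        "controls": {"unstimulated_wells": 12, "pma_wells": 12, "unstim_on_pma_plate": 3,
                     "media_wells": 1, "celastrol_wells": 1, "toxicity_wells": 1},
        "compounds": [
            {"name": "IND-A", "profile": "inducer", "magnitude_by_dose": [0, 0.8, 1, 1]},
            {"name": "INH-A", "profile": "inhibitor", "magnitude_by_dose": [-0.8, -1, -1, -1]},
            {"name": "ENH-A", "profile": "enhancer", "magnitude_by_dose": [0, 0.8, 1, 1]},
            {"name": "BIP-A", "profile": "biphasic_low_inhibit", "magnitude_by_dose": [-1, -1, 1, 1]},
            {"name": "APO-A", "profile": "apoptotic_confounder", "magnitude_by_dose": [0, 0.8, 1, 1]},
            {"name": "NULL-A", "profile": "inert", "magnitude_by_dose": [0, 0, 0, 0]},
        ],
        "exclusion_list": {"ENH-A": "neutropenia association"},
    }
    cfg.update(overrides)
    return cfg
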