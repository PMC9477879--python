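"""Shared fixtures: compact synthetic sections sized for fast tests."""

from __future__ import annotations

import pytest

from dcispatial import SampleType, SimulationParams, simulate_section


def small_params(seed: int = 0, **overrides) -> SimulationParams:
    """Desk-scale section: ~890 cells over 1.2x1.2 mm, 3 ducts."""
    base = dict(
        rng_seed=seed,
        field_width=1200.0,
        field_height=1200.0,
        n_ducts=3,
        duct_radius_range=(80.0, 180.0),
        n_epithelial=400,
        n_lymphocyte=420,
        n_stroma=70,
    )
    base.update(overrides)
    return SimulationParams(**base)


@pytest.fixture
def pure_section():
    return simulate_section(small_params(seed=7), SampleType.PURE_DCIS)


@pytest.fixture
def idc_section():
    return simulate_section(small_params(seed=11), SampleType.IDC_DCIS)
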