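"""Shared fixtures: synthetic islets generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from isletkit import Calibration, IsletSpec, generate_islet
from isletkit.pipeline import PipelineConfig, analyze_sample

CAL = Calibration(0.32, 0.32, 1.0)

#: paper-scale (hundreds of cells) position-only islets for the statistics
#: layer; geometry matches real stacks better than the renderable 100-cell
#: default and is cheap because no channels are rendered.
TABLE_SPEC = dict(n_cells=500, shape=(420, 420, 56))


@pytest.fixture(scope="session")
def default_islet():
    """Rendered default islet: ~100 cells in a 256x256x40 stack."""
    return generate_islet(IsletSpec(seed=1))


@pytest.fixture(scope="session")
def pipeline_bundle(default_islet):
    """Full analysis of the default islet (the expensive end-to-end run)."""
    return analyze_sample(default_islet.volumes, PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def table_islet_random():
    return generate_islet(
        IsletSpec(seed=2, arrangement="random", **TABLE_SPEC), render=False
    )


@pytest.fixture(scope="session")
def table_islet_mantle():
    return generate_islet(
        IsletSpec(seed=2, arrangement="mantle", **TABLE_SPEC), render=False
    )


@pytest.fixture(scope="session")
def table_islet_clustered():
    return generate_islet(
        IsletSpec(seed=2, arrangement="clustered", n_clusters=3, **TABLE_SPEC),
        render=False,
    )
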