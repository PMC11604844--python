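"""Shared fixtures: expensive end-to-end runs are session-scoped so the
default healthy-phantom pipeline is simulated and reconstructed once."""

from __future__ import annotations

import numpy as np
import pytest

from xerecon import pipeline
from xerecon.config import RunConfig
from xerecon.gridding import NufftOperator


@pytest.fixture(scope="session", autouse=True)
def _jit_warmup():
    """Compile the numba gridding kernels once, outside any timed test."""
    op = NufftOperator(np.zeros((4, 3)), 8)
    op.adjoint(op.forward(np.zeros((8, 8, 8), dtype=complex)))


@pytest.fixture(scope="session")
def healthy_run():
    """Default healthy phantom simulated and gridding-reconstructed (AF=1)."""
    cfg = RunConfig()
    phantom, container = pipeline.simulate_run(cfg)
    grid, grid_info = pipeline.reconstruct(container, cfg, "gridding", af=1.0)
    mask, maps_grid = pipeline.derive_maps(grid, cfg)
    return {
        "cfg": cfg,
        "phantom": phantom,
        "container": container,
        "grid": grid,
        "grid_info": grid_info,
        "mask": mask,
        "maps_grid": maps_grid,
    }


@pytest.fixture(scope="session")
def cs_runs(healthy_run):
    """Iterative reconstructions of the same data at AF = 2 and 4."""
    cfg = healthy_run["cfg"]
    container = healthy_run["container"]
    grid = healthy_run["grid"]
    out = {}
    for af in (2.0, 4.0):
        comps, info = pipeline.reconstruct(container, cfg, "cs", af=af)
        _, maps = pipeline.derive_maps(comps, cfg, mask_source=grid)
        out[af] = {"components": comps, "info": info, "maps": maps}
    return out


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down configuration for fast unit-level pipeline checks."""
    cfg = RunConfig()
    cfg.phantom.matrix = 16
    cfg.gridding.matrix = 16
    cfg.acquisition.n_spokes = 250
    cfg.acquisition.samples_per_spoke = 16
    cfg.simulation.noise_sigma = 0.0
    return cfg
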