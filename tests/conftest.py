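"""Shared fixtures: small deterministic stacks and one full-scale run.

The ``default_run`` fixture executes the complete pipeline once, at the
generator's default study conditions (~250 cells, 512x512x60 voxels,
structured ratio field, 30 planted distractors), and is shared by every
test that validates full-pipeline behavior, so the expensive simulation
happens a single time per session.
"""

from __future__ import annotations

import pytest

import somafret as sf
from somafret.config import subseed

#: Reduced-size study field used where full 512x512 resolution is not
#: needed: same voxel grid and cell density as the default conditions.
SMALL_FIELD = dict(
    field_dims_um=(120.0, 186.0, 186.0),
    voxel_size_um=(2.0, 0.62, 0.62),
    min_separation_um=12.0,
)
SMALL_N_CELLS = 86  # matches the default scene's density


def make_small_scene(seed: int, n_cells: int = SMALL_N_CELLS, **kwargs) -> sf.SyntheticScene:
    return sf.make_scene(seed=seed, n_cells=n_cells, **{**SMALL_FIELD, **kwargs})


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default structured scene with distractors."""
    seed = 1
    scene = sf.make_scene(seed=seed)
    scene = sf.add_distractors(scene, 30, seed=subseed(seed, "distractors"))
    out = tmp_path_factory.mktemp("default_run")
    result = sf.run_pipeline(
        sf.PipelineConfig(seed=seed), scene=scene, out_dir=out, write_stacks=False
    )
    return scene, result
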