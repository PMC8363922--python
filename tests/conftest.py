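import numpy as np
import pytest

from psrquant.synth import (
    GroundTruthTile,
    PixelClass,
    StainPalette,
    StainTransform,
    StudyDesign,
    generate_ground_truth,
    render,
)


@pytest.fixture(scope="session")
def palette() -> StainPalette:
    return StainPalette.default()


@pytest.fixture(scope="session")
def small_gt() -> GroundTruthTile:
    """A 128x128 section with ~20% scar, used across unit tests."""
    return generate_ground_truth(
        seed=42, width=128, height=128,
        scar_fraction_target=0.20, lumen_fraction_target=0.02, n_nodules=6,
    )


@pytest.fixture(scope="session")
def clean_tile(small_gt, palette) -> np.ndarray:
    """Noiseless identity rendering: every class is its exact palette colour."""
    return render(small_gt, palette, StainTransform.identity(), seed=0)


@pytest.fixture(scope="session")
def tiny_design() -> StudyDesign:
    """A miniature but complete four-set study for pipeline-level tests."""
    return StudyDesign(
        n_cases=4, tile_size=96, master_seed=123, image_format="png",
        scar_fraction_range=(0.10, 0.35),
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_design, tmp_path_factory):
    from psrquant import pipeline

    out = tmp_path_factory.mktemp("study")
    return pipeline.simulate_study(tiny_design, out)
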