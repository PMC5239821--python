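import numpy as np
import pytest

from topviewmap import PipelineConfig
from topviewmap.synth import EffectPatch, PhantomStudySpec, RibbonGeometry, generate_study

# compact phantom dimensions used throughout the suite
FAST_GEOMETRY = RibbonGeometry(pixel_size=0.03)
FAST_CONFIG = PipelineConfig(k_points=14, smoothing_window=3)


@pytest.fixture(scope="session")
def null_study_dir(tmp_path_factory):
    """Phantom study with no effect: two labeled groups from one condition."""
    spec = PhantomStudySpec(
        slices_per_animal=5,
        geometry=FAST_GEOMETRY,
        noise_sd=0.05,
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("null_study")
    generate_study(spec, outdir)
    return outdir


@pytest.fixture(scope="session")
def patch_study_dir(tmp_path_factory):
    """Phantom study with a strong seeded OD decrease in the treated group."""
    spec = PhantomStudySpec(
        slices_per_animal=8,
        geometry=RibbonGeometry(pixel_size=0.02),
        noise_sd=0.05,
        patches=(EffectPatch("treated", 0.35, 1.6, 0.35, -0.4),),
        seed=3,
    )
    outdir = tmp_path_factory.mktemp("patch_study")
    generate_study(spec, outdir)
    return outdir
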