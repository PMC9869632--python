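import numpy as np
import pytest

from uroslide.pipeline import run_study
from uroslide.synthetic import RegionKind, SyntheticSpec, generate_slide


@pytest.fixture(scope="session")
def study():
    """A small but complete study: 9 training slides, 6 evaluation slides.

    Trains the reference CNN under the full recipe on a separable synthetic
    cohort; shared by tests that need a trained model or slide confidences.
    """
    return run_study(seed=7, n_train_per_class=(4, 4, 4),
                     n_test_per_class=(2, 2, 2))


@pytest.fixture(scope="session")
def hgmi_slide():
    """One muscle-invasive slide: tumour strip abutting muscle, plus aux tissue."""
    spec = SyntheticSpec(width=1024, height=1024, seed=3, layout=(
        (RegionKind.HG_TUMOR, (100, 100, 260, 700)),
        (RegionKind.MUSCLE, (360, 100, 260, 700)),
        (RegionKind.NIA, (700, 100, 280, 280)),
        (RegionKind.IA, (700, 450, 260, 260)),
        (RegionKind.NA, (700, 740, 260, 200)),
    ))
    return generate_slide(spec, slide_id="hgmi_fixture")


def pip_mpl_oracle(vertices, points):
    """Independent point-in-polygon test (matplotlib path)."""
    from matplotlib.path import Path as MplPath
    return MplPath(np.asarray(vertices)).contains_points(np.asarray(points))
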