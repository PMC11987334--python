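import numpy as np
import pytest

from fibroscore.pipeline import RunConfig, run_end_to_end
from fibroscore.synthetic import render_biopsy_slide


@pytest.fixture(scope="session")
def full_slide():
    """One default-geometry slide (2048x3072 at 2 µm/px, severity 0.5)."""
    return render_biopsy_slide(0.5, mpp=2.0, height_px=2048, width_px=3072, seed=3)


@pytest.fixture(scope="session")
def small_slides():
    """Severity grid of small slides for monotonicity checks."""
    sevs = (0.0, 0.25, 0.5, 0.75, 1.0)
    return sevs, [
        render_biopsy_slide(s, mpp=2.0, height_px=512, width_px=768, seed=11)
        for s in sevs
    ]


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The full default synthetic pipeline run (20 patients x 3 visits,
    texture32, seed 17).  Session-scoped: it is the expensive fixture."""
    out = tmp_path_factory.mktemp("default_run")
    return run_end_to_end(RunConfig(), outdir=out)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
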