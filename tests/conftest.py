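import numpy as np
import pytest

import orgoquant as oq


@pytest.fixture(scope="session")
def default_scene():
    """One rendered default confrontation scene with its truth (seed 1)."""
    return oq.render_scene(oq.SceneSpec(seed=1))


@pytest.fixture()
def scene_hints():
    def _hints(truth):
        return oq.ImageHints(
            seed_rc=(int(truth.brain_center_xy[1]), int(truth.brain_center_xy[0])),
            brain_xy=truth.brain_center_xy,
            tumor_xy=truth.tumor_center_xy,
        )

    return _hints


@pytest.fixture(scope="session")
def snowman():
    """Rasterized union of two circles (r=40 at (50,70), r=30 at (105,70))."""
    yy, xx = np.mgrid[0:140, 0:160]
    mask = ((xx - 50) ** 2 + (yy - 70) ** 2 <= 40**2) | (
        (xx - 105) ** 2 + (yy - 70) ** 2 <= 30**2
    )
    return mask
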