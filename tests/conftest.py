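import numpy as np
import pytest

from urbancanopy.vision import GapAnalysisResult


@pytest.fixture
def worked_gap_result() -> GapAnalysisResult:
    """The hand-computable gap-analysis ledger used across modules.

    tp=10000, tg=600, lg=400 give ff=0.94, fc=0.96, phi=1-0.94/0.96.
    """
    return GapAnalysisResult(
        tp=10_000, tg=600, lg=400,
        ff=0.94, fc=0.96, phi=1.0 - 0.94 / 0.96,
    )


@pytest.fixture
def worked_mask() -> np.ndarray:
    """100x100 canopy mask realizing the worked ledger pixel-for-pixel.

    One 20x20 block entirely sky (400 px) and one block holding 200 sky
    pixels; everything else canopy.
    """
    mask = np.ones((100, 100), dtype=bool)
    mask[0:20, 0:20] = False            # large gap block: 400 sky px, 100% sky
    sky = np.zeros((20, 20), dtype=bool)
    sky.ravel()[:200] = True            # 200 sky px: half the 75% threshold
    mask[40:60, 40:60] = ~sky
    return mask
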