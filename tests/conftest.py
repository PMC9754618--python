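import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scanpath3d.io import Fixation, ScanPath

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def make_scanpath():
    """Factory building a valid ScanPath from per-fixation attributes."""

    def _make(
        durations,
        *,
        xs=None,
        ys=None,
        ref_images=None,
        participant="p1",
        sculpture="moses",
        gap_ms=50.0,
        onset0=0.0,
    ) -> ScanPath:
        n = len(durations)
        xs = list(xs) if xs is not None else [100.0] * n
        ys = list(ys) if ys is not None else [100.0] * n
        ref_images = list(ref_images) if ref_images is not None else [1] * n
        fixations = []
        onset = onset0
        for i, d in enumerate(durations):
            fixations.append(
                Fixation(
                    participant_id=participant,
                    sculpture_id=sculpture,
                    ref_image=ref_images[i],
                    x=xs[i],
                    y=ys[i],
                    onset=onset,
                    duration=float(d),
                    ordinal=i,
                )
            )
            onset += float(d) + gap_ms
        return ScanPath(
            participant_id=participant, sculpture_id=sculpture, fixations=fixations
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
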