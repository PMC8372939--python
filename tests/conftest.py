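import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from satoyama import ClassLegend, LandCoverGrid

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def legend() -> ClassLegend:
    return ClassLegend.default()


@pytest.fixture
def make_random_grid(legend):
    """Factory for random categorical rasters with optional nodata holes."""

    def _make(seed: int, shape=(36, 36), nodata_frac: float = 0.1,
              codes=None) -> LandCoverGrid:
        rng = np.random.default_rng(seed)
        codes = np.asarray(codes if codes is not None else legend.codes)
        values = rng.choice(codes, size=shape)
        if nodata_frac > 0:
            holes = rng.uniform(size=shape) < nodata_frac
            values = np.where(holes, 0, values)
        return LandCoverGrid(values=values.astype(np.int64), west=10.0,
                             north=50.0, pixel_size=1.0 / 240.0, nodata_code=0)

    return _make
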