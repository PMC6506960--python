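import numpy as np
import pytest

import cometh as cm

# The seven-row worked example used throughout the docs: chr1 positions with
# mixed coverage, one uncovered site, spanning all four states.
TABLE1_ROWS = [
    # position, coverage, mc_ratio
    (434_314, 2, 0.3),
    (434_326, 19, 1.0),
    (434_329, 17, 1.0),
    (434_343, 15, 0.20),
    (434_360, 20, 0.8),
    (434_405, 21, 0.67),
    (434_436, 0, np.nan),
]


@pytest.fixture
def table1_track() -> cm.MethylationTrack:
    pos, cov, ratio = zip(*TABLE1_ROWS)
    return cm.make_track("example", "chr1", pos, cov, ratio)


@pytest.fixture
def table1_annotated(table1_track) -> cm.MethylationTrack:
    # no coverage filter: the low-coverage first site keeps its state B
    return cm.annotate(table1_track, cm.StateAssignmentConfig(min_coverage=0))


def random_annotated_track(
    rng: np.random.Generator,
    n_sites: int = 200,
    na_fraction: float = 0.1,
    min_coverage: int = 3,
) -> cm.MethylationTrack:
    """A random valid track with a controllable share of NA sites."""
    gaps = rng.integers(2, 200, size=max(n_sites - 1, 0))
    positions = 1000 + np.concatenate([[0], np.cumsum(gaps)])
    coverage = rng.integers(min_coverage, 40, size=n_sites)
    low = rng.random(n_sites) < na_fraction
    coverage[low] = rng.integers(0, min_coverage, size=int(low.sum()))
    ratio = np.round(rng.random(n_sites), 3)
    ratio[coverage == 0] = np.nan
    track = cm.make_track("rand", "chrR", positions, coverage, ratio)
    return cm.annotate(track, cm.StateAssignmentConfig(min_coverage=min_coverage))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
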