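import warnings

import numpy as np
import pytest

import breathcomplex as bc


@pytest.fixture(scope="session")
def breath_series_150():
    """A control-like breath series of 150 breaths (fixed seed)."""
    return bc.generate_breath_series(bc.control_like_template(n_breaths=150, seed=3))


@pytest.fixture(scope="session")
def noiseless_render(breath_series_150):
    """Noiseless, drift-free rendering of the 150-breath series at 1 kHz."""
    return bc.render_signal(breath_series_150, bc.RenderSpec(fs=1000.0))


@pytest.fixture(scope="session")
def mini_cohort_table():
    """Small control/asthma cohort table from the full pipeline (2 x 4)."""
    cfg = bc.SynthCohortConfig(
        groups={
            "control": bc.control_like_template(),
            "asthma": bc.asthma_like_template(),
        },
        n_per_group=4,
        record_duration=420.0,
        render=bc.RenderSpec(fs=125.0, noise_sd=0.05),
        master_seed=7,
    )
    recordings = bc.generate_cohort(cfg)
    config = bc.PipelineConfig(window_duration=300.0, window_hop=30.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bc.run_pipeline(recordings, config)


def naive_sample_entropy(x, m, r_frac):
    """Exhaustive triple-loop SampEn oracle (self-matches excluded, i < j)."""
    import math

    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_frac * np.std(x, ddof=1)
    b = a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def naive_cross_sample_entropy(x, y, m, r):
    """Exhaustive oracle for cross-SampEn on z-normalized series (all i, j)."""
    import math

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    zx = (x - x.mean()) / np.std(x, ddof=1)
    zy = (y - y.mean()) / np.std(y, ddof=1)
    n = len(x)
    b = a = 0
    for i in range(n - m):
        for j in range(n - m):
            if max(abs(zx[i + k] - zy[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(zx[i + k] - zy[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)
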