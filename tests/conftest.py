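import numpy as np
import pytest

import sketchvep as sv


@pytest.fixture(scope="session")
def small_corpus():
    """20 binarized 1/f-noise images, 128 px — fast surrogate corpus."""
    rng = np.random.default_rng(42)
    images = sv.make_image_corpus(20, 128, rng)
    return [sv.binarize_image(im) for im in images]


@pytest.fixture(scope="session")
def corpus_distribution(small_corpus):
    return sv.extract_pattern_distribution(small_corpus, mode="tile")


@pytest.fixture(scope="session")
def feature_sets(corpus_distribution):
    """(optimal, non_optimal) sets under the default constraints."""
    opt = sv.select_optimal(corpus_distribution)
    non = sv.select_nonoptimal(corpus_distribution, 50)
    return opt, non


@pytest.fixture(scope="session")
def toy_distribution():
    """Four patterns with probabilities 0.5 / 0.3 / 0.15 / 0.05."""
    counts = np.zeros(512, dtype=np.int64)
    ids = {"A": 10, "B": 20, "C": 30, "D": 40}
    for pid, c in zip(ids.values(), (10, 6, 3, 1)):
        counts[pid] = c
    return sv.PatternDistribution(counts), ids


@pytest.fixture(scope="session")
def tiny_schedule():
    """1/20-scale schedule: 96 single + 18 2AFC trials, 6 blocks."""
    rng = np.random.default_rng(7)
    return sv.build_schedule(sv.scaled_schedule_config(20), rng)


@pytest.fixture(scope="session")
def quiet_session(tiny_schedule):
    """Noise- and jitter-free session: planted components are exact."""
    lat = sv.LatencyModel(subject_sd_ms=0.0, trial_jitter_sd_ms=0.0)
    noise = sv.NoiseParams(pink_rms_uv=0.0, line_amplitude_uv=0.0,
                           drift_amplitude_uv=0.0)
    return sv.simulate_session(tiny_schedule, lat=lat, noise=noise,
                               rng=np.random.default_rng(3))
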