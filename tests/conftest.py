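import warnings

import pytest

import stutterkit as sk


@pytest.fixture(scope="session")
def tiny_corpus():
    """Three speakers, ~8 s each: enough events for every pipeline stage."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sk.generate_corpus(
            sk.SynthConfig(n_speakers=3, seconds_per_speaker=12.0, seed=5)
        )


@pytest.fixture(scope="session")
def tiny_split(tiny_corpus):
    return sk.assign_speaker_split(
        [r.speaker_id for r in tiny_corpus], (1, 1, 1), seed=0
    )


@pytest.fixture(scope="session")
def headline_result():
    """The full event-vs-interval comparison on the default synthetic corpus.

    Session-scoped: this is the one expensive computation in the suite
    (it trains a Gaussian-kernel SVM under both segmentation schemes).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sk.headline_comparison(seed=11)
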