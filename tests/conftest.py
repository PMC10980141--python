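import pytest

from stbhist import load_lexicon
from stbhist.rules import ExtractorConfig
from stbhist.synth import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def extractor_config():
    return ExtractorConfig()


@pytest.fixture(scope="session")
def small_bundle():
    """Small noise-free bundle for unit tests."""
    return generate_corpus(
        SyntheticConfig(n_patients=40, psh_prevalence=0.4, fsh_prevalence=0.2,
                        timestamp_style_rate=0.0, seed=5)
    )


@pytest.fixture(scope="session")
def study_bundle():
    """The reference study conditions: 200 patients, PSH prevalence 0.3,
    FSH prevalence 0.1, no timestamp-style documentation, distractors on."""
    return generate_corpus(
        SyntheticConfig(n_patients=200, psh_prevalence=0.3, fsh_prevalence=0.1,
                        timestamp_style_rate=0.0, seed=42)
    )
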