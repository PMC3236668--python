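from datetime import datetime

import pytest

from clinicolloc import CleanMessage, RawMessage
from clinicolloc.synthetic import PlantingPlan, SimConfig, demo_lexicon, generate_corpus


def raw(id, body, date=datetime(2008, 11, 3), author="authorA", subject="s"):
    return RawMessage(id=id, date=date, author=author, subject=subject, body=body)


def cm(id, text, date=datetime(2008, 11, 3)):
    return CleanMessage(id=id, date=date, text=text)


@pytest.fixture(scope="session")
def small_sim():
    """A 300-message seeded corpus with default plantings and its manifest."""
    cfg = SimConfig(seed=7, n_messages=300, n_subscribers=60, n_posting=33)
    corpus, manifest = generate_corpus(cfg)
    return cfg, corpus, manifest


@pytest.fixture(scope="session")
def sim_lexicon():
    return demo_lexicon()
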