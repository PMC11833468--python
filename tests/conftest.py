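from __future__ import annotations

from datetime import datetime

import pytest

from fourms import synthdata as sd
from fourms.corpus import Message, TransferEvent


@pytest.fixture(scope="session")
def small_config() -> sd.GeneratorConfig:
    return sd.GeneratorConfig(n_messages=200, n_residents=30, n_events=40, seed=7)


@pytest.fixture(scope="session")
def small_corpus(small_config) -> sd.SyntheticCorpus:
    return sd.generate_corpus(small_config)


@pytest.fixture(scope="session")
def vocabulary(small_config) -> sd.Vocabulary:
    return sd.make_vocabulary(small_config)


@pytest.fixture(scope="session")
def embedder(small_config, vocabulary) -> sd.SyntheticEmbedder:
    return sd.SyntheticEmbedder(small_config, vocabulary)


def make_message(message_id="m1", resident="r1", ts="2016-03-01T10:00",
                 text="please advise", sender="nursing_staff", receiver="aprn"):
    return Message(message_id, resident, "nh01", sender, receiver,
                   datetime.fromisoformat(ts), text)


def make_event(event_id="e1", resident="r1", ts="2016-03-10T12:00"):
    return TransferEvent(event_id, resident, datetime.fromisoformat(ts))
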