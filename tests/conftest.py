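"""Shared fixtures: lexicons, the worked-example corpus, blinded builders."""

import logging

import pytest

import ppi_groupsel as pg
from ppi_groupsel.corpus_io import BlindedInstance

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def lexicon():
    return pg.default_lexicon()


@pytest.fixture(scope="session")
def worked_corpus():
    return pg.worked_example_fixtures()


@pytest.fixture(scope="session")
def worked_sentences(worked_corpus):
    return {s.sent_id: s for s in worked_corpus.sentences()}


def make_blinded(words, p1_index, p2_index, comma_after=(), label=None):
    """Hand-build a blinded instance from a word list (1-based positions)."""
    return BlindedInstance(words=list(words), p1_index=p1_index,
                           p2_index=p2_index,
                           comma_after=list(comma_after),
                           connectors_between=[], label=label,
                           instance=None)


@pytest.fixture
def blinded_factory():
    return make_blinded


def first_instance(sentence):
    return pg.enumerate_instances(sentence)[0]


@pytest.fixture
def instance_of(worked_sentences):
    def get(sent_id, index=0):
        return pg.enumerate_instances(worked_sentences[sent_id])[index]
    return get
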