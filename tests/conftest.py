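"""Shared fixtures: synthetic corpora, a trained tagger, and feature matrices.

The heavy fixtures are session-scoped so that the recovery and screening
suites share one trained model and one fitted representation.
"""

from __future__ import annotations

import numpy as np
import pytest

from picoscreen.features import TopicModelConfig, build_feature_matrix
from picoscreen.pico_tagger import TaggerConfig, predict_nested, train_tagger
from picoscreen.pico_tagger.categories import CategorySet
from picoscreen.synthetic import (
    GrammarConfig,
    RelevanceConfig,
    generate_annotated_corpus,
    generate_screening_collection,
    stats_study_config,
)

# the synthetic grammar uses one fine-grained type per top-level category
GRAMMAR_CATEGORIES = CategorySet(
    ("P", "P.Condition", "I", "I.Pharmacological", "O", "O.Pain")
)


def small_tagger_config(**overrides) -> TaggerConfig:
    """A scaled-down architecture for the synthetic grammar studies."""
    defaults = dict(
        word_dim=20,
        char_dim=8,
        char_lstm_dim=8,
        seq_lstm_dim=18,
        n_tags=13,
        max_epochs=20,
        batch_size=8,
        learning_rate=3e-3,
        dropout_rate=0.1,
        early_stopping_patience=8,
        seed=7,
    )
    defaults.update(overrides)
    return TaggerConfig(**defaults)


@pytest.fixture(scope="session")
def grammar_corpora():
    train = generate_annotated_corpus(GrammarConfig(n_documents=100, seed=7))
    dev = generate_annotated_corpus(GrammarConfig(n_documents=20, seed=8))
    test = generate_annotated_corpus(GrammarConfig(n_documents=20, seed=9))
    return train, dev, test


@pytest.fixture(scope="session")
def trained_tagger(grammar_corpora):
    train, dev, _ = grammar_corpora
    model, history = train_tagger(
        train, dev, small_tagger_config(), categories=GRAMMAR_CATEGORIES
    )
    return model, history


@pytest.fixture(scope="session")
def heldout_span_prf(trained_tagger, grammar_corpora):
    model, _ = trained_tagger
    _, _, test = grammar_corpora
    gold, pred = set(), set()
    for tagged in test:
        gold |= {s.key() for s in tagged.spans}
        for sent in tagged.sentences:
            if sent.tokens:
                pred |= {s.key() for s in predict_nested(model, sent.tokens, sent.ref)}
    tp = len(gold & pred)
    precision = tp / max(len(pred), 1)
    recall = tp / max(len(gold), 1)
    f1 = 2 * precision * recall / max(precision + recall, 1e-12)
    return precision, recall, f1


@pytest.fixture(scope="session")
def relevance_study():
    """The context-relevance screening collection with both feature matrices."""
    collection, tagged = generate_screening_collection(RelevanceConfig(seed=11))
    topic_config = TopicModelConfig(k=20, n_iterations=150, seed=11)
    Xb, _ = build_feature_matrix(tagged, "baseline", topic_config)
    Xp, _ = build_feature_matrix(tagged, "pico", topic_config)
    labels = [t.document.label == "included" for t in tagged]
    ids = [t.document.id for t in tagged]
    return {
        "collection": collection,
        "tagged": tagged,
        "X_baseline": Xb,
        "X_pico": Xp,
        "labels": labels,
        "ids": ids,
    }


@pytest.fixture(scope="session")
def stats_study():
    collection, tagged = generate_screening_collection(stats_study_config(seed=5))
    return collection, tagged


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
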