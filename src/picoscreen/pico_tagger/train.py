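"""Training loop for the nested-span recogniser.

Stochastic first-order optimisation with Adam over batches of sentences,
global-norm gradient clipping, dropout, L2 weight decay, and early stopping
on development-set span-level F1.  Words occurring exactly once in the
training corpus are replaced by UNK with probability 0.5 per occurrence per
epoch, which trains the shared unknown-word vector.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from picoscreen.pico_tagger.categories import CategorySet, default_category_set, tagset
from picoscreen.pico_tagger.iob import encode_nested_spans
from picoscreen.pico_tagger.model import TaggerModel, predict_nested
from picoscreen.pico_tagger.network import (
    UNK,
    TaggerConfig,
    TaggerParams,
    build_char_ids,
    sentence_loss_and_grads,
)
from picoscreen.textprep import TaggedDocument, normalise_for_tagger

__all__ = ["train_tagger", "TrainingHistory", "load_word2vec_text"]


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    dev_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1


@dataclass
class _Instance:
    word_ids: list[int]
    char_ids: list[list[int]]
    targets: list[np.ndarray]
    singleton_positions: list[int]


def _span_f1(gold: set, pred: set) -> float:
    tp = len(gold & pred)
    if tp == 0:
        return 0.0
    p = tp / len(pred)
    r = tp / len(gold)
    return 2 * p * r / (p + r)


def _sentences_with_spans(corpus: list[TaggedDocument]):
    for tagged in corpus:
        by_ref = {}
        for span in tagged.spans:
            by_ref.setdefault(span.sentence_ref, []).append(span)
        for sent in tagged.sentences:
            if sent.tokens:
                yield sent, by_ref.get(sent.ref, [])


def load_word2vec_text(path) -> tuple[dict[str, int], np.ndarray]:
    """Load pretrained embeddings in word2vec text format.

    Returns a vocabulary (with an UNK row 0) and the embedding table; the UNK
    vector is initialised to the mean of all vectors.
    """
    words = []
    vecs = []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().split()
        if len(first) == 2:  # header "n_words dim"
            pass
        else:
            words.append(first[0])
            vecs.append(np.array(first[1:], dtype=float))
        for line in fh:
            parts = line.rstrip().split(" ")
            words.append(parts[0])
            vecs.append(np.array(parts[1:], dtype=float))
    table = np.stack(vecs)
    table = np.vstack([table.mean(axis=0, keepdims=True), table])
    vocab = {"<unk>": UNK}
    for i, w in enumerate(words, start=1):
        vocab[w] = i
    return vocab, table


class _Adam:
    def __init__(self, params: TaggerParams, lr: float, weight_decay: float):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = params.zeros_like()
        self.v = params.zeros_like()

    def step(self, params: TaggerParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, p in params.arrays.items():
            g = grads[name]
            if self.wd > 0.0:
                if name == "word_emb" and params.word_emb_frozen:
                    g = g.copy()
                    g[UNK] += self.wd * p[UNK]  # only the UNK row is trainable
                else:
                    g = g + self.wd * p
            m = self.m[name]
            v = self.v[name]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            update = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if name == "word_emb" and params.word_emb_frozen:
                p[UNK] -= update[UNK]
            else:
                p -= update


def _clip(grads: dict[str, np.ndarray], max_norm: float) -> None:
    if max_norm <= 0:
        return
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def train_tagger(
    corpus: list[TaggedDocument],
    dev_corpus: list[TaggedDocument],
    config: TaggerConfig | None = None,
    embeddings: tuple[dict[str, int], np.ndarray] | None = None,
    categories: CategorySet | None = None,
    verbose: bool = False,
) -> tuple[TaggerModel, TrainingHistory]:
    """Train the nested recogniser; returns the best-dev model and its history.

    The per-sentence loss is the negative CRF log-likelihood summed over the
    sentence's target layers (fine-grained layer first, then top-level
    layers; the fine layer is padded with all-O when no fine-grained span
    exists).  Fully seeded via ``config.seed``.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    if not dev_corpus:
        raise ValueError("a non-empty dev corpus is required for early stopping")
    config = config or TaggerConfig()
    categories = categories or default_category_set()
    tags = tagset(categories)
    if config.n_tags != len(tags):
        raise ValueError(f"config.n_tags={config.n_tags} but tag set has {len(tags)} tags")
    tag_index = {t: i for i, t in enumerate(tags)}
    rng = np.random.default_rng(config.seed)

    # vocabulary over digit-normalised lowercase surfaces
    counts: Counter[str] = Counter()
    for sent, _ in _sentences_with_spans(corpus):
        counts.update(normalise_for_tagger(t.surface) for t in sent.tokens)
    word_vocab = {"<unk>": UNK}
    char_vocab = {"<unk>": UNK}
    if embeddings is not None:
        word_vocab, pretrained = embeddings
    else:
        pretrained = None
        for w in sorted(counts):
            word_vocab[w] = len(word_vocab)
    for w in sorted(counts):
        for ch in w:
            if ch not in char_vocab:
                char_vocab[ch] = len(char_vocab)
    singletons = {word_vocab[w] for w, c in counts.items() if c == 1 and w in word_vocab}

    all_o = tag_index["O"]
    instances: list[_Instance] = []
    for sent, spans in _sentences_with_spans(corpus):
        layers = encode_nested_spans(
            spans, len(sent.tokens), sentence_ref=sent.ref, pad_fine=True
        )
        targets = [
            np.array([tag_index[t] for t in layer.tags], dtype=int) for layer in layers
        ]
        # one all-O terminator layer supervises the stopping criterion:
        # after the outermost spans, the next decoding pass must be empty
        if any((t != all_o).any() for t in targets):
            targets.append(np.full(len(sent.tokens), all_o, dtype=int))
        word_ids = [word_vocab.get(normalise_for_tagger(t.surface), UNK) for t in sent.tokens]
        char_ids = [build_char_ids(t.surface, char_vocab) for t in sent.tokens]
        sing = [i for i, wid in enumerate(word_ids) if wid in singletons]
        instances.append(_Instance(word_ids, char_ids, targets, sing))

    dev_sentences = [
        (sent, {s.key() for s in spans}) for sent, spans in _sentences_with_spans(dev_corpus)
    ]
    dev_gold: set = set()
    for _, keys in dev_sentences:
        dev_gold |= keys

    params = TaggerParams.init(
        config, len(word_vocab), len(char_vocab), rng, pretrained=pretrained
    )
    optimiser = _Adam(params, config.learning_rate, config.weight_decay)
    history = TrainingHistory()
    best_params = params.copy()
    best_f1 = -1.0
    patience_left = config.early_stopping_patience

    model = TaggerModel(config, params, word_vocab, char_vocab, categories)
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(instances))
        epoch_loss = 0.0
        for b0 in range(0, len(order), config.batch_size):
            batch = order[b0 : b0 + config.batch_size]
            grads = params.zeros_like()
            batch_loss = 0.0
            for idx in batch:
                inst = instances[idx]
                word_ids = list(inst.word_ids)
                for pos in inst.singleton_positions:
                    if rng.random() < config.singleton_unk_prob:
                        word_ids[pos] = UNK
                nll, g = sentence_loss_and_grads(
                    params,
                    word_ids,
                    inst.char_ids,
                    inst.targets,
                    rng=rng,
                    dropout_rate=config.dropout_rate,
                )
                batch_loss += nll
                for name in grads:
                    grads[name] += g[name]
            for name in grads:
                grads[name] /= len(batch)
            _clip(grads, config.gradient_clip)
            optimiser.step(params, grads)
            epoch_loss += batch_loss
        history.train_loss.append(epoch_loss / len(instances))

        pred: set = set()
        for sent, _ in dev_sentences:
            for span in predict_nested(model, sent.tokens, sent.ref):
                pred.add(span.key())
        f1 = _span_f1(dev_gold, pred)
        history.dev_f1.append(f1)
        if verbose:
            print(f"epoch {epoch}: loss={history.train_loss[-1]:.4f} dev_f1={f1:.4f}")
        if f1 > best_f1:
            best_f1 = f1
            best_params = params.copy()
            history.best_epoch = epoch
            patience_left = config.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    return (
        TaggerModel(config, best_params, word_vocab, char_vocab, categories),
        history,
    )
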