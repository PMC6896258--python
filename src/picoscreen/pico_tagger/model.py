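"""Trained tagger bundle: vocabulary, parameters, and nested-span prediction."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from picoscreen.pico_tagger.categories import CategorySet, default_category_set, tagset
from picoscreen.pico_tagger.crf import viterbi_decode
from picoscreen.pico_tagger.iob import SpanAnnotation, TagLayer, decode_iob
from picoscreen.pico_tagger.network import (
    TaggerConfig,
    TaggerParams,
    bilstm_forward,
    build_char_ids,
    build_word_id,
    embed_sentence,
)
from picoscreen.textprep import SentenceRef, TaggedDocument

__all__ = ["TaggerModel", "predict_nested", "tag_document", "save_model", "load_model"]


@dataclass
class TaggerModel:
    """A trained nested-span recogniser ready for prediction or archiving."""

    config: TaggerConfig
    params: TaggerParams
    word_vocab: dict[str, int]  # normalised surface -> row; row 0 is UNK
    char_vocab: dict[str, int]
    categories: CategorySet

    @property
    def tags(self) -> list[str]:
        return tagset(self.categories)

    def encode_tokens(self, tokens):
        word_ids = [build_word_id(t.surface, self.word_vocab) for t in tokens]
        char_ids = [build_char_ids(t.surface, self.char_vocab) for t in tokens]
        return word_ids, char_ids


def predict_nested(
    model: TaggerModel,
    tokens,
    sentence_ref: SentenceRef | None = None,
) -> list[SpanAnnotation]:
    """Predict the nested spans of one sentence by iterative decoding.

    Iteration 1 decodes the fine-grained layer from the combined embedding;
    each later iteration feeds the previous sequence-layer hidden states
    back through the (shared) biLSTM, projection and Viterbi decoder.  The
    top-level pass (iteration 2) always runs — an empty fine-grained layer
    does not imply an unannotated sentence — and decoding stops when any
    later iteration yields no spans or ``max_layers`` is reached.  The union
    of spans over iterations is returned, with ``depth`` recording the
    iteration that produced each span.
    """
    if not tokens:
        raise ValueError("cannot tag an empty sentence")
    if sentence_ref is None:
        sentence_ref = SentenceRef("", "title", 0)
    arrays = model.params.arrays
    tags = model.tags
    word_ids, char_ids = model.encode_tokens(tokens)
    inp, _ = embed_sentence(model.params, word_ids, char_ids)
    seen: set[tuple] = set()
    spans: list[SpanAnnotation] = []
    for layer_idx in range(model.config.max_layers):
        h, _ = bilstm_forward(arrays, "seq", inp)
        potentials = h @ arrays["proj_W"] + arrays["proj_b"]
        path = viterbi_decode(potentials, arrays["trans"], arrays["start"], arrays["end"])
        layer = TagLayer(sentence_ref, layer_idx, tuple(tags[i] for i in path))
        layer_spans = decode_iob(layer, mode="lenient")
        if not layer_spans and layer_idx >= 1:
            break
        for span in layer_spans:
            if span.key() not in seen:
                seen.add(span.key())
                spans.append(span)
        inp = h
    return spans


def tag_document(model: TaggerModel, tagged: TaggedDocument) -> TaggedDocument:
    """Tag every sentence of a preprocessed document; returns a new TaggedDocument."""
    spans: list[SpanAnnotation] = []
    for sent in tagged.sentences:
        if sent.tokens:
            spans.extend(predict_nested(model, sent.tokens, sent.ref))
    return TaggedDocument(tagged.document, tagged.sentences, spans, tagged.preprocessor)


def save_model(model: TaggerModel, directory: str | Path) -> None:
    """Archive a model as ``{config.json, vocab.txt, chars.txt, params.npz}``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": model.config.to_dict(),
        "categories": list(model.categories.categories),
        "word_emb_frozen": model.params.word_emb_frozen,
    }
    (directory / "config.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")
    by_row = sorted(model.word_vocab.items(), key=lambda kv: kv[1])
    (directory / "vocab.txt").write_text(
        "\n".join(w for w, _ in by_row) + "\n", encoding="utf-8"
    )
    by_row = sorted(model.char_vocab.items(), key=lambda kv: kv[1])
    (directory / "chars.txt").write_text(
        "\n".join(c for c, _ in by_row) + "\n", encoding="utf-8"
    )
    np.savez(directory / "params.npz", **model.params.arrays)


def load_model(directory: str | Path) -> TaggerModel:
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text(encoding="utf-8"))
    config = TaggerConfig(**meta["config"])
    words = (directory / "vocab.txt").read_text(encoding="utf-8").splitlines()
    chars = (directory / "chars.txt").read_text(encoding="utf-8").splitlines()
    with np.load(directory / "params.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    params = TaggerParams(arrays, word_emb_frozen=meta["word_emb_frozen"])
    return TaggerModel(
        config=config,
        params=params,
        word_vocab={w: i for i, w in enumerate(words)},
        char_vocab={c: i for i, c in enumerate(chars)},
        categories=CategorySet(tuple(meta["categories"])) if meta.get("categories")
        else default_category_set(),
    )
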