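"""Text normalisation and external file formats for screening collections.

A reference (title + abstract) is normalised into sentences, tokens and
lemmata by a deterministic rule-based :class:`RuleBasedPreprocessor`.  The
module also reads and writes every external format the pipeline touches:
tabular collections (CSV/TSV/RIS), and annotated corpora with nested token
spans (brat-style standoff and a JSON-lines dialect).

All offsets are 0-based and half-open, at both the character and the token
level.  Lemmata and tagger input are lowercased; surfaces are kept verbatim.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Literal, NamedTuple

__all__ = [
    "Document",
    "Sentence",
    "Token",
    "Collection",
    "SentenceRef",
    "TokenizedSentence",
    "TaggedDocument",
    "RuleBasedPreprocessor",
    "DEFAULT_PREPROCESSOR",
    "STOPWORDS_VERSION",
    "load_stopwords",
    "split_sentences",
    "tokenize",
    "lemmatize",
    "normalise_for_tagger",
    "filter_bow_lemmata",
    "preprocess_document",
    "read_collection",
    "write_collection",
    "read_annotated_corpus",
    "write_annotated_corpus",
    "CollectionError",
    "CorpusError",
]

Label = Literal["included", "excluded", "unlabelled"]

STOPWORDS_VERSION = "en-v1"

_INCLUDED_ALIASES = {"1", "include", "included", "inc", "relevant", "yes", "true"}
_EXCLUDED_ALIASES = {"0", "exclude", "excluded", "exc", "irrelevant", "no", "false"}


class CollectionError(ValueError):
    """Raised for malformed collection files (missing titles, duplicate ids...)."""


class CorpusError(ValueError):
    """Raised for malformed annotated-corpus files (bad spans, unknown categories...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Document:
    """A reference: title, abstract and screening label."""

    id: str
    title: str
    abstract: str = ""
    label: Label = "unlabelled"

    def __post_init__(self) -> None:
        if not self.title or not self.title.strip():
            raise CollectionError(f"document {self.id!r} has an empty title")
        if self.label not in ("included", "excluded", "unlabelled"):
            raise CollectionError(f"document {self.id!r} has invalid label {self.label!r}")

    def field_text(self, field_name: str) -> str:
        if field_name == "title":
            return self.title
        if field_name == "abstract":
            return self.abstract
        raise KeyError(field_name)


@dataclass(frozen=True)
class Sentence:
    """A sentence located by half-open character offsets within one field."""

    doc_id: str
    field: Literal["title", "abstract"]
    index: int
    char_start: int
    char_end: int


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValueError("token with empty character span")


class SentenceRef(NamedTuple):
    """Identifies one sentence of one field of one document."""

    doc_id: str
    field: str
    sentence_index: int


@dataclass(frozen=True)
class TokenizedSentence:
    ref: SentenceRef
    text: str
    tokens: tuple[Token, ...]


@dataclass
class Collection:
    """An ordered set of documents with unique ids."""

    name: str
    documents: list[Document]

    def __post_init__(self) -> None:
        if not self.documents:
            raise CollectionError(f"collection {self.name!r} has no documents")
        seen: set[str] = set()
        for doc in self.documents:
            if doc.id in seen:
                raise CollectionError(f"duplicate document id {doc.id!r}")
            seen.add(doc.id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def labels(self) -> list[Label]:
        return [d.label for d in self.documents]


@dataclass
class TaggedDocument:
    """A document plus its tokenised sentences and (possibly empty) span annotations.

    ``spans`` is a list of :class:`picoscreen.pico_tagger.SpanAnnotation`; the
    type lives in the tagger module but instances flow through here so that
    corpora can be serialised without importing the model code.
    """

    document: Document
    sentences: list[TokenizedSentence]
    spans: list = field(default_factory=list)
    preprocessor: str = ""

    def sentence(self, ref: SentenceRef) -> TokenizedSentence:
        for s in self.sentences:
            if s.ref == ref:
                return s
        raise KeyError(ref)

    def sentences_for(self, field_name: str) -> list[TokenizedSentence]:
        return [s for s in self.sentences if s.ref.field == field_name]


# ---------------------------------------------------------------------------
# Rule-based preprocessing
# ---------------------------------------------------------------------------

# Sentence boundary: terminator, whitespace, then an uppercase letter, digit,
# or opening quote/bracket.  Deliberately simple and fully deterministic.
_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+(?=[\"'(\[]?[A-Z0-9])")

# Tokens: hyphen/apostrophe-joined alphanumeric words, decimal numbers, or a
# single non-space character.  "migraine-specific" and "0.05" are one token.
_TOKEN_RE = re.compile(
    r"[A-Za-z][A-Za-z0-9]*(?:[-'][A-Za-z0-9]+)*"
    r"|\d+(?:\.\d+)?"
    r"|\S"
)

_VOWELS = "aeiou"
# After stripping -ed/-ing these stem endings get a restored final "e"
# (reduc -> reduce, increas -> increase, randomiz -> randomize).
_E_RESTORE = "csuvzg"


def split_sentences(
    text: str,
    doc_id: str = "",
    field_name: Literal["title", "abstract"] = "title",
) -> list[Sentence]:
    """Split field text into sentences with character offsets.

    Boundaries are placed after a terminator (``.!?``) followed by whitespace
    and a capitalised/numeric sentence opener.  Sentences are trimmed of
    surrounding whitespace, so their spans jointly cover every non-whitespace
    character of ``text``.  Empty text yields an empty list.
    """
    if not text or not text.strip():
        return []
    pieces: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        pieces.append((start, m.start()))
        start = m.end()
    pieces.append((start, len(text)))
    sentences = []
    for i, (s, e) in enumerate(pieces):
        chunk = text[s:e]
        ls = len(chunk) - len(chunk.lstrip())
        rs = len(chunk) - len(chunk.rstrip())
        s, e = s + ls, e - rs
        if s < e:
            sentences.append(Sentence(doc_id, field_name, len(sentences), s, e))
    return sentences


def lemmatize(surface: str) -> str:
    """Lowercase base form via a small deterministic suffix-rule table.

    Rules (applied in order, plural before verbal inflection):

    * ``-ies -> -y`` (studies -> study), ``-Xes -> -X`` after sibilants
      (classes -> class), plain ``-s`` stripped unless the word ends in
      ``ss``/``us``/``is`` (steroids -> steroid).
    * ``-ied -> -y``; ``-eed`` keeps the stem (agreed -> agree);
      otherwise ``-ed``/``-ing`` is stripped, a doubled final consonant is
      reduced (planned -> plan), and a final ``e`` is restored after
      c/s/u/v/z/g (reduced -> reduce, reducing -> reduce).
    """
    w = surface.lower()
    if not w.isalpha():
        return w
    # plural
    if len(w) > 4 and w.endswith("ies"):
        w = w[:-3] + "y"
    elif len(w) > 4 and w.endswith(("sses", "xes", "zes", "ches", "shes")):
        w = w[:-2]
    elif len(w) > 3 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
        w = w[:-1]
    # verbal inflection
    if len(w) > 4 and w.endswith("ied"):
        w = w[:-3] + "y"
    elif len(w) > 4 and w.endswith("eed"):
        w = w[:-1]
    elif len(w) > 4 and w.endswith("ed"):
        w = _restore(w[:-2])
    elif len(w) > 5 and w.endswith("ing"):
        w = _restore(w[:-3])
    return w


def _restore(stem: str) -> str:
    if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS + "s":
        stem = stem[:-1]
    elif stem[-1] in _E_RESTORE and stem[-2:] != "ee":
        stem = stem + "e"
    return stem


def tokenize(sentence_text: str) -> list[Token]:
    """Tokenise one sentence into surface/lemma tokens with offsets."""
    if not sentence_text:
        raise ValueError("cannot tokenise empty sentence text")
    return [
        Token(m.group(), lemmatize(m.group()), m.start(), m.end())
        for m in _TOKEN_RE.finditer(sentence_text)
    ]


_DIGIT_RE = re.compile(r"\d")


def normalise_for_tagger(token_surface: str) -> str:
    """Lowercase and map every decimal digit to zero.

    Applied only when building the span recogniser's input vocabulary, never
    in bag-of-words construction.
    """
    return _DIGIT_RE.sub("0", token_surface.lower())


@lru_cache(maxsize=2)
def load_stopwords(version: str = STOPWORDS_VERSION) -> frozenset[str]:
    """Load the stop word list shipped with the package."""
    path = Path(__file__).parent / "data" / f"stopwords-{version}.txt"
    words = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


def filter_bow_lemmata(
    tokens: Iterable, stopwords: frozenset[str] | set[str] | None = None
) -> set[str]:
    """Set of lemmata usable as bag-of-words features.

    Keeps lemmata that have more than one character, contain at least one
    letter or digit, and are not stop words.  ``tokens`` may be Token objects
    or plain lemma strings.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    out = set()
    for tok in tokens:
        lemma = tok.lemma if isinstance(tok, Token) else str(tok)
        if len(lemma) > 1 and any(c.isalnum() for c in lemma) and lemma not in stopwords:
            out.add(lemma)
    return out


@dataclass(frozen=True)
class RuleBasedPreprocessor:
    """The shipped deterministic preprocessor (splitter + tokeniser + lemmatiser).

    Its ``name`` is recorded in serialised corpora so that offsets stay
    interpretable across runs.
    """

    name: str = "picoscreen-rules-1"

    def split_sentences(self, text, doc_id="", field_name="title"):
        return split_sentences(text, doc_id, field_name)

    def tokenize(self, sentence_text):
        return tokenize(sentence_text)


DEFAULT_PREPROCESSOR = RuleBasedPreprocessor()


def preprocess_document(
    doc: Document, preprocessor: RuleBasedPreprocessor | None = None
) -> TaggedDocument:
    """Split and tokenise a document's title and abstract (no spans yet)."""
    pp = preprocessor or DEFAULT_PREPROCESSOR
    sentences: list[TokenizedSentence] = []
    for field_name in ("title", "abstract"):
        text = doc.field_text(field_name)
        for sent in pp.split_sentences(text, doc.id, field_name):
            stext = text[sent.char_start : sent.char_end]
            sentences.append(
                TokenizedSentence(
                    SentenceRef(doc.id, field_name, sent.index),
                    stext,
                    tuple(pp.tokenize(stext)),
                )
            )
    return TaggedDocument(doc, sentences, [], preprocessor=pp.name)


# ---------------------------------------------------------------------------
# Collections: CSV / TSV / RIS
# ---------------------------------------------------------------------------


def _parse_label(raw: str | None, doc_id: str) -> Label:
    if raw is None:
        return "unlabelled"
    val = str(raw).strip().lower()
    if not val:
        return "unlabelled"
    if val in _INCLUDED_ALIASES:
        return "included"
    if val in _EXCLUDED_ALIASES:
        return "excluded"
    raise CollectionError(f"document {doc_id!r}: cannot parse label {raw!r}")


def _format_label(label: Label) -> str:
    return {"included": "1", "excluded": "0", "unlabelled": ""}[label]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "tsv", "ris"):
        return suffix
    raise CollectionError(f"cannot infer collection format from {path.name!r}")


def read_collection(
    path: str | Path,
    format: str | None = None,
    name: str | None = None,
    ris_label_tag: str = "LB",
) -> Collection:
    """Read a screening collection from CSV, TSV or RIS.

    CSV/TSV files need columns ``id,title,abstract,label``; labels are parsed
    case-insensitively (1/include/included, 0/exclude/excluded, blank for
    unlabelled).  RIS records use TI/AB/ID tags with the label in
    ``ris_label_tag``.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        docs = _read_tabular(path, delimiter="," if fmt == "csv" else "\t")
    elif fmt == "ris":
        docs = _read_ris(path, ris_label_tag)
    else:
        raise CollectionError(f"unknown collection format {fmt!r}")
    return Collection(name or path.stem, docs)


def _read_tabular(path: Path, delimiter: str) -> list[Document]:
    docs = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        required = {"id", "title", "abstract", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CollectionError(
                f"{path.name}: expected columns id,title,abstract,label, "
                f"found {reader.fieldnames}"
            )
        for row in reader:
            doc_id = (row["id"] or "").strip()
            if not doc_id:
                raise CollectionError(f"{path.name}: record with missing id")
            title = (row["title"] or "").strip()
            if not title:
                raise CollectionError(f"{path.name}: document {doc_id!r} has no title")
            docs.append(
                Document(
                    id=doc_id,
                    title=title,
                    abstract=(row["abstract"] or "").strip(),
                    label=_parse_label(row["label"], doc_id),
                )
            )
    return docs


_RIS_TAG_RE = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


def _read_ris(path: Path, label_tag: str) -> list[Document]:
    docs = []
    record: dict[str, list[str]] = {}
    last_tag: str | None = None

    def flush():
        nonlocal record, last_tag
        if record:
            doc_id = " ".join(record.get("ID", [])).strip()
            title = " ".join(record.get("TI", [])).strip()
            if not doc_id:
                raise CollectionError(f"{path.name}: RIS record without ID tag")
            if not title:
                raise CollectionError(f"{path.name}: RIS record {doc_id!r} without TI tag")
            docs.append(
                Document(
                    id=doc_id,
                    title=title,
                    abstract=" ".join(record.get("AB", [])).strip(),
                    label=_parse_label(" ".join(record.get(label_tag, [])) or None, doc_id),
                )
            )
        record, last_tag = {}, None

    for line in path.read_text(encoding="utf-8").splitlines():
        m = _RIS_TAG_RE.match(line)
        if m:
            tag, value = m.group(1), m.group(2)
            if tag == "ER":
                flush()
            else:
                record.setdefault(tag, []).append(value)
                last_tag = tag
        elif line.strip() and last_tag is not None:
            record[last_tag].append(line.strip())
    flush()
    return docs


def write_collection(
    collection: Collection,
    path: str | Path,
    format: str | None = None,
    ris_label_tag: str = "LB",
) -> None:
    """Write a collection as CSV, TSV or RIS (UTF-8)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="," if fmt == "csv" else "\t")
            writer.writerow(["id", "title", "abstract", "label"])
            for doc in collection:
                writer.writerow([doc.id, doc.title, doc.abstract, _format_label(doc.label)])
    elif fmt == "ris":
        lines = []
        for doc in collection:
            lines.append("TY  - JOUR")
            lines.append(f"ID  - {doc.id}")
            lines.append(f"TI  - {doc.title}")
            if doc.abstract:
                lines.append(f"AB  - {doc.abstract}")
            if doc.label != "unlabelled":
                lines.append(f"{ris_label_tag}  - {_format_label(doc.label)}")
            lines.append("ER  - ")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise CollectionError(f"unknown collection format {fmt!r}")


# ---------------------------------------------------------------------------
# Annotated corpora: brat-style standoff and JSON lines
# ---------------------------------------------------------------------------

# In standoff output the document text is title + "\n" + abstract; span
# offsets index into that combined text.  Category names encode the
# hierarchy with underscores: "P", "I_Pharmacological", "O_Adverse_effect".


def _category_to_brat(category: str) -> str:
    return category.replace(".", "_").replace(" ", "_")


def _category_from_brat(name: str, known: set[str]) -> str:
    parts = name.split("_")
    candidates = [parts[0]] if len(parts) == 1 else [parts[0] + "." + " ".join(parts[1:])]
    for cand in candidates:
        if cand in known:
            return cand
    raise CorpusError(f"unknown span category {name!r}")


def _doc_text(doc: Document) -> str:
    return doc.title + "\n" + doc.abstract if doc.abstract else doc.title


def _char_span_to_token_span(tagged: TaggedDocument, start: int, end: int):
    """Locate a character span of the combined text on one sentence's tokens."""
    doc = tagged.document
    title_len = len(doc.title)
    if end <= title_len:
        field_name, offset = "title", 0
    elif start >= title_len + 1:
        field_name, offset = "abstract", title_len + 1
    else:
        raise CorpusError(f"span [{start},{end}) crosses the title/abstract boundary")
    fs, fe = start - offset, end - offset
    for sent, (s_start, s_end) in zip(
        tagged.sentences_for(field_name), _sentence_offsets(doc, field_name, tagged)
    ):
        if s_start <= fs and fe <= s_end:
            t_start = t_end = None
            for ti, tok in enumerate(sent.tokens):
                if tok.char_start + s_start == fs:
                    t_start = ti
                if tok.char_end + s_start == fe:
                    t_end = ti + 1
            if t_start is None or t_end is None:
                raise CorpusError(
                    f"span [{start},{end}) in {doc.id!r} does not align with token boundaries"
                )
            return sent.ref, t_start, t_end
    raise CorpusError(f"span [{start},{end}) in {doc.id!r} crosses a sentence boundary")


def _sentence_offsets(doc: Document, field_name: str, tagged: TaggedDocument):
    """Character offsets of each sentence within its field, recomputed by splitting."""
    text = doc.field_text(field_name)
    return [
        (s.char_start, s.char_end)
        for s in split_sentences(text, doc.id, field_name)  # type: ignore[arg-type]
    ]


def read_annotated_corpus(
    path: str | Path,
    format: str = "standoff",
    preprocessor: RuleBasedPreprocessor | None = None,
) -> list[TaggedDocument]:
    """Read a span-annotated corpus.

    ``standoff``: a directory of paired ``<id>.txt``/``<id>.ann`` files where
    the text file holds title and abstract separated by one newline and
    T-lines carry ``Tn<TAB>Category start end<TAB>text``.  ``jsonl``: one
    document per line with explicit sentences, tokens, and token-level spans.
    """
    from picoscreen.pico_tagger import default_category_set

    known = set(default_category_set().categories)
    path = Path(path)
    if format == "standoff":
        return _read_standoff(path, known, preprocessor)
    if format == "jsonl":
        return _read_jsonl(path, known)
    raise CorpusError(f"unknown corpus format {format!r}")


def _read_standoff(directory: Path, known, preprocessor) -> list[TaggedDocument]:
    from picoscreen.pico_tagger import SpanAnnotation

    tagged_docs = []
    for txt_path in sorted(directory.glob("*.txt")):
        doc_id = txt_path.stem
        text = txt_path.read_text(encoding="utf-8")
        title, _, abstract = text.partition("\n")
        doc = Document(id=doc_id, title=title, abstract=abstract)
        tagged = preprocess_document(doc, preprocessor)
        ann_path = txt_path.with_suffix(".ann")
        if ann_path.exists():
            for line in ann_path.read_text(encoding="utf-8").splitlines():
                if not line.startswith("T"):
                    continue
                try:
                    _tid, middle, _surface = line.split("\t", 2)
                    cat_name, start_s, end_s = middle.rsplit(" ", 2)
                    start, end = int(start_s), int(end_s)
                except ValueError as exc:
                    raise CorpusError(f"{ann_path.name}: malformed T-line {line!r}") from exc
                category = _category_from_brat(cat_name, known)
                ref, t_start, t_end = _char_span_to_token_span(tagged, start, end)
                tagged.spans.append(SpanAnnotation(category, ref, t_start, t_end))
        tagged_docs.append(tagged)
    return tagged_docs


def _read_jsonl(path: Path, known) -> list[TaggedDocument]:
    from picoscreen.pico_tagger import SpanAnnotation

    tagged_docs = []
    for line_no, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        rec = json.loads(line)
        doc = Document(
            id=rec["id"],
            title=rec["title"],
            abstract=rec.get("abstract", ""),
            label=rec.get("label", "unlabelled"),
        )
        sentences = []
        for s in rec["sentences"]:
            tokens = tuple(
                Token(t["surface"], t["lemma"], t["char_start"], t["char_end"])
                for t in s["tokens"]
            )
            sentences.append(
                TokenizedSentence(
                    SentenceRef(doc.id, s["field"], s["index"]), s["text"], tokens
                )
            )
        tagged = TaggedDocument(doc, sentences, [], rec.get("preprocessor", ""))
        n_tokens_by_ref = {s.ref: len(s.tokens) for s in sentences}
        for sp in rec.get("spans", []):
            if sp["category"] not in known:
                raise CorpusError(f"line {line_no}: unknown category {sp['category']!r}")
            ref = SentenceRef(doc.id, sp["field"], sp["sentence_index"])
            if ref not in n_tokens_by_ref:
                raise CorpusError(f"line {line_no}: span references unknown sentence {ref}")
            t_start, t_end = sp["token_start"], sp["token_end"]
            if not (0 <= t_start < t_end <= n_tokens_by_ref[ref]):
                raise CorpusError(
                    f"line {line_no}: span [{t_start},{t_end}) outside sentence of "
                    f"{n_tokens_by_ref[ref]} tokens"
                )
            tagged.spans.append(SpanAnnotation(sp["category"], ref, t_start, t_end))
        tagged_docs.append(tagged)
    return tagged_docs


def write_annotated_corpus(
    tagged_docs: list[TaggedDocument], path: str | Path, format: str = "standoff"
) -> None:
    """Write an annotated corpus as standoff files (to a directory) or JSON lines."""
    path = Path(path)
    if format == "standoff":
        path.mkdir(parents=True, exist_ok=True)
        for tagged in tagged_docs:
            doc = tagged.document
            text = _doc_text(doc)
            (path / f"{doc.id}.txt").write_text(text, encoding="utf-8")
            lines = []
            for i, span in enumerate(tagged.spans, 1):
                start, end = _token_span_to_char_span(tagged, span)
                surface = text[start:end]
                lines.append(
                    f"T{i}\t{_category_to_brat(span.category)} {start} {end}\t{surface}"
                )
            (path / f"{doc.id}.ann").write_text(
                "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
            )
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for tagged in tagged_docs:
                fh.write(json.dumps(_tagged_to_json(tagged), ensure_ascii=False) + "\n")
    else:
        raise CorpusError(f"unknown corpus format {format!r}")


def _token_span_to_char_span(tagged: TaggedDocument, span) -> tuple[int, int]:
    doc = tagged.document
    ref = span.sentence_ref
    sent = tagged.sentence(ref)
    offsets = _sentence_offsets(doc, ref.field, tagged)
    s_start = offsets[ref.sentence_index][0]
    field_offset = 0 if ref.field == "title" else len(doc.title) + 1
    tok_first = sent.tokens[span.token_start]
    tok_last = sent.tokens[span.token_end - 1]
    return (
        field_offset + s_start + tok_first.char_start,
        field_offset + s_start + tok_last.char_end,
    )


def _tagged_to_json(tagged: TaggedDocument) -> dict:
    doc = tagged.document
    return {
        "id": doc.id,
        "title": doc.title,
        "abstract": doc.abstract,
        "label": doc.label,
        "preprocessor": tagged.preprocessor,
        "sentences": [
            {
                "field": s.ref.field,
                "index": s.ref.sentence_index,
                "text": s.text,
                "tokens": [
                    {
                        "surface": t.surface,
                        "lemma": t.lemma,
                        "char_start": t.char_start,
                        "char_end": t.char_end,
                    }
                    for t in s.tokens
                ],
            }
            for s in tagged.sentences
        ],
        "spans": [
            {
                "category": sp.category,
                "field": sp.sentence_ref.field,
                "sentence_index": sp.sentence_ref.sentence_index,
                "token_start": sp.token_start,
                "token_end": sp.token_end,
            }
            for sp in tagged.spans
        ],
    }
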