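"""Layered IOB encoding of nested spans.

A sentence's nested spans are flattened into an ordered list of IOB tag
sequences ("layers"), beginning with the innermost / fine-grained spans and
moving outward to the top-level spans.  Layer membership is determined by
two rules applied in order:

1. category rank — fine-grained spans come before top-level spans;
2. structural nesting within a rank — a span strictly contained in more
   spans of its rank sits in an earlier layer.

For the standard annotation scheme (fine-grained spans nested inside
top-level spans, fine-grained mutually non-nesting) this yields exactly the
fine layer followed by one or more top-level layers.  For coarse-only
corpora where top-level spans nest inside each other, the inner top-level
spans occupy the earlier layers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

from picoscreen.textprep import SentenceRef

__all__ = ["SpanAnnotation", "TagLayer", "NestingError", "encode_nested_spans", "decode_iob"]


class NestingError(ValueError):
    """Raised when spans cannot be expressed as layered IOB sequences."""


@dataclass(frozen=True, order=True)
class SpanAnnotation:
    """A category span over a half-open token interval of one sentence."""

    category: str
    sentence_ref: SentenceRef
    token_start: int
    token_end: int
    depth: int = 0  # layer index assigned at encode/predict time; 0 = innermost

    def __post_init__(self) -> None:
        if self.token_start >= self.token_end:
            raise ValueError(
                f"span {self.category} [{self.token_start},{self.token_end}) is empty"
            )

    def with_category(self, category: str) -> "SpanAnnotation":
        return replace(self, category=category)

    def interval(self) -> tuple[int, int]:
        return (self.token_start, self.token_end)

    def key(self) -> tuple:
        """Identity ignoring depth, used for span-level comparisons."""
        return (self.sentence_ref, self.category, self.token_start, self.token_end)


@dataclass(frozen=True)
class TagLayer:
    """One IOB sequence for one sentence at one nesting depth (0 = innermost)."""

    sentence_ref: SentenceRef
    layer_index: int
    tags: tuple[str, ...]


def _strictly_contains(outer: SpanAnnotation, inner: SpanAnnotation) -> bool:
    return (
        outer.token_start <= inner.token_start
        and inner.token_end <= outer.token_end
        and (outer.token_start, outer.token_end) != (inner.token_start, inner.token_end)
    )


def _partial_overlap(a: SpanAnnotation, b: SpanAnnotation) -> bool:
    if a.token_end <= b.token_start or b.token_end <= a.token_start:
        return False
    return not (
        _strictly_contains(a, b)
        or _strictly_contains(b, a)
        or a.interval() == b.interval()
    )


def _layer_by_nesting(spans: list[SpanAnnotation]) -> list[list[SpanAnnotation]]:
    """Group spans of one rank into layers, innermost first.

    A span's ancestor count is the number of same-rank spans strictly
    containing it; spans with the most ancestors form layer 0 of the group.
    """
    if not spans:
        return []
    ancestors = [
        sum(_strictly_contains(other, s) for other in spans if other is not s)
        for s in spans
    ]
    max_anc = max(ancestors)
    layers: list[list[SpanAnnotation]] = [[] for _ in range(max_anc + 1)]
    for span, anc in zip(spans, ancestors):
        layers[max_anc - anc].append(span)
    return layers


def encode_nested_spans(
    spans,
    n_tokens: int,
    max_layers: int | None = None,
    sentence_ref: SentenceRef | None = None,
    tag_fine_first: bool = True,
    pad_fine: bool = False,
) -> list[TagLayer]:
    """Encode one sentence's nested spans as an ordered list of IOB layers.

    ``pad_fine`` forces an (all-O) fine-grained layer 0 even when no
    fine-grained span exists; training targets use this so that the first
    decoding iteration always corresponds to the fine-grained pass.
    Raises :class:`NestingError` on spans that partially overlap within a
    computed layer or exceed ``n_tokens``.
    """
    spans = list(spans)
    if sentence_ref is None:
        sentence_ref = spans[0].sentence_ref if spans else SentenceRef("", "title", 0)
    for span in spans:
        if span.sentence_ref != sentence_ref:
            raise NestingError(f"span {span} does not belong to sentence {sentence_ref}")
        if span.token_end > n_tokens or span.token_start < 0:
            raise NestingError(
                f"span {span.category} [{span.token_start},{span.token_end}) exceeds "
                f"sentence of {n_tokens} tokens"
            )

    if tag_fine_first:
        fine = [s for s in spans if "." in s.category]
        top = [s for s in spans if "." not in s.category]
    else:
        fine, top = [], spans

    groups = _layer_by_nesting(fine)
    if pad_fine and not groups:
        groups = [[]]
    groups += _layer_by_nesting(top)
    if not groups:
        groups = [[]]

    if max_layers is not None and len(groups) > max_layers:
        raise NestingError(
            f"spans require {len(groups)} layers but max_layers={max_layers}"
        )

    layers = []
    for idx, group in enumerate(groups):
        tags = ["O"] * n_tokens
        for span in sorted(group, key=lambda s: s.interval()):
            for other in group:
                if other is not span and _partial_overlap(span, other):
                    raise NestingError(
                        f"layer {idx}: spans {span.category}{span.interval()} and "
                        f"{other.category}{other.interval()} partially overlap"
                    )
                if other is not span and (
                    other.interval() == span.interval()
                    or _strictly_contains(other, span)
                    or _strictly_contains(span, other)
                ):
                    raise NestingError(
                        f"layer {idx}: spans {span.category}{span.interval()} and "
                        f"{other.category}{other.interval()} cannot share a layer"
                    )
            tags[span.token_start] = f"B-{span.category}"
            for t in range(span.token_start + 1, span.token_end):
                tags[t] = f"I-{span.category}"
        layers.append(TagLayer(sentence_ref, idx, tuple(tags)))
    return layers


def decode_iob(
    layer: TagLayer, mode: Literal["lenient", "strict"] = "lenient"
) -> list[SpanAnnotation]:
    """Decode one IOB layer back into spans.

    Maximal B-led runs become spans.  An ``I-c`` that does not continue a
    ``B-c``/``I-c`` run is repaired to ``B-c`` in lenient mode and rejected
    in strict mode.
    """
    spans: list[SpanAnnotation] = []
    current_cat: str | None = None
    current_start = 0
    for pos, tag in enumerate(layer.tags):
        if tag == "O":
            prefix, cat = "O", None
        elif tag[:2] in ("B-", "I-"):
            prefix, cat = tag[0], tag[2:]
        else:
            raise ValueError(f"position {pos}: unknown tag {tag!r}")
        continues = prefix == "I" and cat == current_cat
        if prefix == "I" and not continues:
            if mode == "strict":
                raise ValueError(
                    f"position {pos}: tag {tag!r} does not continue a span of {cat!r}"
                )
            prefix = "B"  # lenient repair
        if current_cat is not None and not continues:
            spans.append(
                SpanAnnotation(
                    current_cat, layer.sentence_ref, current_start, pos, layer.layer_index
                )
            )
            current_cat = None
        if prefix == "B":
            current_cat, current_start = cat, pos
    if current_cat is not None:
        spans.append(
            SpanAnnotation(
                current_cat, layer.sentence_ref, current_start, len(layer.tags),
                layer.layer_index,
            )
        )
    return spans
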