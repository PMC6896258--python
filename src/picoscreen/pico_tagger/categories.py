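"""The PICO category hierarchy and its IOB tag set.

Three top-level elements — Patient/population (P), Intervention/comparator
(I, comparators merged into interventions) and Outcome (O) — carry 17
fine-grained subtypes.  Fine-grained categories are written ``parent.name``,
e.g. ``"I.Pharmacological"``.  The IOB tag set holds a B- and an I- tag per
category plus the single outside tag: 2 x (3 + 17) + 1 = 41 tags for the
default hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

TOP_LEVEL = ("P", "I", "O")

FINE_GRAINED: dict[str, tuple[str, ...]] = {
    "P": ("Age", "Condition", "Sample size", "Sex"),
    "I": (
        "Control",
        "Educational",
        "Pharmacological",
        "Physical",
        "Psychological",
        "Surgical",
        "Other",
    ),
    "O": ("Adverse effect", "Mental", "Mortality", "Pain", "Physical", "Other"),
}

@dataclass(frozen=True)
class CategorySet:
    """An ordered set of span categories (top-level and fine-grained)."""

    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("empty category set")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("duplicate categories")

    @property
    def top_level(self) -> tuple[str, ...]:
        return tuple(c for c in self.categories if "." not in c)

    @property
    def fine_grained(self) -> tuple[str, ...]:
        return tuple(c for c in self.categories if "." in c)

    def __contains__(self, category: str) -> bool:
        return category in self.categories

    def __len__(self) -> int:
        return len(self.categories)


def default_category_set() -> CategorySet:
    """The full hierarchy: 3 top-level plus 17 fine-grained categories.

    Order is deterministic: each top-level category followed by its
    fine-grained subtypes.
    """
    cats: list[str] = []
    for top in TOP_LEVEL:
        cats.append(top)
        cats.extend(f"{top}.{fine}" for fine in FINE_GRAINED[top])
    return CategorySet(tuple(cats))


def parent_category(category: str) -> str:
    """Top-level parent of a category (identity for top-level)."""
    return category.split(".", 1)[0]


def tagset(categories: CategorySet) -> list[str]:
    """Ordered IOB tag list: ``B-c``, ``I-c`` per category, then ``"O"``."""
    tags: list[str] = []
    for c in categories.categories:
        tags.append(f"B-{c}")
        tags.append(f"I-{c}")
    tags.append("O")
    return tags


def map_to_coarse(spans):
    """Relabel fine-grained spans to their top-level parent, merging duplicates.

    Two spans that collapse onto the same (sentence, interval, category) are
    merged into one.  Input order is preserved for first occurrences.
    """
    seen = set()
    out = []
    for span in spans:
        coarse = span.with_category(parent_category(span.category))
        key = (coarse.sentence_ref, coarse.token_start, coarse.token_end, coarse.category)
        if key not in seen:
            seen.add(key)
            out.append(coarse)
    return out
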