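"""End-to-end flows: tag a collection, then benchmark PICO vs baseline features.

These functions tie the stages together the way a screening study runs them:
the recogniser tags every document, feature matrices are built once per
feature mode (representation is fixed before any simulated screening), and
Monte Carlo simulations compare work saved with and without the PICO bags.
"""

from __future__ import annotations

from dataclasses import dataclass

from picoscreen.evaluation import sign_test_from_deltas
from picoscreen.features import TopicModelConfig, build_feature_matrix
from picoscreen.pico_tagger import TaggerModel, tag_document
from picoscreen.screening import SimulationConfig, monte_carlo
from picoscreen.textprep import Collection, TaggedDocument, preprocess_document

__all__ = ["BenchmarkRow", "BenchmarkReport", "tag_collection", "run_benchmark"]


def tag_collection(
    model: TaggerModel, collection: Collection
) -> list[TaggedDocument]:
    """Preprocess and tag every document of a collection (idempotent)."""
    return [tag_document(model, preprocess_document(doc)) for doc in collection]


@dataclass
class BenchmarkRow:
    collection: str
    wss95_baseline: float
    wss95_pico: float
    sd_baseline: float
    sd_pico: float

    @property
    def delta(self) -> float:
        return self.wss95_pico - self.wss95_baseline


@dataclass
class BenchmarkReport:
    rows: list[BenchmarkRow]
    sign_test_p: float
    successes: int
    n: int

    def render(self) -> str:
        """Plain-text table: per-collection WSS@95% for LR and PICO plus delta."""
        lines = [f"{'Collection':<28}{'LR':>8}{'PICO':>8}{'Delta':>8}"]
        for row in self.rows:
            lines.append(
                f"{row.collection:<28}{row.wss95_baseline:>8.3f}"
                f"{row.wss95_pico:>8.3f}{row.delta:>+8.3f}"
            )
        lines.append(
            f"sign test: {self.successes}/{self.n} improved, one-sided p = "
            f"{self.sign_test_p:.4f}"
        )
        return "\n".join(lines)


def run_benchmark(
    tagged_collections: list[tuple[str, list[TaggedDocument]]],
    sim_config: SimulationConfig | None = None,
    topic_config: TopicModelConfig | None = None,
) -> BenchmarkReport:
    """Monte Carlo WSS@95% with baseline and PICO features per collection.

    Each collection is a (name, tagged documents) pair with labels and spans
    attached.  The per-collection delta (PICO minus baseline mean WSS@95%)
    feeds a one-sided sign test across collections (zero deltas counted as
    successes).
    """
    if not tagged_collections:
        raise ValueError("no collections to benchmark")
    sim_config = sim_config or SimulationConfig()
    rows = []
    for name, tagged_docs in tagged_collections:
        labels = [t.document.label == "included" for t in tagged_docs]
        ids = [t.document.id for t in tagged_docs]
        results = {}
        for mode in ("baseline", "pico"):
            X, _ = build_feature_matrix(tagged_docs, mode=mode, topic_config=topic_config)
            results[mode] = monte_carlo(X, labels, ids, sim_config)
        rows.append(
            BenchmarkRow(
                collection=name,
                wss95_baseline=results["baseline"]["mean"],
                wss95_pico=results["pico"]["mean"],
                sd_baseline=results["baseline"]["sd"],
                sd_pico=results["pico"]["sd"],
            )
        )
    p, successes, n = sign_test_from_deltas([r.delta for r in rows])
    return BenchmarkReport(rows=rows, sign_test_p=p, successes=successes, n=n)
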