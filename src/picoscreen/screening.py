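"""Relevancy classification and screening protocols.

Two simulation protocols are provided, both repeated over Monte Carlo
trials:

* relevance feedback — a random seed batch of 25 references (re-drawn until
  it contains at least one relevant reference) trains an L2-regularised
  logistic regression; the 25 top-scored unscreened references join the
  training set, the classifier is retrained, and so on until the whole
  collection is screened;
* stratified two-fold — half of each class trains a single classifier that
  ranks the held-out half.

The classifier minimises ``0.5 ||w||^2 + C sum log(1 + exp(-y (w.x + b)))``
with C = 1 and an unregularised intercept; ranking scores are posterior
probabilities from the logistic transform of the margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression

from picoscreen.evaluation import wss95, recall_curve

__all__ = [
    "ClassifierConfig",
    "SimulationConfig",
    "Trajectory",
    "train_classifier",
    "score",
    "simulate_feedback",
    "run_twofold",
    "monte_carlo",
]


@dataclass(frozen=True)
class ClassifierConfig:
    C: float = 1.0
    tol: float = 1e-6
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    batch_size: int = 25
    n_trials: int = 100
    base_seed: int = 0
    mode: str = "feedback"  # or "twofold"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.n_trials < 1:
            raise ValueError("batch_size and n_trials must be >= 1")
        if self.mode not in ("feedback", "twofold"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")


@dataclass
class Trajectory:
    """One screening order: document ids, their labels, and the trial seed."""

    doc_ids: list[str]
    labels: list[bool]
    trial_seed: int


def train_classifier(X, y, config: ClassifierConfig | None = None) -> LogisticRegression:
    """Fit the L2-regularised logistic regression (deterministic given data)."""
    config = config or ClassifierConfig()
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    # default penalty is the L2 norm; the intercept is not regularised
    model = LogisticRegression(
        C=config.C, solver="lbfgs", tol=config.tol, max_iter=config.max_iter
    )
    model.fit(X, y)
    return model


def score(model: LogisticRegression, X) -> np.ndarray:
    """Posterior probability of relevance; ranking equals ranking by margin."""
    if X.shape[1] != model.coef_.shape[1]:
        raise ValueError("feature dimension mismatch between model and X")
    return model.predict_proba(X)[:, 1]


def _ordered_by_score(probs, ids_subset):
    # descending probability; ties by ascending doc id
    order = sorted(range(len(ids_subset)), key=lambda i: (-probs[i], ids_subset[i]))
    return order


def simulate_feedback(
    X: sp.csr_matrix,
    labels,
    doc_ids: list[str],
    config: SimulationConfig,
    trial_seed: int,
) -> Trajectory:
    """One relevance-feedback trial; returns the full screening order.

    The trajectory is always a permutation of the collection.  If at some
    retrain the screened labels are single-class (a seed batch with no
    irrelevant reference), that iteration falls back to a random batch.
    """
    labels = np.asarray(labels, dtype=bool)
    n = len(doc_ids)
    if labels.sum() == 0:
        raise ValueError("collection contains no relevant documents")
    rng = np.random.default_rng(trial_seed)
    permutation = rng.permutation(n)
    b = config.batch_size

    screened: list[int] = []
    cursor = 0
    while cursor < n:
        batch = list(permutation[cursor : cursor + b])
        screened.extend(batch)
        cursor += b
        if labels[batch].any():
            break

    remaining = [i for i in permutation[cursor:]]
    while remaining:
        y_screened = labels[screened]
        if y_screened.all() or not y_screened.any():
            batch = remaining[:b]  # single-class fallback: random order
        else:
            model = train_classifier(X[screened], y_screened, config.classifier)
            probs = score(model, X[remaining])
            order = _ordered_by_score(probs, [doc_ids[i] for i in remaining])
            batch = [remaining[i] for i in order[:b]]
        screened.extend(batch)
        batch_set = set(batch)
        remaining = [i for i in remaining if i not in batch_set]

    return Trajectory(
        [doc_ids[i] for i in screened], [bool(labels[i]) for i in screened], trial_seed
    )


def run_twofold(
    X: sp.csr_matrix,
    labels,
    doc_ids: list[str],
    config: SimulationConfig,
    trial_seed: int,
) -> Trajectory:
    """One stratified two-fold trial: train on half of each class, rank the rest.

    With odd class counts the training half receives the floor.
    """
    labels = np.asarray(labels, dtype=bool)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("stratified two-fold needs at least 2 documents per class")
    rng = np.random.default_rng(trial_seed)
    pos = rng.permutation(pos)
    neg = rng.permutation(neg)
    train_idx = np.concatenate([pos[: len(pos) // 2], neg[: len(neg) // 2]])
    test_idx = np.concatenate([pos[len(pos) // 2 :], neg[len(neg) // 2 :]])
    model = train_classifier(X[train_idx], labels[train_idx], config.classifier)
    probs = score(model, X[test_idx])
    order = _ordered_by_score(probs, [doc_ids[i] for i in test_idx])
    ranked = [test_idx[i] for i in order]
    return Trajectory(
        [doc_ids[i] for i in ranked], [bool(labels[i]) for i in ranked], trial_seed
    )


def monte_carlo(
    X: sp.csr_matrix,
    labels,
    doc_ids: list[str],
    config: SimulationConfig,
) -> dict:
    """Run ``n_trials`` simulations (trial t seeded ``base_seed + t``).

    Returns ``{"mean": .., "sd": .., "per_trial": [..], "mode": ..}`` of
    WSS@95% across trials.
    """
    run = simulate_feedback if config.mode == "feedback" else run_twofold
    values = []
    for t in range(config.n_trials):
        traj = run(X, labels, doc_ids, config, config.base_seed + t)
        curve = recall_curve(traj.labels)
        values.append(wss95(curve).wss95)
    values = np.asarray(values)
    return {
        "mode": config.mode,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "per_trial": [float(v) for v in values],
    }
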