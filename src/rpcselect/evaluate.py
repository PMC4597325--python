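"""Evaluation instruments: selection-stability entropy and cluster purity.

Stability: the whole CV-plus-selection pipeline is repeated with different
Gibbs seeds; the frequencies of the chosen topic numbers, normalized to a
distribution P, are scored by Shannon entropy, entropy(P) = sum_i -P_i
log2 P_i. A lower entropy means the selector lands on the same answer more
consistently — the axis on which the RPC change point is compared with
minimum perplexity.

Purity: clusters of the document-topic matrix are labelled by their
dominant true label; overall purity is the size-weighted fraction of
documents carrying their cluster's dominant label, and the misclassified
count is its complement.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .corpus import Corpus
from .lda import GibbsLDA
from .modelsel import (
    PerplexityCurve,
    compute_rpc,
    cross_validate_perplexity,
    select_change_point,
    select_min_perplexity,
)

__all__ = [
    "ClusterEvaluation",
    "SelectionDistribution",
    "StabilityResult",
    "cluster_doc_topics",
    "cluster_purity",
    "shannon_entropy",
    "stability_experiment",
    "top_words",
]


@dataclass
class SelectionDistribution:
    """Frequencies of chosen topic numbers over repeated seeded runs."""

    counts: dict[int, int]
    total: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be nonnegative")
        if sum(self.counts.values()) != self.total:
            raise ValueError("counts must sum to the total number of runs")

    def probabilities(self) -> dict[int, float]:
        return {k: v / self.total for k, v in self.counts.items() if v > 0}


def shannon_entropy(dist: SelectionDistribution | dict[int, int]) -> float:
    """Shannon entropy (bits) of the normalized selection frequencies.

    entropy(P) = sum_i -P_i log2 P_i; zero-count outcomes contribute 0.
    """
    if isinstance(dist, dict):
        dist = SelectionDistribution(counts=dict(dist), total=sum(dist.values()))
    if dist.total <= 0:
        raise ValueError("empty selection distribution")
    p = np.array([v for v in dist.probabilities().values()])
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


@dataclass
class StabilityResult:
    """Per-selector selection distributions, entropies and the raw curves."""

    distributions: dict[str, SelectionDistribution]
    entropies: dict[str, float]
    selections: dict[str, list[int]]
    curves: list[PerplexityCurve] = field(repr=False, default_factory=list)


def stability_experiment(
    corpus: Corpus,
    candidates,
    m_folds: int,
    repeats: int,
    base_seed: int = 0,
    selectors: tuple[str, ...] = ("rpc", "min_perplexity"),
    **lda_params,
) -> StabilityResult:
    """Repeat the CV-select pipeline with seeds base_seed+1..base_seed+repeats.

    One cross-validated perplexity curve is computed per repeat and every
    selector is applied to that same curve, so the selectors are compared
    on identical evidence. Returns frequency tables and entropies per
    selector, plus the curves for downstream inspection.
    """
    if repeats < 2:
        raise ValueError("need at least 2 repeats for a stability estimate")
    chosen: dict[str, list[int]] = {s: [] for s in selectors}
    curves = []
    for r in range(1, repeats + 1):
        curve = cross_validate_perplexity(
            corpus, candidates=candidates, m_folds=m_folds,
            seed=base_seed + r, **lda_params)
        curves.append(curve)
        for s in selectors:
            if s == "rpc":
                chosen[s].append(select_change_point(compute_rpc(curve)).chosen)
            elif s == "min_perplexity":
                chosen[s].append(select_min_perplexity(curve).chosen)
            else:
                raise ValueError(f"unknown selector {s!r}")
    distributions = {
        s: SelectionDistribution(counts=dict(Counter(v)), total=repeats)
        for s, v in chosen.items()
    }
    entropies = {s: shannon_entropy(d) for s, d in distributions.items()}
    return StabilityResult(distributions=distributions, entropies=entropies,
                           selections=chosen, curves=curves)


@dataclass
class ClusterEvaluation:
    """Purity bookkeeping for one clustering against true labels."""

    assignment: dict[str, int]
    labels: dict[str, str]
    dominant_label: dict[int, str]
    cluster_purity: dict[int, float]
    purity: float
    misclassified: int
    n_docs: int


def cluster_purity(assignment, labels) -> ClusterEvaluation:
    """Size-weighted cluster purity against true labels.

    ``assignment`` and ``labels`` are either dicts keyed by document id or
    aligned sequences. Per cluster: purity = dominant-label fraction.
    Overall: sum of dominant-label counts / N; misclassified = N - that sum.
    """
    if not isinstance(assignment, dict):
        assignment = {str(i): c for i, c in enumerate(assignment)}
    if not isinstance(labels, dict):
        labels = {str(i): l for i, l in enumerate(labels)}
    if not assignment:
        raise ValueError("empty clustering")
    missing = set(assignment) - set(labels)
    if missing:
        raise ValueError(f"documents without labels: {sorted(missing)[:5]}")
    members: dict[int, list[str]] = {}
    for doc, c in assignment.items():
        members.setdefault(c, []).append(doc)
    dominant, per_purity = {}, {}
    correct = 0
    for c, docs in members.items():
        tally = Counter(labels[d] for d in docs)
        lab, cnt = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
        dominant[c] = lab
        per_purity[c] = cnt / len(docs)
        correct += cnt
    n = len(assignment)
    return ClusterEvaluation(
        assignment=dict(assignment), labels={d: labels[d] for d in assignment},
        dominant_label=dominant, cluster_purity=per_purity,
        purity=correct / n, misclassified=n - correct, n_docs=n,
    )


def cluster_doc_topics(
    theta: np.ndarray,
    method: str = "kmeans",
    n_clusters: int = 10,
    cut_height: float | None = None,
    linkage_method: str = "average",
    metric: str = "euclidean",
    n_init: int = 10,
    random_state: int = 0,
) -> np.ndarray:
    """Cluster document-topic proportion rows; returns integer cluster ids.

    ``hierarchical`` is agglomerative (default average linkage, Euclidean)
    with flat clusters cut at ``cut_height`` (required); ``kmeans`` uses
    ``n_clusters`` with seeded restarts keeping the best inertia. A cut
    yielding a single cluster or all-singleton clusters is returned with a
    warning rather than rejected.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2:
        raise ValueError("theta must be 2-D (documents x topics)")
    if method == "hierarchical":
        if cut_height is None:
            raise ValueError("hierarchical clustering requires cut_height")
        Z = linkage(theta, method=linkage_method, metric=metric)
        ids = fcluster(Z, t=cut_height, criterion="distance")
        k = len(np.unique(ids))
        if k == 1 or k == theta.shape[0]:
            warnings.warn(
                f"cut height {cut_height} produced {k} cluster(s) for "
                f"{theta.shape[0]} documents", stacklevel=2)
        return ids.astype(np.int64)
    if method == "kmeans":
        km = KMeans(n_clusters=n_clusters, n_init=n_init,
                    random_state=random_state)
        return km.fit_predict(theta).astype(np.int64)
    raise ValueError(f"unknown method {method!r}")


def top_words(model: GibbsLDA, n: int) -> pd.DataFrame:
    """Per-topic ranked top-n words with probabilities.

    Columns: topic, rank (1-based), word, weight; weights descending with
    ties broken by vocabulary order. ``n`` larger than the vocabulary is
    clamped. Suitable as input for any word-cloud renderer.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    phi = model.components_
    vocab = model.vocabulary_
    V = phi.shape[1]
    n = min(n, V)
    rows = []
    idx = np.arange(V)
    for t in range(phi.shape[0]):
        order = np.lexsort((idx, -phi[t]))[:n]
        for r, j in enumerate(order, start=1):
            rows.append((t, r, vocab[j], float(phi[t, j])))
    return pd.DataFrame(rows, columns=["topic", "rank", "word", "weight"])
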