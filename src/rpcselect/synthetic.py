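"""Synthetic data generators with planted ground truth.

Every stage of the pipeline is testable without external data: corpora
drawn from the LDA generative process with a known topic count, an
easy-mode separable corpus with disjoint topic word blocks, a
group-structured SNP alignment emulating bacterial strain sequencing, and
a block-structured binary entity-feature matrix emulating drug /
side-effect profiles. All generators are deterministic under their seed
and return machine-readable ground truth alongside the data.

Default scales mirror the real corpora the pipeline targets (hundreds of
documents, vocabularies of a few thousand, 10^2-10^3 tokens per document)
shrunk to desk size: M=200, V=500, 100 tokens per document.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import AlignedSequences, BinaryMatrix, Corpus

__all__ = [
    "PlantedModel",
    "generate_binary_profiles",
    "generate_lda_corpus",
    "generate_separable_corpus",
    "generate_snp_alignment",
]

_NUC = np.array(list("ACGT"))


@dataclass
class PlantedModel:
    """Ground truth for a generated corpus."""

    n_topics: int
    phi: np.ndarray          # (K, V), rows sum to 1
    theta: np.ndarray        # (M, K), rows sum to 1
    alpha_gen: float
    beta_gen: float
    labels: list[str]        # dominant-topic label per document
    seed: int


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed) % (2**31)))


def generate_lda_corpus(
    n_docs: int = 200,
    vocab_size: int = 500,
    n_topics: int = 20,
    doc_len: int = 100,
    alpha_gen: float = 0.1,
    beta_gen: float = 0.01,
    seed: int = 0,
) -> tuple[Corpus, PlantedModel]:
    """Run the LDA generative process forward with a planted topic count.

    phi_t ~ Dirichlet(beta_gen) over the vocabulary, theta_d ~
    Dirichlet(alpha_gen) over topics; each token draws topic ~ theta_d then
    word ~ phi_topic. Document labels are argmax theta_d.
    """
    if min(n_docs, vocab_size, n_topics) < 1 or doc_len < 0:
        raise ValueError("sizes must be >= 1 (doc_len >= 0)")
    if alpha_gen <= 0 or beta_gen <= 0:
        raise ValueError("concentrations must be > 0")
    rng = _rng(seed)
    phi = rng.dirichlet(np.full(vocab_size, beta_gen), size=n_topics)
    theta = rng.dirichlet(np.full(n_topics, alpha_gen), size=n_docs)
    documents = []
    for d in range(n_docs):
        topics = rng.choice(n_topics, size=doc_len, p=theta[d])
        words = np.empty(doc_len, dtype=np.int64)
        for t in np.unique(topics):
            mask = topics == t
            words[mask] = rng.choice(vocab_size, size=int(mask.sum()), p=phi[t])
        documents.append(words)
    corpus = Corpus(
        documents=documents,
        vocabulary=[f"w{j}" for j in range(vocab_size)],
        doc_ids=[f"doc{d + 1}" for d in range(n_docs)],
    )
    planted = PlantedModel(
        n_topics=n_topics, phi=phi, theta=theta, alpha_gen=alpha_gen,
        beta_gen=beta_gen,
        labels=[f"topic{int(t)}" for t in theta.argmax(axis=1)], seed=seed,
    )
    return corpus, planted


def generate_separable_corpus(
    n_docs: int = 100,
    n_topics: int = 2,
    words_per_topic: int = 20,
    doc_len: int = 50,
    seed: int = 0,
) -> tuple[Corpus, PlantedModel]:
    """Easy-mode corpus: each topic uniform over its private word block.

    Each document draws a primary topic uniformly; with probability 1/2 a
    secondary topic is mixed in at weight 0.3. Because topic word supports
    are disjoint, recovered topic-word rows can be matched to planted ones
    unambiguously — the fixture for posterior-recovery tests.
    """
    rng = _rng(seed)
    V = n_topics * words_per_topic
    phi = np.zeros((n_topics, V))
    for t in range(n_topics):
        phi[t, t * words_per_topic:(t + 1) * words_per_topic] = 1.0 / words_per_topic
    theta = np.zeros((n_docs, n_topics))
    for d in range(n_docs):
        primary = rng.integers(n_topics)
        if n_topics > 1 and rng.random() < 0.5:
            secondary = (primary + 1 + rng.integers(n_topics - 1)) % n_topics
            theta[d, primary], theta[d, secondary] = 0.7, 0.3
        else:
            theta[d, primary] = 1.0
    documents = []
    for d in range(n_docs):
        topics = rng.choice(n_topics, size=doc_len, p=theta[d])
        offsets = rng.integers(words_per_topic, size=doc_len)
        documents.append(topics * words_per_topic + offsets)
    corpus = Corpus(
        documents=documents,
        vocabulary=[f"w{j}" for j in range(V)],
        doc_ids=[f"doc{d + 1}" for d in range(n_docs)],
    )
    planted = PlantedModel(
        n_topics=n_topics, phi=phi, theta=theta, alpha_gen=float("nan"),
        beta_gen=float("nan"),
        labels=[f"topic{int(t)}" for t in theta.argmax(axis=1)], seed=seed,
    )
    return corpus, planted


def generate_snp_alignment(
    n_strains: int = 60,
    n_cols: int = 1000,
    n_variant: int = 200,
    n_groups: int = 3,
    noise_rate: float = 0.02,
    seed: int = 0,
) -> tuple[AlignedSequences, list[str]]:
    """Group-structured aligned sequences with planted variant columns.

    A random consensus is drawn; at each of ``n_variant`` columns the
    groups receive residues that are not all identical (so the column is
    variant by construction). Strains copy their group's sequence with
    within-group flips at variant columns at ``noise_rate``. Returns the
    alignment and the true group label per strain.
    """
    if n_variant > n_cols:
        raise ValueError("n_variant cannot exceed n_cols")
    if n_groups < 1 or n_strains < n_groups:
        raise ValueError("need n_strains >= n_groups >= 1")
    rng = _rng(seed)
    consensus = rng.integers(4, size=n_cols)
    variant_cols = np.sort(rng.choice(n_cols, size=n_variant, replace=False))
    group_rows = np.tile(consensus, (n_groups, 1))
    for j in variant_cols:
        while True:
            residues = rng.integers(4, size=n_groups)
            if n_groups == 1 or len(set(residues.tolist())) >= 2:
                break
        group_rows[:, j] = residues
    groups = [g % n_groups for g in range(n_strains)]
    rows, ids, labels = [], [], []
    for s, g in enumerate(groups):
        seq = group_rows[g].copy()
        if noise_rate > 0:
            flip = variant_cols[rng.random(n_variant) < noise_rate]
            seq[flip] = (seq[flip] + 1 + rng.integers(3, size=flip.size)) % 4
        rows.append("".join(_NUC[seq]))
        ids.append(f"strain{s + 1}")
        labels.append(f"group{g + 1}")
    return AlignedSequences(ids=ids, rows=rows), labels


def generate_binary_profiles(
    n_rows: int = 200,
    n_cols: int = 500,
    n_topics: int = 5,
    density: float = 0.02,
    block_density: float = 0.3,
    seed: int = 0,
) -> tuple[BinaryMatrix, list[str]]:
    """Block-structured binary matrix emulating entity-feature profiles.

    Columns are split into ``n_topics`` contiguous blocks; each row belongs
    to one group and switches its in-block features on with probability
    ``block_density`` and off-block features on at background ``density``.
    ``density=0`` makes the block structure exact. Returns the matrix and
    the true group label per row.
    """
    if not (0 <= density <= 1 and 0 < block_density <= 1):
        raise ValueError("densities must lie in [0, 1]")
    rng = _rng(seed)
    block_of_col = np.minimum(np.arange(n_cols) * n_topics // n_cols, n_topics - 1)
    groups = rng.integers(n_topics, size=n_rows)
    cells = (rng.random((n_rows, n_cols)) < density).astype(np.int8)
    for i in range(n_rows):
        in_block = block_of_col == groups[i]
        cells[i, in_block] = rng.random(int(in_block.sum())) < block_density
    mat = BinaryMatrix(
        row_ids=[f"row{i + 1}" for i in range(n_rows)],
        column_names=[f"f{j + 1}" for j in range(n_cols)],
        cells=cells,
    )
    return mat, [f"group{g + 1}" for g in groups]
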