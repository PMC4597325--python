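"""Document encoders and corpus I/O.

Three encoding procedures produce a uniform bag-of-words :class:`Corpus`:

* :func:`encode_snp_words` — each sequence in a multiple alignment becomes a
  document whose words are ``"<column><residue>"`` tokens at the variant
  (SNP) columns, so all documents have equal length;
* :func:`encode_binary_matrix` — each row of a binary entity x feature
  matrix becomes a document with one token per 1-cell (drug / side-effect
  style data);
* :func:`encode_text` — plain text documents are lowercased, tokenized on
  non-alphabetic boundaries, stopword-filtered and Porter-stemmed.

All encoders are deterministic: identical input yields an identical corpus
including vocabulary order (first appearance during encoding).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._text import DEFAULT_STOPWORDS, porter_stem, tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedSequences",
    "BinaryMatrix",
    "Corpus",
    "encode_binary_matrix",
    "encode_snp_words",
    "encode_text",
    "read_aligned_fasta",
    "read_corpus",
    "read_documents",
    "read_matrix_tsv",
    "write_corpus",
]

_GAPLIKE = {"-", "N"}


class CorpusFormatError(ValueError):
    """Raised for malformed corpus / alignment / matrix inputs."""


@dataclass
class Corpus:
    """A bag-of-words corpus of M documents over a fixed vocabulary.

    Attributes
    ----------
    documents : list of int arrays
        Per-document sequences of vocabulary indices (token order kept).
    vocabulary : list of str
        Ordered, unique word strings; token index ``j`` means word
        ``vocabulary[j]``.
    doc_ids : list of str
        Unique identifiers aligned 1:1 with ``documents``.
    """

    documents: list[np.ndarray]
    vocabulary: list[str]
    doc_ids: list[str]

    def __post_init__(self) -> None:
        self.documents = [np.asarray(d, dtype=np.int64) for d in self.documents]
        if len(self.documents) != len(self.doc_ids):
            raise CorpusFormatError("doc_ids must align 1:1 with documents")
        if len(set(self.doc_ids)) != len(self.doc_ids):
            raise CorpusFormatError("doc_ids must be unique")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise CorpusFormatError("vocabulary entries must be unique")
        V = len(self.vocabulary)
        for did, doc in zip(self.doc_ids, self.documents):
            if doc.size and (doc.min() < 0 or doc.max() >= V):
                raise CorpusFormatError(
                    f"document {did!r} has token index outside vocabulary of size {V}"
                )

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)

    @property
    def doc_lengths(self) -> np.ndarray:
        return np.array([len(d) for d in self.documents], dtype=np.int64)

    @property
    def n_tokens(self) -> int:
        return int(self.doc_lengths.sum())

    def subset(self, indices: Sequence[int]) -> "Corpus":
        """Corpus restricted to the given document positions (vocab shared)."""
        idx = list(indices)
        return Corpus(
            documents=[self.documents[i] for i in idx],
            vocabulary=self.vocabulary,
            doc_ids=[self.doc_ids[i] for i in idx],
        )

    def to_dense_counts(self) -> np.ndarray:
        """M x V document-term count matrix."""
        out = np.zeros((self.n_docs, self.n_words), dtype=np.int64)
        for i, doc in enumerate(self.documents):
            np.add.at(out[i], doc, 1)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return (
            self.vocabulary == other.vocabulary
            and self.doc_ids == other.doc_ids
            and len(self.documents) == len(other.documents)
            and all(np.array_equal(a, b) for a, b in zip(self.documents, other.documents))
        )


@dataclass
class AlignedSequences:
    """Equal-length aligned nucleotide sequences (the consumed MSA product)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise CorpusFormatError("ids and rows must align")
        if len(set(self.ids)) != len(self.ids):
            raise CorpusFormatError("sequence ids must be unique")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise CorpusFormatError(
                f"aligned rows must all have the same length; got lengths {sorted(lengths)}"
            )

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class BinaryMatrix:
    """Rectangular 0/1 entity x feature matrix."""

    row_ids: list[str]
    column_names: list[str]
    cells: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 2 or self.cells.shape != (len(self.row_ids), len(self.column_names)):
            raise CorpusFormatError("cells must be rectangular and match ids/names")
        if not np.isin(self.cells, (0, 1)).all():
            bad = self.cells[~np.isin(self.cells, (0, 1))].flat[0]
            raise CorpusFormatError(f"matrix cells must be 0/1; found {bad!r}")
        self.cells = self.cells.astype(np.int8)


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

def encode_snp_words(aln: AlignedSequences) -> Corpus:
    """Encode each aligned sequence as a document of SNP words.

    A column is variant when at least two distinct non-gap, non-N residues
    occur among the sequences. Each sequence contributes one token per
    variant column: ``"<1-based column><residue>"``, with ``"<column>-"``
    when the sequence has a gap or N there, so every document has the same
    length (the number of variant columns).
    """
    if aln.n_seqs < 2:
        raise CorpusFormatError("SNP encoding needs at least 2 sequences")
    arr = np.array([list(r) for r in aln.rows])
    variant_cols = []
    for j in range(arr.shape[1]):
        residues = {c for c in arr[:, j] if c not in _GAPLIKE}
        if len(residues) >= 2:
            variant_cols.append(j)
    if not variant_cols:
        raise CorpusFormatError("no variant columns: alignment carries no polymorphism")

    vocab: dict[str, int] = {}
    documents = []
    for i in range(aln.n_seqs):
        tokens = np.empty(len(variant_cols), dtype=np.int64)
        for k, j in enumerate(variant_cols):
            residue = arr[i, j]
            word = f"{j + 1}{'-' if residue in _GAPLIKE else residue}"
            tokens[k] = vocab.setdefault(word, len(vocab))
        documents.append(tokens)
    return Corpus(documents=documents, vocabulary=list(vocab), doc_ids=list(aln.ids))


def encode_binary_matrix(mat: BinaryMatrix) -> Corpus:
    """Encode each matrix row as a document with one token per 1-cell.

    The token string is the column name; total token count equals the
    number of 1 entries. All-zero rows are retained as empty documents
    (they contribute nothing to perplexity sums) with a warning.
    """
    if mat.cells.size == 0:
        raise CorpusFormatError("matrix is empty")
    vocab: dict[str, int] = {}
    documents = []
    for i, rid in enumerate(mat.row_ids):
        cols = np.flatnonzero(mat.cells[i])
        if cols.size == 0:
            warnings.warn(f"row {rid!r} is all-zero; kept as empty document", stacklevel=2)
        documents.append(
            np.array([vocab.setdefault(mat.column_names[j], len(vocab)) for j in cols],
                     dtype=np.int64)
        )
    return Corpus(documents=documents, vocabulary=list(vocab), doc_ids=list(mat.row_ids))


def encode_text(
    docs: Sequence[str],
    stopwords: Iterable[str] | None = None,
    doc_ids: Sequence[str] | None = None,
) -> Corpus:
    """Tokenize, stopword-filter and Porter-stem raw text documents.

    Tokenization lowercases and splits on non-alphabetic characters,
    dropping tokens shorter than 2 characters; surviving tokens are checked
    against the stopword list (default: the package's fixed English list)
    and then stemmed. Vocabulary order is first appearance of each stem.
    """
    if len(docs) == 0:
        raise CorpusFormatError("need at least one document")
    stop = DEFAULT_STOPWORDS if stopwords is None else set(stopwords)
    if doc_ids is None:
        doc_ids = [f"doc{i + 1}" for i in range(len(docs))]
    vocab: dict[str, int] = {}
    documents = []
    for did, raw in zip(doc_ids, docs):
        stems = [porter_stem(t) for t in tokenize(raw) if t not in stop]
        if not stems:
            warnings.warn(f"document {did!r} is empty after filtering", stacklevel=2)
        documents.append(np.array([vocab.setdefault(s, len(vocab)) for s in stems],
                                  dtype=np.int64))
    return Corpus(documents=documents, vocabulary=list(vocab), doc_ids=list(doc_ids))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_aligned_fasta(path: str | Path) -> AlignedSequences:
    """Read a multi-record aligned FASTA file (case-folded to upper)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise CorpusFormatError(f"{path}: no FASTA records found")
    return AlignedSequences(
        ids=[r.id for r in records], rows=[str(r.seq).upper() for r in records]
    )


def read_matrix_tsv(path: str | Path) -> BinaryMatrix:
    """Read a TSV with a header of column names and a first row-id column."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise CorpusFormatError(f"{path}: ragged TSV ({exc})") from exc
    try:
        cells = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise CorpusFormatError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.isin(cells, (0.0, 1.0)).all():
        i, j = np.argwhere(~np.isin(cells, (0.0, 1.0)))[0]
        raise CorpusFormatError(
            f"{path}: non-binary cell {df.iat[i, j]!r} at line {i + 2}, "
            f"column {df.columns[j]!r}"
        )
    return BinaryMatrix(
        row_ids=[str(x) for x in df.index],
        column_names=[str(c) for c in df.columns],
        cells=cells.astype(np.int8),
    )


def read_documents(path_or_dir: str | Path) -> list[str]:
    """Read raw documents: one per line of a file, or one per ``.txt`` file."""
    p = Path(path_or_dir)
    if p.is_dir():
        files = sorted(p.glob("*.txt"))
        if not files:
            raise CorpusFormatError(f"{p}: no .txt files in directory")
        return [f.read_text(encoding="utf-8") for f in files]
    if not p.exists():
        raise FileNotFoundError(p)
    return p.read_text(encoding="utf-8").splitlines()


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus to the package's plain-text format.

    Line 1: ``#vocab\\t<V>``; line 2: ``#words\\t<w1> <w2> ...`` in index
    order; then one line per document: ``<doc_id>\\t<token strings>``.
    Token strings never contain whitespace by construction of the encoders.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#vocab\t{corpus.n_words}\n")
        fh.write("#words\t" + " ".join(corpus.vocabulary) + "\n")
        for did, doc in zip(corpus.doc_ids, corpus.documents):
            fh.write(did + "\t" + " ".join(corpus.vocabulary[t] for t in doc) + "\n")


def read_corpus(path: str | Path) -> Corpus:
    """Read a corpus written by :func:`write_corpus` (round-trip identity)."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2 or not lines[0].startswith("#vocab\t"):
        raise CorpusFormatError(f"{path}: line 1 must be '#vocab\\t<size>'")
    try:
        V = int(lines[0].split("\t", 1)[1])
    except ValueError as exc:
        raise CorpusFormatError(f"{path}: line 1 has non-integer vocab size") from exc
    if not lines[1].startswith("#words\t"):
        raise CorpusFormatError(f"{path}: line 2 must be '#words\\t...'")
    words_field = lines[1].split("\t", 1)[1]
    vocabulary = words_field.split() if words_field else []
    if len(vocabulary) != V:
        raise CorpusFormatError(
            f"{path}: header declares {V} words but line 2 lists {len(vocabulary)}"
        )
    index = {w: i for i, w in enumerate(vocabulary)}
    doc_ids, documents = [], []
    for ln, line in enumerate(lines[2:], start=3):
        if not line:
            continue
        if "\t" not in line:
            raise CorpusFormatError(f"{path}: line {ln}: missing doc-id column")
        did, body = line.split("\t", 1)
        try:
            tokens = np.array([index[w] for w in body.split()], dtype=np.int64)
        except KeyError as exc:
            raise CorpusFormatError(
                f"{path}: line {ln}: token {exc.args[0]!r} not in vocabulary"
            ) from exc
        doc_ids.append(did)
        documents.append(tokens)
    return Corpus(documents=documents, vocabulary=vocabulary, doc_ids=doc_ids)
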