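"""Encoders, readers and the corpus round-trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpcselect import (
    AlignedSequences,
    BinaryMatrix,
    Corpus,
    encode_binary_matrix,
    encode_snp_words,
    encode_text,
    read_aligned_fasta,
    read_corpus,
    read_documents,
    read_matrix_tsv,
    write_corpus,
)
from rpcselect.corpus import CorpusFormatError
from rpcselect._text import porter_stem, tokenize


class TestSnpEncoding:
    def test_single_variant_column(self):
        aln = AlignedSequences(ids=["a", "b", "c"],
                               rows=["ACGTA", "ACGTA", "ACCTA"])
        corpus = encode_snp_words(aln)
        assert corpus.vocabulary == ["3G", "3C"]
        assert [list(d) for d in corpus.documents] == [[0], [0], [1]]

    def test_identical_sequences_have_no_polymorphism(self):
        aln = AlignedSequences(ids=["a", "b"], rows=["ACGT", "ACGT"])
        with pytest.raises(CorpusFormatError, match="no variant"):
            encode_snp_words(aln)

    def test_two_variant_columns_token_count(self):
        aln = AlignedSequences(ids=["a", "b", "c"], rows=["AC", "GC", "AT"])
        corpus = encode_snp_words(aln)
        assert all(len(d) == 2 for d in corpus.documents)
        assert corpus.n_tokens == 6  # M x S occurrence scaling

    def test_gap_and_n_do_not_make_a_column_variant(self):
        # column 1: residues {A} plus gap/N -> not variant; column 2: {C,G}
        aln = AlignedSequences(ids=["a", "b", "c"], rows=["AC", "-G", "NC"])
        corpus = encode_snp_words(aln)
        assert all(len(d) == 1 for d in corpus.documents)
        assert set(corpus.vocabulary) == {"2C", "2G"}

    def test_gap_in_variant_column_keeps_lengths_equal(self):
        aln = AlignedSequences(ids=["a", "b", "c"], rows=["A", "C", "-"])
        corpus = encode_snp_words(aln)
        assert corpus.vocabulary == ["1A", "1C", "1-"]
        assert [len(d) for d in corpus.documents] == [1, 1, 1]

    def test_unequal_rows_rejected(self):
        with pytest.raises(CorpusFormatError, match="same length"):
            AlignedSequences(ids=["a", "b"], rows=["ACG", "AC"])

    def test_deterministic(self):
        aln = AlignedSequences(ids=["a", "b", "c"], rows=["AC", "GC", "AT"])
        assert encode_snp_words(aln) == encode_snp_words(aln)


class TestBinaryEncoding:
    def test_row_tokens_are_one_cells(self):
        mat = BinaryMatrix(row_ids=["r1"], column_names=["c1", "c2", "c3", "c4", "c5"],
                           cells=np.array([[0, 1, 0, 0, 1]]))
        corpus = encode_binary_matrix(mat)
        assert [corpus.vocabulary[t] for t in corpus.documents[0]] == ["c2", "c5"]

    def test_identity_matrix(self):
        mat = BinaryMatrix(row_ids=list("abc"), column_names=list("xyz"),
                           cells=np.eye(3, dtype=int))
        corpus = encode_binary_matrix(mat)
        assert [len(d) for d in corpus.documents] == [1, 1, 1]
        assert corpus.n_tokens == 3

    def test_non_binary_cell_rejected(self):
        with pytest.raises(CorpusFormatError, match="0/1"):
            BinaryMatrix(row_ids=["r"], column_names=["c"], cells=np.array([[2]]))

    def test_all_zero_row_kept_with_warning(self):
        mat = BinaryMatrix(row_ids=["r1", "r2"], column_names=["c1", "c2"],
                           cells=np.array([[1, 0], [0, 0]]))
        with pytest.warns(UserWarning, match="all-zero"):
            corpus = encode_binary_matrix(mat)
        assert len(corpus.documents[1]) == 0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 8), st.integers(1, 8), st.integers(0, 2**31 - 1))
    def test_token_count_equals_number_of_ones(self, n, m, seed):
        rng = np.random.default_rng(seed)
        cells = rng.integers(0, 2, size=(n, m))
        mat = BinaryMatrix(row_ids=[f"r{i}" for i in range(n)],
                           column_names=[f"c{j}" for j in range(m)], cells=cells)
        if (cells.sum(axis=1) == 0).any():
            with pytest.warns(UserWarning):
                corpus = encode_binary_matrix(mat)
        else:
            corpus = encode_binary_matrix(mat)
        assert corpus.n_tokens == cells.sum()


class TestTextEncoding:
    def test_stemming_collapses_inflections(self):
        corpus = encode_text(["Genes and the genes"], stopwords={"and", "the"})
        assert [corpus.vocabulary[t] for t in corpus.documents[0]] == ["gene", "gene"]

    def test_all_stopword_document_kept_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            corpus = encode_text(["the and the"], stopwords={"the", "and"})
        assert len(corpus.documents[0]) == 0

    def test_shared_stem_single_vocabulary_entry(self):
        corpus = encode_text(["alignment alignments"], stopwords=set())
        assert len(corpus.documents[0]) == 2
        assert corpus.vocabulary == ["align"]

    def test_tokenizer_drops_short_and_nonalpha(self):
        assert tokenize("A 12 bc-de f") == ["bc", "de"]

    @pytest.mark.parametrize("word,stem", [
        ("caresses", "caress"), ("ponies", "poni"), ("hopping", "hop"),
        ("relational", "relat"), ("adjustable", "adjust"), ("rate", "rate"),
        ("agreed", "agre"), ("sky", "sky"), ("happy", "happi"),
    ])
    def test_porter_reference_pairs(self, word, stem):
        assert porter_stem(word) == stem


class TestIO:
    def test_fasta_round_trip(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACG\nTA\n>s2\nacgta\n")
        aln = read_aligned_fasta(p)
        assert aln.n_seqs == 2 and aln.length == 5
        assert aln.rows[1] == "ACGTA"  # case folded

    def test_empty_fasta_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(CorpusFormatError):
            read_aligned_fasta(p)

    def test_matrix_tsv_round_trip(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tc1\tc2\nr1\t1\t0\nr2\t0\t1\n")
        mat = read_matrix_tsv(p)
        assert mat.row_ids == ["r1", "r2"]
        assert mat.cells.tolist() == [[1, 0], [0, 1]]

    def test_matrix_tsv_nonbinary_cell_names_location(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tc1\tc2\nr1\t1\t0\nr2\t2\t1\n")
        with pytest.raises(CorpusFormatError, match="line 3"):
            read_matrix_tsv(p)

    def test_read_documents_file_and_dir(self, tmp_path):
        f = tmp_path / "docs.txt"
        f.write_text("first doc\nsecond doc\n")
        assert read_documents(f) == ["first doc", "second doc"]
        d = tmp_path / "docs"
        d.mkdir()
        (d / "a.txt").write_text("alpha")
        (d / "b.txt").write_text("beta")
        assert read_documents(d) == ["alpha", "beta"]

    def test_corpus_round_trip_identity(self, tmp_path, tiny_corpus):
        p = tmp_path / "corpus.txt"
        write_corpus(tiny_corpus, p)
        assert read_corpus(p) == tiny_corpus

    def test_corpus_round_trip_with_empty_document(self, tmp_path):
        corpus = Corpus(documents=[np.array([0]), np.array([], dtype=int)],
                        vocabulary=["w"], doc_ids=["a", "b"])
        p = tmp_path / "corpus.txt"
        write_corpus(corpus, p)
        assert read_corpus(p) == corpus

    def test_corpus_reader_rejects_bad_header(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("not a header\n")
        with pytest.raises(CorpusFormatError, match="line 1"):
            read_corpus(p)


class TestCorpusInvariants:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(CorpusFormatError):
            Corpus(documents=[np.array([0]), np.array([0])],
                   vocabulary=["w"], doc_ids=["a", "a"])

    def test_out_of_range_token_rejected(self):
        with pytest.raises(CorpusFormatError):
            Corpus(documents=[np.array([1])], vocabulary=["w"], doc_ids=["a"])

    def test_token_total_is_sum_of_lengths(self, tiny_corpus):
        assert tiny_corpus.n_tokens == sum(len(d) for d in tiny_corpus.documents)
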