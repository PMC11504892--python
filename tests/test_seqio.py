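"""File-dialect readers/writers: FASTA, target/pathway tables, ARFF, CSV."""

import numpy as np
import pytest

from mirclass.exceptions import (
    AlphabetError,
    DomainError,
    FormatError,
    TableAlignmentError,
)
from mirclass.seqio import (
    BINARY,
    NUMERIC,
    FeatureTable,
    MiRNARecord,
    merge_tables,
    read_arff,
    read_csv,
    read_labels,
    read_mirna_fasta,
    read_pathway_sets,
    read_target_table,
    write_arff,
    write_csv,
    write_labels,
    write_mirna_fasta,
)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


class TestMiRNAFasta:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            (">x\nacgu\n", "ACGU"),  # lowercase canonicalized
            (">x\nACGT\n", "ACGU"),  # DNA alphabet mapped to RNA
            (">x\nAC\nGU\n", "ACGU"),  # multi-line sequence
        ],
    )
    def test_canonicalization(self, tmp_path, raw, expected):
        path = tmp_path / "m.fa"
        path.write_text(raw)
        (rec,) = read_mirna_fasta(path)
        assert rec.id == "x"
        assert rec.sequence == expected

    def test_header_split_mirbase_layout(self, tmp_path):
        path = tmp_path / "m.fa"
        path.write_text(">hsa-miR-21-3p MIMAT0004494 Homo sapiens miR-21-3p\nCAACACCAGU\n")
        (rec,) = read_mirna_fasta(path)
        assert rec.id == "hsa-miR-21-3p"
        assert rec.description == "MIMAT0004494 Homo sapiens miR-21-3p"

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "m.fa"
        path.write_text(">x\nACGU\n>x\nGGCC\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_mirna_fasta(path)

    def test_malformed_reports_line_number(self, tmp_path):
        path = tmp_path / "m.fa"
        path.write_text("not a header\n>x\nACGU\n")
        with pytest.raises(FormatError, match=":1:"):
            read_mirna_fasta(path)

    def test_alphabet_violation_names_record(self, tmp_path):
        path = tmp_path / "m.fa"
        path.write_text(">weird\nACGX\n")
        with pytest.raises(AlphabetError, match="weird"):
            read_mirna_fasta(path)

    def test_strict_mode_rejects_dna(self, tmp_path):
        path = tmp_path / "m.fa"
        path.write_text(">x\nACGT\n")
        with pytest.raises(AlphabetError):
            read_mirna_fasta(path, strict=True)

    def test_round_trip_many_random_records(self, tmp_path):
        rng = np.random.default_rng(0)
        records = [
            MiRNARecord(
                id=f"syn-miR-{i}",
                sequence="".join(rng.choice(list("ACGU"), size=rng.integers(16, 29))),
                description=f"SYN{i:07d} synthetic",
            )
            for i in range(1000)
        ]
        path = tmp_path / "all.fa"
        write_mirna_fasta(records, path)
        back = read_mirna_fasta(path)
        assert [(r.id, r.sequence) for r in back] == [
            (r.id, r.sequence) for r in records
        ]


# ---------------------------------------------------------------------------
# target table / pathway sets
# ---------------------------------------------------------------------------


class TestTargetTable:
    def test_basic_row(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("hsa-miR-21-3p\tMAPK1\t92\n")
        targets = read_target_table(path)
        assert targets.entries[("hsa-miR-21-3p", "MAPK1")] == 92.0

    def test_header_row_tolerated(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("mirna\tgene\tscore\nhsa-miR-21-3p\tMAPK1\t92\n")
        assert len(read_target_table(path)) == 1

    def test_empty_file_gives_empty_map(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("")
        assert len(read_target_table(path)) == 0

    def test_bad_score_reports_row(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("a\tG1\t90\nb\tG2\tabc\n")
        with pytest.raises(FormatError, match=":2:"):
            read_target_table(path)

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("a\tG1\n")
        with pytest.raises(FormatError, match="3"):
            read_target_table(path)

    def test_score_range_enforced(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("a\tG1\t150\n")
        with pytest.raises(FormatError):
            read_target_table(path)

    def test_gene_symbols_uppercased(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("a\tmapk1\t90\n")
        targets = read_target_table(path)
        assert ("a", "MAPK1") in targets.entries


class TestPathwaySets:
    def test_tsv_comma_genes(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("p53 signaling pathway\tTP53,CDKN1A\n")
        sets = read_pathway_sets(path)
        assert sets.pathways["p53 signaling pathway"] == frozenset({"TP53", "CDKN1A"})

    def test_tsv_tab_genes_and_blank_lines(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("mTOR signaling pathway\tAKT1\tMTOR\n\n")
        sets = read_pathway_sets(path)
        assert sets.pathways["mTOR signaling pathway"] == frozenset({"AKT1", "MTOR"})

    def test_gmt_dialect_skips_description(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("MAPK signaling pathway\thttp://example\tMAPK1\tMAPK3\n")
        sets = read_pathway_sets(path)
        assert sets.pathways["MAPK signaling pathway"] == frozenset({"MAPK1", "MAPK3"})

    def test_duplicate_names_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("A\tTP53\nA\tAKT1\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_pathway_sets(path)

    def test_empty_gene_set_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("A\t\n")
        with pytest.raises(FormatError):
            read_pathway_sets(path)

    def test_lowercase_genes_canonicalized(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("A\ttp53\n")
        assert read_pathway_sets(path).pathways["A"] == frozenset({"TP53"})


# ---------------------------------------------------------------------------
# FeatureTable + ARFF/CSV
# ---------------------------------------------------------------------------


def _example_table(labeled=True):
    labels = (
        np.asarray(["positive", "negative", "positive"], dtype=object)
        if labeled
        else None
    )
    return FeatureTable(
        ids=["a", "b", "c"],
        attributes=[("length", NUMERIC), ("gc fraction", NUMERIC), ("motif_GCU", BINARY)],
        values=np.array([[21.0, 1 / 3, 1.0], [18.0, 0.25, 0.0], [24.0, 0.5, 1.0]]),
        labels=labels,
    )


class TestFeatureTableContracts:
    def test_binary_attribute_must_be_01(self):
        with pytest.raises(DomainError, match="binary"):
            FeatureTable(
                ids=["a"], attributes=[("b", BINARY)], values=np.array([[2.0]])
            )

    def test_dimension_mismatch(self):
        with pytest.raises(DomainError):
            FeatureTable(
                ids=["a", "b"], attributes=[("x", NUMERIC)], values=np.array([[1.0]])
            )

    def test_duplicate_ids_and_names(self):
        with pytest.raises(DomainError):
            FeatureTable(
                ids=["a", "a"],
                attributes=[("x", NUMERIC)],
                values=np.zeros((2, 1)),
            )
        with pytest.raises(DomainError):
            FeatureTable(
                ids=["a"],
                attributes=[("x", NUMERIC), ("x", NUMERIC)],
                values=np.zeros((1, 2)),
            )


class TestArff:
    @pytest.mark.parametrize("labeled", [True, False])
    def test_round_trip_identity(self, tmp_path, labeled):
        table = _example_table(labeled)
        path = tmp_path / "t.arff"
        write_arff(table, path)
        back = read_arff(path)
        assert back.ids == table.ids
        assert back.attributes == table.attributes
        np.testing.assert_array_equal(back.values, table.values)
        if labeled:
            assert list(back.labels) == list(table.labels)
        else:
            assert back.labels is None

    def test_unlabeled_written_as_question_marks(self, tmp_path):
        path = tmp_path / "t.arff"
        write_arff(_example_table(labeled=False), path)
        data = path.read_text().split("@data\n")[1]
        assert all(line.endswith(",?") for line in data.strip().splitlines())

    def test_zero_instance_table(self, tmp_path):
        table = FeatureTable(
            ids=[], attributes=[("x", NUMERIC)], values=np.empty((0, 1))
        )
        path = tmp_path / "t.arff"
        write_arff(table, path)
        back = read_arff(path)
        assert back.n_instances == 0
        assert back.attributes == table.attributes

    def test_byte_stable_writes(self, tmp_path):
        table = _example_table()
        p1, p2 = tmp_path / "a.arff", tmp_path / "b.arff"
        write_arff(table, p1)
        write_arff(table, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_names_needing_quotes_are_quoted(self, tmp_path):
        path = tmp_path / "t.arff"
        write_arff(_example_table(), path)
        assert "@attribute 'gc fraction' numeric" in path.read_text()

    def test_class_declared_last_as_nominal(self, tmp_path):
        path = tmp_path / "t.arff"
        write_arff(_example_table(), path)
        lines = [l for l in path.read_text().splitlines() if l.startswith("@attribute")]
        assert lines[-1] == "@attribute class {negative,positive}"

    def test_high_precision_numeric_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        table = FeatureTable(
            ids=[f"i{r}" for r in range(50)],
            attributes=[("x", NUMERIC), ("y", NUMERIC)],
            values=rng.normal(size=(50, 2)),
        )
        path = tmp_path / "t.arff"
        write_arff(table, path)
        np.testing.assert_array_equal(read_arff(path).values, table.values)


class TestCsv:
    @pytest.mark.parametrize("labeled", [True, False])
    def test_round_trip(self, tmp_path, labeled):
        table = _example_table(labeled)
        path = tmp_path / "t.csv"
        write_csv(table, path)
        back = read_csv(path)
        assert back.ids == table.ids
        assert back.attribute_names == table.attribute_names
        np.testing.assert_array_equal(back.values, table.values)
        if labeled:
            assert list(back.labels) == list(table.labels)

    def test_comment_lines_skipped(self, tmp_path):
        path = tmp_path / "t.csv"
        write_csv(_example_table(), path, comment="seed=1")
        assert path.read_text().startswith("# seed=1")
        assert read_csv(path).n_instances == 3


class TestLabels:
    def test_round_trip(self, tmp_path):
        labels = {"a": "positive", "b": "negative"}
        path = tmp_path / "l.csv"
        write_labels(labels, path)
        assert read_labels(path) == labels

    def test_unknown_label_rejected(self, tmp_path):
        path = tmp_path / "l.csv"
        path.write_text("id,label\na,maybe\n")
        with pytest.raises(FormatError):
            read_labels(path)


class TestMergeTables:
    def test_concatenation_arity_and_identity(self):
        t = _example_table()
        single = merge_tables([t])
        assert single.attribute_names == t.attribute_names
        other = FeatureTable(
            ids=t.ids,
            attributes=[("extra", NUMERIC)],
            values=np.ones((3, 1)),
        )
        merged = merge_tables([t, other])
        assert merged.attribute_names == t.attribute_names + ["extra"]
        assert merged.labels is not None  # labels carried through

    def test_permuted_ids_rejected(self):
        t = _example_table()
        other = FeatureTable(
            ids=["c", "b", "a"],
            attributes=[("extra", NUMERIC)],
            values=np.ones((3, 1)),
        )
        with pytest.raises(TableAlignmentError):
            merge_tables([t, other])

    def test_name_collision_rejected(self):
        t = _example_table()
        with pytest.raises(DomainError, match="duplicate"):
            merge_tables([t, t.select(["length"])])
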