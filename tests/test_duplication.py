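"""Duplication-table parsing, support filtering, node totals, and
functional-category integration."""

import pytest

from phycomet.duplication import (
    DuplicationRecord,
    compare_node_groups,
    filter_support,
    integrate_annotations,
    node_totals,
    read_duplications,
    read_gene_categories,
    read_species_tree,
    write_duplications,
    write_itol_piechart,
    write_node_summaries,
)

HEADER = "Orthogroup\tSpecies Tree Node\tGene Tree Node\tSupport\tType\tGenes 1\tGenes 2\n"


def _record(node="N1", support=0.8, genes_1=("g1",), genes_2=("g2",), og="OG0000001"):
    return DuplicationRecord(
        orthogroup=og,
        species_tree_node=node,
        gene_tree_node="n1",
        support=support,
        type="Non-Terminal",
        genes_1=tuple(genes_1),
        genes_2=tuple(genes_2),
    )


class TestReadDuplications:
    def test_three_row_fixture(self, tmp_path):
        path = tmp_path / "Duplications.tsv"
        path.write_text(
            HEADER
            + "OG0000001\tN1\tn3\t0.5\tNon-Terminal\tg1, g2\tg3\n"
            + "OG0000002\tN2\tn9\t1\tNon-Terminal\tg4\tg5, g6\n"
            + "OG0000003\tsp1\tn12\t0.25\tTerminal\tg7\tg8\n"
        )
        records = read_duplications(path)
        assert len(records) == 3
        assert records[0].support == 0.5
        assert records[0].genes_1 == ("g1", "g2")
        assert records[2].species_tree_node == "sp1"

    def test_malformed_support(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(HEADER + "OG1\tN1\tn1\tN/A\tTerminal\tg1\tg2\n")
        with pytest.raises(ValueError, match="malformed support"):
            read_duplications(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("Orthogroup\tSpecies Tree Node\tGene Tree Node\tType\tGenes 1\tGenes 2\nx\tN1\tn1\tT\tg1\tg2\n")
        with pytest.raises(ValueError, match="Support"):
            read_duplications(path)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert read_duplications(path) == []

    def test_round_trip(self, tmp_path, dataset):
        path = tmp_path / "Duplications.tsv"
        write_duplications(dataset.duplications, path)
        assert read_duplications(path) == dataset.duplications


class TestFilterSupport:
    def test_inclusive_boundary(self):
        records = [_record(support=s) for s in (0.3, 0.5, 0.9)]
        kept = filter_support(records, 0.5)
        assert len(kept) == 2
        assert {r.support for r in kept} == {0.5, 0.9}

    def test_threshold_extremes(self):
        records = [_record(support=s) for s in (0.0, 0.4, 1.0)]
        assert len(filter_support(records, 0.0)) == 3
        assert [r.support for r in filter_support(records, 1.0)] == [1.0]

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_threshold_bounds(self, bad):
        with pytest.raises(ValueError):
            filter_support([], bad)

    def test_raising_threshold_is_monotone(self, dataset):
        counts = [
            sum(node_totals(filter_support(dataset.duplications, t)).values())
            for t in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestNodeTotals:
    def test_counts_and_conservation(self):
        records = [_record(node="N1", og=f"OG{i}") for i in range(5)] + [
            _record(node="N2", og=f"OGx{i}") for i in range(2)
        ]
        totals = node_totals(records)
        assert totals == {"N1": 5, "N2": 2}
        assert sum(totals.values()) == len(records)

    def test_tree_supplies_zero_nodes(self, tmp_path):
        path = tmp_path / "tree.nwk"
        path.write_text("((sp1,sp2)N2,sp3)N1;\n")
        tree = read_species_tree(path)
        totals = node_totals([_record(node="N2")], tree)
        assert totals == {"N1": 0, "N2": 1, "sp1": 0, "sp2": 0, "sp3": 0}

    def test_unknown_node_listed(self, tmp_path):
        path = tmp_path / "tree.nwk"
        path.write_text("((sp1,sp2)N2,sp3)N1;\n")
        tree = read_species_tree(path)
        with pytest.raises(ValueError, match="NX"):
            node_totals([_record(node="NX")], tree)

    def test_duplicate_tree_labels_rejected(self, tmp_path):
        path = tmp_path / "tree.nwk"
        path.write_text("((sp1,sp2)N1,sp3)N1;\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_species_tree(path)


class TestIntegrateAnnotations:
    def test_counting_rule(self):
        records = [_record(node="N1", genes_1=("g1",), genes_2=("g2",))]
        summaries = integrate_annotations(
            records, {"g1": ("IPR_A",), "g2": ("IPR_A", "GO_B")}
        )
        (s,) = summaries
        assert s.category_counts == {"GO_B": 1, "IPR_A": 2}
        assert s.unannotated_genes == 0
        assert s.distinct_genes == 2 and s.total_events == 1

    def test_all_unannotated(self):
        (s,) = integrate_annotations([_record()], {})
        assert s.category_counts == {}
        assert s.unannotated_genes == s.distinct_genes == 2

    def test_gene_in_two_records_counted_once(self):
        records = [
            _record(node="N1", genes_1=("g1",), genes_2=("g2",), og="OG1"),
            _record(node="N1", genes_1=("g1",), genes_2=("g3",), og="OG2"),
        ]
        (s,) = integrate_annotations(records, {})
        assert s.distinct_genes == 3 and s.total_events == 2

    def test_record_order_invariance(self, dataset):
        forward = integrate_annotations(dataset.duplications, dataset.gene_categories)
        backward = integrate_annotations(
            list(reversed(dataset.duplications)), dataset.gene_categories
        )
        assert forward == backward

    def test_distinct_genes_bounded_by_list_lengths(self, dataset):
        summaries = integrate_annotations(dataset.duplications, dataset.gene_categories)
        by_node = {}
        for r in dataset.duplications:
            by_node[r.species_tree_node] = by_node.get(r.species_tree_node, 0) + len(
                r.genes_1
            ) + len(r.genes_2)
        for s in summaries:
            assert s.distinct_genes <= by_node[s.node]


class TestCompareNodeGroups:
    def test_identical_groups(self):
        totals = {"a1": 1, "a2": 1, "b1": 1, "b2": 1}
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        res = compare_node_groups(totals, groups)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_hand_worked_case(self):
        totals = {"a1": 1, "a2": 2, "a3": 3, "b1": 2, "b2": 4, "b3": 6}
        groups = {n: n[0] for n in totals}
        res = compare_node_groups(totals, groups)
        assert res.statistic == pytest.approx(-2 / (5 / 3) ** 0.5)


def test_gene_category_reader(tmp_path):
    path = tmp_path / "gene_annotations.tsv"
    path.write_text(
        "gene_id\tnamespace\tcategory_id\tcategory_name\n"
        "g1\tInterPro\tIPR019791\tHaem peroxidase, animal type\n"
        "g1\tGO\tGO:0004601\tperoxidase activity\n"
        "g2\tInterPro\tIPR002035\tvon Willebrand factor A\n"
    )
    assert read_gene_categories(path) == {
        "g1": ("IPR019791", "GO:0004601"),
        "g2": ("IPR002035",),
    }
    assert read_gene_categories(path, namespace="GO") == {"g1": ("GO:0004601",)}


def test_exports(tmp_path, dataset):
    summaries = integrate_annotations(
        filter_support(dataset.duplications), dataset.gene_categories
    )
    tsv = tmp_path / "summaries.tsv"
    write_node_summaries(summaries, tsv)
    assert tsv.read_text().startswith("node\ttotal_events")
    itol = tmp_path / "pies.txt"
    write_itol_piechart(summaries, itol, top_k=3)
    text = itol.read_text()
    assert text.startswith("DATASET_PIECHART")
    assert "FIELD_LABELS" in text
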