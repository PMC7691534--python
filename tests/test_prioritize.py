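"""Article ranking, mechanism profiles, disease-gene ranking and panels."""

import random

import pytest

from litvariant.corpus import Document
from litvariant.lexicon import load_lexicons
from litvariant.prioritize import (
    SearchResult,
    build_gene_panel_report,
    compare_panels,
    mechanism_profile,
    prioritize_articles,
    rank_disease_genes,
    rank_search_results,
    subset_intersection_counts,
)


def doc(pmid, title="", abstract="", cites=0, sections=(), mesh=()):
    return Document(
        pmid=pmid, title=title, abstract=abstract, citation_count=cites,
        sections=list(sections), mesh_terms=list(mesh),
    )


class TestPrioritize:
    def test_three_key_sort(self, gene_lexicon, keywords):
        docs = [
            doc("10", title="BRAF signalling", cites=5),                       # A: title, no kw
            doc("11", abstract="BRAF is discussed", title="Other work", cites=100),  # B: no title
            doc("12", title="BRAF in melanoma", cites=5),                      # C: title + cancer kw
        ]
        assert prioritize_articles("BRAF", docs, gene_lexicon, keywords) == ["12", "10", "11"]

    def test_pmid_ascending_tiebreak(self, gene_lexicon, keywords):
        docs = [doc(p, title="BRAF study", cites=1) for p in ("30", "7", "104")]
        assert prioritize_articles("BRAF", docs, gene_lexicon, keywords) == ["7", "30", "104"]

    def test_eligibility_requires_title_or_abstract_mention(self, gene_lexicon, keywords):
        docs = [doc("1", title="Unrelated", sections=[("Results", "BRAF V600E here")])]
        assert prioritize_articles("BRAF", docs, gene_lexicon, keywords) == []

    def test_no_eligible_documents(self, gene_lexicon, keywords):
        assert prioritize_articles("BRAF", [doc("1", title="x")], gene_lexicon, keywords) == []


class TestMechanismProfile:
    def test_hand_counted_percentages(self, gene_lexicon, keywords):
        d = doc(
            "1", title="BRAF",
            sections=[("Results",
                "BRAF amplification was seen. BRAF deletion was confirmed. "
                "The BRAF fusion occurred. BRAF was studied further.")],
        )
        prof = mechanism_profile("BRAF", ["1"], {"1": d}, gene_lexicon, keywords)
        assert prof.evaluated_sentences == 4
        assert prof.percentages["cnv"] == 50.0
        assert prof.percentages["fusion"] == 25.0
        assert prof.percentages["mutation"] == 0.0
        assert prof.percentages["expression"] == 0.0

    def test_sentence_counts_once_per_category(self, gene_lexicon, keywords):
        d = doc("1", title="BRAF",
                sections=[("R", "The BRAF fusion involved an amplification event.")])
        prof = mechanism_profile("BRAF", ["1"], {"1": d}, gene_lexicon, keywords)
        assert prof.percentages["fusion"] == 100.0
        assert prof.percentages["cnv"] == 100.0

    def test_fewer_than_n_articles_all_used(self, gene_lexicon, keywords):
        docs = {str(i): doc(str(i), title="BRAF",
                            sections=[("R", "BRAF mutation observed.")]) for i in range(3)}
        prof = mechanism_profile("BRAF", list(docs), docs, gene_lexicon, keywords, n=100)
        assert prof.evaluated_sentences == 3
        assert prof.percentages["mutation"] == 100.0

    def test_zero_gene_sentences_flagged(self, gene_lexicon, keywords):
        prof = mechanism_profile("BRAF", [], {}, gene_lexicon, keywords)
        assert prof.undefined and prof.evaluated_sentences == 0
        assert all(v == 0.0 for v in prof.percentages.values())


class TestPanelReport:
    def test_report_is_prefix_of_prioritization(self, gene_lexicon, keywords):
        docs = [doc(str(i), title=f"BRAF paper {i}", cites=i) for i in range(15)]
        rep = build_gene_panel_report("BRAF", docs, gene_lexicon, keywords)
        ranked = prioritize_articles("BRAF", docs, gene_lexicon, keywords)
        assert [p for p, _ in rep.top_articles] == ranked[:10]
        assert rep.eligible_articles == 15

    def test_short_corpus_gives_short_report(self, gene_lexicon, keywords):
        docs = [doc(str(i), title="BRAF x") for i in range(3)]
        rep = build_gene_panel_report("BRAF", docs, gene_lexicon, keywords)
        assert len(rep.top_articles) == 3

    def test_empty_corpus(self, gene_lexicon, keywords):
        rep = build_gene_panel_report("BRAF", [], gene_lexicon, keywords)
        assert rep.top_articles == [] and rep.eligible_articles == 0


class TestDiseaseGenes:
    @pytest.fixture()
    def disease_lexicon(self):
        _, diseases, _ = load_lexicons([], ["Leukemia\tleukaemia", "Lymphoma\t"])
        return diseases

    def test_document_counts_not_mention_counts(self, gene_lexicon, disease_lexicon):
        docs = [
            doc("1", mesh=["Leukemia"], sections=[("R", "BRAF BRAF BRAF and KRAS")]),
            doc("2", mesh=["Leukemia"], sections=[("R", "BRAF only")]),
            doc("3", mesh=["Leukemia"], sections=[("R", "KRAS only")]),
            doc("4", mesh=["Humans"], sections=[("R", "BRAF not counted")]),
        ]
        ranked = rank_disease_genes("Leukemia", docs, gene_lexicon, disease_lexicon)
        assert ranked == [("BRAF", 2), ("KRAS", 2)]

    def test_text_mention_also_qualifies(self, gene_lexicon, disease_lexicon):
        docs = [doc("1", abstract="Leukemia with KRAS lesions")]
        assert rank_disease_genes("Leukemia", docs, gene_lexicon, disease_lexicon) == [("KRAS", 1)]

    def test_unknown_disease_raises(self, gene_lexicon, disease_lexicon):
        with pytest.raises(KeyError):
            rank_disease_genes("Gout", [], gene_lexicon, disease_lexicon)

    def test_absent_disease_yields_empty(self, gene_lexicon, disease_lexicon):
        docs = [doc("1", abstract="BRAF in melanoma")]
        assert rank_disease_genes("Leukemia", docs, gene_lexicon, disease_lexicon) == []


class TestPanels:
    def test_worked_example(self):
        cmp_result = compare_panels(
            {"P1": {"A", "B", "C"}, "P2": {"B", "C", "D"}, "P3": {"C", "D", "E"}}
        )
        assert len(cmp_result.union) == 5
        assert cmp_result.consensus == {"C"}
        assert cmp_result.exactly_one == {"A", "E"}
        assert cmp_result.per_k_counts == {1: 2, 2: 2, 3: 1}
        assert cmp_result.pairwise.loc["P1", "P2"] == 2

    def test_identical_panels(self):
        cmp_result = compare_panels({"A": {"X", "Y"}, "B": {"X", "Y"}})
        assert cmp_result.consensus == cmp_result.union

    def test_consensus_bounded_by_min_panel(self):
        rng = random.Random(0)
        genes = [f"G{i}" for i in range(40)]
        panels = {
            f"P{j}": set(rng.sample(genes, rng.randint(5, 25))) for j in range(4)
        }
        cmp_result = compare_panels(panels)
        assert len(cmp_result.consensus) <= min(len(p) for p in panels.values())

    def test_counts_satisfy_inclusion_exclusion(self):
        rng = random.Random(1)
        genes = [f"G{i}" for i in range(30)]
        panels = {f"P{j}": set(rng.sample(genes, rng.randint(5, 20))) for j in range(3)}
        cmp_result = compare_panels(panels)
        inter = subset_intersection_counts(panels)
        names = sorted(panels)
        # |A u B u C| = sum|X| - sum|XY| + |XYZ|
        union_ie = (
            sum(len(panels[n]) for n in names)
            - sum(inter[frozenset(c)] for c in
                  [(names[0], names[1]), (names[0], names[2]), (names[1], names[2])])
            + inter[frozenset(names)]
        )
        assert union_ie == len(cmp_result.union)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            compare_panels({"A": {"X"}, "B": set()})


class TestSearchRanking:
    def test_specificity_tier_primary(self, gene_lexicon, keywords):
        a = SearchResult(doc("1", title="Other", cites=999), "protein_key")
        b = SearchResult(doc("2", title="BRAF hit", cites=1), "exact_cdna")
        ranked = rank_search_results("BRAF", [a, b], gene_lexicon, keywords)
        assert [r.document.pmid for r in ranked] == ["2", "1"]

    def test_within_tier_equals_prioritization(self, gene_lexicon, keywords):
        docs = [doc("5", title="BRAF x", cites=1), doc("6", title="BRAF y", cites=9)]
        results = [SearchResult(d, "protein_key") for d in docs]
        ranked = rank_search_results("BRAF", results, gene_lexicon, keywords)
        assert [r.document.pmid for r in ranked] == ["6", "5"]

    def test_single_reference(self, gene_lexicon, keywords):
        r = SearchResult(doc("1"), "key_group")
        assert rank_search_results("BRAF", [r], gene_lexicon, keywords) == [r]
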