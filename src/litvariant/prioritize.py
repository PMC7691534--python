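"""Article ranking, mechanism profiling, panel reports and panel comparison.

Articles supporting a gene are ranked by a three-part key: presence of the
gene in the title, then citation count (a relevance proxy taken from input
metadata), then presence of a cancer-related keyword in the title; pmid
(ascending, numeric) breaks remaining ties so every sort is total and
deterministic.  The top-ranked articles feed a mechanism profile: the
percentage of gene-mentioning full-text sentences containing keywords of
each genetic mechanism (mutation, copy-number, fusion, expression change).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from litvariant.corpus import Document, normalize_text, segment
from litvariant.lexicon import KeywordLexicon, Lexicon, find_entity_mentions

__all__ = [
    "ArticleRankKey",
    "MechanismProfile",
    "PanelComparison",
    "prioritize_articles",
    "mechanism_profile",
    "build_gene_panel_report",
    "rank_disease_genes",
    "compare_panels",
    "rank_search_results",
]

MECHANISM_CATEGORIES = ("mutation", "cnv", "fusion", "expression")

SPECIFICITY_TIERS = ("exact_cdna", "protein_key", "key_group")


@dataclass(frozen=True)
class ArticleRankKey:
    gene_in_title: bool
    citation_count: int
    cancer_keyword_in_title: bool
    pmid: str

    @property
    def sort_key(self):
        return (
            not self.gene_in_title,
            -self.citation_count,
            not self.cancer_keyword_in_title,
            int(self.pmid) if self.pmid.isdigit() else self.pmid,
        )


@dataclass
class MechanismProfile:
    percentages: dict[str, float]
    evaluated_sentences: int
    undefined: bool = False  # no gene-mentioning sentences found


def _gene_in_text(gene: str, text: str, lexicon: Lexicon) -> bool:
    return any(
        m.entity_id == gene for m in find_entity_mentions(normalize_text(text), lexicon)
    )


def rank_key(gene: str, doc: Document, lexicon: Lexicon, keywords: KeywordLexicon) -> ArticleRankKey:
    title = normalize_text(doc.title)
    return ArticleRankKey(
        gene_in_title=_gene_in_text(gene, title, lexicon),
        citation_count=doc.citation_count,
        cancer_keyword_in_title=keywords.contains("cancer", title),
        pmid=doc.pmid,
    )


def prioritize_articles(
    gene: str,
    documents: list[Document],
    lexicon: Lexicon,
    keywords: KeywordLexicon,
) -> list[str]:
    """Ordered pmids of articles mentioning the gene in title or abstract.

    Sorted by (gene in title, citation count, cancer keyword in title),
    each descending, then pmid ascending.
    """
    eligible = [
        doc for doc in documents
        if _gene_in_text(gene, doc.title, lexicon) or _gene_in_text(gene, doc.abstract, lexicon)
    ]
    eligible.sort(key=lambda d: rank_key(gene, d, lexicon, keywords).sort_key)
    return [d.pmid for d in eligible]


def gene_sentences(gene: str, doc: Document, lexicon: Lexicon) -> list[str]:
    """Full-text sentences of `doc` that mention `gene`."""
    out: list[str] = []
    for name, text in doc.sections:
        norm = normalize_text(text)
        seg = segment(norm, section=name)
        mention_starts = [
            m.span.start for m in find_entity_mentions(norm, lexicon, section=name)
            if m.entity_id == gene
        ]
        for sent in seg.sentences:
            if any(sent.start <= s < sent.end for s in mention_starts):
                out.append(norm[sent.start : sent.end])
    return out


def mechanism_profile(
    gene: str,
    prioritized: list[str],
    documents: dict[str, Document],
    lexicon: Lexicon,
    keywords: KeywordLexicon,
    n: int = 100,
) -> MechanismProfile:
    """Keyword-category percentages over gene sentences of the top-n articles.

    For each mechanism category the value is the percentage of evaluated
    sentences containing at least one category keyword; a sentence can
    count toward several categories.  With zero gene sentences all
    percentages are 0 and the profile is flagged undefined.
    """
    sentences: list[str] = []
    for pmid in prioritized[:n]:
        doc = documents.get(pmid)
        if doc is not None:
            sentences.extend(gene_sentences(gene, doc, lexicon))
    if not sentences:
        return MechanismProfile({c: 0.0 for c in MECHANISM_CATEGORIES}, 0, undefined=True)
    pct = {
        cat: 100.0 * sum(keywords.contains(cat, s) for s in sentences) / len(sentences)
        for cat in MECHANISM_CATEGORIES
    }
    return MechanismProfile(pct, len(sentences))


@dataclass
class GenePanelReport:
    gene: str
    top_articles: list[tuple[str, str]]  # (pmid, title)
    profile: MechanismProfile
    eligible_articles: int


def build_gene_panel_report(
    gene: str,
    documents: list[Document],
    lexicon: Lexicon,
    keywords: KeywordLexicon,
    top: int = 10,
    profile_n: int = 100,
) -> GenePanelReport:
    """Panel evidence report: top-10 prioritized articles + mechanism profile."""
    by_pmid = {d.pmid: d for d in documents}
    ranked = prioritize_articles(gene, documents, lexicon, keywords)
    return GenePanelReport(
        gene=gene,
        top_articles=[(p, by_pmid[p].title) for p in ranked[:top]],
        profile=mechanism_profile(gene, ranked, by_pmid, lexicon, keywords, n=profile_n),
        eligible_articles=len(ranked),
    )


def rank_disease_genes(
    disease: str,
    documents: list[Document],
    gene_lexicon: Lexicon,
    disease_lexicon: Lexicon,
) -> list[tuple[str, int]]:
    """Genes cited with a disease, by descending document count.

    Restricted to documents mentioning the disease in MeSH metadata or any
    text field; counts are distinct documents per gene (not mention
    counts); ties break alphabetically.  Unknown disease terms raise.
    """
    ids = disease_lexicon.lookup(disease)
    if not ids:
        raise KeyError(f"unknown disease term {disease!r}")
    target = sorted(ids)[0]
    entry = disease_lexicon.entries[target]
    synonyms_folded = {s.lower() for s in entry.synonyms}

    counts: dict[str, int] = {}
    for doc in documents:
        in_mesh = any(t.lower() in synonyms_folded for t in doc.mesh_terms)
        if not in_mesh:
            texts = [doc.title, doc.abstract] + [t for _, t in doc.sections]
            in_text = any(
                m.entity_id == target
                for t in texts
                for m in find_entity_mentions(normalize_text(t), disease_lexicon)
            )
            if not in_text:
                continue
        genes_here: set[str] = set()
        for t in [doc.title, doc.abstract] + [t for _, t in doc.sections]:
            genes_here.update(
                m.entity_id for m in find_entity_mentions(normalize_text(t), gene_lexicon)
            )
        for g in genes_here:
            counts[g] = counts.get(g, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class PanelComparison:
    union: set[str]
    consensus: set[str]
    exactly_one: set[str]
    per_k_counts: dict[int, int]  # genes present on exactly k panels
    pairwise: pd.DataFrame
    membership: pd.DataFrame

    @property
    def consensus_pct(self) -> float:
        return 100.0 * len(self.consensus) / len(self.union)

    @property
    def exactly_one_pct(self) -> float:
        return 100.0 * len(self.exactly_one) / len(self.union)


def compare_panels(panels: dict[str, set[str]]) -> PanelComparison:
    """Set algebra over >= 2 gene panels with HGNC-normalized symbols."""
    if len(panels) < 2:
        raise ValueError("need at least two panels")
    for name, genes in panels.items():
        if not genes:
            raise ValueError(f"panel {name!r} is empty")
    union = set().union(*panels.values())
    names = sorted(panels)
    membership = pd.DataFrame(
        {name: [g in panels[name] for g in sorted(union)] for name in names},
        index=sorted(union),
    )
    k_per_gene = membership.sum(axis=1)
    per_k = k_per_gene.value_counts().to_dict()
    pairwise = pd.DataFrame(
        [[len(panels[a] & panels[b]) for b in names] for a in names],
        index=names, columns=names,
    )
    return PanelComparison(
        union=union,
        consensus=set(k_per_gene[k_per_gene == len(panels)].index),
        exactly_one=set(k_per_gene[k_per_gene == 1].index),
        per_k_counts={int(k): int(v) for k, v in per_k.items()},
        pairwise=pairwise,
        membership=membership,
    )


def subset_intersection_counts(panels: dict[str, set[str]]) -> dict[frozenset, int]:
    """|intersection| for every panel subset of size >= 2 (inclusion-exclusion aid)."""
    out: dict[frozenset, int] = {}
    names = sorted(panels)
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(panels[c] for c in combo))
            out[frozenset(combo)] = len(inter)
    return out


@dataclass(frozen=True)
class SearchResult:
    document: Document
    specificity: str  # exact_cdna | protein_key | key_group

    def __post_init__(self) -> None:
        if self.specificity not in SPECIFICITY_TIERS:
            raise ValueError(f"unknown specificity {self.specificity!r}")


def rank_search_results(
    gene: str,
    results: list[SearchResult],
    lexicon: Lexicon,
    keywords: KeywordLexicon,
) -> list[SearchResult]:
    """Order references by match specificity, then by article rank key.

    A reference matching the exact cDNA change searched for outranks a
    same-key protein-level match, which outranks a key-group match; within
    a tier the ordering equals :func:`prioritize_articles`.
    """
    return sorted(
        results,
        key=lambda r: (
            SPECIFICITY_TIERS.index(r.specificity),
            rank_key(gene, r.document, lexicon, keywords).sort_key,
        ),
    )


def load_panel_tsv(path_or_rows, name: str | None = None) -> tuple[str, set[str]]:
    """Read a one-gene-per-row panel TSV; first column is the symbol."""
    if isinstance(path_or_rows, (str, bytes)):
        with open(path_or_rows, encoding="utf-8") as fh:
            rows = fh.readlines()
        if name is None:
            import os
            name = os.path.splitext(os.path.basename(path_or_rows))[0]
    else:
        rows = list(path_or_rows)
        name = name or "panel"
    genes = set()
    for row in rows:
        row = row.strip()
        if not row or row.startswith("#"):
            continue
        genes.add(row.split("\t")[0].strip())
    return name, genes
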