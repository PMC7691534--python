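"""Gene-fusion pair extraction, canonical merging and database comparison.

Fusions appear in text in three dominant delimiter formats —
``gene1:gene2``, ``gene1/gene2`` and ``gene1-gene2`` — and, less reliably,
as two gene symbols co-mentioned in one sentence or paragraph.  Delimiter
matches require both tokens to resolve to distinct lexicon genes and the
joined token itself not to be a gene symbol (``HLA-B`` is one gene, not a
fusion).  Co-mention matches additionally require a fusion-category keyword
("fusion", "rearrangement", "translocation", "chimeric") in the same
window, standing in for the manual validation step a production pipeline
would apply.  Articles citing the same pair in either order merge into a
single canonical (alphabetical) entry; the cited 5'/3' order is preserved
in per-order counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import re

from litvariant.corpus import Segmentation, TextSpan, segment
from litvariant.lexicon import KeywordLexicon, Lexicon, find_entity_mentions

__all__ = [
    "FusionMention",
    "FusionPair",
    "FusionComparison",
    "detect_fusion_mentions",
    "aggregate_fusion_pairs",
    "compare_fusions_to_reference",
    "fusion_trends",
]

_DELIMITED = re.compile(
    r"(?<![A-Za-z0-9])([A-Za-z0-9]+)([:/-])([A-Za-z0-9]+)(?![A-Za-z0-9])"
)
_FORMAT = {":": "COLON", "/": "SLASH", "-": "HYPHEN"}


@dataclass(frozen=True)
class FusionMention:
    pmid: str
    gene5: str
    gene3: str
    format: str  # COLON | SLASH | HYPHEN | SENTENCE | PARAGRAPH
    span: TextSpan

    def __post_init__(self) -> None:
        if self.gene5 == self.gene3:
            raise ValueError("fusion genes must be distinct")

    @property
    def canonical(self) -> tuple[str, str]:
        return tuple(sorted((self.gene5, self.gene3)))


@dataclass
class FusionPair:
    genes: tuple[str, str]  # canonical alphabetical order
    pmids: set[str] = field(default_factory=set)
    format_counts: dict[str, int] = field(default_factory=dict)
    order_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    first_year: int | None = None

    @property
    def article_count(self) -> int:
        return len(self.pmids)


def _resolve_gene(token: str, lexicon: Lexicon) -> str | None:
    ids = lexicon.lookup(token)
    return next(iter(ids)) if len(ids) == 1 else (sorted(ids)[0] if ids else None)


def detect_fusion_mentions(
    text: str,
    gene_lexicon: Lexicon,
    keywords: KeywordLexicon,
    segmentation: Segmentation | None = None,
    pmid: str = "",
    section: str = "",
    require_keyword_for_comention: bool = True,
    include_paragraph: bool = True,
) -> list[FusionMention]:
    """Fusion-pair mentions in one normalized text unit.

    Delimiter matches (``A-B``, ``A/B``, ``A:B``) are rejected when the
    joined token is itself a lexicon entry, when the two tokens resolve to
    the same gene, or when either token is an ambiguous synonym and no
    fusion keyword co-occurs in the sentence.  Sentence/paragraph
    co-mentions of two distinct genes require a fusion keyword by default.
    """
    seg = segmentation or segment(text, section=section)
    mentions: list[FusionMention] = []
    delimited_spans: list[tuple[int, int]] = []

    for m in _DELIMITED.finditer(text):
        t1, delim, t2 = m.group(1), m.group(2), m.group(3)
        if gene_lexicon.lookup(m.group(0)):
            continue  # the joined token is a single gene symbol
        g1, g2 = _resolve_gene(t1, gene_lexicon), _resolve_gene(t2, gene_lexicon)
        if g1 is None or g2 is None or g1 == g2:
            continue
        if gene_lexicon.is_ambiguous(t1) or gene_lexicon.is_ambiguous(t2):
            sent = seg.sentence_of(m.start())
            context = text[sent.start : sent.end] if sent else text
            if not keywords.contains("fusion", context):
                continue
        mentions.append(
            FusionMention(pmid, g1, g2, _FORMAT[delim],
                          TextSpan(section, m.start(), m.end()))
        )
        delimited_spans.append((m.start(), m.end()))

    gene_mentions = [
        gm for gm in find_entity_mentions(text, gene_lexicon, section=section)
        if not any(s <= gm.span.start < e for s, e in delimited_spans)
    ]

    def co_mentions(window: TextSpan, fmt: str, exclude: set[tuple[str, str]]):
        inside = [g for g in gene_mentions if window.start <= g.span.start < window.end]
        wtext = text[window.start : window.end]
        if require_keyword_for_comention and not keywords.contains("fusion", wtext):
            return
        seen: set[tuple[str, str]] = set()
        ordered: dict[str, int] = {}
        for g in inside:
            ordered.setdefault(g.entity_id, g.span.start)
        for a, b in combinations(sorted(ordered, key=ordered.get), 2):
            pair = tuple(sorted((a, b)))
            if pair in seen or pair in exclude:
                continue
            seen.add(pair)
            mentions.append(FusionMention(pmid, a, b, fmt, window))

    delimited_pairs_by_sentence: dict[tuple[int, int], set[tuple[str, str]]] = {}
    for fm, (s, e) in zip([m for m in mentions if m.format in ("COLON", "SLASH", "HYPHEN")], delimited_spans):
        sent = seg.sentence_of(s)
        key = (sent.start, sent.end) if sent else (-1, -1)
        delimited_pairs_by_sentence.setdefault(key, set()).add(fm.canonical)

    sentence_pairs: set[tuple[str, str]] = set()
    for sent in seg.sentences:
        exclude = delimited_pairs_by_sentence.get((sent.start, sent.end), set())
        before = len(mentions)
        co_mentions(sent, "SENTENCE", exclude)
        sentence_pairs.update(m.canonical for m in mentions[before:])

    if include_paragraph:
        for para in seg.paragraphs:
            exclude = sentence_pairs | {
                p for pairs in delimited_pairs_by_sentence.values() for p in pairs
            }
            co_mentions(para, "PARAGRAPH", exclude)
    return mentions


def aggregate_fusion_pairs(
    mentions_by_pmid: dict[str, list[FusionMention]],
    years: dict[str, int | None] | None = None,
) -> list[FusionPair]:
    """Merge order-symmetric mentions across the corpus into canonical pairs."""
    years = years or {}
    pairs: dict[tuple[str, str], FusionPair] = {}
    for pmid, mentions in mentions_by_pmid.items():
        for fm in mentions:
            pair = pairs.setdefault(fm.canonical, FusionPair(fm.canonical))
            pair.pmids.add(pmid)
            pair.format_counts[fm.format] = pair.format_counts.get(fm.format, 0) + 1
            order = (fm.gene5, fm.gene3)
            pair.order_counts[order] = pair.order_counts.get(order, 0) + 1
            year = years.get(pmid)
            if year is not None and (pair.first_year is None or year < pair.first_year):
                pair.first_year = year
    return sorted(pairs.values(), key=lambda p: p.genes)


@dataclass
class FusionComparison:
    common: dict[tuple[str, str], tuple[int, int, float]]  # pair -> (tool, ref, ratio)
    novel: list[tuple[str, str]]
    reference_only: list[tuple[str, str]]
    yield_increase_pct: float | None


def compare_fusions_to_reference(
    pairs: list[FusionPair],
    reference: dict[tuple[str, str], int | None],
) -> FusionComparison:
    """Partition extracted pairs against a reference list with counts.

    ``reference`` maps canonical pairs to reference article counts (may be
    None).  For common pairs the tool/reference article-count ratio is
    reported; the overall yield increase is
    ``(N_tool - N_ref) / N_ref * 100`` (None when the reference is empty).
    """
    ref = {tuple(sorted(p)): c for p, c in reference.items()}
    tool = {p.genes: p for p in pairs}
    common = {}
    for genes in sorted(set(tool) & set(ref)):
        t = tool[genes].article_count
        r = ref[genes]
        ratio = round(t / r, 1) if r else float("nan")
        common[genes] = (t, r, ratio)
    novel = sorted(set(tool) - set(ref))
    ref_only = sorted(set(ref) - set(tool))
    if ref:
        increase = round(100 * (len(tool) - len(ref)) / len(ref))
    else:
        increase = None
    return FusionComparison(common, novel, ref_only, increase)


def fusion_trends(pairs: list[FusionPair], years: dict[str, int | None]) -> dict:
    """Per-year article totals and counts of pairs first seen that year.

    Articles lacking a year are excluded from the trend and tallied under
    ``missing_year_articles``.
    """
    articles_by_year: dict[int, set[str]] = {}
    missing: set[str] = set()
    for pair in pairs:
        for pmid in pair.pmids:
            year = years.get(pmid)
            if year is None:
                missing.add(pmid)
            else:
                articles_by_year.setdefault(year, set()).add(pmid)
    novel_by_year: dict[int, int] = {}
    for pair in pairs:
        if pair.first_year is not None:
            novel_by_year[pair.first_year] = novel_by_year.get(pair.first_year, 0) + 1
    all_years = sorted(set(articles_by_year) | set(novel_by_year))
    return {
        "by_year": {
            y: {
                "articles": len(articles_by_year.get(y, ())),
                "novel_pairs": novel_by_year.get(y, 0),
            }
            for y in all_years
        },
        "missing_year_articles": len(missing),
    }
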