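"""End-to-end corpus indexing: variants, CNVs and fusions in one pass.

Thin composition of the per-module extractors, used by the CLI and by the
synthetic-corpus evaluation.  Fusion co-mentions are taken at sentence
confidence by default; paragraph-level co-mentions are recorded by the
fusion module but excluded from automatic aggregation (they stand in for
results a production pipeline would hold for manual review).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from litvariant.cnv import CnvCitation, CytobandMap, extract_cnv_citations
from litvariant.corpus import Document, normalize_text
from litvariant.fusion import FusionMention, FusionPair, aggregate_fusion_pairs, detect_fusion_mentions
from litvariant.lexicon import KeywordLexicon, Lexicon
from litvariant.variant_norm import NormalizedVariant, TranscriptModel, index_document

__all__ = ["IndexedCorpus", "run_pipeline"]


@dataclass
class IndexedCorpus:
    variants: dict[str, list[NormalizedVariant]] = field(default_factory=dict)
    cnvs: dict[str, list[CnvCitation]] = field(default_factory=dict)
    fusion_mentions: dict[str, list[FusionMention]] = field(default_factory=dict)
    fusion_pairs: list[FusionPair] = field(default_factory=list)

    def prediction_sets(self) -> dict[str, dict[str, set]]:
        """Identity sets per class, in the shape the scorer expects."""
        return {
            "variants": {
                pmid: {v.identity for v in vs} for pmid, vs in self.variants.items() if vs
            },
            "cnvs": {
                pmid: {
                    (c.level, c.interval.chrom, c.interval.start, c.interval.end, c.direction)
                    for c in cs if c.interval is not None
                }
                for pmid, cs in self.cnvs.items() if cs
            },
            "fusions": {
                pmid: {m.canonical for m in ms}
                for pmid, ms in self.fusion_mentions.items() if ms
            },
        }


def run_pipeline(
    documents: list[Document],
    gene_lexicon: Lexicon,
    transcripts: dict[str, TranscriptModel],
    cytobands: CytobandMap,
    keywords: KeywordLexicon,
    rsid_map: dict[str, tuple[str, str]] | None = None,
    include_paragraph_fusions: bool = False,
) -> IndexedCorpus:
    """Index every document for variants, CNV citations and fusion pairs."""
    out = IndexedCorpus()
    years: dict[str, int | None] = {}
    for doc in documents:
        years[doc.pmid] = doc.year
        out.variants[doc.pmid] = index_document(
            doc, gene_lexicon, transcripts, rsid_map=rsid_map
        )
        units = [("__title__", doc.title), ("__abstract__", doc.abstract)]
        units += list(doc.sections)
        units += [(f"supplement:{n}", t) for n, t in doc.supplements]
        cnvs: list[CnvCitation] = []
        fusions: list[FusionMention] = []
        for name, text in units:
            if not text:
                continue
            norm = normalize_text(text)
            cnvs.extend(
                extract_cnv_citations(
                    norm, cytobands, gene_lexicon, keywords,
                    pmid=doc.pmid, section=name,
                )
            )
            fusions.extend(
                detect_fusion_mentions(
                    norm, gene_lexicon, keywords,
                    pmid=doc.pmid, section=name,
                    include_paragraph=include_paragraph_fusions,
                )
            )
        out.cnvs[doc.pmid] = cnvs
        out.fusion_mentions[doc.pmid] = fusions
    out.fusion_pairs = aggregate_fusion_pairs(out.fusion_mentions, years)
    return out
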