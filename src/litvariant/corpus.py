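"""Article ingestion, text repair, reference stripping and segmentation.

Articles are represented by :class:`Document`.  All downstream extractors
operate on *normalized* section text (see :func:`normalize_text`), and every
span they report is a 0-based half-open codepoint interval into that
normalized text, so the whole toolkit shares one coordinate space.
"""

from __future__ import annotations

import json
import logging
import re
import sys
import unicodedata
from dataclasses import dataclass, field

from lxml import etree

log = logging.getLogger(__name__)

__all__ = [
    "Document",
    "TextSpan",
    "Segmentation",
    "normalize_text",
    "strip_reference_sections",
    "segment",
    "read_jsonl",
    "write_jsonl",
    "read_medline_xml",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class TextSpan:
    """0-based half-open codepoint interval into a named section's text."""

    section: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass
class Document:
    """One article record: identifier, metadata fields and text sections."""

    pmid: str
    title: str = ""
    abstract: str = ""
    mesh_terms: list[str] = field(default_factory=list)
    gene_fields: list[str] = field(default_factory=list)
    substances: list[str] = field(default_factory=list)
    sections: list[tuple[str, str]] = field(default_factory=list)
    supplements: list[tuple[str, str]] = field(default_factory=list)
    citation_count: int = 0
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if self.citation_count < 0:
            raise ValueError("citation_count must be >= 0")
        names = [name for name, _ in self.sections]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate section names in pmid {self.pmid}")

    def to_dict(self) -> dict:
        return {
            "pmid": self.pmid,
            "title": self.title,
            "abstract": self.abstract,
            "mesh_terms": list(self.mesh_terms),
            "gene_fields": list(self.gene_fields),
            "substances": list(self.substances),
            "sections": [list(s) for s in self.sections],
            "supplements": [list(s) for s in self.supplements],
            "citation_count": self.citation_count,
            "year": self.year,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Document":
        return cls(
            pmid=str(d["pmid"]),
            title=d.get("title", ""),
            abstract=d.get("abstract", ""),
            mesh_terms=list(d.get("mesh_terms", [])),
            gene_fields=list(d.get("gene_fields", [])),
            substances=list(d.get("substances", [])),
            sections=[tuple(s) for s in d.get("sections", [])],
            supplements=[tuple(s) for s in d.get("supplements", [])],
            citation_count=int(d.get("citation_count") or 0),
            year=d.get("year"),
        )


@dataclass
class Segmentation:
    """Sentence and paragraph spans of one section's normalized text."""

    sentences: list[TextSpan]
    paragraphs: list[TextSpan]

    def sentence_of(self, pos: int) -> TextSpan | None:
        for s in self.sentences:
            if s.start <= pos < s.end:
                return s
        return None

    def paragraph_of(self, pos: int) -> TextSpan | None:
        for p in self.paragraphs:
            if p.start <= pos < p.end:
                return p
        return None


# ---------------------------------------------------------------------------
# Text normalization
# ---------------------------------------------------------------------------

# Single-codepoint substitutions applied first.  Greek letters are spelled
# out (authors write α-thalassemia, ΔF508, ...); arrows become the HGVS ">";
# typographic dashes, ligatures and exotic spaces collapse to ASCII.
_CHAR_TABLE = {
    "Α": "Alpha", "α": "alpha",
    "Β": "Beta", "β": "beta",
    "Γ": "Gamma", "γ": "gamma",
    "Δ": "Delta", "δ": "Delta",  # both cases mark deletions in variant text
    "Ε": "Epsilon", "ε": "epsilon",
    "Κ": "Kappa", "κ": "kappa",
    "Λ": "Lambda", "λ": "lambda",
    "Ω": "Omega", "ω": "omega",
    "→": ">", "⇒": ">",
    "–": "-", "—": "-", "−": "-", "‐": "-", "‑": "-",
    "ﬁ": "fi", "ﬂ": "fl",
    " ": " ", " ": " ", " ": " ", " ": " ", " ": " ",
    "­": "",  # soft hyphen
    "​": "",  # zero-width space
    "‘": "'", "’": "'", "“": '"', "”": '"',
}
_TRANSLATION = str.maketrans(_CHAR_TABLE)

# Word-level unification of the deletion marker: delta/Delta -> Delta.
_DELTA_WORD = re.compile(r"\bdelta\b")
_ASCII_ARROW = re.compile(r"-+>")  # "->", "-->", ...


def normalize_text(raw: str) -> str:
    """Repair common font-encoding and character-set problems.

    Applies a fixed substitution table: Greek letters are spelled out, arrow
    glyphs and ASCII arrows become ``>``, the deletion markers ``Δ`` /
    ``delta`` / ``Delta`` unify to the canonical token ``Delta``, ligatures
    and non-breaking spaces are normalized and soft hyphens removed.  The
    function is idempotent; empty input yields empty output.
    """
    if not raw:
        return ""
    text = unicodedata.normalize("NFC", raw)
    text = text.translate(_TRANSLATION)
    text = _ASCII_ARROW.sub(">", text)
    text = _DELTA_WORD.sub("Delta", text)
    return text


# ---------------------------------------------------------------------------
# Reference-section exclusion
# ---------------------------------------------------------------------------

_REFERENCE_HEADINGS = re.compile(
    r"^\s*(references?|bibliography|literature\s+cited|works\s+cited)\s*$",
    re.IGNORECASE,
)

# Off by default: drop a trailing block of numbered citations ("1. Smith ...")
# when a document carries references inside its last body section.
_NUMBERED_CITATION_BLOCK = re.compile(
    r"(?:\n\s*\d{1,3}\.\s+\S[^\n]*){5,}\s*\Z"
)


def strip_reference_sections(
    sections: list[tuple[str, str]],
    *,
    drop_trailing_citation_block: bool = False,
) -> list[tuple[str, str]]:
    """Remove bibliography sections; retained sections are untouched.

    Section names matching a bibliography heading ("References",
    "Bibliography", "Literature cited", case-insensitive) are dropped; order
    of the remainder is preserved and their text is unchanged byte-for-byte.
    """
    kept: list[tuple[str, str]] = []
    for name, text in sections:
        if _REFERENCE_HEADINGS.match(name):
            continue
        kept.append((name, text))
    if drop_trailing_citation_block and kept:
        name, text = kept[-1]
        trimmed = _NUMBERED_CITATION_BLOCK.sub("", text)
        if trimmed != text:
            kept[-1] = (name, trimmed)
    return kept


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

# Tokens after which a period does not end a sentence.
_ABBREVIATIONS = {
    "e.g", "i.e", "cf", "vs", "etc", "fig", "figs", "eq", "ref", "refs",
    "al", "dr", "no", "ca", "approx", "suppl", "chr",
}

_SENT_BREAK = re.compile(r"[.!?]+(?=\s+[A-Z0-9\"(])")
_PARA_BREAK = re.compile(r"\n\s*\n")


def _trimmed_span(section: str, text: str, start: int, end: int) -> TextSpan | None:
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    if start >= end:
        return None
    return TextSpan(section, start, end)


def _is_abbreviation(text: str, dot_pos: int) -> bool:
    """True when the token ending at `dot_pos` is on the protected list."""
    i = dot_pos
    while i > 0 and (text[i - 1].isalpha() or text[i - 1] == "."):
        i -= 1
    token = text[i:dot_pos].lower().rstrip(".")
    if token in _ABBREVIATIONS:
        return True
    # Single capital letter: an initial ("M. Smith"), not a sentence end.
    return len(token) == 1 and text[i].isupper()


def segment(text: str, section: str = "") -> Segmentation:
    """Split normalized text into sentence and paragraph spans.

    Paragraphs break on blank lines.  Sentences break on terminal
    punctuation followed by whitespace and an uppercase letter or digit,
    protected by an abbreviation list ("e.g.", "Fig.", "et al.", ...).
    Sentences nest within paragraphs; spans are trimmed of flanking
    whitespace, disjoint and ordered.
    """
    paragraphs: list[TextSpan] = []
    sentences: list[TextSpan] = []
    if not text.strip():
        return Segmentation(sentences, paragraphs)

    cursor = 0
    bounds: list[tuple[int, int]] = []
    for m in _PARA_BREAK.finditer(text):
        bounds.append((cursor, m.start()))
        cursor = m.end()
    bounds.append((cursor, len(text)))

    for pstart, pend in bounds:
        pspan = _trimmed_span(section, text, pstart, pend)
        if pspan is None:
            continue
        paragraphs.append(pspan)
        sstart = pspan.start
        for m in _SENT_BREAK.finditer(text, pspan.start, pspan.end):
            if _is_abbreviation(text, m.start()):
                continue
            span = _trimmed_span(section, text, sstart, m.end())
            if span is not None:
                sentences.append(span)
            sstart = m.end()
        tail = _trimmed_span(section, text, sstart, pspan.end)
        if tail is not None:
            sentences.append(tail)
    return Segmentation(sentences, paragraphs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_jsonl(path_or_lines) -> list[Document]:
    """Read Documents from JSON-lines (one object per line).

    Accepts a path or an iterable of lines.  Duplicate pmids raise.
    """
    if isinstance(path_or_lines, (str, bytes)):
        with open(path_or_lines, encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    docs: list[Document] = []
    seen: set[str] = set()
    for i, line in enumerate(lines, 1):
        line = line.strip()
        if not line:
            continue
        try:
            doc = Document.from_dict(json.loads(line))
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise ValueError(f"line {i}: malformed document record: {exc}") from exc
        if doc.pmid in seen:
            raise ValueError(f"line {i}: duplicate pmid {doc.pmid}")
        seen.add(doc.pmid)
        docs.append(doc)
    return docs


def write_jsonl(documents, path_or_handle) -> None:
    """Write Documents as JSON-lines."""
    close = False
    if isinstance(path_or_handle, (str, bytes)):
        fh = open(path_or_handle, "w", encoding="utf-8")
        close = True
    else:
        fh = path_or_handle
    try:
        for doc in documents:
            fh.write(json.dumps(doc.to_dict(), ensure_ascii=False) + "\n")
    finally:
        if close:
            fh.close()


def _xml_text(node) -> str:
    return "".join(node.itertext()).strip() if node is not None else ""


def read_medline_xml(source) -> list[Document]:
    """Read a MEDLINE-style XML file (PubmedArticle element subset).

    Recognized per article: PMID, ArticleTitle, Abstract/AbstractText,
    MeshHeading DescriptorNames, Chemical NameOfSubstance, GeneSymbol,
    PubDate/Year.  Unknown elements are ignored; articles lacking a PMID
    are skipped with a warning.
    """
    tree = etree.parse(source)
    docs: list[Document] = []
    for art in tree.iter("PubmedArticle", "MedlineCitation"):
        if art.tag == "PubmedArticle":
            cit = art.find("MedlineCitation")
            if cit is None:
                continue
        else:
            if art.getparent() is not None and art.getparent().tag == "PubmedArticle":
                continue  # handled via its parent
            cit = art
        pmid = _xml_text(cit.find("PMID"))
        if not pmid:
            log.warning("skipping article without PMID")
            continue
        article = cit.find("Article")
        title = _xml_text(article.find("ArticleTitle")) if article is not None else ""
        abstract = ""
        if article is not None and article.find("Abstract") is not None:
            abstract = "\n".join(
                _xml_text(t) for t in article.findall("Abstract/AbstractText")
            )
        mesh = [_xml_text(d) for d in cit.findall(".//MeshHeading/DescriptorName")]
        substances = [_xml_text(c) for c in cit.findall(".//Chemical/NameOfSubstance")]
        genes = [_xml_text(g) for g in cit.findall(".//GeneSymbolList/GeneSymbol")]
        year_node = cit.find(".//JournalIssue/PubDate/Year")
        year = int(_xml_text(year_node)) if year_node is not None and _xml_text(year_node).isdigit() else None
        docs.append(
            Document(
                pmid=pmid,
                title=title,
                abstract=abstract,
                mesh_terms=[m for m in mesh if m],
                gene_fields=[g for g in genes if g],
                substances=[s for s in substances if s],
                year=year,
            )
        )
    return docs


def normalize_document(doc: Document, *, strip_refs: bool = True) -> Document:
    """Return a copy with all text fields normalized (and references dropped)."""
    sections = [(n, normalize_text(t)) for n, t in doc.sections]
    if strip_refs:
        sections = strip_reference_sections(sections)
    return Document(
        pmid=doc.pmid,
        title=normalize_text(doc.title),
        abstract=normalize_text(doc.abstract),
        mesh_terms=list(doc.mesh_terms),
        gene_fields=list(doc.gene_fields),
        substances=list(doc.substances),
        sections=sections,
        supplements=[(n, normalize_text(t)) for n, t in doc.supplements],
        citation_count=doc.citation_count,
        year=doc.year,
    )


def warn(msg: str) -> None:  # pragma: no cover - CLI plumbing
    print(msg, file=sys.stderr)
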