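"""Copy-number citation extraction, normalization and interval matching.

CNVs are cited in the literature at very different granularities: ISCN
karyotype strings (``46,XX,del(22)(q11.2)``), cytoband tokens (``1p36.33``),
whole-gene or exon-level deletion/amplification phrases, or raw genomic
coordinates.  Everything is normalized to 0-based half-open genomic
intervals via a UCSC-format cytoband table, after which citations are
classified against a query interval:

``EXACT``
    identical endpoints after normalization,
``CONTAINED``
    the citation lies strictly within the query,
``SURROUNDING``
    the citation strictly contains the query,
``INTERSECTING``
    partial overlap.

Matches are listed in that type order, then by overlap proportion of the
query (descending), then by citation size (ascending).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from litvariant.corpus import Segmentation, TextSpan, segment
from litvariant.lexicon import KeywordLexicon, Lexicon, find_entity_mentions

log = logging.getLogger(__name__)

MATCH_ORDER = ("EXACT", "CONTAINED", "SURROUNDING", "INTERSECTING")

#: deletion_amplification terms implying each direction
_DEL_TERMS = re.compile(
    r"\b(dele?t\w*|microdeletion\w*|copy.number loss|hemizygous|homozygous)\b", re.I)
_AMP_TERMS = re.compile(
    r"\b(amplif\w*|duplicat\w*|microduplication\w*|copy.number gain|gain\w*)\b", re.I)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def size(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Cytoband:
    chrom: str
    name: str  # arm + band, e.g. "q11.2"
    start: int
    end: int
    stain: str | None = None

    @property
    def token(self) -> str:
        return f"{self.chrom.removeprefix('chr')}{self.name}"

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class CnvCitation:
    pmid: str
    interval: GenomicInterval | None
    level: str  # CYTOBAND | KARYOTYPE | GENE | EXON | COORDS
    direction: str = "UNKNOWN"  # DEL | AMP | UNKNOWN
    gene: str | None = None
    raw: str = ""
    span: TextSpan | None = None

    def __post_init__(self) -> None:
        if self.level in ("GENE", "EXON") and not self.gene:
            raise ValueError(f"{self.level}-level citation requires a gene")


@dataclass(frozen=True)
class CnvMatch:
    citation: CnvCitation
    match_type: str
    overlap_fraction: float  # of the query
    citation_size: int


@dataclass
class KaryotypeEvent:
    kind: str  # del | dup | amp | gain | loss | translocation
    chroms: tuple[str, ...]
    bands: tuple[str, ...]
    raw: str
    span: TextSpan | None = None


class CytobandError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Cytoband table
# ---------------------------------------------------------------------------

class CytobandMap:
    """Ordered per-chromosome band lists with token lookup.

    Input follows the UCSC cytoBand.txt convention (tab-separated chrom,
    start, end, band, stain; 0-based half-open).  Bands must be
    non-overlapping and sorted; lookups accept "22q11.2"-style tokens,
    band-prefix tokens ("22q11" spans all q11.* sub-bands) and whole arms
    ("11q").
    """

    def __init__(self, bands: list[Cytoband]):
        self.by_chrom: dict[str, list[Cytoband]] = {}
        for b in bands:
            self.by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, lst in self.by_chrom.items():
            lst.sort(key=lambda b: b.start)
            for a, b in zip(lst, lst[1:]):
                if a.end > b.start:
                    raise CytobandError(f"overlapping bands {a.token} / {b.token}")
        self._index = {b.token: b for lst in self.by_chrom.values() for b in lst}

    @classmethod
    def from_rows(cls, rows, one_based: bool = False) -> "CytobandMap":
        bands = []
        for i, raw in enumerate(rows, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise CytobandError(f"row {i}: expected >= 4 tab-separated columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if one_based:
                start -= 1
            stain = parts[4] if len(parts) > 4 else None
            bands.append(Cytoband(chrom, name, start, end, stain))
        return cls(bands)

    @classmethod
    def from_file(cls, path, one_based: bool = False) -> "CytobandMap":
        with open(path, encoding="utf-8") as fh:
            return cls.from_rows(fh, one_based=one_based)

    # -- lookups -----------------------------------------------------------

    def lookup(self, token: str) -> GenomicInterval | None:
        """Interval for "22q11.2", a band prefix, or a whole arm "11q"."""
        m = re.fullmatch(r"(?:chr)?(\d{1,2}|X|Y)([pq])((?:\d+(?:\.\d+)?)?)", token)
        if not m:
            return None
        chrom, arm, band = f"chr{m.group(1)}", m.group(2), m.group(3)
        if not band:
            return self.arm_interval(chrom, arm)
        exact = self._index.get(f"{m.group(1)}{arm}{band}")
        if exact:
            return exact.interval
        prefix = [
            b for b in self.by_chrom.get(chrom, [])
            if b.name.startswith(f"{arm}{band}.")
        ]
        if not prefix:
            return None
        return GenomicInterval(chrom, min(b.start for b in prefix), max(b.end for b in prefix))

    def band(self, token: str) -> Cytoband | None:
        return self._index.get(token.removeprefix("chr"))

    def arm_interval(self, chrom: str, arm: str) -> GenomicInterval | None:
        bands = [b for b in self.by_chrom.get(chrom, []) if b.name.startswith(arm)]
        if not bands:
            return None
        return GenomicInterval(chrom, min(b.start for b in bands), max(b.end for b in bands))

    def chrom_interval(self, chrom: str) -> GenomicInterval | None:
        if not chrom.startswith("chr"):
            chrom = f"chr{chrom}"
        bands = self.by_chrom.get(chrom)
        if not bands:
            return None
        return GenomicInterval(chrom, bands[0].start, bands[-1].end)

    def band_of(self, chrom: str, pos: int) -> Cytoband | None:
        for b in self.by_chrom.get(chrom, []):
            if b.start <= pos < b.end:
                return b
        return None


def load_cytoband_table(path_or_rows, one_based: bool = False) -> CytobandMap:
    """Read a UCSC cytoBand.txt-format table into a :class:`CytobandMap`."""
    if isinstance(path_or_rows, (str, bytes)):
        return CytobandMap.from_file(path_or_rows, one_based=one_based)
    return CytobandMap.from_rows(path_or_rows, one_based=one_based)


def expand_band_range(chrom: str, start_band: str, end_band: str, bands: CytobandMap) -> list[Cytoband]:
    """All bands from `start_band` to `end_band` inclusive, in map order.

    Both endpoints must resolve on the same chromosome; the result is the
    contiguous run between them (order-insensitive endpoints).
    """
    if not chrom.startswith("chr"):
        chrom = f"chr{chrom}"
    num = chrom.removeprefix("chr")
    a = bands.band(f"{num}{start_band}")
    b = bands.band(f"{num}{end_band}")
    if a is None or b is None:
        raise CytobandError(f"cannot resolve range {start_band}-{end_band} on {chrom}")
    lst = bands.by_chrom[chrom]
    i, j = sorted((lst.index(a), lst.index(b)))
    return lst[i : j + 1]


# ---------------------------------------------------------------------------
# Mention detection
# ---------------------------------------------------------------------------

_CYTOBAND_TOKEN = re.compile(
    r"(?<![\w.])((?:[1-9]|1\d|2[0-2]|X|Y))([pq])(\d+(?:\.\d+)?)"
    r"(?:-(?:((?:[1-9]|1\d|2[0-2]|X|Y))?([pq]))?(\d+(?:\.\d+)?))?"
    r"(?!\w)(?!\.\d)"
)
_FIGURE_CONTEXT = re.compile(r"(fig\w*\.?|table|panel)\s*$", re.I)


@dataclass(frozen=True)
class CytobandMention:
    chrom: str
    start_band: str
    end_band: str | None
    span: TextSpan
    raw: str


def detect_cytoband_mentions(text: str, section: str = "") -> list[CytobandMention]:
    """Cytoband tokens and band ranges, with figure/decimal false-positive filters.

    A chromosome number is required ("p36 patients" alone is not a band);
    tokens immediately preceded by a figure/table reference or embedded in
    decimal context are suppressed.
    """
    out: list[CytobandMention] = []
    for m in _CYTOBAND_TOKEN.finditer(text):
        if _FIGURE_CONTEXT.search(text[: m.start()]):
            continue
        chrom, arm, band = m.group(1), m.group(2), m.group(3)
        end_band = None
        if m.group(6):
            end_arm = m.group(5) or arm
            if m.group(4) and m.group(4) != chrom:
                continue  # cross-chromosome "ranges" are not CNV ranges
            end_band = f"{end_arm}{m.group(6)}"
        out.append(
            CytobandMention(
                chrom=chrom,
                start_band=f"{arm}{band}",
                end_band=end_band,
                span=TextSpan(section, m.start(), m.end()),
                raw=m.group(0),
            )
        )
    return out


_KARYO_DELDUP = re.compile(
    r"\b(del|dup|amp)\((\d{1,2}|X|Y)\)"
    r"\(([pq]\d+(?:\.\d+)?)(?:[-;]?([pq]\d+(?:\.\d+)?))?\)"
)
_KARYO_GAINLOSS = re.compile(r"(?<=,)([+-])(\d{1,2}|X|Y)(?![\w.(])")
_KARYO_TRANSLOC = re.compile(
    r"\bt\((\d{1,2}|X|Y);(\d{1,2}|X|Y)\)"
    r"(?:\(([pq]\d+(?:\.\d+)?);([pq]\d+(?:\.\d+)?)\))?"
)


def parse_karyotype(text: str, section: str = "") -> list[KaryotypeEvent]:
    """Parse the ISCN subset used for CNV extraction.

    Handles ``del(11)(q23)``, ``del(5)(q13q33)``, ``dup(1)(q21q32)``,
    ``amp(...)``, comma-context whole-chromosome ``+8`` / ``-7`` and
    translocations ``t(9;22)(q34;q11)`` (recorded as rearrangements only,
    never as CNV intervals).  Malformed tokens are skipped with a warning.
    """
    events: list[KaryotypeEvent] = []
    for m in _KARYO_DELDUP.finditer(text):
        bands = (m.group(3),) + ((m.group(4),) if m.group(4) else ())
        events.append(
            KaryotypeEvent(m.group(1), (m.group(2),), bands, m.group(0),
                           TextSpan(section, m.start(), m.end()))
        )
    for m in _KARYO_GAINLOSS.finditer(text):
        kind = "gain" if m.group(1) == "+" else "loss"
        events.append(
            KaryotypeEvent(kind, (m.group(2),), (), m.group(0),
                           TextSpan(section, m.start(), m.end()))
        )
    for m in _KARYO_TRANSLOC.finditer(text):
        bands = tuple(b for b in (m.group(3), m.group(4)) if b)
        events.append(
            KaryotypeEvent("translocation", (m.group(1), m.group(2)), bands,
                           m.group(0), TextSpan(section, m.start(), m.end()))
        )
    events.sort(key=lambda e: e.span.start)
    return events


def _direction_from_context(sentence_text: str) -> str:
    has_del = bool(_DEL_TERMS.search(sentence_text))
    has_amp = bool(_AMP_TERMS.search(sentence_text))
    if has_del and not has_amp:
        return "DEL"
    if has_amp and not has_del:
        return "AMP"
    return "UNKNOWN"


def karyotype_event_to_citation(
    event: KaryotypeEvent, bands: CytobandMap, pmid: str = ""
) -> CnvCitation | None:
    """Normalize one karyotype event to a genomic interval, or None.

    Translocations carry no copy-number interval.  Band ranges within one
    event expand to the union of intervening bands.
    """
    if event.kind == "translocation":
        return None
    if event.kind in ("gain", "loss"):
        iv = bands.chrom_interval(event.chroms[0])
        if iv is None:
            log.warning("karyotype %s: unknown chromosome", event.raw)
            return None
        direction = "AMP" if event.kind == "gain" else "DEL"
        return CnvCitation(pmid, iv, "KARYOTYPE", direction, raw=event.raw, span=event.span)
    chrom = event.chroms[0]
    if len(event.bands) == 2:
        try:
            run = expand_band_range(chrom, event.bands[0], event.bands[1], bands)
        except CytobandError as exc:
            log.warning("karyotype %s: %s", event.raw, exc)
            return None
        iv = GenomicInterval(run[0].chrom, run[0].start, run[-1].end)
    else:
        iv = bands.lookup(f"{chrom}{event.bands[0]}")
        if iv is None:
            log.warning("karyotype %s: unknown band", event.raw)
            return None
    direction = "DEL" if event.kind == "del" else "AMP"
    return CnvCitation(pmid, iv, "KARYOTYPE", direction, raw=event.raw, span=event.span)


_EXON_PHRASE = re.compile(r"\bexons?\s+(\d+)(?:\s*(?:-|to|through)\s*(\d+))?", re.I)


def detect_gene_level_cnv(
    text: str,
    gene_lexicon: Lexicon,
    keywords: KeywordLexicon,
    segmentation: Segmentation | None = None,
    pmid: str = "",
    section: str = "",
) -> list[CnvCitation]:
    """Gene/exon-level deletions and amplifications by keyword co-occurrence.

    A gene mention co-occurring with a deletion/amplification term within
    the window (default: the same sentence) yields a GENE-level citation
    whose direction comes from the term; an "exon N" phrase in the same
    window upgrades it to EXON level.  Expression vocabulary never
    triggers a citation.
    """
    seg = segmentation or segment(text, section=section)
    out: list[CnvCitation] = []
    gene_mentions = find_entity_mentions(text, gene_lexicon, section=section)
    for sent in seg.sentences:
        stext = text[sent.start : sent.end]
        if not keywords.contains("deletion_amplification", stext):
            continue
        direction = _direction_from_context(stext)
        if direction == "UNKNOWN" and not keywords.contains("cnv", stext):
            continue
        exon_m = _EXON_PHRASE.search(stext)
        for gm in (g for g in gene_mentions if sent.start <= g.span.start < sent.end):
            entry = gene_lexicon.entries.get(gm.entity_id)
            locus = getattr(entry, "locus", None)
            iv = GenomicInterval(locus[0], locus[1], locus[2]) if locus else None
            out.append(
                CnvCitation(
                    pmid=pmid,
                    interval=iv,
                    level="EXON" if exon_m else "GENE",
                    direction=direction,
                    gene=gm.entity_id,
                    raw=stext.strip(),
                    span=gm.span,
                )
            )
    return out


def extract_cnv_citations(
    text: str,
    bands: CytobandMap,
    gene_lexicon: Lexicon | None = None,
    keywords: KeywordLexicon | None = None,
    pmid: str = "",
    section: str = "",
) -> list[CnvCitation]:
    """All CNV citations from one normalized text unit (all levels)."""
    seg = segment(text, section=section)
    out: list[CnvCitation] = []
    for cm in detect_cytoband_mentions(text, section=section):
        sent = seg.sentence_of(cm.span.start)
        context = text[sent.start : sent.end] if sent else text
        if cm.end_band:
            try:
                run = expand_band_range(cm.chrom, cm.start_band, cm.end_band, bands)
                iv = GenomicInterval(run[0].chrom, run[0].start, run[-1].end)
            except CytobandError:
                continue
        else:
            iv = bands.lookup(f"{cm.chrom}{cm.start_band}")
            if iv is None:
                continue
        out.append(
            CnvCitation(pmid, iv, "CYTOBAND", _direction_from_context(context),
                        raw=cm.raw, span=cm.span)
        )
    for ev in parse_karyotype(text, section=section):
        cit = karyotype_event_to_citation(ev, bands, pmid=pmid)
        if cit is not None:
            out.append(cit)
    if gene_lexicon is not None and keywords is not None:
        out.extend(
            detect_gene_level_cnv(text, gene_lexicon, keywords, seg, pmid=pmid, section=section)
        )
    return out


# ---------------------------------------------------------------------------
# Query matching
# ---------------------------------------------------------------------------

def classify_overlap(query: GenomicInterval, citation: GenomicInterval) -> str | None:
    """The unique match type for an overlapping pair, else None."""
    if query.overlap(citation) == 0:
        return None
    if (citation.start, citation.end) == (query.start, query.end):
        return "EXACT"
    if query.start <= citation.start and citation.end <= query.end:
        return "CONTAINED"
    if citation.start <= query.start and query.end <= citation.end:
        return "SURROUNDING"
    return "INTERSECTING"


def match_cnv_query(query: GenomicInterval, citations: list[CnvCitation]) -> list[CnvMatch]:
    """Classify and prioritize citations against a query interval.

    Non-overlapping (or interval-less) citations are excluded.  Ordering:
    match type (Exact, Contained, Surrounding, Intersecting), then overlap
    proportion of the query descending, then citation size ascending.
    """
    matches: list[CnvMatch] = []
    for cit in citations:
        if cit.interval is None:
            continue
        mtype = classify_overlap(query, cit.interval)
        if mtype is None:
            continue
        frac = query.overlap(cit.interval) / query.size
        matches.append(CnvMatch(cit, mtype, frac, cit.interval.size))
    matches.sort(
        key=lambda m: (MATCH_ORDER.index(m.match_type), -m.overlap_fraction, m.citation_size)
    )
    return matches


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def citations_to_bed(citations: list[CnvCitation]) -> str:
    """BED4 text of the normalized citation intervals."""
    lines = []
    for cit in citations:
        if cit.interval is None:
            continue
        name = f"{cit.pmid or '.'}|{cit.level}|{cit.direction}"
        iv = cit.interval
        lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}")
    return "\n".join(lines) + ("\n" if lines else "")


def match_table(matches: list[CnvMatch]) -> str:
    """TSV report: pmid, match type, overlap fraction, interval, size."""
    lines = ["pmid\tmatch_type\toverlap_fraction\tchrom\tstart\tend\tsize_bp"]
    for m in matches:
        iv = m.citation.interval
        lines.append(
            f"{m.citation.pmid}\t{m.match_type}\t{m.overlap_fraction:.4f}"
            f"\t{iv.chrom}\t{iv.start}\t{iv.end}\t{m.citation_size}"
        )
    return "\n".join(lines) + "\n"


def plot_cnv_matches(query: GenomicInterval, matches: list[CnvMatch], path=None):
    """Stacked-interval figure of matches against the query (presentation only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 0.4 * (len(matches) + 2) + 1))
    ax.hlines(0, query.start, query.end, colors="black", linewidth=4, label="query")
    colors = {"EXACT": "tab:green", "CONTAINED": "tab:blue",
              "SURROUNDING": "tab:orange", "INTERSECTING": "tab:red"}
    for i, m in enumerate(matches, 1):
        iv = m.citation.interval
        ax.hlines(-i, iv.start, iv.end, colors=colors[m.match_type], linewidth=3)
    ax.set_yticks([0] + [-i for i in range(1, len(matches) + 1)])
    ax.set_yticklabels(["query"] + [m.citation.pmid or m.match_type for m in matches])
    ax.set_xlabel(f"{query.chrom} position (bp)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig
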