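"""SNV/indel mention recognition, transcript validation and key generation.

The pattern inventory recognizes variant descriptions in standard HGVS
notation, by rsID, and in the legacy forms that pervade older literature
(``T1799A``, ``1799 T > A``, ``DeltaF508`` ...).  Each candidate is checked
against transcript and protein sequences for the article's candidate genes;
cDNA positions are converted to protein effects and every validated variant
is assigned a protein-level key that groups equivalent citations:

========================  =============================================
``V600E``                 substitution (``X`` = stop gained)
``F508del``               single-residue deletion
``M123fs``                frameshift, indexed at the first shifted codon
``E80sd``/``E80sa``       splice donor/acceptor (first/last 2 intron nt)
``E80srd``/``E80sra``     splice region (deeper flanking intron nt)
``E80int``                other intronic
``5UTR``/``3UTR``         any untranslated-region variant
========================  =============================================

Intronic keys are indexed by the amino acid coded at the 5' side of the
intron.  cDNA numbering is HGVS: the A of the start codon is c.1, 5'UTR
positions are ``c.-n``, 3'UTR positions ``c.*n``.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

from litvariant.corpus import Document, TextSpan, normalize_text, segment
from litvariant.lexicon import Lexicon, find_entity_mentions

log = logging.getLogger(__name__)

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA3 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*", "Stop": "*",
}
_AA3_ALT = "|".join(AA3)

#: Known non-variant tokens that the 1-letter substitution pattern would
#: otherwise match (cell lines, plasmid names ...).  Extensible.
DEFAULT_TRAP_TOKENS = frozenset({
    "T47D", "H69AR", "A2B5", "C8D1A", "L5178Y", "P3X63", "T84M",  # cell lines
})

KEY_GRAMMAR = re.compile(
    rf"^(?:[{AA1}]\d+(?:[{AA1}X]|del|fs|sd|sa|int|srd|sra)|[53]UTR)$"
)


class SyntaxClass:
    PROTEIN_SUB_1 = "PROTEIN_SUB_1"
    PROTEIN_SUB_3 = "PROTEIN_SUB_3"
    PROTEIN_DEL = "PROTEIN_DEL"
    PROTEIN_FS = "PROTEIN_FS"
    CDNA_HGVS = "CDNA_HGVS"
    CDNA_LEGACY = "CDNA_LEGACY"
    CDNA_UTR = "CDNA_UTR"
    INTRONIC = "INTRONIC"
    RSID = "RSID"
    DELTA_FORM = "DELTA_FORM"


@dataclass
class VariantMention:
    """One textual variant match with parsed fields.

    ``unit`` is ``"nt"`` for cDNA-level and ``"aa"`` for protein-level
    positions.  Legacy three-token forms like ``T1799A`` whose letters are
    valid both as bases and residues carry ``aa_plausible=True``; transcript
    validation is the disambiguator.
    """

    span: TextSpan
    raw: str
    syntax_class: str
    ref: str | None = None
    pos: int | None = None
    alt: str | None = None
    unit: str = "nt"
    intron_offset: int | None = None
    utr: str | None = None  # "5" or "3"
    rsid: str | None = None
    del_length: int | None = None
    consequence: str | None = None  # "del" | "fs" | "ins" | "dup"
    aa_plausible: bool = False

    def __post_init__(self) -> None:
        if self.pos is not None and self.utr is None and self.pos < 1:
            raise ValueError("coding/protein position must be >= 1")


@dataclass(frozen=True)
class ProteinEffect:
    ref: str
    codon: int
    alt: str | None = None
    consequence: str = "substitution"  # substitution|deletion|frameshift|...


@dataclass(frozen=True)
class IntronPosition:
    """An intron-relative position anchored at a coding exon boundary."""

    anchor_cds_pos: int  # last coding position of the 5' exon
    offset: int          # +n into intron from donor, -n from acceptor
    intron_length: int | None = None


@dataclass(frozen=True)
class Verdict:
    passed: bool
    reason: str = ""


class UnkeyedVariant(Exception):
    """Raised when a consequence has no key form (kept with HGVS only)."""


@dataclass
class SpliceConfig:
    """Key-window widths around exon/intron junctions, in intron bases."""

    site: int = 2     # sd / sa: first and last bases of the intron
    region: int = 8   # srd / sra: up to this offset past the site window
    exon_flank: int = 3  # coding bases near a junction flagged splice-region


@dataclass
class NormalizedVariant:
    gene: str
    key: str | None
    hgvs_p: str | None = None
    hgvs_c: str | None = None
    rsid: str | None = None
    provenance: list[tuple[str, TextSpan, str]] = field(default_factory=list)

    @property
    def identity(self) -> tuple[str, str]:
        return (self.gene, self.key if self.key is not None else f"rs{self.rsid}")


# ---------------------------------------------------------------------------
# Transcript model
# ---------------------------------------------------------------------------

@dataclass
class Exon:
    cdna_start: int  # 1-based inclusive, in cDNA coordinates
    cdna_end: int
    chrom: str | None = None
    g_start: int | None = None  # 0-based half-open genomic interval
    g_end: int | None = None
    strand: str = "+"


@dataclass
class TranscriptModel:
    """A toy/real transcript: cDNA, CDS bounds, exon table, protein.

    ``cds_start``/``cds_end`` are 1-based inclusive positions in the cDNA.
    Construction verifies that the CDS length is a multiple of three, that
    its translation (stop trimmed) equals the protein, and that the exon
    segments tile the cDNA.
    """

    gene: str
    cdna: str
    cds_start: int
    cds_end: int
    exons: list[Exon]
    protein: str
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        cds = self.cds_seq
        if len(cds) % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length {len(cds)} not divisible by 3")
        translated = str(Seq(cds).translate())
        if translated.endswith("*"):
            translated = translated[:-1]
        if translated != self.protein:
            raise ValueError(f"{self.gene}: CDS translation does not match protein")
        pos = 1
        for ex in self.exons:
            if ex.cdna_start != pos:
                raise ValueError(f"{self.gene}: exons do not tile the cDNA")
            pos = ex.cdna_end + 1
        if pos != len(self.cdna) + 1:
            raise ValueError(f"{self.gene}: exons do not cover the cDNA")

    # -- coordinates -------------------------------------------------------

    @property
    def cds_seq(self) -> str:
        return self.cdna[self.cds_start - 1 : self.cds_end]

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start + 1

    def cdna_index(self, c_pos: int, utr: str | None = None) -> int:
        """1-based cDNA index for an HGVS c. position (c.-n / c.n / c.*n)."""
        if utr == "5":
            return self.cds_start - c_pos
        if utr == "3":
            return self.cds_end + c_pos
        return self.cds_start + c_pos - 1

    def base_at_c(self, c_pos: int, utr: str | None = None) -> str | None:
        idx = self.cdna_index(c_pos, utr)
        if 1 <= idx <= len(self.cdna):
            return self.cdna[idx - 1]
        return None

    def donor_sites(self) -> set[int]:
        """cDNA indices that end an exon followed by an intron."""
        return {ex.cdna_end for ex in self.exons[:-1]}

    def acceptor_sites(self) -> set[int]:
        """cDNA indices that start an exon preceded by an intron."""
        return {ex.cdna_start for ex in self.exons[1:]}

    def genomic_position(self, cdna_idx: int) -> tuple[str, int, str] | None:
        """(chrom, 0-based genomic position, strand) of one cDNA base."""
        for ex in self.exons:
            if ex.cdna_start <= cdna_idx <= ex.cdna_end and ex.g_start is not None:
                off = cdna_idx - ex.cdna_start
                if ex.strand == "+":
                    return ex.chrom, ex.g_start + off, "+"
                return ex.chrom, ex.g_end - 1 - off, "-"
        return None

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "transcript_id": self.transcript_id,
            "cdna": self.cdna,
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
            "protein": self.protein,
            "exons": [
                [e.cdna_start, e.cdna_end, e.chrom, e.g_start, e.g_end, e.strand]
                for e in self.exons
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TranscriptModel":
        return cls(
            gene=d["gene"],
            cdna=d["cdna"],
            cds_start=d["cds_start"],
            cds_end=d["cds_end"],
            protein=d["protein"],
            transcript_id=d.get("transcript_id"),
            exons=[Exon(*row) for row in d["exons"]],
        )


def load_transcripts(path_or_handle) -> dict[str, TranscriptModel]:
    """Read a ``{gene: transcript}`` map from the JSON transcript schema."""
    if isinstance(path_or_handle, (str, bytes)):
        with open(path_or_handle, encoding="utf-8") as fh:
            data = json.load(fh)
    else:
        data = json.load(path_or_handle)
    return {d["gene"]: TranscriptModel.from_dict(d) for d in data}


def save_transcripts(transcripts: dict[str, TranscriptModel], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([t.to_dict() for t in transcripts.values()], fh)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

_PATTERNS: list[tuple[str, re.Pattern]] = [
    (SyntaxClass.INTRONIC, re.compile(
        r"c\.(\d+)([+-])(\d+)(?:([ACGT])>([ACGT])|del[ACGT]*)")),
    (SyntaxClass.CDNA_UTR, re.compile(
        r"c\.([-*])(\d+)(?:([ACGT])>([ACGT])|(del)[ACGT]*)")),
    (SyntaxClass.CDNA_HGVS, re.compile(
        r"c\.(\d+)(?:_(\d+))?"
        r"(?:([ACGT])>([ACGT])|(del)(?:[ACGT]+|\d+)?|(ins|dup)[ACGT]*)")),
    (SyntaxClass.DELTA_FORM, re.compile(
        rf"Delta ?-?(?:({_AA3_ALT})|([{AA1}]))(\d+)")),
    (SyntaxClass.PROTEIN_FS, re.compile(
        rf"(?:p\.)?(?:({_AA3_ALT})|([{AA1}]))(\d+)fs(?![A-Za-z])")),
    (SyntaxClass.PROTEIN_DEL, re.compile(
        rf"(?:p\.)?(?:({_AA3_ALT})|([{AA1}]))(\d+)del(?![A-Za-z])")),
    (SyntaxClass.PROTEIN_SUB_3, re.compile(
        rf"(?:p\.)?({_AA3_ALT})(\d+)({_AA3_ALT}|Ter|X|\*)")),
    (SyntaxClass.RSID, re.compile(r"rs(\d+)")),
    (SyntaxClass.CDNA_LEGACY, re.compile(
        r"(\d+)\s?([ACGT])\s?>\s?([ACGT])")),
    (SyntaxClass.PROTEIN_SUB_1, re.compile(
        rf"(?:p\.)?([{AA1}])(\d+)([{AA1}X*])")),
]

_BOUND_BEFORE = re.compile(r"[A-Za-z0-9.]")
_BOUND_AFTER = re.compile(r"[A-Za-z0-9]")


def _bounded(text: str, start: int, end: int, raw: str) -> bool:
    """Word-boundary check; a leading 'p.'/'c.' prefix is part of the match."""
    if start > 0:
        prev = text[start - 1]
        if _BOUND_BEFORE.fullmatch(prev) and not raw.startswith(("p.", "c.", "rs")):
            return False
        if prev == "." and raw.startswith(("p.", "c.")):
            return False
        if _BOUND_AFTER.fullmatch(prev) and raw.startswith(("p.", "c.", "rs")):
            return False
    if end < len(text) and _BOUND_AFTER.fullmatch(text[end]):
        return False
    return True


def _parse(cls: str, m: re.Match, section: str) -> VariantMention | None:
    span = TextSpan(section, m.start(), m.end())
    raw = m.group(0)
    if cls == SyntaxClass.INTRONIC:
        base, sign, off = int(m.group(1)), m.group(2), int(m.group(3))
        if off == 0:
            return None
        return VariantMention(
            span, raw, cls, ref=m.group(4), alt=m.group(5), pos=base,
            unit="nt", intron_offset=off if sign == "+" else -off,
        )
    if cls == SyntaxClass.CDNA_UTR:
        utr = "5" if m.group(1) == "-" else "3"
        cons = "del" if m.group(5) else None
        return VariantMention(
            span, raw, cls, ref=m.group(3), alt=m.group(4), pos=int(m.group(2)),
            unit="nt", utr=utr, consequence=cons,
        )
    if cls == SyntaxClass.CDNA_HGVS:
        start_pos = int(m.group(1))
        end_pos = int(m.group(2)) if m.group(2) else start_pos
        if m.group(5):  # del
            length = end_pos - start_pos + 1
            return VariantMention(
                span, raw, cls, pos=start_pos, unit="nt",
                consequence="del", del_length=length,
            )
        if m.group(6):  # ins/dup: detected, left unkeyed downstream
            return VariantMention(
                span, raw, cls, pos=start_pos, unit="nt", consequence=m.group(6),
            )
        return VariantMention(
            span, raw, cls, ref=m.group(3), pos=start_pos, alt=m.group(4), unit="nt",
        )
    if cls == SyntaxClass.DELTA_FORM:
        ref = AA3[m.group(1)] if m.group(1) else m.group(2)
        return VariantMention(
            span, raw, cls, ref=ref, pos=int(m.group(3)), unit="aa",
            consequence="del",
        )
    if cls == SyntaxClass.PROTEIN_FS:
        ref = AA3[m.group(1)] if m.group(1) else m.group(2)
        return VariantMention(
            span, raw, cls, ref=ref, pos=int(m.group(3)), unit="aa",
            consequence="fs",
        )
    if cls == SyntaxClass.PROTEIN_DEL:
        ref = AA3[m.group(1)] if m.group(1) else m.group(2)
        return VariantMention(
            span, raw, cls, ref=ref, pos=int(m.group(3)), unit="aa",
            consequence="del",
        )
    if cls == SyntaxClass.PROTEIN_SUB_3:
        alt = m.group(3)
        alt1 = AA3.get(alt, "*" if alt in ("X", "*") else None)
        return VariantMention(
            span, raw, cls, ref=AA3[m.group(1)], pos=int(m.group(2)),
            alt=alt1, unit="aa",
        )
    if cls == SyntaxClass.RSID:
        return VariantMention(span, raw, cls, rsid=m.group(1))
    if cls == SyntaxClass.CDNA_LEGACY:
        return VariantMention(
            span, raw, cls, ref=m.group(2), pos=int(m.group(1)),
            alt=m.group(3), unit="nt",
        )
    if cls == SyntaxClass.PROTEIN_SUB_1:
        ref, alt = m.group(1), m.group(3)
        nt = set("ACGT")
        return VariantMention(
            span, raw, cls if not ({ref, alt} <= nt) else SyntaxClass.CDNA_LEGACY,
            ref=ref, pos=int(m.group(2)),
            alt="*" if alt in ("X", "*") else alt,
            unit="aa" if not ({ref, alt} <= nt) else "nt",
            aa_plausible=({ref, alt} <= nt),
        )
    raise AssertionError(cls)


def detect_variant_mentions(
    text: str,
    section: str = "",
    trap_tokens: frozenset[str] = DEFAULT_TRAP_TOKENS,
) -> list[VariantMention]:
    """All non-overlapping variant-description matches in normalized text.

    Patterns are tried in specificity order (HGVS cDNA/intronic/UTR first,
    bare 1-letter substitutions last); overlapping candidates resolve to the
    earlier, more specific, longer match.  Tokens on the trap list (cell
    lines etc.) and tokens embedded in longer words are suppressed.
    """
    candidates: list[tuple[int, int, int, VariantMention]] = []
    for prio, (cls, pat) in enumerate(_PATTERNS):
        for m in pat.finditer(text):
            raw = m.group(0)
            if not _bounded(text, m.start(), m.end(), raw):
                continue
            if raw in trap_tokens:
                continue
            mention = _parse(cls, m, section)
            if mention is not None:
                candidates.append((m.start(), -(m.end() - m.start()), prio, mention))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    out: list[VariantMention] = []
    last_end = -1
    for start, neg_len, _, mention in candidates:
        if start < last_end:
            continue
        out.append(mention)
        last_end = start - neg_len
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_mention(mention: VariantMention, transcript: TranscriptModel) -> Verdict:
    """Check a mention's stated reference against transcript/protein sequence."""
    sc = mention.syntax_class
    if sc == SyntaxClass.RSID:
        return Verdict(False, "rsID mentions validate via the rsID map")

    if mention.utr is not None:
        idx = transcript.cdna_index(mention.pos, mention.utr)
        if not (1 <= idx <= len(transcript.cdna)):
            return Verdict(False, "out of range")
        region_ok = idx < transcript.cds_start if mention.utr == "5" else idx > transcript.cds_end
        if not region_ok:
            return Verdict(False, "position not in stated UTR")
        if mention.ref and transcript.cdna[idx - 1] != mention.ref:
            return Verdict(False, "reference base mismatch")
        return Verdict(True)

    if sc == SyntaxClass.INTRONIC:
        cidx = transcript.cdna_index(mention.pos)
        if not (transcript.cds_start <= cidx <= transcript.cds_end):
            return Verdict(False, "anchor outside CDS")
        if mention.intron_offset > 0 and cidx not in transcript.donor_sites():
            return Verdict(False, "no intron after stated position")
        if mention.intron_offset < 0 and cidx not in transcript.acceptor_sites():
            return Verdict(False, "no intron before stated position")
        return Verdict(True)

    if mention.unit == "aa":
        if mention.pos > len(transcript.protein):
            return Verdict(False, "out of range")
        if mention.ref and transcript.protein[mention.pos - 1] != mention.ref:
            return Verdict(False, "reference residue mismatch")
        return Verdict(True)

    # cDNA-level: position within CDS, stated base must match
    if mention.pos > transcript.cds_len:
        return Verdict(False, "out of range")
    base = transcript.base_at_c(mention.pos)
    if mention.ref and base != mention.ref:
        return Verdict(False, "reference base mismatch")
    return Verdict(True)


def validate_legacy_as_protein(mention: VariantMention, transcript: TranscriptModel) -> Verdict:
    """Second reading of an ambiguous legacy token as a protein substitution."""
    if not mention.aa_plausible:
        return Verdict(False, "not amino-acid plausible")
    as_protein = replace(mention, syntax_class=SyntaxClass.PROTEIN_SUB_1, unit="aa")
    return validate_mention(as_protein, transcript)


# ---------------------------------------------------------------------------
# cDNA -> protein
# ---------------------------------------------------------------------------

def cdna_to_protein(mention: VariantMention, transcript: TranscriptModel) -> ProteinEffect:
    """Convert a validated coding cDNA mention to its protein effect.

    Substitutions translate the reference and mutated codon; indels whose
    length is not a multiple of three become a frameshift at the index
    codon.  UTR/intronic mentions are rejected (they key by region instead).
    """
    if mention.utr is not None or mention.syntax_class == SyntaxClass.INTRONIC:
        raise ValueError("mention outside CDS: use UTR/intronic keying")
    if mention.pos is None or mention.pos > transcript.cds_len:
        raise ValueError("position outside CDS")
    codon_idx = math.ceil(mention.pos / 3)
    cds = transcript.cds_seq
    codon = cds[(codon_idx - 1) * 3 : codon_idx * 3]
    ref_aa = str(Seq(codon).translate())

    if mention.consequence == "del":
        length = mention.del_length or (3 if mention.unit == "aa" else 1)
        if mention.unit == "aa":
            return ProteinEffect(ref_aa, codon_idx, None, "deletion")
        if length % 3 != 0:
            return ProteinEffect(ref_aa, codon_idx, None, "frameshift")
        if length == 3 and (mention.pos - 1) % 3 == 0:
            return ProteinEffect(ref_aa, codon_idx, None, "deletion")
        return ProteinEffect(ref_aa, codon_idx, None, "inframe_del")
    if mention.consequence in ("ins", "dup"):
        return ProteinEffect(ref_aa, codon_idx, None, "inframe_ins")
    if mention.consequence == "fs":
        return ProteinEffect(ref_aa, codon_idx, None, "frameshift")

    offset = (mention.pos - 1) % 3
    mutated = codon[:offset] + mention.alt + codon[offset + 1 :]
    alt_aa = str(Seq(mutated).translate())
    return ProteinEffect(ref_aa, codon_idx, alt_aa, "substitution")


# ---------------------------------------------------------------------------
# Key generation
# ---------------------------------------------------------------------------

def make_mastermind_key(
    effect: ProteinEffect | IntronPosition | str,
    transcript: TranscriptModel | None = None,
    splice: SpliceConfig | None = None,
    stop_char: str = "X",
) -> str:
    """Build the protein-level grouping key for an effect or region.

    Accepts a :class:`ProteinEffect`, an :class:`IntronPosition` (keyed
    ``sd``/``srd``/``int``/``sra``/``sa`` by distance into the intron, with
    the index amino acid coded at the intron's 5' side), or the strings
    ``"5UTR"``/``"3UTR"``.  Consequences with no key form (in-frame
    insertions, multi-codon deletions) raise :class:`UnkeyedVariant`.
    """
    if isinstance(effect, str):
        if effect in ("5UTR", "3UTR"):
            return effect
        raise UnkeyedVariant(f"no key form for {effect!r}")

    if isinstance(effect, IntronPosition):
        if transcript is None:
            raise ValueError("intronic keys require a transcript")
        splice = splice or SpliceConfig()
        codon_idx = math.ceil(effect.anchor_cds_pos / 3)
        aa = transcript.protein[codon_idx - 1]
        off = effect.offset
        if off > 0:
            if off <= splice.site:
                suffix = "sd"
            elif off <= splice.region:
                suffix = "srd"
            else:
                suffix = "int"
        else:
            if -off <= splice.site:
                suffix = "sa"
            elif -off <= splice.region:
                suffix = "sra"
            else:
                suffix = "int"
        return f"{aa}{codon_idx}{suffix}"

    if effect.consequence == "substitution":
        alt = effect.alt
        if alt == "*":
            alt = stop_char
        if effect.ref == "*" or alt is None:
            raise UnkeyedVariant("unsupported substitution")
        return f"{effect.ref}{effect.codon}{alt}"
    if effect.consequence == "deletion":
        return f"{effect.ref}{effect.codon}del"
    if effect.consequence == "frameshift":
        return f"{effect.ref}{effect.codon}fs"
    raise UnkeyedVariant(f"no key form for consequence {effect.consequence!r}")


# ---------------------------------------------------------------------------
# Gene association and document indexing
# ---------------------------------------------------------------------------

def resolve_candidate_genes(document: Document, gene_lexicon: Lexicon) -> list[str]:
    """Genes mentioned anywhere in the document, most-mentioned first.

    Counts mentions across title, abstract, metadata gene fields and all
    sections/supplements; ties break alphabetically.
    """
    counts: dict[str, int] = {}
    texts = [document.title, document.abstract]
    texts += [t for _, t in document.sections]
    texts += [t for _, t in document.supplements]
    for text in texts:
        for men in find_entity_mentions(normalize_text(text), gene_lexicon):
            counts[men.entity_id] = counts.get(men.entity_id, 0) + 1
    for token in document.gene_fields:
        for eid in gene_lexicon.lookup(token):
            counts[eid] = counts.get(eid, 0) + 1
    return sorted(counts, key=lambda g: (-counts[g], g))


def _proximity_tier(mention_span, gene_spans, segmentation) -> int:
    """0 same sentence, 1 same paragraph, 2 elsewhere in document."""
    best = 2
    if segmentation is None:
        return best
    sent = segmentation.sentence_of(mention_span.start)
    para = segmentation.paragraph_of(mention_span.start)
    for gs in gene_spans:
        if gs.section != mention_span.section:
            continue
        if sent and sent.start <= gs.start < sent.end:
            return 0
        if para and para.start <= gs.start < para.end:
            best = min(best, 1)
    return best


def associate_gene(
    mention: VariantMention,
    candidates: list[str],
    transcripts: dict[str, TranscriptModel],
    segmentation=None,
    gene_mention_spans: dict[str, list[TextSpan]] | None = None,
    mention_counts: dict[str, int] | None = None,
) -> str | None:
    """Pick the candidate gene whose transcript validates the mention.

    Precedence: same sentence > same paragraph > anywhere in the document,
    then higher document mention count, then alphabetical.  Returns None
    when no candidate validates (the mention is dropped as a false
    positive).
    """
    gene_mention_spans = gene_mention_spans or {}
    mention_counts = mention_counts or {}
    scored: list[tuple[int, int, str]] = []
    for gene in candidates:
        tx = transcripts.get(gene)
        if tx is None:
            continue
        verdict = validate_mention(mention, tx)
        if not verdict.passed and mention.aa_plausible:
            verdict = validate_legacy_as_protein(mention, tx)
        if not verdict.passed:
            continue
        tier = _proximity_tier(mention.span, gene_mention_spans.get(gene, []), segmentation)
        scored.append((tier, -mention_counts.get(gene, 0), gene))
    if not scored:
        return None
    scored.sort()
    return scored[0][2]


def _tier_of_section(name: str) -> str:
    if name == "__title__":
        return "title"
    if name == "__abstract__":
        return "abstract"
    if name == "__metadata__":
        return "metadata"
    if name.startswith("supplement:"):
        return "supplement"
    return "fulltext"


def _hgvs_c(mention: VariantMention) -> str | None:
    if mention.unit != "nt" or mention.pos is None:
        return None
    if mention.utr == "5":
        stem = f"c.-{mention.pos}"
    elif mention.utr == "3":
        stem = f"c.*{mention.pos}"
    elif mention.intron_offset is not None:
        stem = f"c.{mention.pos}{mention.intron_offset:+d}"
    else:
        stem = f"c.{mention.pos}"
    if mention.consequence == "del":
        if mention.del_length and mention.del_length > 1:
            return f"{stem}_{mention.pos + mention.del_length - 1}del"
        return f"{stem}del"
    if mention.ref and mention.alt:
        return f"{stem}{mention.ref}>{mention.alt}"
    return stem


def _normalize_one(
    mention: VariantMention,
    gene: str,
    transcript: TranscriptModel,
    splice: SpliceConfig,
) -> tuple[str | None, str | None, str | None]:
    """(key, hgvs_p, hgvs_c) for a validated mention; key may be None."""
    sc = mention.syntax_class
    if mention.utr is not None:
        return f"{mention.utr}UTR", None, _hgvs_c(mention)
    if sc == SyntaxClass.INTRONIC:
        anchor = mention.pos if mention.intron_offset > 0 else mention.pos - 1
        ip = IntronPosition(anchor, mention.intron_offset)
        return make_mastermind_key(ip, transcript, splice), None, _hgvs_c(mention)
    if mention.unit == "aa" or (
        mention.aa_plausible and not validate_mention(mention, transcript).passed
    ):
        ref, pos = mention.ref, mention.pos
        if mention.consequence == "del":
            return f"{ref}{pos}del", f"p.{ref}{pos}del", None
        if mention.consequence == "fs":
            return f"{ref}{pos}fs", f"p.{ref}{pos}fs", None
        alt = "X" if mention.alt == "*" else mention.alt
        return f"{ref}{pos}{alt}", f"p.{ref}{pos}{alt}", None
    # coding cDNA
    try:
        effect = cdna_to_protein(mention, transcript)
        key = make_mastermind_key(effect)
        alt = "X" if (effect.alt == "*") else effect.alt
        hp = f"p.{effect.ref}{effect.codon}{alt}" if effect.consequence == "substitution" else None
        return key, hp, _hgvs_c(mention)
    except UnkeyedVariant:
        return None, None, _hgvs_c(mention)


def index_document(
    document: Document,
    gene_lexicon: Lexicon,
    transcripts: dict[str, TranscriptModel],
    rsid_map: dict[str, tuple[str, str]] | None = None,
    splice: SpliceConfig | None = None,
    trap_tokens: frozenset[str] = DEFAULT_TRAP_TOKENS,
) -> list[NormalizedVariant]:
    """Run detect -> associate -> normalize -> key over one document.

    Text units are scanned by source tier (title, abstract, fulltext
    sections, supplements); duplicate (gene, key) results merge with
    combined provenance.  Mentions that validate under no candidate gene
    are dropped; unresolvable rsIDs without a nearby gene are dropped with
    a log line.
    """
    splice = splice or SpliceConfig()
    rsid_map = rsid_map or {}
    units: list[tuple[str, str]] = [("__title__", document.title), ("__abstract__", document.abstract)]
    units += [(name, text) for name, text in document.sections]
    units += [(f"supplement:{name}", text) for name, text in document.supplements]
    units = [(n, normalize_text(t)) for n, t in units if t]

    candidates = resolve_candidate_genes(document, gene_lexicon)
    counts: dict[str, int] = {}
    spans_by_unit: dict[str, dict[str, list[TextSpan]]] = {}
    for name, text in units:
        per_gene: dict[str, list[TextSpan]] = {}
        for men in find_entity_mentions(text, gene_lexicon, section=name):
            per_gene.setdefault(men.entity_id, []).append(men.span)
            counts[men.entity_id] = counts.get(men.entity_id, 0) + 1
        spans_by_unit[name] = per_gene

    results: dict[tuple[str, str], NormalizedVariant] = {}
    for name, text in units:
        seg = segment(text, section=name)
        tier = _tier_of_section(name)
        for mention in detect_variant_mentions(text, section=name, trap_tokens=trap_tokens):
            if mention.syntax_class == SyntaxClass.RSID:
                mapped = rsid_map.get(mention.rsid)
                if mapped:
                    gene, key = mapped
                    nv = NormalizedVariant(gene, key, rsid=mention.rsid)
                else:
                    gene = _nearest_gene(mention, spans_by_unit[name], seg, counts)
                    if gene is None:
                        log.debug("pmid %s: unresolved rsID rs%s dropped", document.pmid, mention.rsid)
                        continue
                    nv = NormalizedVariant(gene, None, rsid=mention.rsid)
            else:
                gene = associate_gene(
                    mention, candidates, transcripts, seg,
                    spans_by_unit[name], counts,
                )
                if gene is None:
                    continue
                tx = transcripts[gene]
                key, hp, hc = _normalize_one(mention, gene, tx, splice)
                if key is None and hc is None:
                    continue
                nv = NormalizedVariant(gene, key, hgvs_p=hp, hgvs_c=hc)
            ident = nv.identity
            if ident in results:
                existing = results[ident]
                existing.provenance.append((document.pmid, mention.span, tier))
                if nv.hgvs_c and not existing.hgvs_c:
                    existing.hgvs_c = nv.hgvs_c
                if nv.hgvs_p and not existing.hgvs_p:
                    existing.hgvs_p = nv.hgvs_p
            else:
                nv.provenance.append((document.pmid, mention.span, tier))
                results[ident] = nv
    return list(results.values())


def _nearest_gene(mention, per_gene_spans, seg, counts) -> str | None:
    scored = []
    for gene, spans in per_gene_spans.items():
        tier = _proximity_tier(mention.span, spans, seg)
        scored.append((tier, -counts.get(gene, 0), gene))
    if not scored:
        return None
    scored.sort()
    return scored[0][2] if scored[0][0] < 2 else None


# ---------------------------------------------------------------------------
# CVR export (VCF)
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def export_cvr(
    variants: list[NormalizedVariant],
    transcripts: dict[str, TranscriptModel],
    max_ref_span: int = 3,
) -> str:
    """Render indexed variants as VCFv4.2 text with reference counts.

    Only variants with a genomically mappable cDNA description and a
    reference span shorter than ``max_ref_span + 1`` nucleotides are
    emitted; INFO carries GENE, KEY and REFCOUNT (provenance count).
    Unmappable variants are skipped with a warning and tallied.
    """
    contigs: dict[str, int] = {}
    rows: list[tuple[str, int, str, str, str]] = []
    skipped = 0
    for nv in sorted(variants, key=lambda v: (v.gene, v.key or "")):
        hc = nv.hgvs_c
        tx = transcripts.get(nv.gene)
        if not hc or tx is None:
            skipped += 1
            continue
        m = re.fullmatch(r"c\.(\d+)(?:_(\d+))?(?:([ACGT])>([ACGT])|del)", hc)
        if not m:
            skipped += 1
            log.warning("cannot map %s %s to genome", nv.gene, hc)
            continue
        start_c = int(m.group(1))
        end_c = int(m.group(2)) if m.group(2) else start_c
        span = end_c - start_c + 1
        if m.group(3):  # SNV
            loc = tx.genomic_position(tx.cdna_index(start_c))
            if loc is None:
                skipped += 1
                continue
            chrom, gpos, strand = loc
            ref, alt = m.group(3), m.group(4)
            if strand == "-":
                ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
            rows.append((chrom, gpos + 1, ref, alt, _info(nv)))
            contigs[chrom] = max(contigs.get(chrom, 0), gpos + 2)
            continue
        # deletion: anchored at the base before; excluded when >= 4 nt
        if span > max_ref_span:
            continue
        locs = [tx.genomic_position(tx.cdna_index(c)) for c in range(start_c - 1, end_c + 1)]
        if any(l is None for l in locs) or len({l[0] for l in locs}) != 1:
            skipped += 1
            log.warning("deletion %s %s spans unmappable bases", nv.gene, hc)
            continue
        positions = [l[1] for l in locs]
        if max(positions) - min(positions) != len(positions) - 1:
            skipped += 1
            log.warning("deletion %s %s crosses an exon junction", nv.gene, hc)
            continue
        strand = locs[0][2]
        bases = tx.cdna[tx.cdna_index(start_c - 1) - 1 : tx.cdna_index(end_c)]
        if strand == "-":
            bases = bases.translate(_COMPLEMENT)[::-1]
        chrom = locs[0][0]
        rows.append((chrom, min(positions) + 1, bases, bases[0], _info(nv)))
        contigs[chrom] = max(contigs.get(chrom, 0), max(positions) + 2)

    lines = ["##fileformat=VCFv4.2"]
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Associated gene symbol">',
        '##INFO=<ID=KEY,Number=1,Type=String,Description="Protein-level variant key">',
        '##INFO=<ID=REFCOUNT,Number=1,Type=Integer,Description="Number of citing references">',
    ]
    for chrom in sorted(contigs):
        lines.append(f"##contig=<ID={chrom},length={contigs[chrom] + 1000}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for chrom, pos, ref, alt, info in sorted(rows):
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}")
    if skipped:
        log.info("export_cvr: %d variants skipped", skipped)
    return "\n".join(lines) + "\n"


def _info(nv: NormalizedVariant) -> str:
    return f"GENE={nv.gene};KEY={nv.key};REFCOUNT={len(nv.provenance)}"
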