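"""Gene/disease/keyword vocabularies and entity-mention search.

A :class:`Lexicon` maps canonical entries (HGNC-style gene symbols, MeSH-style
disease headings) and their synonyms to occurrences in normalized text.  The
matching case policy controls false positives from English words colliding
with short gene aliases (``WAS``, ``MET``): synonyms of up to four characters
written in upper case match case-sensitively, longer synonyms match
case-insensitively.  Synonyms shared by several entries are retained but
flagged ambiguous; disambiguation is deferred to whole-article context in the
variant and fusion extractors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from litvariant.corpus import TextSpan

__all__ = [
    "GeneEntry",
    "DiseaseEntry",
    "Lexicon",
    "KeywordLexicon",
    "EntityMention",
    "PrunePolicy",
    "LexiconError",
    "load_lexicons",
    "default_keyword_lexicon",
    "prune_nonspecific_synonyms",
    "find_entity_mentions",
    "find_entity_mentions_bruteforce",
]

REQUIRED_KEYWORD_CATEGORIES = (
    "mutation", "cnv", "fusion", "expression", "cancer", "deletion_amplification",
)


class LexiconError(ValueError):
    pass


@dataclass
class GeneEntry:
    """One gene: canonical symbol, synonyms and optional annotation."""

    symbol: str
    synonyms: set[str] = field(default_factory=set)
    transcript_id: str | None = None
    locus: tuple[str, int, int, str] | None = None  # chrom, start, end, strand

    def __post_init__(self) -> None:
        self.synonyms = set(self.synonyms)
        self.synonyms.add(self.symbol)


@dataclass
class DiseaseEntry:
    heading: str
    synonyms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.synonyms = set(self.synonyms)
        self.synonyms.add(self.heading)


@dataclass(frozen=True)
class EntityMention:
    entity_id: str
    synonym: str
    span: TextSpan


@dataclass
class PrunePolicy:
    """Approximation of manual non-specific-synonym review."""

    min_length: int = 3
    stoplist: frozenset[str] = frozenset()
    ambiguity_cap: int = 5


class Lexicon:
    """Synonym-indexed entity vocabulary with compiled match automata."""

    def __init__(self, entries: dict[str, GeneEntry | DiseaseEntry]):
        self.entries = entries
        self._rebuild()

    # -- index ------------------------------------------------------------

    @staticmethod
    def _case_sensitive(synonym: str) -> bool:
        return len(synonym) <= 4 and synonym.isupper()

    def _rebuild(self) -> None:
        self.exact: dict[str, set[str]] = {}
        self.folded: dict[str, set[str]] = {}
        for eid, entry in self.entries.items():
            for syn in entry.synonyms:
                if self._case_sensitive(syn):
                    self.exact.setdefault(syn, set()).add(eid)
                else:
                    self.folded.setdefault(syn.lower(), set()).add(eid)
        self.ambiguous: set[str] = {
            s for s, ids in self.exact.items() if len(ids) > 1
        } | {s for s, ids in self.folded.items() if len(ids) > 1}
        self._regex_cs = self._compile(self.exact.keys(), flags=0)
        self._regex_ci = self._compile(self.folded.keys(), flags=re.IGNORECASE)

    @staticmethod
    def _compile(synonyms, flags: int) -> re.Pattern | None:
        syns = sorted(synonyms, key=len, reverse=True)
        if not syns:
            return None
        body = "|".join(re.escape(s) for s in syns)
        return re.compile(rf"(?<![A-Za-z0-9])(?:{body})(?![A-Za-z0-9])", flags)

    # -- queries -----------------------------------------------------------

    def lookup(self, token: str) -> set[str]:
        """Entity ids for a verbatim token under the case policy."""
        hits = set(self.exact.get(token, ()))
        hits |= self.folded.get(token.lower(), set())
        return hits

    def is_ambiguous(self, synonym: str) -> bool:
        return synonym in self.ambiguous or synonym.lower() in self.ambiguous

    def symbols(self) -> list[str]:
        return sorted(self.entries)


class KeywordLexicon:
    """Lower-cased mechanism/context terms grouped by category."""

    def __init__(self, categories: dict[str, set[str]]):
        for cat in REQUIRED_KEYWORD_CATEGORIES:
            if not categories.get(cat):
                raise LexiconError(f"keyword category {cat!r} is empty or missing")
        self.categories = {c: {t.lower() for t in ts} for c, ts in categories.items()}
        self._patterns = {
            c: re.compile(
                r"(?<![A-Za-z0-9])(?:"
                + "|".join(re.escape(t).replace(r"\ ", r"[\s-]+") for t in sorted(ts, key=len, reverse=True))
                + r")(?![A-Za-z0-9])",
                re.IGNORECASE,
            )
            for c, ts in self.categories.items()
        }

    def categories_in(self, text: str) -> set[str]:
        return {c for c, pat in self._patterns.items() if pat.search(text)}

    def contains(self, category: str, text: str) -> bool:
        return bool(self._patterns[category].search(text))

    def terms_in(self, category: str, text: str) -> list[str]:
        return [m.group(0) for m in self._patterns[category].finditer(text)]


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _parse_rows(rows, kind: str):
    """Parse 2-column TSV rows: canonical id TAB pipe-delimited synonyms."""
    out: dict[str, set[str]] = {}
    for i, raw in enumerate(rows, 1):
        line = raw.rstrip("\n") if isinstance(raw, str) else "\t".join(raw)
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if not parts[0].strip():
            raise LexiconError(f"{kind} row {i}: empty canonical id")
        if len(parts) > 2:
            raise LexiconError(f"{kind} row {i}: expected 2 columns, got {len(parts)}")
        canon = parts[0].strip()
        if canon in out:
            raise LexiconError(f"{kind} row {i}: duplicate canonical id {canon!r}")
        syns = set()
        if len(parts) == 2 and parts[1].strip():
            syns = {s.strip() for s in parts[1].split("|") if s.strip()}
        out[canon] = syns
    return out


def default_keyword_lexicon() -> KeywordLexicon:
    """The built-in keyword categories shipped as package data."""
    text = resources.files("litvariant.data").joinpath("default_keywords.yaml").read_text()
    data = yaml.safe_load(text)
    return KeywordLexicon({c: set(ts) for c, ts in data.items()})


def load_lexicons(gene_rows, disease_rows=(), keyword_rows=None):
    """Build (gene lexicon, disease lexicon, keyword lexicon) from TSV rows.

    Gene/disease rows are 2-column TSV (canonical, pipe-delimited synonyms).
    Keyword rows are ``category<TAB>term`` pairs; when absent the built-in
    defaults ship.  Malformed rows and duplicate canonical ids raise
    :class:`LexiconError` with the offending row number.
    """
    genes = {
        sym: GeneEntry(symbol=sym, synonyms=syns)
        for sym, syns in _parse_rows(gene_rows, "gene").items()
    }
    diseases = {
        h: DiseaseEntry(heading=h, synonyms=syns)
        for h, syns in _parse_rows(disease_rows, "disease").items()
    }
    if keyword_rows:
        cats: dict[str, set[str]] = {}
        for i, raw in enumerate(keyword_rows, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LexiconError(f"keyword row {i}: expected 2 columns")
            cats.setdefault(parts[0].strip(), set()).add(parts[1].strip())
        kw = KeywordLexicon(cats)
    else:
        kw = default_keyword_lexicon()
    return Lexicon(genes), Lexicon(diseases), kw


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune_nonspecific_synonyms(lexicon: Lexicon, policy: PrunePolicy) -> Lexicon:
    """Drop synonyms that are too short, stoplisted, numeric or too shared.

    Canonical symbols/headings are never removed.  Returns a new lexicon;
    the input is left untouched.  Pruning is monotone: the pruned lexicon
    can only lose mentions relative to the unpruned one.
    """
    stop = {w.lower() for w in policy.stoplist}
    share: dict[str, int] = {}
    for entry in lexicon.entries.values():
        for syn in entry.synonyms:
            share[syn.lower()] = share.get(syn.lower(), 0) + 1

    new_entries: dict[str, GeneEntry | DiseaseEntry] = {}
    for eid, entry in lexicon.entries.items():
        canon = entry.symbol if isinstance(entry, GeneEntry) else entry.heading
        keep = set()
        for syn in entry.synonyms:
            if syn == canon:
                keep.add(syn)
                continue
            if len(syn) < policy.min_length:
                continue
            if syn.lower() in stop:
                continue
            if syn.isdigit():
                continue
            if share[syn.lower()] > policy.ambiguity_cap:
                continue
            keep.add(syn)
        if isinstance(entry, GeneEntry):
            new_entries[eid] = GeneEntry(entry.symbol, keep, entry.transcript_id, entry.locus)
        else:
            new_entries[eid] = DiseaseEntry(entry.heading, keep)
    return Lexicon(new_entries)


# ---------------------------------------------------------------------------
# Mention search
# ---------------------------------------------------------------------------

def find_entity_mentions(text: str, lexicon: Lexicon, section: str = "") -> list[EntityMention]:
    """All maximal word-boundary entity matches in normalized text.

    Overlapping candidates resolve to the longest (then leftmost) match;
    a synonym mapping to several entries yields one mention per entry.
    """
    by_span: dict[tuple[int, int], set[str]] = {}
    if lexicon._regex_cs is not None:
        for m in lexicon._regex_cs.finditer(text):
            ids = lexicon.exact.get(m.group(0))
            if ids:
                by_span.setdefault((m.start(), m.end()), set()).update(ids)
    if lexicon._regex_ci is not None:
        for m in lexicon._regex_ci.finditer(text):
            ids = lexicon.folded.get(m.group(0).lower())
            if ids:
                by_span.setdefault((m.start(), m.end()), set()).update(ids)
    return _resolve_overlaps(text, by_span, section)


def _resolve_overlaps(text: str, by_span: dict, section: str) -> list[EntityMention]:
    mentions: list[EntityMention] = []
    last_end = -1
    for (start, end), ids in sorted(by_span.items(), key=lambda kv: (kv[0][0], -(kv[0][1] - kv[0][0]))):
        if start < last_end:
            continue
        for eid in sorted(ids):
            mentions.append(EntityMention(eid, text[start:end], TextSpan(section, start, end)))
        last_end = end
    return mentions


def find_entity_mentions_bruteforce(text: str, lexicon: Lexicon, section: str = "") -> list[EntityMention]:
    """Independent oracle: scan every synonym one at a time.

    Quadratic; intended for equivalence checks on small corpora only.
    """
    by_span: dict[tuple[int, int], set[str]] = {}
    for eid, entry in lexicon.entries.items():
        for syn in entry.synonyms:
            flags = 0 if Lexicon._case_sensitive(syn) else re.IGNORECASE
            pat = re.compile(rf"(?<![A-Za-z0-9]){re.escape(syn)}(?![A-Za-z0-9])", flags)
            for m in pat.finditer(text):
                by_span.setdefault((m.start(), m.end()), set()).add(eid)
    return _resolve_overlaps(text, by_span, section)
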