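# Methods

This note documents the models, rules and numerical conventions behind
litvariant: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where design
choices were genuinely open.

## Text normalization and segmentation

All extractors run on *normalized* text: a fixed substitution table spells
out Greek letters, collapses the arrow family (`→`, `-->`, `->`) onto the
HGVS operator `>`, unifies the deletion markers `Δ`/`delta`/`Delta` to the
canonical token `Delta`, maps typographic dashes and exotic spaces to
ASCII, and removes soft hyphens.  The table is idempotent by construction
(verified by a property test on random unicode), so offsets into normalized
text form a single stable coordinate space — 0-based half-open codepoint
intervals — that every downstream span references.

Reference sections are excluded by heading match ("References",
"Bibliography", "Literature cited", case-insensitive).  Heading-based
detection is a deliberate simplification of layout-aware reference
detection; an optional toggle additionally drops a trailing block of
numbered citations from the last body section (off by default because it
edits retained text).  No other section types are treated as extraneous.

Sentences split on terminal punctuation followed by whitespace and an
uppercase letter or digit, protected by an abbreviation list ("e.g.",
"Fig.", "et al.", single-initial names, ...); paragraphs split on blank
lines.  Segmentation feeds the same-sentence/same-paragraph windows used
by gene association, gene-level CNV extraction, fusion co-mention and
mechanism profiling, so those four stages share one notion of "nearby".

## Vocabularies

Gene and disease lexicons are 2-column TSVs (canonical id, pipe-delimited
synonyms).  Matching case policy: synonyms of ≤ 4 characters written in
upper case match case-sensitively (`WAS` the gene vs "was"), longer
synonyms case-insensitively; matches require non-alphanumeric boundaries
and overlaps resolve to the longest match.  Synonym pruning
(`min_length=3`, an optional English stoplist, purely numeric synonyms,
and synonyms shared by more than `ambiguity_cap=5` entries) approximates
the manual removal of non-specific aliases that production systems apply;
canonical symbols are never pruned, and pruning is provably monotone on
the mention set.  Shared synonyms that survive pruning are retained but
flagged ambiguous; final resolution is deferred to whole-article context.

Keyword categories (mutation, cnv, fusion, expression, cancer,
deletion_amplification) ship as package data in YAML and are fully
overridable; published pipelines do not disclose their exact lists, so the
defaults are ordinary mechanism vocabulary.

## Variant recognition and normalization

The pattern inventory covers every nomenclature family the package aims
at: HGVS cDNA (`c.1799T>A`, `c.100_102del`, `c.-15A>G`, `c.*20del`,
`c.240+1G>A`), protein 1- and 3-letter substitutions (stop as `X` or `*`),
deletions (`F508del`, `DeltaF508`, `Delta-F508`, `DeltaPhe508` after
normalization of `Δ`), frameshifts (`M123fs`), legacy three-token forms
(`T1799A`, `1799 T > A`) and rsIDs.  Patterns are tried in specificity
order and overlapping candidates resolve to the earliest/longest match.
False-positive suppression uses word boundaries plus a small extensible
trap list of non-variant tokens (cell lines such as T47D).

Validation checks the stated reference against the transcript: protein
mentions against the protein sequence, cDNA mentions against the CDS,
UTR/intronic mentions against region structure (an intron must actually
exist at the stated junction).  A legacy token whose letters are all
nucleotides is validated as cDNA first and re-read as a protein
substitution only when the cDNA reading fails — validation is the
disambiguator, matching how such tokens must be reconciled in practice.

cDNA→protein conversion takes codon `ceil(pos/3)`, translates reference
and mutated codons (Biopython), and classes indels by length: not a
multiple of three → frameshift at the index codon; a single aligned codon
→ residue deletion; longer in-frame events and insertions/duplications
are detected but deliberately *unkeyed* (kept with their HGVS string
only), since the key grammar defines no form for them.

Splice-region keying is parameterized (`SpliceConfig`): intron offsets
±1–2 are splice site (`sd`/`sa`), ±3–8 splice region (`srd`/`sra`), and
anything deeper `int`; the exact extent of the splice region is not fixed
by any standard, so the window is configurable and the 3 coding bases
flanking a junction can also be flagged.  The index amino acid is always
the residue coded at the intron's 5′ side.

Gene association evaluates each mention against all candidate genes of the
article (any gene mentioned in title, abstract, metadata or body, ordered
by mention count): among validating candidates, same sentence beats same
paragraph beats anywhere, then higher mention count, then alphabetical
order.  This tie-break chain is this package's concretization of
"whole-article context"; it is deterministic and fully tested.
Unresolved rsIDs (no entry in the optional rsID map) attach to the nearest
gene as rsID-keyed entities or are dropped when no gene is nearby.

### Transcript JSON schema

A transcript is a JSON object `{gene, transcript_id, cdna, cds_start,
cds_end, protein, exons}` with 1-based inclusive CDS bounds in cDNA
coordinates and exon rows `[cdna_start, cdna_end, chrom, g_start, g_end,
strand]` (genomic 0-based half-open).  Construction enforces: CDS length
divisible by 3, CDS translation equal to the protein, exons tiling the
cDNA.  A file is a JSON array of such objects.

### CVR (VCF) export

Indexed variants with a mappable coding cDNA description are written as
VCFv4.2 with INFO fields GENE, KEY and REFCOUNT (provenance count).
Deletions anchor at the preceding base; minus-strand transcripts emit
reverse-complemented alleles.  Events whose reference span is ≥ 4 nt are
excluded by design, deletions crossing exon junctions and region-keyed
entities (5UTR/3UTR/splice) are skipped with a warning and tallied.

## CNV extraction and matching

Cytoband tables follow the UCSC `cytoBand.txt` convention (0-based
half-open; a loader flag converts 1-based listings).  Lookups accept exact
bands (`22q11.2`), prefixes spanning sub-bands (`22q11`), and whole arms
(`11q` = the union of that arm's bands).  Band ranges expand to every
intervening band; expansion requires both endpoints on one chromosome and
yields a contiguous run.

The ISCN subset parsed is exactly what CNV extraction needs:
`del/dup/amp(chrom)(band[band2])`, comma-context `+N`/`-N` whole-chromosome
gains/losses, and translocations `t(a;b)(p;q)` — recorded as rearrangements
but never as CNV intervals.  Gene/exon-level citations require a gene
mention and a deletion/amplification term in the same sentence; expression
vocabulary never triggers a citation, and an "exon N" phrase upgrades the
level to EXON.  Direction is DEL or AMP only when the sentence's terms are
unanimous, otherwise UNKNOWN.

Match classification fixes the geometry unambiguously: SURROUNDING means
the citation contains the query and CONTAINED means the citation lies
within it, consistent with the priority order Exact, Contained,
Surrounding, Intersecting.  The prose this order derives from admits both
readings; the package states its choice here and sorts matches by type,
then overlap proportion of the query (descending), then citation size
(ascending).  Classification is verified against a brute-force
set-relation oracle on 10^5 random integer-grid interval pairs.

## Fusion pairs

Delimiter extraction (`gene1:gene2`, `gene1/gene2`, `gene1-gene2`) demands
that both tokens resolve to distinct lexicon genes and that the joined
token is not itself a gene symbol (`HLA-B`).  Ambiguous-synonym tokens are
rejected unless a fusion keyword co-occurs.  Sentence/paragraph co-mention
extraction requires a fusion-category keyword in the window; the keyword
gate substitutes for the manual validation step a production pipeline
applies to plain co-mentions, and can be switched off.  Paragraph-level
co-mentions are recorded at lower confidence and excluded from the default
end-to-end aggregation: pairing genes across sentences within a paragraph
is exactly the regime that manual review exists to clean up, and keeping it
out of the automatic path keeps extraction precision exact.

Canonical pairs are alphabetical; the cited 5′/3′ order is preserved in
per-order counts because it matters clinically even though article merging
ignores it.  Comparison against a reference list partitions pairs into
common/novel/reference-only, reports per-common-pair article-count ratios
and the overall unique-pair yield increase `(N_tool − N_ref)/N_ref × 100 %`
(not applicable for an empty reference).

## Article ranking and panels

Articles supporting a gene are eligible when the gene appears in title or
abstract, and rank by gene-in-title, then citation count (metadata;
missing → 0; no citation source is prescribed), then cancer keyword in
title, with ascending numeric pmid as the final tie-break so all sorts are
total and stable.  Mechanism profiles evaluate the gene-mentioning
full-text sentences of the top 100 ranked articles (all of them if fewer)
and report, per category, the percentage of sentences containing at least
one category keyword; a sentence can count toward several categories, and
a zero-sentence profile is flagged undefined rather than silently zero.
Panel reports carry the top-10 pmids with titles.  Panel comparison is
plain set algebra (union, consensus, exactly-one-panel, per-k counts,
pairwise overlap matrix) over caller-supplied gene lists; search-result
ranking puts exact-cDNA matches above same-key protein matches above
key-group matches, then applies the article rank key within tiers.

## Benchmark tables

The four bundled TSVs are transcriptions of printed comparison tables
(per-variant resource counts for 108 clinically encountered variants;
27-gene interpretation-category counts; 10-cytoband CNV reference counts;
127 common fusion pairs plus unique-pair totals 1,896 vs 297).  The module
recomputes every derived figure: means of per-row true-positive
percentages are taken over rows where the resource returned at least one
paper (rows with zero papers have no percentage — required to reproduce
the printed per-resource means); reference-level sensitivity divides by
the union estimate (first-resource true positives plus the aggregate 13
references it missed, which the source reports only in aggregate);
per-gene and per-row fold ratios are rounded half-up to one decimal before
averaging, matching how the printed summary rows were formed.  Rounding is
half-up at one decimal everywhere.  Two flags in the variant table (MORE,
MISSING) depend on reference identity rather than counts — one row carries
MORE with tied counts — so they are fixture-carried; ONLY is recomputed.

## Synthetic corpus generator

The generator plants variants (every supported nomenclature style plus a
deliberately unsupported prose style for recall-degradation testing), CNVs
(cytoband tokens and ranges, karyotype events including whole-chromosome
gains, gene-level deletion/amplification phrases) and fusions (three
delimiter formats and keyworded sentence co-mention) into templated
sentences alongside decoys (cell lines, protein-family tokens, figure
references, hyphenated single-gene symbols, expression phrasing).  Toy
transcripts are random sequences with engineered codons so that the
classic worked coordinates hold, and every planted mention is true by
construction against its transcript; expected keys are derived during
generation by direct codon translation with Biopython, independent of the
extraction code under test.  Ambiguous three-token protein forms (both
letters also bases, e.g. `A185G`) are planted only through the legacy
cDNA styles, because their correct resolution is validation-dependent by
design.  Generation is driven entirely by one `random.Random(seed)`
stream, so a spec plus seed reproduces the corpus byte for byte on any
platform.

What passing the end-to-end suite shows — and what it does not: perfect
precision/recall on this corpus demonstrates that each extractor handles
every supported nomenclature with its context requirements satisfied and
rejects the planted decoy families.  Real articles contain OCR noise,
tables, unseen nomenclatures, genuinely ambiguous gene symbols and
cross-sentence coreference that the templates do not emulate, so these
scores are upper bounds, not field estimates.

Default study conditions: 100 documents, 1–2 variants, 0–1 CNVs, 0–1
fusions and 1–3 decoys per document, publication years 1995–2020 —
a small corpus in which every extractor stage is exercised while the whole
suite stays fast.

## Known limitations

* The regular-expression inventory is extensible but not exhaustive;
  genuinely novel author nomenclatures fall outside it (by design the
  synthetic prose style measures exactly this failure mode).
* Reference-section detection is heading-based; references embedded
  without a heading are only caught by the optional trailing-block toggle.
* CVR export covers coding substitutions and short aligned deletions;
  region-keyed entities have no single-base genomic anchor in this schema.
* Karyotype parsing covers the CNV-relevant ISCN subset only (no
  `der`/`idem`/`mar` forms).
* Disease/phenotype/therapy annotation beyond MeSH-style disease lexicons
  is out of scope.
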