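# litvariant

Literature mining for clinical genomics: recognize genetic-variant mentions
in article text in any of the nomenclatures authors actually use, validate
them against transcript and protein sequences, normalize them to
protein-level keys, and do the same for copy-number variants (cytobands,
ISCN karyotypes, gene/exon-level phrases) and gene-fusion pairs.  On top of
the extractors sit article-ranking utilities for evidence-based gene-panel
design and a benchmark module that recomputes database-comparison summary
statistics from bundled tables.

## Who this is for

Groups building or evaluating genomic literature indexes: variant-curation
teams that need one canonical identifier for the dozens of ways a variant
is written ("V600E", "p.Val600Glu", "c.1799T>A", "T1799A", "1799 T → A"),
and methodologists who want a ground-truthed synthetic corpus to measure an
extractor's precision and recall without any proprietary data.

## The core normalization

Every validated mention is reduced to a **protein-level key** that groups
equivalent citations:

| form | key |
|---|---|
| substitution | `V600E` (stop gained → `X`, as in `R19X`) |
| single-residue deletion | `F508del` |
| frameshift | `M123fs` (index = first shifted codon) |
| splice donor / acceptor (first/last 2 intron nt) | `E80sd` / `E80sa` |
| splice region (intron nt 3–8 from the junction) | `E80srd` / `E80sra` |
| deeper intronic | `E80int` |
| untranslated regions | `5UTR` / `3UTR` |

Intronic keys are indexed by the amino acid coded at the 5′ side of the
intron.  cDNA numbering is HGVS (A of the start codon = c.1; `c.-n` and
`c.*n` for the UTRs).  A legacy token such as `T1799A` is read as cDNA when
it validates against the candidate gene's transcript and as a protein
substitution otherwise — sequence validation is the disambiguator, and a
mention that validates under no candidate gene is dropped as a false
positive.  Gene association prefers a validating gene in the same sentence,
then the same paragraph, then the document, breaking ties by mention count
and alphabetically.

CNV citations are normalized to 0-based half-open genomic intervals through
a UCSC-format cytoband table and classified against a query interval as
**Exact**, **Contained** (citation within query), **Surrounding** (citation
contains query) or **Intersecting**, listed in that order.  Fusion pairs
cited in either order (`NPM1-ALK`, `ALK/NPM1`) merge into one canonical
alphabetical entry with per-order and per-format counts.

## Worked example

```python
from litvariant import Document, index_document
from litvariant.synth import toy_gene_lexicon, toy_transcripts

doc = Document(
    pmid="104",
    title="BRAF mutations in melanoma",
    abstract="The recurrent BRAF T1799A (V600E) mutation was characterised.",
    sections=[("Results", "We confirmed BRAF c.1799T>A in 40 of 52 tumors. "
                          "One case carried the splice variant BRAF c.240+1G>A.")],
)
for v in index_document(doc, toy_gene_lexicon(), toy_transcripts()):
    print(f"{v.gene:5s} {v.key:6s} hgvs_c={v.hgvs_c} "
          f"tiers={sorted({t for _,_,t in v.provenance})} n_mentions={len(v.provenance)}")
```

prints

```
BRAF  V600E  hgvs_c=c.1799T>A tiers=['abstract', 'fulltext'] n_mentions=3
BRAF  E80sd  hgvs_c=c.240+1G>A tiers=['fulltext'] n_mentions=1
```

Three textual forms — `T1799A`, `V600E` and `c.1799T>A` — collapse into one
normalized variant with provenance from both the abstract and the full
text; the intronic mention keys as a splice-donor variant at the exon
boundary after codon 80 (a glutamate), hence `E80sd`.

The toy transcripts are synthetic sequences engineered so that well-known
coordinates hold (codon 600 = GTG, codon 508 = TTT, ...); real transcript
models are supplied as JSON (see `docs/methods.md` for the schema).

## Command line

`litvariant` exposes the pipeline as subcommands: `corpus normalize`,
`index`, `cvr` (VCF export of indexed variants affecting < 4 nt, with
per-variant reference counts), `cnv-match`, `fusions`, `panel-report`,
`panel-compare`, `benchmark` and `synth`.  Run any of them with `--help`.

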