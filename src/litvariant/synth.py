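"""Ground-truthed synthetic corpora for end-to-end extraction testing.

No public corpus with span-level variant/CNV/fusion truth exists at this
scale, so the generator plants entities into templated article text in the
nomenclature styles that occur in real literature — ``V600E``,
``p.Val600Glu``, ``c.1799T>A``, ``T1799A``, ``1799 T → A``, ``ΔF508`` /
``DeltaPhe508`` / ``F508del``, ``M123fs``, UTR and intronic HGVS, rsIDs,
``del(11)(q23)`` karyotypes, cytoband tokens and the three fusion delimiter
formats — alongside decoy sentences (cell lines, protein families, figure
references, single-gene hyphen symbols) that must extract to nothing.

Every planted variant is rendered from a toy transcript built so that the
stated reference base/residue is true by construction; the expected
protein-level key is derived during generation by direct codon translation
(Biopython), independently of the extraction pipeline under test.

Generation is deterministic: the same spec and seed reproduce the corpus
byte for byte.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from Bio.Seq import Seq

from litvariant.corpus import Document
from litvariant.lexicon import GeneEntry, Lexicon
from litvariant.variant_norm import AA1, Exon, TranscriptModel

__all__ = [
    "CorpusSpec",
    "GroundTruth",
    "generate_corpus",
    "score_extraction",
    "toy_transcripts",
    "toy_cytoband_rows",
    "toy_gene_lexicon",
    "toy_rsid_map",
    "VARIANT_STYLES",
    "CNV_STYLES",
    "FUSION_STYLES",
]

VARIANT_STYLES = (
    "aa1", "aa3", "cdna", "legacy", "legacy_spaced",
    "del_hgvs", "delta", "delta_hyphen", "delta_aa3",
    "fs", "utr5", "utr3", "intronic", "rsid",
    "prose",  # deliberately outside the extractor inventory
)
CNV_STYLES = ("cytoband", "cytoband_range", "karyotype", "karyotype_gain", "gene_del", "gene_amp")
FUSION_STYLES = ("hyphen", "colon", "slash", "sentence")

_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if str(Seq(a + b + c).translate()) not in ("*",)
]


# ---------------------------------------------------------------------------
# Toy reference data
# ---------------------------------------------------------------------------

def _build_transcript(
    gene: str,
    n_codons: int,
    rng: random.Random,
    codon_overrides: dict[int, str],
    exon_codon_bounds: list[int],
    chrom: str,
    g_offset: int,
    strand: str = "+",
    utr5: int = 30,
    utr3: int = 30,
) -> TranscriptModel:
    codons = [rng.choice(_CODONS) for _ in range(n_codons)]
    codons[0] = "ATG"
    for idx, codon in codon_overrides.items():
        codons[idx - 1] = codon
    cds = "".join(codons) + "TAA"
    five = "".join(rng.choice("ACGT") for _ in range(utr5))
    three = "".join(rng.choice("ACGT") for _ in range(utr3))
    cdna = five + cds + three
    cds_start = utr5 + 1
    cds_end = utr5 + len(cds)
    protein = str(Seq(cds).translate())[:-1]

    # exon boundaries are given as last *coding* position of each non-final exon
    cut_points = [utr5 + 3 * b for b in exon_codon_bounds if 3 * b < len(cds)]
    bounds = sorted(set(cut_points)) + [len(cdna)]
    exons: list[Exon] = []
    pos = 1
    gpos = g_offset
    intron = 500
    for end in bounds:
        length = end - pos + 1
        exons.append(Exon(pos, end, chrom, gpos, gpos + length, strand))
        gpos += length + intron
        pos = end + 1
    return TranscriptModel(
        gene=gene, cdna=cdna, cds_start=cds_start, cds_end=cds_end,
        exons=exons, protein=protein, transcript_id=f"SYNTX_{gene}",
    )


def toy_transcripts(seed: int = 0) -> dict[str, TranscriptModel]:
    """Deterministic toy transcripts mimicking well-known worked cases.

    The BRAF-like model has codon 600 = GTG (so c.1799T>A is p.V600E) and
    an exon boundary after codon 80 (= c.240, a glutamate) for the splice
    keys; the CFTR-like model has codon 508 = TTT; the TP53-like model has
    codon 123 = ATG.  Sequences are synthetic, not the real genes'.
    """
    rng = random.Random(seed)
    txs = {}
    txs["BRAF"] = _build_transcript(
        "BRAF", 640, rng,
        codon_overrides={600: "GTG", 80: "GAA"},
        exon_codon_bounds=[80, 320],
        chrom="chr7", g_offset=140_000_000,
    )
    txs["CFTR"] = _build_transcript(
        "CFTR", 560, rng,
        codon_overrides={508: "TTT"},
        exon_codon_bounds=[250],
        chrom="chr7", g_offset=117_000_000,
    )
    txs["TP53"] = _build_transcript(
        "TP53", 200, rng,
        codon_overrides={123: "ATG"},
        exon_codon_bounds=[60],
        chrom="chr17", g_offset=7_500_000, strand="-",
    )
    txs["KRAS"] = _build_transcript(
        "KRAS", 189, rng,
        codon_overrides={12: "GGT", 61: "CAA"},
        exon_codon_bounds=[37, 97],
        chrom="chr12", g_offset=25_200_000, strand="-",
    )
    txs["EGFR"] = _build_transcript(
        "EGFR", 300, rng,
        codon_overrides={290: "TGC"},
        exon_codon_bounds=[120],
        chrom="chr7", g_offset=55_000_000,
    )
    txs["PTEN"] = _build_transcript(
        "PTEN", 403, rng,
        codon_overrides={130: "CGA"},
        exon_codon_bounds=[85, 212],
        chrom="chr10", g_offset=89_600_000,
    )
    return txs


def toy_cytoband_rows() -> list[str]:
    """A small contiguous UCSC-format band table (0-based half-open).

    The chr22 and chr11 rows reproduce the published coordinates used in
    the worked examples (22q11.2 = chr22:17,400,000-25,500,000; 11q23 =
    chr11:110,600,000-121,300,000).
    """
    rows = [
        ("chr22", 0, 10_000_000, "p12"),
        ("chr22", 10_000_000, 14_700_000, "p11"),
        ("chr22", 14_700_000, 17_400_000, "q11.1"),
        ("chr22", 17_400_000, 25_500_000, "q11.2"),
        ("chr22", 25_500_000, 30_000_000, "q12"),
        ("chr22", 30_000_000, 43_800_000, "q13.1"),
        ("chr22", 43_800_000, 50_818_467, "q13.3"),
        ("chr11", 0, 20_000_000, "p15"),
        ("chr11", 20_000_000, 53_700_000, "p11"),
        ("chr11", 53_700_000, 110_600_000, "q14"),
        ("chr11", 110_600_000, 121_300_000, "q23"),
        ("chr11", 121_300_000, 127_000_000, "q24"),
        ("chr11", 127_000_000, 135_086_622, "q25"),
        ("chr5", 0, 48_800_000, "p13"),
        ("chr5", 48_800_000, 68_400_000, "q13"),
        ("chr5", 68_400_000, 98_000_000, "q21"),
        ("chr5", 98_000_000, 139_000_000, "q31"),
        ("chr5", 139_000_000, 159_000_000, "q33"),
        ("chr5", 159_000_000, 181_538_259, "q35"),
        ("chr8", 0, 45_200_000, "p11"),
        ("chr8", 45_200_000, 146_364_022, "q22"),
        ("chr1", 0, 2_300_000, "p36.33"),
        ("chr1", 2_300_000, 125_000_000, "p31"),
        ("chr1", 125_000_000, 248_956_422, "q32"),
        ("chr7", 0, 60_100_000, "p14"),
        ("chr7", 60_100_000, 159_345_973, "q31"),
        ("chr10", 0, 39_800_000, "p12"),
        ("chr10", 39_800_000, 133_797_422, "q23"),
        ("chr17", 0, 24_000_000, "p11.2"),
        ("chr17", 24_000_000, 83_257_441, "q21"),
        ("chr12", 0, 35_500_000, "p12"),
        ("chr12", 35_500_000, 133_275_309, "q21"),
    ]
    return [f"{c}\t{s}\t{e}\t{b}\tgneg" for c, s, e, b in rows]


_FUSION_GENES = ["EML4", "ALK", "NPM1", "NTRK3", "KHDRBS1", "RUNX1", "ETV6", "PML", "RARA"]
_GENE_LOCI = {
    "BRAF": ("chr7", 140_000_000, 140_200_000, "+"),
    "CFTR": ("chr7", 117_000_000, 117_250_000, "+"),
    "TP53": ("chr17", 7_500_000, 7_530_000, "-"),
    "KRAS": ("chr12", 25_200_000, 25_250_000, "-"),
    "EGFR": ("chr7", 55_000_000, 55_200_000, "+"),
    "PTEN": ("chr10", 89_600_000, 89_730_000, "+"),
}


def toy_gene_lexicon() -> Lexicon:
    """Gene lexicon covering the toy transcripts, fusion partners and traps."""
    entries: dict[str, GeneEntry] = {}
    for gene, locus in _GENE_LOCI.items():
        entries[gene] = GeneEntry(gene, {gene}, transcript_id=f"SYNTX_{gene}", locus=locus)
    for gene in _FUSION_GENES:
        entries.setdefault(gene, GeneEntry(gene, {gene}))
    # single genes whose symbols contain fusion delimiters (suppression traps)
    entries["HLA-B"] = GeneEntry("HLA-B", {"HLA-B"})
    return Lexicon(entries)


def toy_rsid_map() -> dict[str, tuple[str, str]]:
    """rsID resolution table for the planted rsID style."""
    return {
        "113488022": ("BRAF", "V600E"),
        "121913529": ("KRAS", "G12D"),
        "121909001": ("PTEN", "R130X"),
    }


# ---------------------------------------------------------------------------
# Spec and truth containers
# ---------------------------------------------------------------------------

@dataclass
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    Defaults emulate a small full-text corpus in which most documents carry
    one or two planted entities in varied nomenclature plus decoy text.
    """

    n_documents: int = 100
    variants_per_doc: tuple[int, int] = (1, 2)
    cnvs_per_doc: tuple[int, int] = (0, 1)
    fusions_per_doc: tuple[int, int] = (0, 1)
    decoys_per_doc: tuple[int, int] = (1, 3)
    variant_styles: tuple[str, ...] = tuple(s for s in VARIANT_STYLES if s != "prose")
    cnv_styles: tuple[str, ...] = CNV_STYLES
    fusion_styles: tuple[str, ...] = FUSION_STYLES
    year_range: tuple[int, int] = (1995, 2020)

    def validate(self) -> None:
        for s in self.variant_styles:
            if s not in VARIANT_STYLES:
                raise ValueError(f"unknown variant style {s!r}")
        for s in self.cnv_styles:
            if s not in CNV_STYLES:
                raise ValueError(f"unknown CNV style {s!r}")
        for s in self.fusion_styles:
            if s not in FUSION_STYLES:
                raise ValueError(f"unknown fusion style {s!r}")


@dataclass
class GroundTruth:
    """Expected extraction output per document."""

    variants: dict[str, set[tuple[str, str]]] = field(default_factory=dict)   # pmid -> {(gene, key)}
    variant_tiers: dict[str, set[tuple[str, str, str]]] = field(default_factory=dict)
    cnvs: dict[str, set[tuple]] = field(default_factory=dict)    # pmid -> {(level, chrom, start, end, direction)}
    fusions: dict[str, set[tuple[str, str]]] = field(default_factory=dict)  # pmid -> {canonical pair}

    def totals(self) -> dict[str, int]:
        return {
            "variants": sum(len(v) for v in self.variants.values()),
            "cnvs": sum(len(v) for v in self.cnvs.values()),
            "fusions": sum(len(v) for v in self.fusions.values()),
        }


# ---------------------------------------------------------------------------
# Rendering helpers
# ---------------------------------------------------------------------------

_AA_NAMES = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}
_AA_FULL = {
    "V": "valine", "E": "glutamate", "A": "alanine", "G": "glycine",
    "R": "arginine", "L": "leucine", "M": "methionine", "F": "phenylalanine",
}


def _pick_substitution(tx: TranscriptModel, rng: random.Random) -> tuple[int, str, str, str, str]:
    """(cds_pos, ref_base, alt_base, ref_aa, alt_aa) with aa change, by construction."""
    for _ in range(200):
        codon_idx = rng.randrange(2, len(tx.protein) + 1)
        offset = rng.randrange(3)
        cds_pos = (codon_idx - 1) * 3 + offset + 1
        codon = tx.cds_seq[(codon_idx - 1) * 3 : codon_idx * 3]
        ref_base = codon[offset]
        alt_base = rng.choice([b for b in "ACGT" if b != ref_base])
        mutated = codon[:offset] + alt_base + codon[offset + 1 :]
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(mutated).translate())
        if alt_aa != ref_aa and alt_aa != "*" and ref_aa in AA1:
            return cds_pos, ref_base, alt_base, ref_aa, alt_aa
    raise RuntimeError("could not sample a missense substitution")


def _render_variant(style: str, gene: str, tx: TranscriptModel, rng: random.Random):
    """(mention text, expected key or None-for-untracked, rsid or None)."""
    if style == "rsid":
        rsid, (g, key) = rng.choice(sorted(toy_rsid_map().items()))
        return f"rs{rsid}", (g, key), rsid

    if style in ("aa1", "aa3", "cdna", "legacy", "legacy_spaced", "prose"):
        cds_pos, ref_b, alt_b, ref_aa, alt_aa = _pick_substitution(tx, rng)
        if style == "aa1":
            # tokens like "A185G" read as legacy cDNA under validation-first
            # disambiguation; plant only unambiguous residue pairs here (the
            # nucleotide-plausible forms are exercised by the legacy styles)
            while {ref_aa, alt_aa} <= set("ACGT"):
                cds_pos, ref_b, alt_b, ref_aa, alt_aa = _pick_substitution(tx, rng)
        codon_idx = (cds_pos - 1) // 3 + 1
        key = f"{ref_aa}{codon_idx}{alt_aa}"
        if style == "aa1":
            text = f"{ref_aa}{codon_idx}{alt_aa}"
        elif style == "aa3":
            text = f"p.{_AA_NAMES[ref_aa]}{codon_idx}{_AA_NAMES[alt_aa]}"
        elif style == "cdna":
            text = f"c.{cds_pos}{ref_b}>{alt_b}"
        elif style == "legacy":
            text = f"{ref_b}{cds_pos}{alt_b}"
        elif style == "legacy_spaced":
            text = f"{cds_pos} {ref_b} → {alt_b}"
        else:  # prose: outside the inventory on purpose
            ref_full = _AA_FULL.get(ref_aa, _AA_NAMES[ref_aa].lower())
            alt_full = _AA_FULL.get(alt_aa, _AA_NAMES[alt_aa].lower())
            text = f"a substitution of {ref_full} to {alt_full} at residue {codon_idx}"
        return text, (gene, key), None

    if style in ("del_hgvs", "delta", "delta_hyphen", "delta_aa3"):
        codon_idx = rng.randrange(2, len(tx.protein) + 1)
        ref_aa = tx.protein[codon_idx - 1]
        key = f"{ref_aa}{codon_idx}del"
        if style == "del_hgvs":
            text = f"{ref_aa}{codon_idx}del"
        elif style == "delta":
            text = f"Δ{ref_aa}{codon_idx}"
        elif style == "delta_hyphen":
            text = f"Δ-{ref_aa}{codon_idx}"
        else:
            text = f"Delta{_AA_NAMES[ref_aa]}{codon_idx}"
        return text, (gene, key), None

    if style == "fs":
        codon_idx = rng.randrange(2, len(tx.protein) + 1)
        ref_aa = tx.protein[codon_idx - 1]
        return f"{ref_aa}{codon_idx}fs", (gene, f"{ref_aa}{codon_idx}fs"), None

    if style == "utr5":
        n = rng.randrange(1, tx.cds_start)
        ref = tx.cdna[tx.cds_start - n - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return f"c.-{n}{ref}>{alt}", (gene, "5UTR"), None

    if style == "utr3":
        tail = len(tx.cdna) - tx.cds_end
        n = rng.randrange(1, tail + 1)
        ref = tx.cdna[tx.cds_end + n - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return f"c.*{n}{ref}>{alt}", (gene, "3UTR"), None

    if style == "intronic":
        donors = sorted(tx.donor_sites())
        if not donors:
            raise ValueError(f"{gene}: no introns for intronic style")
        anchor = rng.choice(donors)
        cds_anchor = anchor - tx.cds_start + 1
        codon_idx = (cds_anchor - 1) // 3 + 1
        aa = tx.protein[codon_idx - 1]
        offset, suffix = rng.choice([(1, "sd"), (2, "sd"), (5, "srd"), (40, "int")])
        ref = rng.choice("ACGT")
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return f"c.{cds_anchor}+{offset}{ref}>{alt}", (gene, f"{aa}{codon_idx}{suffix}"), None

    raise ValueError(f"unknown variant style {style!r}")


_VARIANT_TEMPLATES = [
    "We identified the {gene} {var} mutation in affected individuals.",
    "Sequencing revealed {var} in {gene} in two probands.",
    "The recurrent {gene} {var} change segregated with disease.",
]
_CNV_TEMPLATES = {
    "cytoband": "Array analysis showed a deletion of {band} in three patients.",
    "cytoband_range": "A deletion spanning {band} was confirmed by FISH.",
    "karyotype": "Cytogenetics revealed 46,XX,{event} in two cases.",
    "karyotype_gain": "Cytogenetics revealed 47,XY,{event} in most samples.",
    "gene_del": "Homozygous deletion of {gene} was detected in the tumor cohort.",
    "gene_amp": "{gene} amplification was frequent in resistant samples.",
}
_FUSION_TEMPLATES = {
    "hyphen": "The {g1}-{g2} fusion transcript was detected by RT-PCR.",
    "colon": "We confirmed the {g1}:{g2} fusion in all positive cases.",
    "slash": "The {g1}/{g2} fusion was the sole driver rearrangement.",
    "sentence": "We report a novel fusion of {g1} with {g2} in this tumor type.",
}
_DECOY_SENTENCES = [
    "The S100 protein and the cell line T47D were used as controls.",
    "HLA-B expression was unchanged across groups.",
    "See Fig. 2 for the complete gating strategy.",
    "CD34-positive cells were sorted before culture.",
    "Samples were processed at 37 degrees for 45 min.",
    "Statistical significance was assessed at p < 0.05.",
    "Western blots were quantified with ImageJ software.",
]
_FILLER_SENTENCES = [
    "Patients were recruited after informed consent.",
    "Genomic DNA was extracted from peripheral blood.",
    "All assays were performed in triplicate.",
    "Clinical records were reviewed retrospectively.",
]


def _cnv_truth_and_text(style: str, rng: random.Random):
    """(sentence text, truth tuple). Coordinates follow toy_cytoband_rows."""
    if style == "cytoband":
        band, chrom, s, e = rng.choice([
            ("22q11.2", "chr22", 17_400_000, 25_500_000),
            ("1p36.33", "chr1", 0, 2_300_000),
            ("11q23", "chr11", 110_600_000, 121_300_000),
        ])
        return (_CNV_TEMPLATES[style].format(band=band),
                ("CYTOBAND", chrom, s, e, "DEL"))
    if style == "cytoband_range":
        return (_CNV_TEMPLATES[style].format(band="11q23-q25"),
                ("CYTOBAND", "chr11", 110_600_000, 135_086_622, "DEL"))
    if style == "karyotype":
        event, chrom, s, e, d = rng.choice([
            ("del(22)(q11.2)", "chr22", 17_400_000, 25_500_000, "DEL"),
            ("del(5)(q13q33)", "chr5", 48_800_000, 159_000_000, "DEL"),
            ("dup(1)(p36.33)", "chr1", 0, 2_300_000, "AMP"),
        ])
        return (_CNV_TEMPLATES[style].format(event=event),
                ("KARYOTYPE", chrom, s, e, d))
    if style == "karyotype_gain":
        return (_CNV_TEMPLATES[style].format(event="+8"),
                ("KARYOTYPE", "chr8", 0, 146_364_022, "AMP"))
    if style in ("gene_del", "gene_amp"):
        gene = rng.choice(sorted(_GENE_LOCI))
        chrom, s, e, _ = _GENE_LOCI[gene]
        direction = "DEL" if style == "gene_del" else "AMP"
        return (_CNV_TEMPLATES[style].format(gene=gene),
                ("GENE", chrom, s, e, direction))
    raise ValueError(f"unknown CNV style {style!r}")


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def generate_corpus(
    spec: CorpusSpec, seed: int
) -> tuple[list[Document], GroundTruth]:
    """Deterministically generate documents plus their extraction truth.

    Each planted entity is templated so that its extractor's context
    requirements hold (gene in the same sentence, fusion keyword present);
    decoy sentences are non-extractable by construction.
    """
    spec.validate()
    rng = random.Random(seed)
    transcripts = toy_transcripts(seed=0)  # fixed reference set, not per-corpus
    docs: list[Document] = []
    truth = GroundTruth()

    for i in range(spec.n_documents):
        pmid = str(9_000_000 + i)
        gene_pool = sorted(transcripts)
        focus = rng.choice(gene_pool)
        sentences: list[str] = []
        tv: set[tuple[str, str]] = set()
        tiers: set[tuple[str, str, str]] = set()
        tc: set[tuple] = set()
        tf: set[tuple[str, str]] = set()

        n_var = rng.randint(*spec.variants_per_doc)
        for _ in range(n_var):
            style = rng.choice(spec.variant_styles)
            gene = focus if rng.random() < 0.6 else rng.choice(gene_pool)
            text, expected, rsid = _render_variant(style, gene, transcripts[gene], rng)
            sentences.append(rng.choice(_VARIANT_TEMPLATES).format(gene=gene, var=text))
            if style != "prose":
                tv.add(expected)
                tiers.add((expected[0], expected[1], "fulltext"))
            else:
                tv.add(expected)  # truth includes it; the extractor cannot

        for _ in range(rng.randint(*spec.cnvs_per_doc)):
            style = rng.choice(spec.cnv_styles)
            text, ctruth = _cnv_truth_and_text(style, rng)
            sentences.append(text)
            tc.add(ctruth)

        for _ in range(rng.randint(*spec.fusions_per_doc)):
            style = rng.choice(spec.fusion_styles)
            g1, g2 = rng.sample(_FUSION_GENES, 2)
            sentences.append(_FUSION_TEMPLATES[style].format(g1=g1, g2=g2))
            tf.add(tuple(sorted((g1, g2))))

        for _ in range(rng.randint(*spec.decoys_per_doc)):
            sentences.append(rng.choice(_DECOY_SENTENCES))
        sentences.append(rng.choice(_FILLER_SENTENCES))
        rng.shuffle(sentences)

        doc = Document(
            pmid=pmid,
            title=f"Molecular findings in {focus}-associated disease (study {i})",
            abstract=f"We characterised {focus} alterations in a patient cohort.",
            mesh_terms=["Humans"],
            sections=[("Results", " ".join(sentences))],
            citation_count=rng.randint(0, 300),
            year=rng.randint(*spec.year_range),
        )
        docs.append(doc)
        if tv:
            truth.variants[pmid] = tv
            truth.variant_tiers[pmid] = tiers
        if tc:
            truth.cnvs[pmid] = tc
        if tf:
            truth.fusions[pmid] = tf
    return docs, truth


def decoy_only_spec(n_documents: int = 20) -> CorpusSpec:
    """A spec whose documents contain decoy and filler text only."""
    return CorpusSpec(
        n_documents=n_documents,
        variants_per_doc=(0, 0),
        cnvs_per_doc=(0, 0),
        fusions_per_doc=(0, 0),
        decoys_per_doc=(2, 4),
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class ExtractionScore:
    precision: float
    recall: float
    true_positives: int
    false_positives: int
    false_negatives: int
    span_mismatches: int = 0


def _score_sets(pred: set, true: set) -> ExtractionScore:
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    return ExtractionScore(
        precision=tp / (tp + fp) if (tp + fp) else 1.0,
        recall=tp / (tp + fn) if (tp + fn) else 1.0,
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
    )


def score_extraction(
    predicted: dict[str, dict[str, set]], truth: GroundTruth
) -> dict[str, ExtractionScore]:
    """Precision/recall per entity class on exact (pmid, identity) matches.

    ``predicted`` maps class name ("variants"/"cnvs"/"fusions") to
    ``{pmid: identity set}`` using the same identity tuples as
    :class:`GroundTruth`.  An "overall" entry pools all classes.
    """
    out: dict[str, ExtractionScore] = {}
    pooled_pred: set = set()
    pooled_true: set = set()
    for cls, true_map in (
        ("variants", truth.variants), ("cnvs", truth.cnvs), ("fusions", truth.fusions)
    ):
        pred_map = predicted.get(cls, {})
        pred = {(pmid, ident) for pmid, idents in pred_map.items() for ident in idents}
        true = {(pmid, ident) for pmid, idents in true_map.items() for ident in idents}
        out[cls] = _score_sets(pred, true)
        pooled_pred |= {(cls,) + t for t in pred}
        pooled_true |= {(cls,) + t for t in true}
    out["overall"] = _score_sets(pooled_pred, pooled_true)
    return out
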