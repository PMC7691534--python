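"""Transcript validation, cDNA->protein conversion, keys and indexing."""

import math
import random
import re

import pytest
from Bio.Seq import Seq

from litvariant.corpus import Document, normalize_text, segment
from litvariant.synth import _build_transcript
from litvariant.variant_norm import (
    KEY_GRAMMAR,
    IntronPosition,
    ProteinEffect,
    SyntaxClass,
    UnkeyedVariant,
    associate_gene,
    cdna_to_protein,
    detect_variant_mentions,
    export_cvr,
    index_document,
    load_transcripts,
    make_mastermind_key,
    save_transcripts,
    validate_mention,
)


def mention(text, idx=0):
    ms = detect_variant_mentions(normalize_text(text))
    return ms[idx]


def random_transcript(rng, gene="G1", n_codons=None, bounds=None):
    n = n_codons or rng.randint(40, 120)
    return _build_transcript(
        gene, n, rng, codon_overrides={}, exon_codon_bounds=bounds or [n // 3],
        chrom="chr1", g_offset=1_000_000,
    )


class TestTranscriptModel:
    def test_invariants_enforced(self, transcripts):
        tx = transcripts["BRAF"]
        assert len(tx.cds_seq) % 3 == 0
        assert str(Seq(tx.cds_seq).translate())[:-1] == tx.protein

    def test_json_roundtrip(self, tmp_path, transcripts):
        path = tmp_path / "tx.json"
        save_transcripts(transcripts, str(path))
        back = load_transcripts(str(path))
        assert back.keys() == transcripts.keys()
        assert back["BRAF"].cdna == transcripts["BRAF"].cdna
        assert back["TP53"].exons[0].strand == "-"


class TestValidation:
    def test_protein_pass_and_fail(self, transcripts):
        tx = transcripts["BRAF"]  # codon 600 is GTG = V
        assert validate_mention(mention("V600E"), tx).passed
        bad = validate_mention(mention("A600E"), tx)
        assert not bad.passed and "mismatch" in bad.reason

    def test_cdna_pass(self, transcripts):
        assert validate_mention(mention("c.1799T>A"), transcripts["BRAF"]).passed

    def test_out_of_range(self, transcripts):
        v = validate_mention(mention("V9999A"), transcripts["BRAF"])
        assert not v.passed and v.reason == "out of range"

    def test_utr_and_intronic_region_checks(self, transcripts):
        tx = transcripts["BRAF"]
        ref5 = tx.cdna[tx.cds_start - 15 - 1]
        alt = "A" if ref5 != "A" else "G"
        assert validate_mention(mention(f"c.-15{ref5}>{alt}"), tx).passed
        assert validate_mention(mention("c.240+1G>A"), tx).passed
        assert not validate_mention(mention("c.100+1G>A"), tx).passed  # no intron there

    def test_randomized_wrong_reference_always_rejected(self, transcripts):
        # residues outside {A,C,G,T} keep the token unambiguously protein-level
        # (letters that double as bases flip the reading to legacy cDNA)
        aa_only = [a for a in "DEFHIKLMNPQRSVWY"]
        rng = random.Random(0)
        tx = transcripts["CFTR"]
        rejected = 0
        for _ in range(300):
            pos = rng.randrange(1, len(tx.protein) + 1)
            true_aa = tx.protein[pos - 1]
            wrong = rng.choice([a for a in aa_only if a != true_aa])
            alt = rng.choice([a for a in aa_only if a != wrong])
            v = validate_mention(mention(f"{wrong}{pos}{alt}"), tx)
            assert not v.passed
            rejected += 1
        assert rejected == 300


class TestCdnaToProtein:
    def test_worked_cases(self, transcripts):
        eff = cdna_to_protein(mention("c.1799T>A"), transcripts["BRAF"])
        assert (eff.ref, eff.codon, eff.alt) == ("V", 600, "E")
        eff = cdna_to_protein(mention("c.3G>A"), transcripts["BRAF"])  # ATG start
        assert (eff.ref, eff.codon, eff.alt) == ("M", 1, "I")
        eff = cdna_to_protein(mention("c.367del"), transcripts["TP53"])  # codon 123 = ATG
        assert (eff.ref, eff.codon, eff.consequence) == ("M", 123, "frameshift")

    def test_agrees_with_direct_translation_all_positions(self):
        """Exhaustive oracle check over the full CDS of random toy transcripts."""
        rng = random.Random(7)
        for t in range(20):
            tx = random_transcript(rng, gene=f"G{t}")
            cds = tx.cds_seq
            for pos in range(1, tx.cds_len + 1):
                ref = cds[pos - 1]
                alt = rng.choice([b for b in "ACGT" if b != ref])
                m = mention(f"c.{pos}{ref}>{alt}")
                eff = cdna_to_protein(m, tx)
                # independent oracle: mutate the whole CDS, translate both
                codon_idx = math.ceil(pos / 3)
                mutated = cds[: pos - 1] + alt + cds[pos:]
                before = str(Seq(cds).translate())
                after = str(Seq(mutated).translate())
                assert eff.codon == codon_idx
                assert eff.ref == before[codon_idx - 1]
                assert eff.alt == after[codon_idx - 1]

    def test_outside_cds_rejected(self, transcripts):
        with pytest.raises(ValueError, match="UTR"):
            cdna_to_protein(mention("c.-15A>G"), transcripts["BRAF"])


class TestKeys:
    def test_substitution_deletion_frameshift_forms(self):
        assert make_mastermind_key(ProteinEffect("V", 600, "E")) == "V600E"
        assert make_mastermind_key(ProteinEffect("R", 19, "*")) == "R19X"
        assert make_mastermind_key(ProteinEffect("F", 508, None, "deletion")) == "F508del"
        assert make_mastermind_key(ProteinEffect("M", 123, None, "frameshift")) == "M123fs"
        assert make_mastermind_key("5UTR") == "5UTR"
        assert make_mastermind_key("3UTR") == "3UTR"

    def test_splice_key_windows(self, transcripts):
        tx = transcripts["BRAF"]  # exon ends at c.240, codon 80 = E
        expected = {1: "E80sd", 2: "E80sd", 3: "E80srd", 8: "E80srd", 9: "E80int",
                    -1: "E80sa", -2: "E80sa", -3: "E80sra", -8: "E80sra", -40: "E80int"}
        for off, key in expected.items():
            assert make_mastermind_key(IntronPosition(240, off), tx) == key

    def test_unkeyed_consequences_raise(self):
        with pytest.raises(UnkeyedVariant):
            make_mastermind_key(ProteinEffect("A", 5, None, "inframe_ins"))
        with pytest.raises(UnkeyedVariant):
            make_mastermind_key("not-a-region")

    def test_all_emitted_keys_match_grammar(self, gene_lexicon, transcripts, cytobands, keywords, rsid_map):
        from litvariant.pipeline import run_pipeline
        from litvariant.synth import CorpusSpec, generate_corpus

        docs, _ = generate_corpus(CorpusSpec(n_documents=60), seed=11)
        indexed = run_pipeline(docs, gene_lexicon, transcripts, cytobands, keywords, rsid_map)
        keys = [v.key for vs in indexed.variants.values() for v in vs if v.key]
        assert keys, "pipeline emitted no keys"
        for key in keys:
            assert KEY_GRAMMAR.fullmatch(key), key


class TestAssociation:
    def test_same_sentence_gene_wins(self, gene_lexicon, transcripts):
        text = normalize_text(
            "KRAS was studied extensively before. The BRAF V600E mutation is common."
        )
        seg = segment(text)
        from litvariant.lexicon import find_entity_mentions

        spans = {}
        for men in find_entity_mentions(text, gene_lexicon):
            spans.setdefault(men.entity_id, []).append(men.span)
        m = detect_variant_mentions(text)[0]
        # make KRAS protein also carry V at 600?  it is shorter, so only BRAF validates;
        # force the precedence question with two validating genes instead:
        gene = associate_gene(m, ["BRAF", "KRAS"], transcripts, seg, spans, {"KRAS": 5, "BRAF": 1})
        assert gene == "BRAF"

    def test_no_validating_candidate_drops_mention(self, transcripts):
        m = mention("A600E")  # BRAF has V at 600
        assert associate_gene(m, ["BRAF"], transcripts) is None

    def test_mention_count_breaks_tie_when_no_proximity(self, transcripts):
        rng = random.Random(1)
        # two genes with identical protein -> both validate any protein mention
        t1 = random_transcript(rng, "AAA1", n_codons=60)
        t2 = random_transcript(rng, "AAB1", n_codons=80)
        pos = 10
        aa = t1.protein[pos - 1]
        t2b = _build_transcript(
            "AAB1", 80, random.Random(2),
            codon_overrides={pos: {"A": "GCT", "R": "CGT", "L": "CTT", "S": "TCT",
                                    "G": "GGT", "V": "GTT", "T": "ACT", "P": "CCT",
                                    }.get(aa, "GCT")},
            exon_codon_bounds=[40], chrom="chr1", g_offset=2_000_000,
        )
        txs = {"AAA1": t1, "AAB1": t2b}
        alt = "W" if aa != "W" else "C"
        m = mention(f"{aa}{pos}{alt}")
        both = [g for g in txs if validate_mention(m, txs[g]).passed]
        counts = {"AAB1": 3, "AAA1": 1}
        got = associate_gene(m, sorted(txs), txs, None, {}, counts)
        if set(both) == {"AAA1", "AAB1"}:
            assert got == "AAB1"  # higher count wins
        else:
            assert got in both


class TestIndexDocument:
    def test_merge_across_nomenclatures_with_tiers(self, gene_lexicon, transcripts):
        doc = Document(
            pmid="77",
            title="BRAF mutations in cancer",
            abstract="The BRAF V600E mutation is recurrent.",
            sections=[("Results", "We confirmed BRAF c.1799T>A in all samples.")],
        )
        nvs = index_document(doc, gene_lexicon, transcripts)
        assert len(nvs) == 1
        nv = nvs[0]
        assert (nv.gene, nv.key) == ("BRAF", "V600E")
        tiers = {t for _, _, t in nv.provenance}
        assert tiers == {"abstract", "fulltext"}
        assert nv.hgvs_c == "c.1799T>A"

    def test_supplement_tier_recorded(self, gene_lexicon, transcripts):
        doc = Document(
            pmid="78",
            title="CFTR screening",
            abstract="CFTR variants were tabulated.",
            supplements=[("tableS1.txt", "CFTR F508del carrier frequencies")],
        )
        nvs = index_document(doc, gene_lexicon, transcripts)
        assert [(v.gene, v.key) for v in nvs] == [("CFTR", "F508del")]
        assert nvs[0].provenance[0][2] == "supplement"

    def test_legacy_token_disambiguated_by_validation(self, gene_lexicon, transcripts):
        doc = Document(
            pmid="79", title="BRAF", abstract="",
            sections=[("Results", "The BRAF T1799A change was found.")],
        )
        nvs = index_document(doc, gene_lexicon, transcripts)
        assert [(v.gene, v.key) for v in nvs] == [("BRAF", "V600E")]

    def test_empty_document_yields_nothing(self, gene_lexicon, transcripts):
        assert index_document(Document(pmid="80"), gene_lexicon, transcripts) == []

    def test_rsid_resolution(self, gene_lexicon, transcripts, rsid_map):
        doc = Document(
            pmid="81", title="BRAF", abstract="",
            sections=[("Results", "Genotyping covered rs113488022 in BRAF.")],
        )
        nvs = index_document(doc, gene_lexicon, transcripts, rsid_map=rsid_map)
        assert [(v.gene, v.key, v.rsid) for v in nvs] == [("BRAF", "V600E", "113488022")]


class TestCvrExport:
    def _index_corpus(self, gene_lexicon, transcripts):
        docs = [
            Document(pmid="1", title="BRAF", abstract="BRAF c.1799T>A found."),
            Document(pmid="2", title="BRAF", abstract="BRAF V600E and c.1799T>A."),
            Document(pmid="3", title="TP53", abstract="TP53 c.100_102del carrier."),
            Document(pmid="4", title="TP53", abstract="TP53 c.100_105del carrier."),
        ]
        merged = {}
        for d in docs:
            for nv in index_document(d, gene_lexicon, transcripts):
                key = (nv.gene, nv.key)
                if key in merged:
                    merged[key].provenance.extend(nv.provenance)
                    merged[key].hgvs_c = merged[key].hgvs_c or nv.hgvs_c
                else:
                    merged[key] = nv
        return list(merged.values())

    def test_roundtrip_and_refcounts(self, tmp_path, gene_lexicon, transcripts):
        from cyvcf2 import VCF

        variants = self._index_corpus(gene_lexicon, transcripts)
        text = export_cvr(variants, transcripts)
        path = tmp_path / "cvr.vcf"
        path.write_text(text)
        records = list(VCF(str(path)))
        by_key = {r.INFO.get("KEY"): r for r in records}
        assert "V600E" in by_key
        # provenance count is conserved into REFCOUNT
        v600e = next(v for v in variants if v.key == "V600E")
        assert by_key["V600E"].INFO.get("REFCOUNT") == len(v600e.provenance)

    def test_size_cutoff_3nt_in_6nt_out(self, gene_lexicon, transcripts):
        variants = self._index_corpus(gene_lexicon, transcripts)
        text = export_cvr(variants, transcripts)
        assert "c.100_102del" in " ".join(v.hgvs_c or "" for v in variants)
        keys_in_vcf = re.findall(r"KEY=([^;]+)", text)
        deletions = [v for v in variants if v.hgvs_c and "_" in v.hgvs_c]
        short = [v.key for v in deletions if int(v.hgvs_c.split("_")[1].rstrip("del")) - int(v.hgvs_c[2:].split("_")[0]) + 1 <= 3]
        long = [v.key for v in deletions if v.key not in short]
        for k in short:
            assert k in keys_in_vcf or k is None
        for k in long:
            assert k not in keys_in_vcf

    def test_minus_strand_complemented(self, gene_lexicon, transcripts):
        tx = transcripts["TP53"]  # minus strand
        doc = Document(pmid="9", title="TP53", abstract="TP53 c.367T>A was seen." if tx.cds_seq[366] == "T" else "")
        ref = tx.cds_seq[366]
        alt = "A" if ref != "A" else "G"
        doc = Document(pmid="9", title="TP53", abstract=f"TP53 c.367{ref}>{alt} was seen.")
        nvs = index_document(doc, gene_lexicon, transcripts)
        text = export_cvr(nvs, transcripts)
        data = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(data) == 1
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        fields = data[0].split("\t")
        assert fields[3] == comp[ref]
        assert fields[4] == comp[alt]

    def test_empty_input_gives_valid_header_only_vcf(self, transcripts, tmp_path):
        from cyvcf2 import VCF

        text = export_cvr([], transcripts)
        path = tmp_path / "empty.vcf"
        path.write_text(text)
        assert list(VCF(str(path))) == []
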