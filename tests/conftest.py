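import pytest

from neovax.antigen import (
    GermlineVariantCall,
    SomaticVariant,
    TranscriptRecord,
    VariantKind,
)

# Codons of a small handcrafted transcript; protein = M A Y H K L E F G I K W ...
_CODONS = [
    "ATG", "GCA", "TAC", "CAT", "AAA", "CTG", "GAA", "TTT", "GGG", "ATC",
    "AAG", "TGG", "CAG", "GTG", "TCC", "AAC", "GAT", "CGC", "ACA", "CCG",
    "TAA",
]


@pytest.fixture
def toy_transcript() -> TranscriptRecord:
    return TranscriptRecord(
        transcript_id="TX1",
        cds_sequence="".join(_CODONS),
        expression_rpkm=25.0,
        gene_symbol="TOY1",
    )


def make_snv(vid, pos, ref, alt, transcript_id="TX1", rna_vaf=0.4, dna_vaf=0.3):
    return SomaticVariant(
        variant_id=vid,
        transcript_id=transcript_id,
        kind=VariantKind.SNV,
        cds_position=pos,
        ref_allele=ref,
        alt_allele=alt,
        dna_vaf=dna_vaf,
        rna_vaf=rna_vaf,
    )


def make_indel(vid, pos, ref, alt, kind, transcript_id="TX1", rna_vaf=0.4):
    return SomaticVariant(
        variant_id=vid,
        transcript_id=transcript_id,
        kind=kind,
        cds_position=pos,
        ref_allele=ref,
        alt_allele=alt,
        dna_vaf=0.3,
        rna_vaf=rna_vaf,
    )


@pytest.fixture
def toy_variants(toy_transcript):
    cds = toy_transcript.cds_sequence
    return {
        # GCA -> GCG, codon 2 third base (position 6): synonymous (A)
        "synonymous": make_snv("v_syn", 6, "A", "G"),
        # TAC -> TAA, codon 3 third base (position 9): nonsense
        "nonsense": make_snv("v_non", 9, "C", "A"),
        # CAT -> CGT, codon 4 second base (position 11): H -> R missense
        "missense": make_snv("v_mis", 11, "A", "G"),
        # single-base deletion anchored at position 13 (codon 5): frameshift
        "frameshift": make_indel("v_fs", 13, cds[12:14], cds[12], VariantKind.DELETION),
        # 3-base in-frame deletion anchored at position 15 (removes codon 6)
        "inframe": make_indel("v_if", 15, cds[14:18], cds[14], VariantKind.DELETION),
    }


@pytest.fixture
def toy_germline():
    # AAA -> AGA at codon 5 (position 14, K -> R), in phase with v_mis
    return GermlineVariantCall(
        germline_id="gl1",
        transcript_id="TX1",
        cds_position=14,
        ref_allele="A",
        alt_allele="G",
        in_phase_with=frozenset({"v_mis"}),
    )
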