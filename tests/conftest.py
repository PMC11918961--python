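import pytest

from splicedx.gene_model import Region, TranscriptModel
from splicedx.fixtures import load_study_records, study_variants, synthetic_myo5b_model


@pytest.fixture(scope="session")
def packaged_model():
    return synthetic_myo5b_model()


@pytest.fixture(scope="session")
def study_records(packaged_model):
    return load_study_records(packaged_model)


@pytest.fixture(scope="session")
def study_rows(study_records):
    return [r for r in study_records if r.role == "study"]


@pytest.fixture
def tiny_gene():
    """Hand-built 5-exon gene, 60-nt CDS, every exon/intron junction codon-aligned.

    Protein: M E E E E E E E W W W W H H H H P P P (19 residues + stop).
    Intron 2's acceptor tail is Ser-Val-Gln codons so a 9-nt acceptor-side
    retention is a clean 3-residue in-frame insertion.
    """
    exons = (
        Region(1, 12, "ATG" + "GAA" * 3),
        Region(2, 12, "GAG" * 4),
        Region(3, 12, "TGG" * 4),
        Region(4, 12, "CAT" * 4),
        Region(5, 12, "CCC" * 3 + "TAA"),
    )
    introns = (
        Region(1, 10, "GT" + "A" * 6 + "AG"),
        Region(2, 15, "GTAAAA" + "TCTGTGCAG"),
        Region(3, 12, "GT" + "C" * 8 + "AG"),
        Region(4, 10, "GT" + "T" * 6 + "AG"),
    )
    return TranscriptModel(
        transcript_id="tiny", exons=exons, introns=introns, cds_start=1, cds_end=60
    )
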