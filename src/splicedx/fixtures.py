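"""Packaged study dataset: the 11-variant table and a transcript model.

The variant table ships as ``data/variants.tsv`` with every printed field
(prediction outputs, genotype counts, assay outcomes, evidence strings)
plus two canonical-site positive controls.

The transcript model is a SYNTHETIC, length-only reconstruction of the
MYO5B coding transcript: the public reference's exon lengths are not
reproduced here, but every exon/intron boundary that a study variant's c.
coordinate pins down is honored exactly (e.g. exon 4 ends at c.455, exon 6
starts at c.613, exon 10 is long enough for a 134-nt truncation, the CDS is
5547 nt = 1848 residues + stop).  It supports coordinate arithmetic and
variant localization; sequence-level consequences need a user-supplied
FASTA for the real transcript.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .acmg import CohortRow, FunctionalResult, parse_evidence_string
from .assay import AssayOutcome, classify_outcome
from .gene_model import (
    Region,
    SpliceVariantDescriptor,
    TranscriptModel,
    parse_hgvs_c,
    write_model,
)
from .insilico import ToolPredictions, PopulationCounts, parse_gnomad_field, parse_spliceai_field
from .splice_consequence import SpliceEvent

SYNTHETIC_MODEL_ID = "MYO5B-like-synthetic-v1"

# c. coordinate of the last base of each exon.  Boundaries pinned by study
# variants: 455 (i4 donor), 612 (i5/c.613), 838 (i6/c.839), 1322 (i10),
# 1668 (i13/c.1669), 2090 (i17), 2414 (i19), 3045 (i22), 3537 (i25/c.3538),
# 4852 (i36); exon 19 must hold c.2349 and a 71-nt truncation, exon 31 must
# hold c.4221, exon 10 >= 134 nt, exon 22 >= 125 nt.  Unpinned boundaries
# are synthetic round numbers.
_EXON_CUMULATIVE_ENDS = (
    100, 220, 340, 455, 612, 838, 960, 1090, 1180, 1322,
    1440, 1560, 1668, 1800, 1900, 2000, 2090, 2230, 2414, 2550,
    2800, 3045, 3180, 3300, 3537, 3650, 3780, 3900, 4020, 4140,
    4260, 4380, 4500, 4620, 4740, 4852, 5000, 5150, 5350, 5547,
)
_SYNTHETIC_INTRON_LENGTH = 1000  # uniform placeholder; real intron lengths unknown here


def synthetic_myo5b_model() -> TranscriptModel:
    """The packaged length-only transcript model (synthetic; see module docstring)."""
    exons = []
    prev = 0
    for i, end in enumerate(_EXON_CUMULATIVE_ENDS, start=1):
        exons.append(Region(index=i, length=end - prev))
        prev = end
    introns = [
        Region(index=i, length=_SYNTHETIC_INTRON_LENGTH)
        for i in range(1, len(exons))
    ]
    return TranscriptModel(
        transcript_id=SYNTHETIC_MODEL_ID,
        exons=tuple(exons),
        introns=tuple(introns),
        cds_start=1,
        cds_end=_EXON_CUMULATIVE_ENDS[-1],
    )


def _read_packaged_table() -> pd.DataFrame:
    text = resources.files("splicedx").joinpath("data/variants.tsv").read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str).fillna("")
    return df


@dataclass(frozen=True)
class StudyRecord:
    """One fully parsed row of the packaged variant table."""

    hgvs_c: str
    role: str  # study | positive_control
    novel: bool
    location_label: str
    descriptor: SpliceVariantDescriptor
    predictions: Optional[ToolPredictions]
    counts: Optional[PopulationCounts]
    events: tuple[SpliceEvent, ...]
    normal_fraction: float
    blood_rna: str
    original_evidence: str
    removals: tuple[str, ...]
    notes: str

    @property
    def outcome(self) -> AssayOutcome:
        species: list[Optional[SpliceEvent]] = list(self.events)
        if self.normal_fraction > 0:
            species.append(None)
        return AssayOutcome(
            variant=self.hgvs_c,
            species=tuple(species),
            normal_fraction=self.normal_fraction,
            source="minigene",
        )

    @property
    def functional_result(self) -> FunctionalResult:
        category = classify_outcome(self.outcome)
        if category == "no_effect":
            outcome = "no_effect"
        elif category == "complete_aberration":
            outcome = "aberrant"
        else:
            outcome = "partial_aberrant"
        source = "both" if self.blood_rna.strip() else "minigene"
        return FunctionalResult(outcome=outcome, source=source)

    @property
    def cohort_row(self) -> CohortRow:
        return CohortRow(
            variant=self.hgvs_c,
            original=parse_evidence_string(self.original_evidence),
            functional=self.functional_result,
            removals=self.removals,
        )


def _parse_events(text: str, model: TranscriptModel, normal_fraction: float) -> tuple[SpliceEvent, ...]:
    events = []
    for token in filter(None, (t.strip() for t in text.split("|"))):
        kind, region, size, side = token.split(":")
        region_i = int(region)
        size_nt = model.exons[region_i - 1].length if size == "." else int(size)
        events.append(
            SpliceEvent(
                event_kind=kind,
                region_index=region_i,
                size_nt=size_nt,
                anchor_side=side,
                fraction_normal=normal_fraction,
            )
        )
    return tuple(events)


def load_study_records(model: Optional[TranscriptModel] = None) -> list[StudyRecord]:
    """Parse the packaged table into typed records (controls included)."""
    model = model or synthetic_myo5b_model()
    records = []
    for _, row in _read_packaged_table().iterrows():
        is_study = row["role"] == "study"
        predictions = None
        if is_study:
            predictions = ToolPredictions(
                spliceai_scores=parse_spliceai_field(row["spliceai"]),
                varseak_class=int(row["varseak_class"]),
                maxent_ref=float(row["maxent_ref"]),
                maxent_alt=float(row["maxent_alt"]),
                hsf_verdict=row["hsf_verdict"],
                mutationtaster_verdict=row["mt_verdict"],
            )
        normal_fraction = float(row["normal_fraction"])
        records.append(
            StudyRecord(
                hgvs_c=row["hgvs_c"],
                role=row["role"],
                novel=row["novel"] == "1",
                location_label=row["location"],
                descriptor=parse_hgvs_c(row["hgvs_c"]),
                predictions=predictions,
                counts=parse_gnomad_field(row["gnomad"]),
                events=_parse_events(row["events"], model, normal_fraction) if is_study else (),
                normal_fraction=normal_fraction,
                blood_rna=row["blood_rna"],
                original_evidence=row["original_evidence"].strip(),
                removals=tuple(
                    t.strip() for t in row["removals"].split(",") if t.strip()
                ),
                notes=row["notes"],
            )
        )
    return records


def study_variants(records: Optional[list[StudyRecord]] = None) -> list[StudyRecord]:
    records = records if records is not None else load_study_records()
    return [r for r in records if r.role == "study"]


def export_study_fixture(directory: str | Path) -> dict[str, Path]:
    """Write the packaged dataset (variant table + transcript model) to ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table_path = directory / "variants.tsv"
    table_path.write_text(
        resources.files("splicedx").joinpath("data/variants.tsv").read_text()
    )
    model_path = directory / "myo5b_synthetic_model.txt"
    write_model(
        synthetic_myo5b_model(),
        model_path,
        header_notes=[
            "SYNTHETIC length-only reconstruction of the MYO5B coding transcript",
            "exon boundaries pinned by the study variants' c. coordinates; all other",
            "exon ends and every intron length are synthetic placeholders",
            "supply real sequences via FASTA for sequence-level consequences",
        ],
    )
    return {"variants": table_path, "model": model_path}
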