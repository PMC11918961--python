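"""Transcript models and HGVS c.-coordinate arithmetic.

A :class:`TranscriptModel` holds one coding transcript in mRNA orientation:
ordered exons and introns (1-indexed) with lengths and, optionally,
sequences, plus the CDS extent in c. coordinates (``cds_start`` = 1 by HGVS
convention, ``cds_end`` = last base of the stop codon).  All downstream
computation happens in transcript space; genomic strand and coordinate
liftover are out of scope.

HGVS c. coordinates are 1-based and inclusive.  Intronic positions are
written relative to the nearest exon boundary: ``c.613-11`` is 11 nt
upstream of the acceptor of the exon starting at c.613, ``c.2090+3`` is
3 nt downstream of the donor of the exon ending at c.2090.  The parser
covers the grammar subset used for splice-variant tables — substitutions,
range deletions and delins, with optional intron offsets — and rejects
anything else (5'UTR ``c.-N`` and 3'UTR ``c.*N`` positions included)
rather than guessing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio.Seq import Seq

MODEL_FORMAT_TAG = "splicedx-transcript-model v1"

_STOPS = {"TAA", "TAG", "TGA"}


class GeneModelError(ValueError):
    """Invalid transcript model or coordinate."""


class HgvsParseError(ValueError):
    """Malformed or unsupported HGVS c. string."""


# ---------------------------------------------------------------------------
# Transcript model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """One exon or intron: 1-based index, length in nt, optional sequence."""

    index: int
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise GeneModelError(f"region index must be >= 1, got {self.index}")
        if self.length < 1:
            raise GeneModelError(f"region length must be >= 1, got {self.length}")
        if self.sequence is not None:
            seq = self.sequence.upper()
            object.__setattr__(self, "sequence", seq)
            if len(seq) != self.length:
                raise GeneModelError(
                    f"region {self.index}: sequence length {len(seq)} != declared {self.length}"
                )
            if not re.fullmatch(r"[ACGTN]+", seq):
                raise GeneModelError(f"region {self.index}: non-nucleotide characters in sequence")


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/intron structure, CDS extent and (optionally) sequence of one transcript."""

    transcript_id: str
    exons: tuple[Region, ...]
    introns: tuple[Region, ...]
    cds_start: int = 1
    cds_end: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        object.__setattr__(self, "introns", tuple(self.introns))
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        if len(self.exons) < 1:
            raise GeneModelError("transcript needs at least one exon")
        if len(self.introns) != len(self.exons) - 1:
            raise GeneModelError(
                f"{len(self.exons)} exons require {len(self.exons) - 1} introns, "
                f"got {len(self.introns)}"
            )
        for kind, regions in (("exon", self.exons), ("intron", self.introns)):
            for i, r in enumerate(regions, start=1):
                if r.index != i:
                    raise GeneModelError(f"{kind} records out of order at index {r.index}")
        if self.cds_start != 1:
            raise GeneModelError("cds_start must be 1 (HGVS c. convention)")
        if not 1 <= self.cds_end <= self.exonic_length:
            raise GeneModelError(
                f"cds_end {self.cds_end} outside exonic length {self.exonic_length}"
            )
        if self.cds_length % 3 != 0:
            raise GeneModelError(f"CDS length {self.cds_length} is not a multiple of 3")
        if self.has_exon_sequences:
            cds = self.coding_sequence()
            if cds[:3] != "ATG":
                raise GeneModelError("CDS does not begin with ATG")
            prot = str(Seq(cds).translate())
            if not prot.endswith("*"):
                raise GeneModelError("CDS does not end in a stop codon")
            if "*" in prot[:-1]:
                raise GeneModelError("CDS contains an internal stop codon")

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def has_exon_sequences(self) -> bool:
        return all(e.sequence is not None for e in self.exons)

    @property
    def has_intron_sequences(self) -> bool:
        return bool(self.introns) and all(i.sequence is not None for i in self.introns)

    def exon_end(self, index: int) -> int:
        """c. coordinate of the last base of exon ``index``."""
        if not 1 <= index <= len(self.exons):
            raise GeneModelError(f"no exon {index}")
        return sum(e.length for e in self.exons[:index])

    def exon_start(self, index: int) -> int:
        return self.exon_end(index) - self.exons[index - 1].length + 1

    def spliced_sequence(self) -> str:
        if not self.has_exon_sequences:
            raise GeneModelError("transcript model carries no exon sequences")
        return "".join(e.sequence for e in self.exons)  # type: ignore[misc]

    def coding_sequence(self) -> str:
        return self.spliced_sequence()[self.cds_start - 1 : self.cds_end]

    def protein(self) -> str:
        """Reference protein, without the terminal stop."""
        return str(Seq(self.coding_sequence()).translate())[:-1]

    def intron_sequence(self, index: int) -> str:
        if not 1 <= index <= len(self.introns):
            raise GeneModelError(f"no intron {index}")
        seq = self.introns[index - 1].sequence
        if seq is None:
            raise GeneModelError(
                f"intron {index} of {self.transcript_id} has no sequence; "
                "supply intronic sequence (FASTA) for retention events"
            )
        return seq


def cds_to_exon_offset(model: TranscriptModel, pos: int) -> tuple[int, int]:
    """Map a c. coordinate to (exon index, 1-based offset within that exon)."""
    if not 1 <= pos <= model.exonic_length:
        raise GeneModelError(
            f"position {pos} outside transcript (1..{model.exonic_length})"
        )
    running = 0
    for exon in model.exons:
        if pos <= running + exon.length:
            return exon.index, pos - running
        running += exon.length
    raise AssertionError("unreachable")


def exon_offset_to_cds(model: TranscriptModel, exon_index: int, offset: int) -> int:
    """Inverse of :func:`cds_to_exon_offset`."""
    exon = model.exons[exon_index - 1]
    if not 1 <= offset <= exon.length:
        raise GeneModelError(f"offset {offset} outside exon {exon_index} (length {exon.length})")
    return model.exon_start(exon_index) + offset - 1


# ---------------------------------------------------------------------------
# HGVS c. parsing
# ---------------------------------------------------------------------------

_POS = re.compile(r"(?P<anchor>-?\*?\d+)(?P<offset>[+-]\d+)?")
_NT = r"[ACGTacgt]"

_SUB = re.compile(
    rf"^(?P<pos>[^_>]+?)(?P<ref>{_NT})>(?P<alt>{_NT})$"
)
_DEL = re.compile(r"^(?P<start>[^_]+)_(?P<end>[^_]+)del$")
_DELINS = re.compile(rf"^(?P<start>[^_]+)_(?P<end>[^_]+)delins(?P<alt>{_NT}+)$")


@dataclass(frozen=True)
class SpliceVariantDescriptor:
    """A parsed HGVS c. variant, localized as exonic (offset 0) or intronic."""

    hgvs_c: str
    anchor_position: int
    intron_offset: int
    ref_allele: str
    alt_allele: str
    edit_kind: str  # substitution | deletion | insertion | delins
    end_anchor: Optional[int] = None
    end_offset: Optional[int] = None

    @property
    def is_exonic(self) -> bool:
        return self.intron_offset == 0

    @property
    def is_canonical_site(self) -> bool:
        return abs(self.intron_offset) in (1, 2)


def _parse_position(token: str, context: str) -> tuple[int, int]:
    m = _POS.fullmatch(token)
    if m is None:
        raise HgvsParseError(f"cannot parse position token {token!r} in {context!r}")
    anchor_txt = m.group("anchor")
    if anchor_txt.startswith("*"):
        raise HgvsParseError(f"3'UTR position {token!r} unsupported in {context!r}")
    anchor = int(anchor_txt)
    if anchor <= 0:
        raise HgvsParseError(f"5'UTR/non-positive anchor {token!r} unsupported in {context!r}")
    offset = int(m.group("offset")) if m.group("offset") else 0
    return anchor, offset


def parse_hgvs_c(text: str) -> SpliceVariantDescriptor:
    """Parse an HGVS c. description of the supported grammar subset.

    Supported: substitutions (``c.2349A>G``, ``c.613-11G>A``), range
    deletions (``c.2996_2998del``) and delins (``c.1669-2_1669-1delinsTT``),
    with an optional ``/p.(=)`` synonymous suffix which is stripped.
    """
    original = text.strip()
    body = original
    # synonymous protein suffix, e.g. "c.2349A>G/p.(=)"
    body = re.sub(r"/p\.\(=\)$", "", body)
    if not body.startswith("c."):
        raise HgvsParseError(f"not a c. description: {original!r}")
    core = body[2:]
    if not core:
        raise HgvsParseError(f"empty variant body in {original!r}")

    m = _SUB.fullmatch(core)
    if m is not None:
        anchor, offset = _parse_position(m.group("pos"), original)
        return SpliceVariantDescriptor(
            hgvs_c=original,
            anchor_position=anchor,
            intron_offset=offset,
            ref_allele=m.group("ref").upper(),
            alt_allele=m.group("alt").upper(),
            edit_kind="substitution",
        )
    m = _DELINS.fullmatch(core)
    if m is not None:
        a1, o1 = _parse_position(m.group("start"), original)
        a2, o2 = _parse_position(m.group("end"), original)
        return SpliceVariantDescriptor(
            hgvs_c=original,
            anchor_position=a1,
            intron_offset=o1,
            ref_allele="",
            alt_allele=m.group("alt").upper(),
            edit_kind="delins",
            end_anchor=a2,
            end_offset=o2,
        )
    m = _DEL.fullmatch(core)
    if m is not None:
        a1, o1 = _parse_position(m.group("start"), original)
        a2, o2 = _parse_position(m.group("end"), original)
        return SpliceVariantDescriptor(
            hgvs_c=original,
            anchor_position=a1,
            intron_offset=o1,
            ref_allele="",
            alt_allele="",
            edit_kind="deletion",
            end_anchor=a2,
            end_offset=o2,
        )
    raise HgvsParseError(f"unsupported HGVS grammar: {original!r}")


def _format_position(anchor: int, offset: int) -> str:
    if offset == 0:
        return str(anchor)
    return f"{anchor}{offset:+d}"


def format_hgvs_c(v: SpliceVariantDescriptor) -> str:
    """Canonical string for a descriptor; inverse of :func:`parse_hgvs_c`."""
    start = _format_position(v.anchor_position, v.intron_offset)
    if v.edit_kind == "substitution":
        return f"c.{start}{v.ref_allele}>{v.alt_allele}"
    end = _format_position(v.end_anchor, v.end_offset)  # type: ignore[arg-type]
    if v.edit_kind == "deletion":
        return f"c.{start}_{end}del"
    if v.edit_kind == "delins":
        return f"c.{start}_{end}delins{v.alt_allele}"
    raise HgvsParseError(f"cannot format edit kind {v.edit_kind!r}")


def normalize_hgvs_c(text: str) -> str:
    """parse → format; used as the join key across tables."""
    return format_hgvs_c(parse_hgvs_c(text))


# ---------------------------------------------------------------------------
# Variant localization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantLocus:
    """Where a variant falls on the transcript, relative to splice sites."""

    region_kind: str  # exon | intron
    region_index: int
    distance_to_donor: int
    distance_to_acceptor: int
    is_canonical_site: bool

    @property
    def label(self) -> str:
        return f"{self.region_kind.capitalize()} {self.region_index}"


def locate_variant(model: TranscriptModel, v: SpliceVariantDescriptor) -> VariantLocus:
    """Localize a parsed variant to an exon or intron of ``model``.

    Exonic variants map to the exon containing the anchor.  Intronic
    variants map to the intron adjacent to the anchor in the direction of
    the offset sign: a positive offset hangs off a donor (exon end), a
    negative offset off an acceptor (exon start).  Distances are measured
    in nt, counting the first intronic/exonic base as 1.
    """
    if not 1 <= v.anchor_position <= model.exonic_length:
        raise GeneModelError(
            f"anchor c.{v.anchor_position} beyond transcript "
            f"(exonic length {model.exonic_length})"
        )
    exon_idx, offset_in_exon = cds_to_exon_offset(model, v.anchor_position)
    exon = model.exons[exon_idx - 1]

    if v.intron_offset == 0:
        return VariantLocus(
            region_kind="exon",
            region_index=exon_idx,
            distance_to_donor=exon.length - offset_in_exon + 1,
            distance_to_acceptor=offset_in_exon,
            is_canonical_site=False,
        )

    if v.intron_offset > 0:
        # donor side: anchor must be the last base of its exon
        if offset_in_exon != exon.length:
            raise GeneModelError(
                f"c.{v.anchor_position}+{v.intron_offset}: anchor is not an exon 3' boundary"
            )
        if exon_idx > len(model.introns):
            raise GeneModelError(f"no intron downstream of exon {exon_idx}")
        intron = model.introns[exon_idx - 1]
        d_donor = v.intron_offset
        d_acceptor = intron.length - v.intron_offset + 1
    else:
        # acceptor side: anchor must be the first base of its exon
        if offset_in_exon != 1:
            raise GeneModelError(
                f"c.{v.anchor_position}{v.intron_offset}: anchor is not an exon 5' boundary"
            )
        if exon_idx == 1:
            raise GeneModelError("no intron upstream of exon 1")
        intron = model.introns[exon_idx - 2]
        d_acceptor = -v.intron_offset
        d_donor = intron.length + v.intron_offset + 1
    if d_donor < 1 or d_acceptor < 1:
        raise GeneModelError(
            f"intron offset {v.intron_offset} outside intron {intron.index} "
            f"(length {intron.length})"
        )
    return VariantLocus(
        region_kind="intron",
        region_index=intron.index,
        distance_to_donor=d_donor,
        distance_to_acceptor=d_acceptor,
        is_canonical_site=min(d_donor, d_acceptor) in (1, 2),
    )


# ---------------------------------------------------------------------------
# Model file I/O
# ---------------------------------------------------------------------------

def write_model(model: TranscriptModel, path: str | Path, header_notes: Iterable[str] = ()) -> None:
    """Write the self-contained transcript-model text format.

    Tab-separated records after ``#``-prefixed header lines; sequences are
    written inline, or ``.`` for length-only records.  Coordinates are HGVS
    c.-style (1-based, inclusive, transcript orientation).
    """
    lines = [f"# {MODEL_FORMAT_TAG}", "# coordinates: HGVS c., 1-based, transcript orientation"]
    lines += [f"# {note}" for note in header_notes]
    lines.append(f"transcript_id\t{model.transcript_id}")
    lines.append(f"cds_start\t{model.cds_start}")
    lines.append(f"cds_end\t{model.cds_end}")
    for exon in model.exons:
        lines.append(f"exon\t{exon.index}\t{exon.length}\t{exon.sequence or '.'}")
    for intron in model.introns:
        lines.append(f"intron\t{intron.index}\t{intron.length}\t{intron.sequence or '.'}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> TranscriptModel:
    """Read the transcript-model text format written by :func:`write_model`."""
    transcript_id = None
    cds_start = cds_end = None
    exons: list[Region] = []
    introns: list[Region] = []
    saw_tag = False
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if MODEL_FORMAT_TAG in line:
                saw_tag = True
            continue
        fields = line.split("\t")
        key = fields[0]
        if key == "transcript_id":
            transcript_id = fields[1]
        elif key == "cds_start":
            cds_start = int(fields[1])
        elif key == "cds_end":
            cds_end = int(fields[1])
        elif key in ("exon", "intron"):
            idx, length = int(fields[1]), int(fields[2])
            seq = fields[3] if len(fields) > 3 and fields[3] != "." else None
            region = Region(index=idx, length=length, sequence=seq)
            (exons if key == "exon" else introns).append(region)
        else:
            raise GeneModelError(f"unknown record {key!r} in {path}")
    if not saw_tag:
        raise GeneModelError(f"{path} lacks the '{MODEL_FORMAT_TAG}' format tag")
    if transcript_id is None or cds_start is None or cds_end is None:
        raise GeneModelError(f"{path} missing transcript_id/cds_start/cds_end")
    return TranscriptModel(
        transcript_id=transcript_id,
        exons=tuple(exons),
        introns=tuple(introns),
        cds_start=cds_start,
        cds_end=cds_end,
    )


def attach_sequences_from_fasta(model: TranscriptModel, fasta_path: str | Path) -> TranscriptModel:
    """Attach region sequences from a FASTA of records named ``exon_N`` / ``intron_N``."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    exons = []
    for exon in model.exons:
        seq = seqs.get(f"exon_{exon.index}", exon.sequence)
        exons.append(replace(exon, sequence=seq))
    introns = []
    for intron in model.introns:
        seq = seqs.get(f"intron_{intron.index}", intron.sequence)
        introns.append(replace(intron, sequence=seq))
    return TranscriptModel(
        transcript_id=model.transcript_id,
        exons=tuple(exons),
        introns=tuple(introns),
        cds_start=model.cds_start,
        cds_end=model.cds_end,
    )


def read_gff3_exons(path: str | Path, transcript_id: str, cds_end: int) -> TranscriptModel:
    """Build a length-only model from minimal GFF3-style exon rows.

    Convenience reader: takes ``exon`` feature rows (columns 4/5 are start
    and end), sorts them by start, and derives intron lengths from the gaps.
    Strand handling beyond '+' is not attempted.
    """
    spans: list[tuple[int, int]] = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) < 5 or cols[2] != "exon":
            continue
        spans.append((int(cols[3]), int(cols[4])))
    if not spans:
        raise GeneModelError(f"no exon rows in {path}")
    spans.sort()
    exons = [Region(index=i, length=e - s + 1) for i, (s, e) in enumerate(spans, start=1)]
    introns = [
        Region(index=i, length=spans[i][0] - spans[i - 1][1] - 1)
        for i in range(1, len(spans))
    ]
    return TranscriptModel(
        transcript_id=transcript_id,
        exons=tuple(exons),
        introns=tuple(introns),
        cds_start=1,
        cds_end=cds_end,
    )
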