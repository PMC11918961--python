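"""mRNA and protein consequences of aberrant splicing outcomes.

An observed splicing aberration — intron retention, activation of a cryptic
splice site truncating an exon, or whole-exon skipping — is represented as a
:class:`SpliceEvent` describing *what the sequencing showed*: which region,
how many nucleotides, and which end of the region the segment abuts.  No
splice-site scoring happens here; the event is the observation.

:func:`apply_splice_event` turns the event into the edited mature mRNA and
:func:`translate_consequence` into the predicted protein change, with HGVS
p.-style naming (3'-normalized) and ``fs*N`` counting where the first
changed residue is position 1 and N is the position of the new stop in the
shifted frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .gene_model import GeneModelError, TranscriptModel

EVENT_KINDS = (
    "intron_retention",
    "partial_intron_retention",
    "exon_internal_deletion",
    "exon_skipping",
)

CATEGORIES = (
    "frameshift",
    "premature_stop",
    "in_frame_deletion",
    "in_frame_insertion",
    "in_frame_delins",
    "no_change",
    "start_loss",
    "stop_loss_extension",
)


class SpliceEventError(ValueError):
    """Invalid splice event for the given transcript model."""


@dataclass(frozen=True)
class SpliceEvent:
    """One aberrant-splicing outcome for one transcript species.

    ``anchor_side`` says which end of the region the retained or deleted
    segment abuts: ``donor`` = the 5' end of an intron / 3' end of an exon,
    ``acceptor`` = the 3' end of an intron / 5' end of an exon.
    ``fraction`` is this species' abundance; ``fraction_normal`` the
    correctly spliced fraction co-occurring with it (0 for complete
    aberrations).
    """

    event_kind: str
    region_index: int
    size_nt: int
    anchor_side: str = "donor"
    fraction: Optional[float] = None
    fraction_normal: float = 0.0

    def __post_init__(self) -> None:
        if self.event_kind not in EVENT_KINDS:
            raise SpliceEventError(f"unknown event kind {self.event_kind!r}")
        if self.anchor_side not in ("donor", "acceptor"):
            raise SpliceEventError(f"anchor_side must be donor|acceptor, got {self.anchor_side!r}")
        if self.size_nt < 1:
            raise SpliceEventError(f"size_nt must be >= 1, got {self.size_nt}")
        if not 0.0 <= self.fraction_normal <= 1.0:
            raise SpliceEventError(f"fraction_normal {self.fraction_normal} outside [0,1]")
        if self.fraction is not None and not 0.0 <= self.fraction <= 1.0:
            raise SpliceEventError(f"fraction {self.fraction} outside [0,1]")

    def describe(self) -> str:
        side = "" if self.event_kind == "exon_skipping" else f" ({self.anchor_side} side)"
        region = "intron" if "intron" in self.event_kind else "exon"
        return f"{self.event_kind} of {self.size_nt} nt, {region} {self.region_index}{side}"


@dataclass(frozen=True)
class AlteredTranscript:
    """Edited exonic sequence plus a description of the edit span.

    ``edit_pos`` is the 0-based position in the reference exonic sequence
    where the edit starts; ``deleted``/``inserted`` are the removed and
    added segments (either may be empty).
    """

    model_id: str
    sequence: str
    edit_pos: int
    deleted: str
    inserted: str

    @property
    def delta_nt(self) -> int:
        return len(self.inserted) - len(self.deleted)


@dataclass(frozen=True)
class ProteinConsequence:
    category: str
    hgvs_p: Optional[str] = None
    frame_preserved: bool = True
    stop_offset: Optional[int] = None  # fs*N; None = not applicable or unknown (extension)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SpliceEventError(f"unknown consequence category {self.category!r}")


def classify_frame(size_nt: int, event_kind: str) -> bool:
    """True iff a net change of ``size_nt`` nucleotides preserves the reading frame.

    Retentions/insertions and deletions alike: the frame survives exactly
    when the size is a multiple of 3.
    """
    if size_nt < 0:
        raise SpliceEventError(f"size_nt must be >= 0, got {size_nt}")
    if event_kind not in EVENT_KINDS:
        raise SpliceEventError(f"unknown event kind {event_kind!r}")
    return size_nt % 3 == 0


def apply_splice_event(model: TranscriptModel, e: SpliceEvent) -> AlteredTranscript:
    """Apply one splicing aberration to the transcript's exonic sequence."""
    if not model.has_exon_sequences:
        raise GeneModelError("transcript model carries no exon sequences")
    ref = model.spliced_sequence()

    if e.event_kind in ("intron_retention", "partial_intron_retention"):
        if not 1 <= e.region_index <= len(model.introns):
            raise SpliceEventError(f"no intron {e.region_index}")
        intron_seq = model.intron_sequence(e.region_index)  # raises if length-only
        if e.size_nt > len(intron_seq):
            raise SpliceEventError(
                f"retention of {e.size_nt} nt exceeds intron {e.region_index} "
                f"length {len(intron_seq)}"
            )
        retained = (
            intron_seq[: e.size_nt] if e.anchor_side == "donor" else intron_seq[-e.size_nt :]
        )
        junction = model.exon_end(e.region_index)  # last base of upstream exon
        seq = ref[:junction] + retained + ref[junction:]
        return AlteredTranscript(model.transcript_id, seq, junction, "", retained)

    if not 1 <= e.region_index <= len(model.exons):
        raise SpliceEventError(f"no exon {e.region_index}")
    exon = model.exons[e.region_index - 1]
    start = model.exon_start(e.region_index) - 1  # 0-based
    end = model.exon_end(e.region_index)  # 0-based exclusive

    if e.event_kind == "exon_skipping":
        if e.size_nt != exon.length:
            raise SpliceEventError(
                f"exon_skipping size {e.size_nt} != exon {e.region_index} length {exon.length}"
            )
        deleted = ref[start:end]
        return AlteredTranscript(model.transcript_id, ref[:start] + ref[end:], start, deleted, "")

    # exon_internal_deletion: truncation from the stated end of the exon
    if e.size_nt >= exon.length:
        raise SpliceEventError(
            f"deleting {e.size_nt} nt from exon {e.region_index} of length "
            f"{exon.length}: use exon_skipping for whole-exon loss"
        )
    if e.anchor_side == "donor":  # last size_nt bases of the exon
        del_start = end - e.size_nt
        deleted = ref[del_start:end]
        seq = ref[:del_start] + ref[end:]
        return AlteredTranscript(model.transcript_id, seq, del_start, deleted, "")
    deleted = ref[start : start + e.size_nt]  # first size_nt bases
    seq = ref[:start] + ref[start + e.size_nt :]
    return AlteredTranscript(model.transcript_id, seq, start, deleted, "")


# ---------------------------------------------------------------------------
# Protein consequence
# ---------------------------------------------------------------------------

def _translate_to_stop(cds: str) -> tuple[str, bool]:
    """Translate codons until the first stop; returns (peptide, stop_found)."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    idx = prot.find("*")
    if idx == -1:
        return prot, False
    return prot[:idx], True


def _aa3(residue: str) -> str:
    return seq3(residue)


def _normalize_deletion(p_ref: str, start: int, length: int) -> int:
    """3'-shift a deletion window of ``length`` residues starting at 0-based ``start``."""
    while start + length < len(p_ref) and p_ref[start] == p_ref[start + length]:
        start += 1
    return start


def _normalize_insertion(p_ref: str, after: int, run: str) -> tuple[int, str]:
    """3'-shift an insertion of ``run`` placed after 0-based residue index ``after``−1.

    ``after`` is the number of reference residues preceding the insertion.
    """
    run = list(run)
    while after < len(p_ref) and run and run[0] == p_ref[after]:
        run.append(run.pop(0))
        after += 1
    return after, "".join(run)


def translate_consequence(altered: AlteredTranscript, model: TranscriptModel) -> ProteinConsequence:
    """Predict the protein-level consequence of an edited transcript.

    The edited sequence must begin at the original translation start.
    Frameshifts report ``fs*N`` with the first changed residue as position 1
    and N the stop position in the new frame; in-frame edits report the
    deleted/inserted residue run, right-normalized per the HGVS 3' rule.
    Edits entirely 3' of the stop codon are ``no_change``; loss of the
    initiator ATG is ``start_loss``; loss of the stop codon without a new
    in-frame stop is ``stop_loss_extension``.
    """
    ref_cds = model.coding_sequence()
    p_ref = model.protein()
    alt_full = altered.sequence[model.cds_start - 1 :]

    if altered.edit_pos >= model.cds_end or (altered.delta_nt == 0 and not altered.deleted):
        return ProteinConsequence(category="no_change", hgvs_p="p.(=)", frame_preserved=True)

    # initiator codon occupies 0-based [cds_start-1, cds_start+2)
    init_end = model.cds_start - 1 + 3
    edit_end = altered.edit_pos + len(altered.deleted)
    touches_start = altered.edit_pos < init_end and edit_end >= model.cds_start - 1
    if touches_start and alt_full[:3] != "ATG":
        return ProteinConsequence(
            category="start_loss", hgvs_p="p.(Met1?)",
            frame_preserved=altered.delta_nt % 3 == 0,
        )

    frame_ok = altered.delta_nt % 3 == 0
    p_alt, stop_found = _translate_to_stop(alt_full)

    # first residue where the proteins differ (0-based)
    first = 0
    limit = min(len(p_ref), len(p_alt))
    while first < limit and p_ref[first] == p_alt[first]:
        first += 1

    if p_alt == p_ref and stop_found:
        return ProteinConsequence(category="no_change", hgvs_p="p.(=)", frame_preserved=frame_ok)

    if not frame_ok:
        if not stop_found:
            return ProteinConsequence(
                category="stop_loss_extension", hgvs_p=None,
                frame_preserved=False, stop_offset=None,
            )
        if first == len(p_alt):
            # new frame stops immediately at the first altered codon
            name = f"p.({_aa3(p_ref[first])}{first + 1}*)"
            return ProteinConsequence(
                category="premature_stop", hgvs_p=name, frame_preserved=False, stop_offset=1,
            )
        stop_offset = len(p_alt) - first + 1  # stop codon position, first changed residue = 1
        name = f"p.({_aa3(p_ref[first])}{first + 1}{_aa3(p_alt[first])}fs*{stop_offset})"
        return ProteinConsequence(
            category="frameshift", hgvs_p=name, frame_preserved=False, stop_offset=stop_offset,
        )

    # in-frame edit
    if not stop_found:
        return ProteinConsequence(category="stop_loss_extension", hgvs_p=None,
                                  frame_preserved=True, stop_offset=None)
    n_res = abs(altered.delta_nt) // 3

    if altered.delta_nt < 0:
        # candidate deletion of n_res residues starting at `first`
        start = _normalize_deletion(p_ref, first, n_res)
        if p_ref[:start] + p_ref[start + n_res :] == p_alt:
            if n_res == 1:
                name = f"p.({_aa3(p_ref[start])}{start + 1}del)"
            else:
                name = (
                    f"p.({_aa3(p_ref[start])}{start + 1}_"
                    f"{_aa3(p_ref[start + n_res - 1])}{start + n_res}del)"
                )
            return ProteinConsequence(category="in_frame_deletion", hgvs_p=name,
                                      frame_preserved=True)
        if len(p_alt) <= first:
            name = f"p.({_aa3(p_ref[first])}{first + 1}*)"
            return ProteinConsequence(category="premature_stop", hgvs_p=name,
                                      frame_preserved=True, stop_offset=1)
        return ProteinConsequence(category="in_frame_delins", hgvs_p=None, frame_preserved=True)

    if altered.delta_nt > 0:
        run = p_alt[first : first + n_res]
        if p_alt[:first] + p_alt[first + n_res :] == p_ref:
            after, run = _normalize_insertion(p_ref, first, run)
            if 1 <= after < len(p_ref):
                name = (
                    f"p.({_aa3(p_ref[after - 1])}{after}_"
                    f"{_aa3(p_ref[after])}{after + 1}ins{seq3(run)})"
                )
            else:
                name = None
            return ProteinConsequence(category="in_frame_insertion", hgvs_p=name,
                                      frame_preserved=True)
        if len(p_alt) <= first:
            name = f"p.({_aa3(p_ref[first])}{first + 1}*)"
            return ProteinConsequence(category="premature_stop", hgvs_p=name,
                                      frame_preserved=True, stop_offset=1)
        return ProteinConsequence(category="in_frame_delins", hgvs_p=None, frame_preserved=True)

    # delta 0 with differing protein: substitution-like delins
    if len(p_alt) < len(p_ref):
        name = f"p.({_aa3(p_ref[first])}{first + 1}*)"
        return ProteinConsequence(category="premature_stop", hgvs_p=name,
                                  frame_preserved=True, stop_offset=1)
    return ProteinConsequence(category="in_frame_delins", hgvs_p=None, frame_preserved=True)


# ---------------------------------------------------------------------------
# Per-variant summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesRow:
    """One transcript species observed for a variant."""

    species: str  # "normal" or the event description
    fraction: Optional[float]
    category: str
    hgvs_p: Optional[str]


def describe_event_set(
    model: TranscriptModel,
    events: Sequence[SpliceEvent],
    fraction_normal: Optional[float] = None,
) -> list[SpeciesRow]:
    """Summarize all transcript species produced by one variant.

    Aberrant species carry their consequence; a normal species row is
    emitted whenever the correctly spliced fraction is > 0 (or when there
    are no events at all).  Rows are ordered by descending fraction, ties
    broken by description.  Fractions must not sum above 1.
    """
    if fraction_normal is None:
        fraction_normal = events[0].fraction_normal if events else 1.0
    if not 0.0 <= fraction_normal <= 1.0:
        raise SpliceEventError(f"fraction_normal {fraction_normal} outside [0,1]")

    known = [e.fraction for e in events if e.fraction is not None]
    total = fraction_normal + sum(known)
    if total > 1.0 + 1e-9:
        raise SpliceEventError(f"species fractions sum to {total:.3f} > 1")
    n_unknown = sum(1 for e in events if e.fraction is None)
    residual = max(0.0, 1.0 - total)
    fill = residual / n_unknown if n_unknown else 0.0

    rows: list[SpeciesRow] = []
    for e in events:
        altered = apply_splice_event(model, e)
        cons = translate_consequence(altered, model)
        frac = e.fraction if e.fraction is not None else fill
        rows.append(SpeciesRow(e.describe(), frac, cons.category, cons.hgvs_p))
    if fraction_normal > 0.0 or not events:
        rows.append(SpeciesRow("normal", fraction_normal, "no_change", "p.(=)"))
    rows.sort(key=lambda r: (-(r.fraction if r.fraction is not None else 0.0), r.species))
    return rows


# ---------------------------------------------------------------------------
# Event-table I/O (tab-separated, documented header)
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["variant", "event_kind", "region_index", "size_nt", "anchor_side",
                 "fraction", "fraction_normal"]


def read_event_table(path: str | Path) -> list[tuple[str, SpliceEvent]]:
    """Read a tab-separated event table: one row per (variant, species)."""
    rows: list[tuple[str, SpliceEvent]] = []
    lines = [l for l in Path(path).read_text().splitlines() if l.strip() and not l.startswith("#")]
    if not lines:
        return rows
    header = lines[0].split("\t")
    missing = set(EVENT_COLUMNS) - set(header)
    if missing:
        raise SpliceEventError(f"event table missing columns: {sorted(missing)}")
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        rows.append(
            (
                rec["variant"],
                SpliceEvent(
                    event_kind=rec["event_kind"],
                    region_index=int(rec["region_index"]),
                    size_nt=int(rec["size_nt"]),
                    anchor_side=rec["anchor_side"] or "donor",
                    fraction=float(rec["fraction"]) if rec["fraction"] not in ("", "NA") else None,
                    fraction_normal=float(rec["fraction_normal"] or 0.0),
                ),
            )
        )
    return rows


def write_event_table(path: str | Path, rows: Sequence[tuple[str, SpliceEvent]]) -> None:
    out = ["\t".join(EVENT_COLUMNS)]
    for variant, e in rows:
        out.append("\t".join([
            variant, e.event_kind, str(e.region_index), str(e.size_nt), e.anchor_side,
            "" if e.fraction is None else f"{e.fraction:g}", f"{e.fraction_normal:g}",
        ]))
    Path(path).write_text("\n".join(out) + "\n")


def summary_to_json(summaries: dict[str, list[SpeciesRow]]) -> str:
    payload = {
        variant: [
            {"species": r.species, "fraction": r.fraction,
             "category": r.category, "hgvs_p": r.hgvs_p}
            for r in rows
        ]
        for variant, rows in summaries.items()
    }
    return json.dumps(payload, indent=2, sort_keys=True)
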