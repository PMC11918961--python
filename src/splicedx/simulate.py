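"""Synthetic data with known ground truth for every pipeline stage.

Three generators, all deterministic under a seed:

* :func:`make_toy_transcript` — random multi-exon transcripts with valid
  ORFs (ATG start, no internal stop, terminal stop), built codon-aware so
  no rejection loops are needed for the CDS itself.
* :func:`inject_event` — an engineered splice aberration plus its oracle
  protein consequence, computed by direct string editing and a naive codon
  scan that shares no code with the consequence engine it is used to check.
* :func:`make_cohort` — variant tables with planted per-tool operating
  characteristics (sensitivity/specificity) and a planted true
  splice-aberration rate; numeric scores are sampled on the call-consistent
  side of each decision threshold with a small guard band so boundary
  behavior never flips a planted call.

Defaults mirror the study conditions: a true splice rate of 8/11, partial
aberrations with 10–35% residual normal splicing, and per-tool profiles at
the operating points observed on the 11-variant study table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gene_model import Region, TranscriptModel
from .insilico import (
    MAXENT_PERCENT_DROP,
    NEGATIVE_VERDICTS,
    SPLICEAI_THRESHOLD,
    VARSEAK_AFFECTING_MIN_CLASS,
)
from .splice_consequence import EVENT_KINDS, SpliceEvent

_GUARD = 0.02  # relative guard band keeping sampled scores clear of thresholds

_SENSE_CODONS = sorted(
    {
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
    }
    - {"TAA", "TAG", "TGA", "ATG"}
)
_STOP_CODONS = ("TAA", "TAG", "TGA")

# observed operating points of the five predictors on the 11-variant study
# table (sensitivity over 8 truly spliceogenic, specificity over 3 negative)
DEFAULT_TOOL_PROFILES: dict[str, tuple[float, float]] = {
    "hsf": (8 / 8, 2 / 3),
    "spliceai": (7 / 8, 3 / 3),
    "varseak": (6 / 8, 3 / 3),
    "mutationtaster": (4 / 8, 1 / 3),
    "maxentscan": (6 / 8, 2 / 3),
}

_AFFIRMATIVE_VERDICT = "Alteration of the WT splice site, most probably affecting splicing"


class SimulationError(ValueError):
    """Unsatisfiable simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; identical configs give identical outputs."""

    seed: int = 0
    n_exons: int = 5
    exon_length_range: tuple[int, int] = (60, 180)
    intron_length_range: tuple[int, int] = (80, 300)
    n_variants: int = 11
    true_splice_rate: float = 8 / 11
    complete_fraction: float = 3 / 8  # of truly spliceogenic variants
    tool_profiles: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TOOL_PROFILES)
    )
    normal_fraction_range: tuple[float, float] = (0.10, 0.35)
    measurement_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_exons < 2:
            raise SimulationError("need at least 2 exons")
        for name, (lo, hi) in (
            ("exon_length_range", self.exon_length_range),
            ("intron_length_range", self.intron_length_range),
        ):
            if not 1 <= lo <= hi:
                raise SimulationError(f"invalid {name}: {(lo, hi)}")
        if self.exon_length_range[0] < 12:
            raise SimulationError("exons shorter than 12 nt cannot host the test events")
        for name, p in (
            ("true_splice_rate", self.true_splice_rate),
            ("complete_fraction", self.complete_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"{name} outside [0,1]")
        lo, hi = self.normal_fraction_range
        if not 0.0 < lo <= hi < 1.0:
            raise SimulationError(f"normal_fraction_range {self.normal_fraction_range} invalid")
        for tool, (sens, spec) in self.tool_profiles.items():
            if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
                raise SimulationError(f"{tool}: sensitivity/specificity outside [0,1]")
        if self.measurement_noise_sd < 0:
            raise SimulationError("measurement_noise_sd must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        data = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SimulationError(f"unknown config fields: {sorted(unknown)}")
        for key in ("exon_length_range", "intron_length_range", "normal_fraction_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "tool_profiles" in data:
            data["tool_profiles"] = {
                tool: tuple(pair) for tool, pair in data["tool_profiles"].items()
            }
        return cls(**data)


# ---------------------------------------------------------------------------
# Toy transcripts
# ---------------------------------------------------------------------------

def make_toy_transcript(config: SimulationConfig, rng: Optional[np.random.Generator] = None
                        ) -> TranscriptModel:
    """A random transcript whose CDS spans all exons and satisfies every model invariant.

    Exon lengths are drawn from ``exon_length_range`` and the last exon is
    nudged so the total is a multiple of 3; the CDS is then assembled
    codon-aware (ATG + sense codons + one stop) and split across the exons.
    Introns are random sequence with canonical GT...AG terminal dinucleotides.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.exon_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_exons).tolist()
    total = sum(lengths)
    bump = (-total) % 3
    lengths[-1] += bump
    total += bump

    n_codons = total // 3
    if n_codons < 3:
        raise SimulationError("transcript too short for start + body + stop")
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    cds = "ATG" + "".join(body) + _STOP_CODONS[int(rng.integers(0, 3))]
    assert len(cds) == total

    exons = []
    pos = 0
    for i, length in enumerate(lengths, start=1):
        exons.append(Region(index=i, length=length, sequence=cds[pos : pos + length]))
        pos += length

    ilo, ihi = config.intron_length_range
    introns = []
    for i in range(1, config.n_exons):
        length = int(rng.integers(max(ilo, 4), ihi + 1))
        inner = "".join(rng.choice(list("ACGT"), size=length - 4))
        introns.append(Region(index=i, length=length, sequence="GT" + inner + "AG"))

    return TranscriptModel(
        transcript_id=f"toy-{config.seed}-{config.n_exons}ex",
        exons=tuple(exons),
        introns=tuple(introns),
        cds_start=1,
        cds_end=total,
    )


# ---------------------------------------------------------------------------
# Independent consequence oracle
# ---------------------------------------------------------------------------

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _oracle_translate(seq: str) -> tuple[str, bool]:
    """Naive codon scan to the first stop; returns (peptide, stop_found)."""
    peptide = []
    for i in range(0, len(seq) - 2, 3):
        aa = _CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            return "".join(peptide), True
        peptide.append(aa)
    return "".join(peptide), False


@dataclass(frozen=True)
class OracleConsequence:
    category: str
    stop_offset: Optional[int]
    n_residues_changed: int  # inserted (in-frame +) or deleted (in-frame -) residues


def oracle_consequence(model: TranscriptModel, event: SpliceEvent) -> OracleConsequence:
    """Consequence by direct string edit + naive translation (the test oracle).

    Independent of the consequence engine: builds the edited cDNA by slicing
    the raw strings, translates with a local codon table, and classifies by
    comparing peptides.
    """
    exon_seqs = [e.sequence for e in model.exons]
    intron_seqs = [i.sequence for i in model.introns]
    if any(s is None for s in exon_seqs):
        raise SimulationError("oracle needs exon sequences")

    pieces = list(exon_seqs)
    k = event.region_index
    if event.event_kind in ("intron_retention", "partial_intron_retention"):
        iseq = intron_seqs[k - 1]
        if iseq is None or event.size_nt > len(iseq):
            raise SimulationError("oracle: invalid retention")
        retained = iseq[: event.size_nt] if event.anchor_side == "donor" else iseq[-event.size_nt :]
        pieces[k - 1] = pieces[k - 1] + retained
    elif event.event_kind == "exon_skipping":
        pieces[k - 1] = ""
    else:  # exon_internal_deletion
        exon = pieces[k - 1]
        if event.size_nt >= len(exon):
            raise SimulationError("oracle: deletion covers whole exon")
        pieces[k - 1] = (
            exon[: -event.size_nt] if event.anchor_side == "donor" else exon[event.size_nt :]
        )

    edited = "".join(pieces)[model.cds_start - 1 :]
    ref_pep, _ = _oracle_translate(model.coding_sequence())
    alt_pep, stop_found = _oracle_translate(edited)

    if alt_pep == ref_pep and stop_found:
        return OracleConsequence("no_change", None, 0)
    if not alt_pep.startswith("M"):
        return OracleConsequence("start_loss", None, 0)

    if event.event_kind in ("intron_retention", "partial_intron_retention"):
        delta = event.size_nt
    else:
        delta = -event.size_nt

    first = 0
    while first < min(len(ref_pep), len(alt_pep)) and ref_pep[first] == alt_pep[first]:
        first += 1

    if delta % 3 != 0:
        if not stop_found:
            return OracleConsequence("stop_loss_extension", None, 0)
        if first == len(alt_pep):
            return OracleConsequence("premature_stop", 1, 0)
        return OracleConsequence("frameshift", len(alt_pep) - first + 1, 0)

    if not stop_found:
        return OracleConsequence("stop_loss_extension", None, 0)
    n = abs(delta) // 3
    if delta > 0 and alt_pep[:first] + alt_pep[first + n :] == ref_pep:
        return OracleConsequence("in_frame_insertion", None, n)
    if delta < 0:
        # try every deletion window consistent with the common prefix
        for start in range(first, min(first + n, len(ref_pep)) + 1):
            if ref_pep[:start] + ref_pep[start + n :] == alt_pep:
                return OracleConsequence("in_frame_deletion", None, -n)
    if len(alt_pep) <= first:
        return OracleConsequence("premature_stop", 1, 0)
    return OracleConsequence("in_frame_delins", None, 0)


def inject_event(
    model: TranscriptModel,
    kind: str,
    region_index: int,
    size_nt: int,
    anchor_side: str = "donor",
    fraction_normal: float = 0.0,
) -> tuple[SpliceEvent, OracleConsequence]:
    """Build a splice event on ``model`` and return it with its oracle consequence."""
    if kind not in EVENT_KINDS:
        raise SimulationError(f"unknown event kind {kind!r}")
    regions = model.introns if "intron" in kind else model.exons
    if not 1 <= region_index <= len(regions):
        raise SimulationError(f"no {'intron' if 'intron' in kind else 'exon'} {region_index}")
    region = regions[region_index - 1]
    if kind == "exon_skipping":
        size_nt = region.length
    elif kind == "exon_internal_deletion":
        if size_nt >= region.length:
            raise SimulationError(
                f"deletion of {size_nt} nt >= exon length {region.length}"
            )
    elif size_nt > region.length:
        raise SimulationError(f"retention of {size_nt} nt > intron length {region.length}")
    event = SpliceEvent(
        event_kind=kind,
        region_index=region_index,
        size_nt=size_nt,
        anchor_side=anchor_side,
        fraction_normal=fraction_normal,
    )
    return event, oracle_consequence(model, event)


def random_event(model: TranscriptModel, rng: np.random.Generator,
                 fraction_normal: float = 0.0) -> tuple[SpliceEvent, OracleConsequence]:
    """A random valid event on ``model`` (uniform over kinds, sizes and regions)."""
    kind = EVENT_KINDS[int(rng.integers(0, len(EVENT_KINDS)))]
    if "intron" in kind:
        region = int(rng.integers(1, len(model.introns) + 1))
        max_size = model.introns[region - 1].length
        size = int(rng.integers(1, max_size + 1))
        side = ("donor", "acceptor")[int(rng.integers(0, 2))]
    elif kind == "exon_skipping":
        # skipping exon 1 would remove the start codon by construction; allowed,
        # the oracle labels it start_loss
        region = int(rng.integers(1, len(model.exons) + 1))
        size = model.exons[region - 1].length
        side = "donor"
    else:
        region = int(rng.integers(1, len(model.exons) + 1))
        size = int(rng.integers(1, model.exons[region - 1].length))
        side = ("donor", "acceptor")[int(rng.integers(0, 2))]
    return inject_event(model, kind, region, size, side, fraction_normal)


# ---------------------------------------------------------------------------
# Cohorts with planted tool operating characteristics
# ---------------------------------------------------------------------------

def _sample_scores_for_call(tool: str, positive: bool, rng: np.random.Generator) -> dict:
    """Predictor output consistent with the planted call, clear of the threshold."""
    if tool == "spliceai":
        if positive:
            score = rng.uniform(SPLICEAI_THRESHOLD + _GUARD, 1.0)
        else:
            score = rng.uniform(0.0, SPLICEAI_THRESHOLD - _GUARD)
        channel = ("acceptor_loss", "acceptor_gain", "donor_loss", "donor_gain")[
            int(rng.integers(0, 4))
        ]
        return {"spliceai": f"{channel}:{score:.3f}"}
    if tool == "varseak":
        cls = int(rng.integers(VARSEAK_AFFECTING_MIN_CLASS, 6)) if positive else int(rng.integers(1, 3))
        return {"varseak_class": cls}
    if tool == "maxentscan":
        ref = rng.uniform(5.0, 12.0)
        if positive:
            pct = rng.uniform(-100.0, -(MAXENT_PERCENT_DROP + 100 * _GUARD))
        else:
            pct = rng.uniform(-(MAXENT_PERCENT_DROP - 100 * _GUARD), 20.0)
        alt = ref * (1 + pct / 100.0)
        return {"maxent_ref": round(ref, 2), "maxent_alt": round(alt, 2)}
    phrase = _AFFIRMATIVE_VERDICT if positive else NEGATIVE_VERDICTS[int(rng.integers(0, 2))]
    key = "hsf_verdict" if tool == "hsf" else "mt_verdict"
    return {key: phrase}


@dataclass(frozen=True)
class GroundTruthRecord:
    variant: str
    truly_spliceogenic: bool
    outcome_category: str
    normal_fraction: float
    event: Optional[SpliceEvent]
    oracle: Optional[OracleConsequence]
    tool_calls: dict[str, bool]


def make_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[GroundTruthRecord], TranscriptModel]:
    """Simulate a study-shaped cohort.

    Returns (prediction table, assay outcome table, ground-truth records,
    the shared toy transcript).  Each variant's true status is Bernoulli
    (``true_splice_rate``); each tool's binary call is drawn from its
    planted (sensitivity, specificity); scores are then sampled consistent
    with the call.  Truly spliceogenic variants get a concrete engineered
    event on the toy transcript and either a complete aberration or a
    partial one with a noisy normal fraction from the configured range.
    """
    rng = np.random.default_rng(config.seed)
    model = make_toy_transcript(config, rng)

    pred_rows, outcome_rows, truth = [], [], []
    for i in range(config.n_variants):
        variant = f"synthetic_v{i + 1:05d}"
        spliceogenic = bool(rng.random() < config.true_splice_rate)

        if spliceogenic:
            complete = bool(rng.random() < config.complete_fraction)
            if complete:
                normal_fraction = 0.0
            else:
                nf = rng.uniform(*config.normal_fraction_range)
                nf += rng.normal(0.0, config.measurement_noise_sd)
                normal_fraction = float(np.clip(nf, 0.01, 0.99))
            event, oracle = random_event(model, rng, fraction_normal=normal_fraction)
            category = "complete_aberration" if complete else "predominant_aberration"
        else:
            event, oracle = None, None
            normal_fraction = 1.0
            category = "no_effect"

        calls = {}
        row: dict = {"variant": variant}
        for tool, (sens, spec) in config.tool_profiles.items():
            p_positive = sens if spliceogenic else 1.0 - spec
            positive = bool(rng.random() < p_positive)
            calls[tool] = positive
            row.update(_sample_scores_for_call(tool, positive, rng))
        pred_rows.append(row)

        outcome_rows.append(
            {
                "variant": variant,
                "category": category,
                "normal_fraction": normal_fraction,
                "event_kind": event.event_kind if event else "",
                "region_index": event.region_index if event else "",
                "size_nt": event.size_nt if event else "",
                "anchor_side": event.anchor_side if event else "",
            }
        )
        truth.append(
            GroundTruthRecord(
                variant=variant,
                truly_spliceogenic=spliceogenic,
                outcome_category=category,
                normal_fraction=normal_fraction,
                event=event,
                oracle=oracle,
                tool_calls=calls,
            )
        )

    predictions = pd.DataFrame(pred_rows)
    outcomes = pd.DataFrame(outcome_rows)
    return predictions, outcomes, truth, model
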