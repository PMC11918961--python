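"""Thresholded interpretation of external splice-prediction outputs.

The five predictors (SpliceAI, varSEAK, MaxEntScan, Human Splicing Finder,
MutationTaster) are *inputs*: their precomputed scores, classes and verdict
phrases are turned into binary splice-affecting calls with the study's
decision rules —

* SpliceAI: any delta score strictly > 0.2;
* varSEAK: class > 2 (i.e. 3–5);
* MaxEntScan: splice-site score decrease of at least 15%;
* HSF / MutationTaster: any verdict phrase except the two explicit
  negatives ("No significant impact on splicing signals", "No abrogation
  of potential splice sites").

Variant prioritization combines the calls with a gnomAD-style rarity gate
(overall allele frequency below a cutoff, alleles counted as 2 x persons).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .gene_model import VariantLocus

logger = logging.getLogger(__name__)

SPLICEAI_THRESHOLD = 0.2  # strictly greater than
VARSEAK_AFFECTING_MIN_CLASS = 3  # "class > 2"
MAXENT_PERCENT_DROP = 15.0  # decrease of >= 15% is a positive call
DEFAULT_AF_CUTOFF = 1e-3

NEGATIVE_VERDICTS = (
    "No significant impact on splicing signals",
    "No abrogation of potential splice sites",
)

# "max" is a pseudo-channel for tables that print only the top delta score
SPLICEAI_CHANNELS = ("acceptor_loss", "acceptor_gain", "donor_loss", "donor_gain", "max")

TOOLS = ("hsf", "spliceai", "varseak", "mutationtaster", "maxentscan")


class PredictionError(ValueError):
    """Missing or out-of-range predictor output."""


@dataclass(frozen=True)
class ToolPredictions:
    """Precomputed outputs of the five predictors for one variant.

    Any field may be absent (None / empty); each ``call_*`` function
    requires only its own input.
    """

    spliceai_scores: Mapping[str, float] = field(default_factory=dict)
    varseak_class: Optional[int] = None
    maxent_ref: Optional[float] = None
    maxent_alt: Optional[float] = None
    hsf_verdict: Optional[str] = None
    mutationtaster_verdict: Optional[str] = None

    def __post_init__(self) -> None:
        for channel, score in self.spliceai_scores.items():
            if channel not in SPLICEAI_CHANNELS:
                raise PredictionError(f"unknown SpliceAI channel {channel!r}")
            if not 0.0 <= score <= 1.0:
                raise PredictionError(f"SpliceAI {channel} score {score} outside [0,1]")
        if self.varseak_class is not None and self.varseak_class not in range(1, 6):
            raise PredictionError(f"varSEAK class {self.varseak_class} outside 1..5")


@dataclass(frozen=True)
class ToolCall:
    tool: str
    affects_splicing: bool
    rationale: str

    def __post_init__(self) -> None:
        if not self.rationale:
            raise PredictionError("a ToolCall must carry a rationale")


@dataclass(frozen=True)
class PopulationCounts:
    """gnomAD-style genotype counts: homozygotes / heterozygotes / persons tested."""

    hom: int
    het: int
    total_persons: int
    popmax_af: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.hom, self.het, self.total_persons) < 0:
            raise PredictionError("genotype counts must be non-negative")
        if self.hom + self.het > self.total_persons:
            raise PredictionError(
                f"carriers ({self.hom}+{self.het}) exceed persons tested ({self.total_persons})"
            )


def call_spliceai(p: ToolPredictions) -> ToolCall:
    """Positive iff the maximum reported delta score is strictly above 0.2."""
    if not p.spliceai_scores:
        raise PredictionError("no SpliceAI delta scores present (distinct from a score of 0)")
    channel, top = max(p.spliceai_scores.items(), key=lambda kv: (kv[1], kv[0]))
    affecting = top > SPLICEAI_THRESHOLD
    return ToolCall(
        tool="spliceai",
        affects_splicing=affecting,
        rationale=(
            f"max delta score {top:g} ({channel}) "
            f"{'>' if affecting else '<='} {SPLICEAI_THRESHOLD}"
        ),
    )


def call_varseak(p: ToolPredictions) -> ToolCall:
    """Positive iff the varSEAK class is 3, 4 or 5 ('class > 2')."""
    if p.varseak_class is None:
        raise PredictionError("varSEAK class absent")
    affecting = p.varseak_class >= VARSEAK_AFFECTING_MIN_CLASS
    return ToolCall(
        tool="varseak",
        affects_splicing=affecting,
        rationale=f"class {p.varseak_class} {'>=' if affecting else '<'} "
                  f"{VARSEAK_AFFECTING_MIN_CLASS}",
    )


def maxent_percent_change(ref: float, alt: float) -> float:
    """Signed percent change of the MaxEntScan splice-site score, (alt-ref)/ref*100.

    Returned unrounded; round to one decimal for display only.
    """
    if ref == 0:
        raise PredictionError("MaxEntScan reference score is 0: percent change undefined")
    return (alt - ref) / ref * 100.0


def call_maxent(p: ToolPredictions) -> ToolCall:
    """Positive iff the splice-site score drops by at least 15%."""
    if p.maxent_ref is None or p.maxent_alt is None:
        raise PredictionError("MaxEntScan ref/alt scores absent")
    pct = maxent_percent_change(p.maxent_ref, p.maxent_alt)
    affecting = pct <= -MAXENT_PERCENT_DROP
    return ToolCall(
        tool="maxentscan",
        affects_splicing=affecting,
        rationale=(
            f"{p.maxent_ref:g} -> {p.maxent_alt:g} = {pct:.1f}% "
            f"({'decrease >= ' if affecting else 'decrease < '}{MAXENT_PERCENT_DROP:g}%)"
        ),
    )


def _normalize_phrase(phrase: str) -> str:
    return re.sub(r"\s+", " ", phrase).strip().casefold().rstrip(".")


_NEGATIVE_NORMALIZED = {_normalize_phrase(p) for p in NEGATIVE_VERDICTS}


def call_text_verdict(tool: str, phrase: str) -> ToolCall:
    """Interpret an HSF or MutationTaster verdict phrase.

    Only the two explicit negative phrases mean "no effect"; every other
    phrase — including ambiguous ones like "Donor increased" — counts as
    predicting altered splicing, which is the rule's literal consequence.
    Unknown phrases are logged but never rejected.
    """
    if tool not in ("hsf", "mutationtaster"):
        raise PredictionError(f"call_text_verdict handles hsf|mutationtaster, not {tool!r}")
    if not phrase or not phrase.strip():
        raise PredictionError(f"empty {tool} verdict phrase")
    norm = _normalize_phrase(phrase)
    if norm in _NEGATIVE_NORMALIZED:
        return ToolCall(tool=tool, affects_splicing=False,
                        rationale=f"negative phrase: {phrase!r}")
    if not any(key in norm for key in ("splic", "donor", "acceptor", "site", "branch")):
        logger.warning("unrecognized %s verdict treated as affecting: %r", tool, phrase)
    return ToolCall(tool=tool, affects_splicing=True,
                    rationale=f"phrase not among the negative verdicts: {phrase!r}")


def calls_for(p: ToolPredictions) -> dict[str, ToolCall]:
    """All five calls for one variant (each tool's input must be present)."""
    return {
        "hsf": call_text_verdict("hsf", p.hsf_verdict or ""),
        "spliceai": call_spliceai(p),
        "varseak": call_varseak(p),
        "mutationtaster": call_text_verdict("mutationtaster", p.mutationtaster_verdict or ""),
        "maxentscan": call_maxent(p),
    }


def available_calls(p: ToolPredictions) -> dict[str, ToolCall]:
    """Calls for every tool whose input is present; absent tools are skipped.

    Unlike :func:`calls_for`, which demands all five inputs, this is the
    entry point for tables covering a subset of the predictors.
    """
    calls: dict[str, ToolCall] = {}
    if p.spliceai_scores:
        calls["spliceai"] = call_spliceai(p)
    if p.varseak_class is not None:
        calls["varseak"] = call_varseak(p)
    if p.maxent_ref is not None and p.maxent_alt is not None:
        calls["maxentscan"] = call_maxent(p)
    if p.hsf_verdict and p.hsf_verdict.strip():
        calls["hsf"] = call_text_verdict("hsf", p.hsf_verdict)
    if p.mutationtaster_verdict and p.mutationtaster_verdict.strip():
        calls["mutationtaster"] = call_text_verdict("mutationtaster", p.mutationtaster_verdict)
    return calls


def allele_frequency(c: PopulationCounts) -> float:
    """Overall allele frequency: (2*hom + het) / (2*persons)."""
    if c.total_persons <= 0:
        raise PredictionError("total_persons must be > 0 for an allele frequency")
    return (2 * c.hom + c.het) / (2 * c.total_persons)


@dataclass(frozen=True)
class PrioritizationResult:
    include: bool
    reasons: tuple[str, ...]


def prioritize_variant(
    locus: Optional[VariantLocus],
    calls: Mapping[str, ToolCall],
    counts: Optional[PopulationCounts],
    cutoff: float = DEFAULT_AF_CUTOFF,
    auto_qualifying: bool = False,
    use_popmax: bool = False,
) -> PrioritizationResult:
    """Apply the inclusion filter: rare AND (auto-qualifying OR >=1 positive call).

    A variant absent from the population database counts as frequency 0.
    ``auto_qualifying`` marks classes that need no in silico support
    (nonsense/frameshift/canonical-site); a canonical-site locus qualifies
    automatically.  ``use_popmax`` gates on the highest per-population
    frequency instead of the overall one when it is available (stricter,
    optional mode).
    """
    reasons: list[str] = []
    if counts is None:
        af = 0.0
        reasons.append(f"absent from population database: AF treated as 0 < {cutoff:g}")
        rare = True
    else:
        af = allele_frequency(counts)
        if use_popmax and counts.popmax_af is not None:
            af = counts.popmax_af
            reasons.append(f"popmax AF {af:.3g} vs cutoff {cutoff:g}")
        else:
            reasons.append(f"overall AF {af:.3g} vs cutoff {cutoff:g}")
        rare = af < cutoff
    if not rare:
        reasons.append("frequency gate failed: excluded regardless of predictions")
        return PrioritizationResult(False, tuple(reasons))

    if auto_qualifying or (locus is not None and locus.is_canonical_site):
        reasons.append("automatically qualifying variant class (no in silico support needed)")
        return PrioritizationResult(True, tuple(reasons))

    positive = sorted(name for name, call in calls.items() if call.affects_splicing)
    if positive:
        reasons.append(f"{len(positive)}/{len(calls)} tools affecting: {', '.join(positive)}")
        return PrioritizationResult(True, tuple(reasons))
    reasons.append(f"0/{len(calls)} tools call the variant splice-affecting")
    return PrioritizationResult(False, tuple(reasons))


# ---------------------------------------------------------------------------
# Serialization helpers for prediction tables
# ---------------------------------------------------------------------------

def parse_spliceai_field(text: str) -> dict[str, float]:
    """Parse 'acceptor_loss:0.84;acceptor_gain:0.99' into a score mapping."""
    scores: dict[str, float] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        channel, _, value = part.partition(":")
        scores[channel.strip()] = float(value)
    return scores


def format_spliceai_field(scores: Mapping[str, float]) -> str:
    return ";".join(f"{k}:{scores[k]:g}" for k in sorted(scores))


def tool_predictions_from_row(row: Mapping[str, object]) -> ToolPredictions:
    """Build :class:`ToolPredictions` from one prediction-table row.

    Recognized columns: ``spliceai`` (channel:score pairs), ``varseak_class``,
    ``maxent_ref``/``maxent_alt``, ``hsf_verdict``, ``mt_verdict``.  Absent or
    empty columns stay unset.
    """
    def _get(key: str) -> Optional[str]:
        value = row.get(key)  # type: ignore[union-attr]
        if value is None:
            return None
        text = str(value).strip()
        return text or None

    spliceai = _get("spliceai")
    varseak = _get("varseak_class")
    ref, alt = _get("maxent_ref"), _get("maxent_alt")
    return ToolPredictions(
        spliceai_scores=parse_spliceai_field(spliceai) if spliceai else {},
        varseak_class=int(float(varseak)) if varseak else None,
        maxent_ref=float(ref) if ref else None,
        maxent_alt=float(alt) if alt else None,
        hsf_verdict=_get("hsf_verdict"),
        mutationtaster_verdict=_get("mt_verdict"),
    )


def parse_gnomad_field(text: str) -> Optional[PopulationCounts]:
    """Parse 'hom/het/total' ('0/71/280946'); '', '-' or '—' mean not reported."""
    text = text.strip()
    if text in ("", "-", "—", "NA"):
        return None
    hom, het, total = (int(x) for x in text.split("/"))
    return PopulationCounts(hom=hom, het=het, total_persons=total)
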