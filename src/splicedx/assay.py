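"""Minigene / blood-RNA assay outcomes and prediction-tool concordance.

An assay outcome for one variant lists the transcript species seen on the
gel — aberrant splicing events and/or a normally spliced band — with the
normally spliced fraction estimated by qPCR.  Categories are structural,
not threshold-based:

* ``complete_aberration``    — aberrant species only (normal fraction 0);
* ``predominant_aberration`` — aberrant species plus any nonzero normal
  fraction (the study's partial range is 10–35%);
* ``no_effect``              — only the normal species.

Concordance scores each predictor's binary calls against the assay truth
(complete or predominant => splice-affecting) as a per-tool confusion
table with accuracy, PPV and NPV; ratios with a zero denominator are
reported as undefined, never as 0 or 100.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .splice_consequence import SpliceEvent

logger = logging.getLogger(__name__)

COMPLETE = "complete_aberration"
PREDOMINANT = "predominant_aberration"
NO_EFFECT = "no_effect"


class AssayError(ValueError):
    """Inconsistent assay record."""


@dataclass(frozen=True)
class AssayOutcome:
    """Observed splicing result for one variant from one evidence source."""

    variant: str
    species: tuple[Optional[SpliceEvent], ...]  # None = the normal species
    normal_fraction: float
    source: str = "minigene"  # minigene | patient_rna

    def __post_init__(self) -> None:
        if not 0.0 <= self.normal_fraction <= 1.0:
            raise AssayError(f"normal_fraction {self.normal_fraction} outside [0,1]")
        if self.source not in ("minigene", "patient_rna"):
            raise AssayError(f"unknown assay source {self.source!r}")
        has_normal = any(s is None for s in self.species)
        if not self.species and self.normal_fraction != 1.0:
            raise AssayError(f"{self.variant}: empty species list requires normal_fraction = 1")
        if self.aberrant_events and self.normal_fraction == 1.0:
            raise AssayError(
                f"{self.variant}: aberrant species observed but normal_fraction = 1"
            )
        if has_normal and self.normal_fraction == 0.0 and self.aberrant_events:
            raise AssayError(
                f"{self.variant}: normal species listed but normal_fraction = 0"
            )

    @property
    def aberrant_events(self) -> tuple[SpliceEvent, ...]:
        return tuple(s for s in self.species if s is not None)


def classify_outcome(o: AssayOutcome) -> str:
    """Category from (presence of aberrant species, normal fraction) alone."""
    if not o.aberrant_events:
        return NO_EFFECT
    if o.normal_fraction == 0.0:
        return COMPLETE
    return PREDOMINANT


def truth_label(category: str) -> bool:
    """Experimental truth for concordance: does the variant affect splicing?"""
    if category in (COMPLETE, PREDOMINANT):
        return True
    if category == NO_EFFECT:
        return False
    raise AssayError(f"unknown outcome category {category!r}")


def reconcile_sources(outcomes: Sequence[AssayOutcome]) -> str:
    """Category for a variant assayed by several sources.

    Sources are expected to agree (the study's blood-RNA result matched the
    minigene); a discordance is flagged with a warning and the minigene
    category is returned — no automatic resolution is attempted.
    """
    if not outcomes:
        raise AssayError("no outcomes to reconcile")
    categories = {o.source: classify_outcome(o) for o in outcomes}
    if len(set(categories.values())) > 1:
        logger.warning(
            "discordant assay sources for %s: %s (keeping minigene)",
            outcomes[0].variant, categories,
        )
    return categories.get("minigene", next(iter(categories.values())))


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceTable:
    """Confusion counts and derived metrics for one predictor."""

    tool: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> Optional[float]:
        return None if self.total == 0 else 100.0 * (self.tp + self.tn) / self.total

    @property
    def ppv(self) -> Optional[float]:
        denom = self.tp + self.fp
        return None if denom == 0 else 100.0 * self.tp / denom

    @property
    def npv(self) -> Optional[float]:
        denom = self.tn + self.fn
        return None if denom == 0 else 100.0 * self.tn / denom

    def as_dict(self) -> dict:
        rounded = lambda x: None if x is None else round(x, 1)
        return {
            "tool": self.tool, "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "accuracy_pct": rounded(self.accuracy),
            "ppv_pct": rounded(self.ppv),
            "npv_pct": rounded(self.npv),
        }


def concordance(
    calls: Mapping[str, Sequence[bool]], truth: Sequence[bool]
) -> dict[str, ConcordanceTable]:
    """Score per-tool call vectors against the assay truth vector.

    All vectors must be aligned on the same variant list.
    """
    tables: dict[str, ConcordanceTable] = {}
    for tool, vector in calls.items():
        if len(vector) != len(truth):
            raise AssayError(
                f"{tool}: {len(vector)} calls vs {len(truth)} truth labels"
            )
        tp = fp = tn = fn = 0
        for call, actual in zip(vector, truth):
            if call and actual:
                tp += 1
            elif call and not actual:
                fp += 1
            elif not call and not actual:
                tn += 1
            else:
                fn += 1
        tables[tool] = ConcordanceTable(tool=tool, tp=tp, fp=fp, tn=tn, fn=fn)
    return tables


def cohort_splice_rate(categories: Sequence[str]) -> float:
    """Fraction of variants with any aberrant splicing (complete or predominant)."""
    if not categories:
        raise AssayError("cannot compute a splice rate over zero outcomes")
    aberrant = sum(1 for c in categories if truth_label(c))
    return aberrant / len(categories)


def concordance_report_json(
    tables: Mapping[str, ConcordanceTable], splice_rate: Optional[float] = None
) -> str:
    payload: dict = {"tools": [tables[t].as_dict() for t in sorted(tables)]}
    if splice_rate is not None:
        payload["aberrant_splicing_rate_pct"] = round(100.0 * splice_rate, 1)
    return json.dumps(payload, indent=2)


def concordance_report_tsv(
    tables: Mapping[str, ConcordanceTable], splice_rate: Optional[float] = None
) -> str:
    fmt = lambda x: "undefined" if x is None else f"{x:.1f}"
    lines = ["tool\tTP\tFP\tTN\tFN\taccuracy_pct\tppv_pct\tnpv_pct"]
    for name in sorted(tables):
        t = tables[name]
        lines.append(
            f"{t.tool}\t{t.tp}\t{t.fp}\t{t.tn}\t{t.fn}\t"
            f"{fmt(t.accuracy)}\t{fmt(t.ppv)}\t{fmt(t.npv)}"
        )
    if splice_rate is not None:
        lines.append(f"# aberrant_splicing_rate_pct\t{100.0 * splice_rate:.1f}")
    return "\n".join(lines) + "\n"
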