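"""ACMG/AMP point-based variant classification with functional reclassification.

Evidence codes carry an intrinsic strength given by their prefix (PVS very
strong, PS strong, PM moderate, PP supporting; BA stand-alone, BS strong,
BP supporting) that a ``_P`` / ``_Supporting`` suffix lowers to supporting.
Points are additive: +1/+2/+4/+8 for pathogenic supporting/moderate/strong/
very strong, the negated values for benign codes.  The five tiers are fixed
point bands:

    >= 10  pathogenic
    6..9   likely pathogenic
    0..5   VUS
    -6..-1 likely benign
    <= -7  benign

Reclassification adds the functional code matching the assay outcome (PS3
for an aberrant or partially aberrant result, BS3 for no effect) and applies
only removals the caller names explicitly — no removal policy is inferred.
An optional ``consistency`` mode additionally drops PP3 (computational
splice support) whenever BS3 is added, since the two contradict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

VALID_CODES = (
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
    | {"BA1"}
    | {f"BS{i}" for i in range(1, 5)}
    | {f"BP{i}" for i in range(1, 8)}
)

STRENGTHS = ("very_strong", "strong", "moderate", "supporting")

_STRENGTH_POINTS = {"supporting": 1, "moderate": 2, "strong": 4, "very_strong": 8}

CLASS_PATHOGENIC = "pathogenic"
CLASS_LIKELY_PATHOGENIC = "likely_pathogenic"
CLASS_VUS = "vus"
CLASS_LIKELY_BENIGN = "likely_benign"
CLASS_BENIGN = "benign"

OUTCOME_ABERRANT = "aberrant"
OUTCOME_PARTIAL = "partial_aberrant"
OUTCOME_NO_EFFECT = "no_effect"


class EvidenceError(ValueError):
    """Invalid evidence code, strength or combination."""


def _intrinsic_strength(code: str) -> str:
    prefix = code[:2] if code[:2] in ("PV", "PS", "PM", "PP", "BA", "BS", "BP") else code
    return {
        "PV": "very_strong",
        "PS": "strong",
        "PM": "moderate",
        "PP": "supporting",
        "BA": "very_strong",  # stand-alone treated as very strong for points
        "BS": "strong",
        "BP": "supporting",
    }[prefix]


def _is_benign(code: str) -> bool:
    return code.startswith("B")


@dataclass(frozen=True)
class EvidenceItem:
    """One ACMG code, possibly applied at a lowered strength."""

    code: str
    strength: Optional[str] = None  # None = the code's intrinsic strength

    def __post_init__(self) -> None:
        if self.code not in VALID_CODES:
            raise EvidenceError(f"unknown ACMG code {self.code!r}")
        if self.strength is None:
            object.__setattr__(self, "strength", _intrinsic_strength(self.code))
        elif self.strength not in STRENGTHS:
            raise EvidenceError(f"unknown strength {self.strength!r}")

    @property
    def label(self) -> str:
        """Code string with a ``_P`` suffix when applied below intrinsic strength."""
        if self.strength == _intrinsic_strength(self.code):
            return self.code
        if self.strength == "supporting":
            return f"{self.code}_P"
        raise EvidenceError(
            f"{self.code} at non-standard strength {self.strength} has no printable label"
        )


def parse_evidence_item(token: str) -> EvidenceItem:
    """Parse 'PM2', 'PM2_P' or 'PM2_Supporting'."""
    token = token.strip()
    if not token:
        raise EvidenceError("empty evidence token")
    code, _, suffix = token.partition("_")
    if suffix == "":
        return EvidenceItem(code=code)
    if suffix.casefold() in ("p", "supporting"):
        return EvidenceItem(code=code, strength="supporting")
    raise EvidenceError(f"unknown strength suffix {suffix!r} in {token!r}")


def item_points(item: EvidenceItem) -> int:
    """Signed point value: +-1/2/4/8 by strength, negative for benign codes."""
    pts = _STRENGTH_POINTS[item.strength]  # type: ignore[index]
    return -pts if _is_benign(item.code) else pts


def classification_for_points(points: int) -> str:
    if points >= 10:
        return CLASS_PATHOGENIC
    if points >= 6:
        return CLASS_LIKELY_PATHOGENIC
    if points >= 0:
        return CLASS_VUS
    if points >= -6:
        return CLASS_LIKELY_BENIGN
    return CLASS_BENIGN


@dataclass(frozen=True)
class EvidenceSet:
    """A combination of evidence items with derived point total and tier."""

    items: tuple[EvidenceItem, ...]

    def __post_init__(self) -> None:
        codes = [i.code for i in self.items]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise EvidenceError(f"duplicate evidence codes: {sorted(dupes)}")

    @property
    def points(self) -> int:
        return sum(item_points(i) for i in self.items)

    @property
    def classification(self) -> str:
        return classification_for_points(self.points)

    @property
    def label(self) -> str:
        return "+".join(i.label for i in self.items) if self.items else ""

    def has(self, code: str) -> bool:
        return any(i.code == code for i in self.items)


def combine(items: Iterable[EvidenceItem]) -> EvidenceSet:
    """Combine evidence items; order never affects points or tier."""
    return EvidenceSet(items=tuple(items))


def parse_evidence_string(text: str) -> EvidenceSet:
    """Parse 'PM2_P+PP3+PP4' (the Table-style grammar); '' is the empty set."""
    text = text.strip()
    if not text:
        return EvidenceSet(items=())
    return combine(parse_evidence_item(tok) for tok in text.split("+") if tok.strip())


# ---------------------------------------------------------------------------
# Functional reclassification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FunctionalResult:
    """A minigene / patient-RNA assay outcome feeding PS3 or BS3."""

    outcome: str  # aberrant | partial_aberrant | no_effect
    source: str = "minigene"  # minigene | patient_rna | both

    def __post_init__(self) -> None:
        if self.outcome not in (OUTCOME_ABERRANT, OUTCOME_PARTIAL, OUTCOME_NO_EFFECT):
            raise EvidenceError(f"unknown functional outcome {self.outcome!r}")
        if self.source not in ("minigene", "patient_rna", "both"):
            raise EvidenceError(f"unknown functional source {self.source!r}")

    @property
    def functional_code(self) -> str:
        return "BS3" if self.outcome == OUTCOME_NO_EFFECT else "PS3"


@dataclass(frozen=True)
class ReclassificationResult:
    evidence: EvidenceSet
    audit: tuple[str, ...]


def reclassify(
    original: EvidenceSet,
    functional: FunctionalResult,
    removals: Sequence[str] = (),
    mode: str = "literal",
) -> ReclassificationResult:
    """Fold a functional assay result into an evidence set.

    Adds PS3 (aberrant / partially aberrant splicing, applied at full
    strong strength in both cases) or BS3 (no effect), removes exactly the
    caller-named codes, and records every edit in an audit trail.  In
    ``consistency`` mode, PP3 is additionally dropped whenever BS3 is
    added, so computational splice support never coexists with a negative
    functional result.
    """
    if mode not in ("literal", "consistency"):
        raise EvidenceError(f"unknown reclassification mode {mode!r}")
    add_code = functional.functional_code
    if original.has(add_code):
        raise EvidenceError(f"{add_code} already present in the original evidence set")
    if add_code == "PS3" and original.has("BS3") or add_code == "BS3" and original.has("PS3"):
        raise EvidenceError("PS3 and BS3 cannot coexist in one evidence set")

    audit: list[str] = []
    removal_set = list(dict.fromkeys(removals))
    for code in removal_set:
        if not original.has(code) and not any(i.label == code for i in original.items):
            raise EvidenceError(f"cannot remove {code}: not in the original set")
    if mode == "consistency" and add_code == "BS3" and original.has("PP3") and \
            "PP3" not in removal_set:
        removal_set.append("PP3")
        audit.append("removed PP3: computational splice support contradicts BS3 "
                     "(consistency mode)")

    kept = []
    for item in original.items:
        if item.code in removal_set or item.label in removal_set:
            if not any(a.startswith(f"removed {item.code}") for a in audit):
                audit.append(f"removed {item.label}: caller-specified removal")
            continue
        kept.append(item)
    kept.append(EvidenceItem(code=add_code))
    audit.append(
        f"added {add_code}: {functional.source} assay outcome '{functional.outcome}'"
    )
    new_set = combine(kept)
    audit.append(
        f"points {original.points} -> {new_set.points}; "
        f"{original.classification} -> {new_set.classification}"
    )
    return ReclassificationResult(evidence=new_set, audit=tuple(audit))


# ---------------------------------------------------------------------------
# Cohort classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortRow:
    variant: str
    original: EvidenceSet
    functional: Optional[FunctionalResult]
    removals: tuple[str, ...] = ()


@dataclass(frozen=True)
class CohortClassification:
    per_variant: tuple[tuple[str, EvidenceSet, EvidenceSet | None, tuple[str, ...]], ...]
    counts: dict[str, int]

    def to_json(self) -> str:
        payload = {
            "counts": self.counts,
            "variants": [
                {
                    "variant": v,
                    "original": {"evidence": orig.label, "points": orig.points,
                                 "classification": orig.classification},
                    "reclassified": None if new is None else {
                        "evidence": new.label, "points": new.points,
                        "classification": new.classification,
                    },
                    "audit": list(audit),
                }
                for v, orig, new, audit in self.per_variant
            ],
        }
        return json.dumps(payload, indent=2)


def classify_cohort(rows: Sequence[CohortRow], mode: str = "literal") -> CohortClassification:
    """(Re)classify every variant; counts are over the final classification."""
    per_variant = []
    counts = {
        CLASS_PATHOGENIC: 0,
        CLASS_LIKELY_PATHOGENIC: 0,
        CLASS_VUS: 0,
        CLASS_LIKELY_BENIGN: 0,
        CLASS_BENIGN: 0,
    }
    for row in rows:
        if row.functional is None:
            per_variant.append((row.variant, row.original, None, ()))
            counts[row.original.classification] += 1
            continue
        result = reclassify(row.original, row.functional, row.removals, mode=mode)
        per_variant.append((row.variant, row.original, result.evidence, result.audit))
        counts[result.evidence.classification] += 1
    return CohortClassification(per_variant=tuple(per_variant), counts=counts)
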