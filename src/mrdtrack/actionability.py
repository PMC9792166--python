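"""Drug-actionability classification against an editable rule table.

Variants are matched to OncoKB-style evidence rules: each rule names a
gene, a match mode (exact protein change, codon set, or any
non-synonymous mutation), a drug, a direction (sensitivity or
resistance) and an evidence level (L1 FDA-approved, L3 clinical
evidence, L4 laboratory evidence, R1 resistance to an approved drug).

A default colorectal-cancer rule table ships with the package
(``mrdtrack/data/actionability_rules.tsv``); rows whose drug name is
marked as a synthetic placeholder stand in for supplementary
laboratory-evidence listings that are not public.  Users supply their
own table for anything serious.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variant_io import Consequence, SomaticVariant, parse_protein_change

__all__ = [
    "MatchMode",
    "Direction",
    "EvidenceLevel",
    "ActionabilityRule",
    "ActionabilityReport",
    "load_rules",
    "classify_patient",
    "cohort_actionability",
]


class MatchMode(str, enum.Enum):
    EXACT_PROTEIN_CHANGE = "exact_protein_change"
    CODON_SET = "codon_set"
    ANY_NONSYNONYMOUS = "any_nonsynonymous"


class Direction(str, enum.Enum):
    SENSITIVITY = "sensitivity"
    RESISTANCE = "resistance"


class EvidenceLevel(str, enum.Enum):
    L1 = "L1"
    L3 = "L3"
    L4 = "L4"
    R1 = "R1"


@dataclass(frozen=True)
class ActionabilityRule:
    gene: str
    match: MatchMode
    codons_or_changes: frozenset[str]
    drug: str
    direction: Direction
    level: EvidenceLevel

    def __post_init__(self) -> None:
        if self.match is not MatchMode.ANY_NONSYNONYMOUS and not self.codons_or_changes:
            raise ValueError(
                f"rule {self.gene}/{self.drug}: {self.match.value} "
                "requires a non-empty target set"
            )

    def matches(self, variant: SomaticVariant) -> bool:
        if variant.gene != self.gene:
            return False
        if self.match is MatchMode.ANY_NONSYNONYMOUS:
            return variant.consequence is not Consequence.SYNONYMOUS
        if variant.protein_change is None:
            return False
        try:
            ref_aa, residue, suffix = parse_protein_change(variant.protein_change)
        except ValueError:
            return False
        if self.match is MatchMode.EXACT_PROTEIN_CHANGE:
            normalized = f"{ref_aa}{residue}{suffix}"
            return normalized in self.codons_or_changes
        # codon match: reference amino acid + residue number only, so
        # G12D and G12V both satisfy codon "G12"
        return f"{ref_aa}{residue}" in self.codons_or_changes


@dataclass(frozen=True)
class ActionabilityReport:
    """Per-patient hits plus OR-ed summary flags per (level, direction)."""

    patient_id: str
    hits: tuple[tuple[SomaticVariant, ActionabilityRule], ...]
    summary: dict[tuple[EvidenceLevel, Direction], bool]

    def __post_init__(self) -> None:
        for variant, _ in self.hits:
            if variant.patient_id != self.patient_id:
                raise ValueError(
                    f"hit variant belongs to {variant.patient_id}, "
                    f"not {self.patient_id}"
                )

    def has(self, level: EvidenceLevel, direction: Direction) -> bool:
        return self.summary.get((level, direction), False)


def load_rules(path: str | Path | None = None) -> list[ActionabilityRule]:
    """Load a rule table; with no path, the bundled default CRC table."""
    if path is None:
        source = resources.files("mrdtrack.data") / "actionability_rules.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "match_mode", "targets", "drug", "direction", "level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rule table missing columns: {sorted(missing)}")
    rules = []
    for i, row in enumerate(df.to_dict("records")):
        targets = row["targets"]
        target_set = (
            frozenset()
            if pd.isna(targets) or str(targets).strip() in ("", "-")
            else frozenset(t.strip() for t in str(targets).split(",") if t.strip())
        )
        try:
            rules.append(
                ActionabilityRule(
                    gene=str(row["gene"]),
                    match=MatchMode(str(row["match_mode"])),
                    codons_or_changes=target_set,
                    drug=str(row["drug"]),
                    direction=Direction(str(row["direction"])),
                    level=EvidenceLevel(str(row["level"])),
                )
            )
        except ValueError as exc:
            raise ValueError(f"rule table row {i + 1}: {exc}") from None
    return rules


def classify_patient(
    variants: Sequence[SomaticVariant],
    rules: Sequence[ActionabilityRule],
    patient_id: str | None = None,
) -> ActionabilityReport:
    """Record a hit for every (variant, rule) pair that matches."""
    if patient_id is None:
        patient_id = variants[0].patient_id if variants else ""
    hits = tuple(
        (v, r) for v in variants for r in rules if r.matches(v)
    )
    summary: dict[tuple[EvidenceLevel, Direction], bool] = {}
    for _, rule in hits:
        summary[(rule.level, rule.direction)] = True
    return ActionabilityReport(patient_id=patient_id, hits=hits, summary=summary)


def cohort_actionability(
    cohort: Mapping[str, Sequence[SomaticVariant]],
    rules: Sequence[ActionabilityRule],
) -> dict[tuple[str, str], float]:
    """Fraction of patients with >= 1 hit per (level, direction).

    Keys are ``(level, direction)`` value strings plus ``("any",
    direction)`` aggregates; a patient counts once per category
    regardless of hit count.
    """
    if not cohort:
        raise ValueError("empty cohort")
    n = len(cohort)
    counts: dict[tuple[str, str], int] = {}
    for pid in sorted(cohort):
        report = classify_patient(cohort[pid], rules, patient_id=pid)
        seen: set[tuple[str, str]] = set()
        for (level, direction) in report.summary:
            seen.add((level.value, direction.value))
            seen.add(("any", direction.value))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    return {key: c / n for key, c in sorted(counts.items())}


def report_to_frame(report: ActionabilityReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": report.patient_id,
                "gene": v.gene,
                "protein_change": v.protein_change or "",
                "drug": r.drug,
                "direction": r.direction.value,
                "level": r.level.value,
            }
            for v, r in report.hits
        ]
    )
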