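"""Tracking-mutation scoring and per-patient panel selection.

Each patient's non-synonymous somatic mutations are ranked by a
five-criterion score and the top mutations become the personalized
plasma tracking panel (default 5 per patient, bounded to 2-10).

The five criteria:

1. FFPE VAF — higher tumor-tissue allele fraction means more tumor
   DNA carrying the mutation, hence better plasma detectability.
2. Annotated pathogenic (ClinVar) or predicted deleterious
   (SIFT/PolyPhen-style), taken as an OR of the two evidence flags.
3. Stop-gained (nonsense) mutation in a tumor-suppressor gene.
4. Mutation in an oncogene recurrently reported in COSMIC
   (strictly more than 3 records).
5. Previously validated as tumor-derived in an in-house database.

Criteria 2-5 are booleans; the score is the count of satisfied boolean
criteria plus the FFPE VAF as a strictly subordinate fractional term,
so the criterion count dominates and VAF ranks within a tier.
Mutations in low-complexity regions are excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .variant_io import Consequence, GeneRole, SomaticVariant

__all__ = [
    "VariantScore",
    "TrackingPanel",
    "score_variant",
    "select_panel",
    "build_panel",
    "plasma_detectability_flag",
    "PANEL_SIZE_DEFAULT",
    "PANEL_SIZE_MIN",
    "PANEL_SIZE_MAX",
    "COSMIC_RECURRENCE_MIN",
]

PANEL_SIZE_DEFAULT = 5
PANEL_SIZE_MIN = 2
PANEL_SIZE_MAX = 10
#: an oncogene mutation counts as recurrent when COSMIC reports it
#: strictly more than this many times
COSMIC_RECURRENCE_MIN = 3

#: FFPE VAF at/above which plasma detection is empirically much more likely
DETECTABILITY_VAF_THRESHOLD = 0.10


@dataclass(frozen=True)
class VariantScore:
    """A scored tracking candidate.

    ``rank`` is assigned by :func:`select_panel` (1 = best) and is
    ``None`` on a freshly scored variant.
    """

    variant: SomaticVariant
    pathogenic_deleterious: bool
    stopgain_in_tsg: bool
    recurrent_oncogene: bool
    in_house_validated: bool
    score: float
    rank: int | None = None

    @property
    def criterion_flags(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.pathogenic_deleterious,
            self.stopgain_in_tsg,
            self.recurrent_oncogene,
            self.in_house_validated,
        )


@dataclass(frozen=True)
class TrackingPanel:
    """Ranked per-patient subset of mutations selected for plasma tracking."""

    patient_id: str
    members: tuple[VariantScore, ...]
    n_requested: int = PANEL_SIZE_DEFAULT
    below_minimum: bool = False

    def __post_init__(self) -> None:
        scores = [m.score for m in self.members]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("panel members must be sorted by score descending")
        if any(m.variant.in_low_complexity for m in self.members):
            raise ValueError("low-complexity variants are not trackable")

    @property
    def variant_keys(self) -> set[tuple[str, int, str, str]]:
        return {m.variant.key for m in self.members}


def score_variant(v: SomaticVariant) -> VariantScore:
    """Score a single non-synonymous variant.

    Raises ``ValueError`` for synonymous input: silent mutations carry
    no tumor-biology evidence and are ineligible for tracking.
    """
    if v.consequence is Consequence.SYNONYMOUS:
        raise ValueError(
            f"synonymous variant {v.gene} {v.chrom}:{v.pos} is not trackable"
        )
    pathogenic_deleterious = v.clinvar_pathogenic or v.predicted_deleterious
    stopgain_in_tsg = (
        v.consequence is Consequence.NONSENSE
        and v.gene_role is GeneRole.TUMOR_SUPPRESSOR
    )
    recurrent_oncogene = (
        v.gene_role is GeneRole.ONCOGENE
        and v.cosmic_count > COSMIC_RECURRENCE_MIN
    )
    n_flags = (
        int(pathogenic_deleterious)
        + int(stopgain_in_tsg)
        + int(recurrent_oncogene)
        + int(v.in_house_validated)
    )
    return VariantScore(
        variant=v,
        pathogenic_deleterious=pathogenic_deleterious,
        stopgain_in_tsg=stopgain_in_tsg,
        recurrent_oncogene=recurrent_oncogene,
        in_house_validated=v.in_house_validated,
        score=n_flags + v.ffpe_vaf,
    )


def _chrom_key(chrom: str) -> tuple[int, int, str]:
    """Sort chromosomes numerically where possible (1..22 < X < Y < other)."""
    c = chrom.lower().removeprefix("chr")
    if c.isdigit():
        return (0, int(c), "")
    if c in ("x", "y", "m", "mt"):
        return (0, {"x": 23, "y": 24, "m": 25, "mt": 25}[c], "")
    return (1, 0, c)


def selection_key(s: VariantScore) -> tuple:
    """Total order used for panel selection (best first when sorted).

    Score descending, ties broken by FFPE VAF descending, then by
    genomic coordinate ascending, then by the remaining variant fields
    — a total order over value-distinct variants, so selection is
    deterministic and invariant to input permutation.
    """
    v = s.variant
    return (
        -s.score,
        -v.ffpe_vaf,
        _chrom_key(v.chrom),
        v.pos,
        v.ref,
        v.alt,
        v.gene,
        v.consequence.value,
        v.protein_change or "",
        v.cosmic_count,
        v.clinvar_pathogenic,
        v.predicted_deleterious,
        v.gene_role.value,
        v.in_house_validated,
    )


def select_panel(
    scored: Sequence[VariantScore], n: int = PANEL_SIZE_DEFAULT
) -> TrackingPanel:
    """Select the tracking panel from scored candidates.

    Low-complexity variants are removed first (assay exclusion
    criterion).  ``n`` is clamped to [2, 10]; the panel holds
    ``min(n, available)`` members.  With fewer than two eligible
    variants the panel is still emitted, flagged ``below_minimum``.
    Zero eligible variants is an error.
    """
    eligible = [s for s in scored if not s.variant.in_low_complexity]
    if not eligible:
        raise ValueError("no trackable mutations")
    n = max(PANEL_SIZE_MIN, min(PANEL_SIZE_MAX, int(n)))
    ordered = sorted(eligible, key=selection_key)
    chosen = [
        replace(s, rank=i + 1) for i, s in enumerate(ordered[: min(n, len(ordered))])
    ]
    return TrackingPanel(
        patient_id=chosen[0].variant.patient_id,
        members=tuple(chosen),
        n_requested=n,
        below_minimum=len(chosen) < PANEL_SIZE_MIN,
    )


def build_panel(
    variants: Sequence[SomaticVariant], n: int = PANEL_SIZE_DEFAULT
) -> TrackingPanel:
    """Convenience: score all eligible variants of one patient and select.

    Synonymous variants are silently skipped (they are ineligible, not
    an input error at this level).
    """
    scored = [
        score_variant(v)
        for v in variants
        if v.consequence is not Consequence.SYNONYMOUS
    ]
    return select_panel(scored, n=n)


def plasma_detectability_flag(
    v: SomaticVariant, threshold: float = DETECTABILITY_VAF_THRESHOLD
) -> bool:
    """Advisory flag: FFPE VAF at/above the plasma-detectability threshold.

    Mutations below ~10% FFPE VAF have a markedly lower plasma
    detection rate; the flag is metadata on panel members and never an
    exclusion.
    """
    return v.ffpe_vaf >= threshold
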