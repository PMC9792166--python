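"""Cohort-level mutational-spectrum summaries.

Per-gene patient frequencies, mutation-class distribution, pairwise
co-occurrence / mutual-exclusivity testing and hotspot summaries over
a cohort of tumor profiles.  A cohort is a mapping
``patient_id -> list[SomaticVariant]``.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import Consequence, SomaticVariant, parse_protein_change

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSummary",
    "GenePairStat",
    "InteractionLabel",
    "summarize_cohort",
    "pairwise_interaction",
    "hotspot_fraction",
]


@dataclass(frozen=True)
class CohortSummary:
    """Cohort spectrum summary.

    ``per_gene_frequency`` counts a gene once per patient (fraction of
    patients with at least one mutation in the gene);
    ``class_distribution`` pools all mutations.
    """

    n_patients: int
    per_gene_frequency: dict[str, float]
    class_distribution: dict[Consequence, float]
    mutations_per_patient: list[int]

    def __post_init__(self) -> None:
        if self.class_distribution:
            total = sum(self.class_distribution.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"class distribution sums to {total}, not 1")
        if any(not 0 <= f <= 1 for f in self.per_gene_frequency.values()):
            raise ValueError("per-gene frequencies must be in [0, 1]")
        if len(self.mutations_per_patient) != self.n_patients:
            raise ValueError("mutations_per_patient length != n_patients")

    @property
    def mean_mutations_per_patient(self) -> float:
        return float(np.mean(self.mutations_per_patient))


class InteractionLabel(str, enum.Enum):
    CO_OCCURRING = "co_occurring"
    MUTUALLY_EXCLUSIVE = "mutually_exclusive"
    NONE = "none"


@dataclass(frozen=True)
class GenePairStat:
    """Pairwise patient-level association between two mutated genes.

    ``counts`` is the 2x2 contingency ``(both, a_only, b_only,
    neither)`` over patients; the odds ratio is the conditional
    maximum-likelihood estimate (0 and inf permitted at zero cells).
    """

    gene_a: str
    gene_b: str
    counts: tuple[int, int, int, int]
    odds_ratio: float
    p_value: float
    label: InteractionLabel

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of range: {self.p_value}")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative contingency cell")


def summarize_cohort(
    cohort: Mapping[str, Sequence[SomaticVariant]],
) -> CohortSummary:
    """Summarize gene frequencies, class mix and per-patient burden."""
    if not cohort:
        raise ValueError("empty cohort")
    patients = sorted(cohort)
    gene_patients: Counter[str] = Counter()
    class_counts: Counter[Consequence] = Counter()
    burden = []
    for pid in patients:
        variants = cohort[pid]
        burden.append(len(variants))
        for gene in {v.gene for v in variants}:
            gene_patients[gene] += 1
        for v in variants:
            class_counts[v.consequence] += 1
    n = len(patients)
    total = sum(class_counts.values())
    return CohortSummary(
        n_patients=n,
        per_gene_frequency={g: c / n for g, c in gene_patients.items()},
        class_distribution=(
            {c: k / total for c, k in class_counts.items()} if total else {}
        ),
        mutations_per_patient=burden,
    )


def _pair_table(
    cohort: Mapping[str, Sequence[SomaticVariant]], gene_a: str, gene_b: str
) -> tuple[int, int, int, int]:
    both = a_only = b_only = neither = 0
    for variants in cohort.values():
        genes = {v.gene for v in variants}
        a, b = gene_a in genes, gene_b in genes
        if a and b:
            both += 1
        elif a:
            a_only += 1
        elif b:
            b_only += 1
        else:
            neither += 1
    return both, a_only, b_only, neither


def _conditional_odds_ratio(table: np.ndarray) -> float:
    """Conditional-MLE odds ratio; 0/inf at zero cells, nan if degenerate."""
    row, col = table.sum(axis=1), table.sum(axis=0)
    if 0 in row or 0 in col:
        return float("nan")
    return float(stats.contingency.odds_ratio(table, kind="conditional").statistic)


def pairwise_interaction(
    cohort: Mapping[str, Sequence[SomaticVariant]],
    genes: Sequence[str],
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[GenePairStat]:
    """Test every unordered gene pair for co-occurrence / exclusivity.

    For each pair the patient-level mutated/not-mutated 2x2 table is
    tested with the two-sided Fisher exact test.  A pair is labelled
    ``co_occurring`` when p < alpha and OR > 1, ``mutually_exclusive``
    when p < alpha and OR < 1, else ``none``.

    ``correction="bh"`` applies Benjamini-Hochberg across all pairs
    before labelling; the default applies none.
    """
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    mutated = {g for variants in cohort.values() for v in variants for g in [v.gene]}
    usable = []
    for g in genes:
        if g in mutated:
            usable.append(g)
        else:
            logger.warning("gene %s not mutated in cohort; excluded", g)
    pairs = [
        (usable[i], usable[j])
        for i in range(len(usable))
        for j in range(i + 1, len(usable))
    ]
    raw: list[tuple[str, str, tuple[int, int, int, int], float, float]] = []
    for ga, gb in pairs:
        counts = _pair_table(cohort, ga, gb)
        table = np.array(
            [[counts[0], counts[1]], [counts[2], counts[3]]], dtype=int
        )
        _, p = stats.fisher_exact(table, alternative="two-sided")
        oddsr = _conditional_odds_ratio(table)
        raw.append((ga, gb, counts, oddsr, float(p)))

    pvals = np.array([r[4] for r in raw])
    if correction == "bh" and len(pvals):
        adjusted = stats.false_discovery_control(pvals, method="bh")
    elif correction is None:
        adjusted = pvals
    else:
        raise ValueError(f"unknown correction {correction!r}")

    out = []
    for (ga, gb, counts, oddsr, p), p_adj in zip(raw, adjusted):
        if p_adj < alpha and not np.isnan(oddsr) and oddsr > 1:
            label = InteractionLabel.CO_OCCURRING
        elif p_adj < alpha and not np.isnan(oddsr) and oddsr < 1:
            label = InteractionLabel.MUTUALLY_EXCLUSIVE
        else:
            label = InteractionLabel.NONE
        out.append(
            GenePairStat(
                gene_a=ga,
                gene_b=gb,
                counts=counts,
                odds_ratio=oddsr,
                p_value=float(p_adj),
                label=label,
            )
        )
    return out


def hotspot_fraction(
    cohort: Mapping[str, Sequence[SomaticVariant]],
    gene: str,
    residues: Collection[int],
) -> float:
    """Fraction of gene-mutated patients hit at any of the given residues.

    Residues are protein positions (e.g. ``{12, 13}`` for the KRAS
    G12/G13 hotspot); a patient counts when any mutation in ``gene``
    has a parseable protein change at one of them.
    """
    residues = set(residues)
    carriers = 0
    hot = 0
    for variants in cohort.values():
        in_gene = [v for v in variants if v.gene == gene]
        if not in_gene:
            continue
        carriers += 1
        for v in in_gene:
            if v.protein_change is None:
                continue
            try:
                _, pos, _ = parse_protein_change(v.protein_change)
            except ValueError:
                continue
            if pos in residues:
                hot += 1
                break
    if carriers == 0:
        raise ValueError(f"gene {gene} is not mutated in the cohort")
    return hot / carriers


# ---------------------------------------------------------------------------
# TSV export helpers


def summary_tables(summary: CohortSummary) -> dict[str, pd.DataFrame]:
    """Render a CohortSummary as plot-ready TSV-shaped tables."""
    gene_df = pd.DataFrame(
        sorted(
            summary.per_gene_frequency.items(), key=lambda kv: (-kv[1], kv[0])
        ),
        columns=["gene", "patient_frequency"],
    )
    class_df = pd.DataFrame(
        [(c.value, f) for c, f in sorted(summary.class_distribution.items(),
                                         key=lambda kv: -kv[1])],
        columns=["consequence", "fraction"],
    )
    return {"gene_frequency": gene_df, "class_distribution": class_df}


def interactions_to_frame(pairs: Sequence[GenePairStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "both": p.counts[0],
                "a_only": p.counts[1],
                "b_only": p.counts[2],
                "neither": p.counts[3],
                "odds_ratio": p.odds_ratio,
                "p_value": p.p_value,
                "label": p.label.value,
            }
            for p in pairs
        ]
    )
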