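"""Plasma MRD calling: amplicon QC, LOD calibration, ctDNA positivity.

The plasma side of the assay sequences each tracked mutation site to
~100,000X by multiplex amplicon sequencing.  This module:

* fails amplicons under 10,000X coverage (``qc_amplicons``),
* calibrates a detection limit (LOD) from a titration series and a
  healthy-donor panel such that the healthy-panel false-positive rate
  stays below a maximum (``calibrate_lod``),
* calls a sample ctDNA-positive when at least one QC-passing tracked
  mutation reaches VAF >= LOD, with the two-branch mean-VAF rule:
  mean over positive mutations when any exist, otherwise mean over
  all retained tracked mutations (``call_sample``).

A sample whose amplicons all fail QC is *indeterminate*, never
silently negative.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AmpliconMeasurement",
    "LODCalibration",
    "CallStatus",
    "CtdnaCall",
    "MIN_AMPLICON_DEPTH",
    "DEFAULT_LOD",
    "compute_vaf",
    "qc_amplicons",
    "calibrate_lod",
    "sample_level_fp_rate",
    "call_sample",
    "cfdna_input_check",
    "read_plasma_table",
    "measurements_to_frame",
]

#: amplicons below this coverage are failed and excluded downstream
MIN_AMPLICON_DEPTH = 10_000
#: assay detection limit: 0.05% VAF
DEFAULT_LOD = 5e-4


def compute_vaf(alt_reads: int, depth: int) -> float:
    """Allele fraction ``alt_reads / depth``; undefined at zero depth."""
    if depth <= 0:
        raise ValueError("VAF undefined at zero depth")
    if not 0 <= alt_reads <= depth:
        raise ValueError(f"alt_reads {alt_reads} outside [0, depth={depth}]")
    return alt_reads / depth


@dataclass(frozen=True)
class AmpliconMeasurement:
    """One tracked mutation in one plasma sample."""

    patient_id: str
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_reads < 0:
            raise ValueError("depth and alt_reads must be non-negative")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} exceeds depth {self.depth}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def qc_pass(self) -> bool:
        return self.depth >= MIN_AMPLICON_DEPTH

    @property
    def vaf(self) -> float:
        return 0.0 if self.depth == 0 else self.alt_reads / self.depth


def qc_amplicons(
    measurements: Sequence[AmpliconMeasurement],
    min_depth: int = MIN_AMPLICON_DEPTH,
) -> tuple[list[AmpliconMeasurement], list[AmpliconMeasurement]]:
    """Split measurements into (retained, failed) by the depth gate.

    The boundary is inclusive: exactly ``min_depth`` passes ("less
    than 10,000X" fails).
    """
    retained = [m for m in measurements if m.depth >= min_depth]
    failed = [m for m in measurements if m.depth < min_depth]
    return retained, failed


@dataclass(frozen=True)
class LODCalibration:
    """Result of detection-limit calibration.

    ``fp_table`` maps every candidate threshold to its per-measurement
    healthy-panel false-positive rate; ``chosen_lod`` is the smallest
    candidate whose rate is below ``fp_max``.
    """

    candidate_thresholds: tuple[float, ...]
    chosen_lod: float
    fp_rate_at_lod: float
    fp_max: float
    fp_table: dict[float, float]
    per_level_detection: dict[float, float]

    def __post_init__(self) -> None:
        if self.chosen_lod not in self.candidate_thresholds:
            raise ValueError("chosen LOD must be one of the candidates")
        if not self.fp_rate_at_lod < self.fp_max:
            raise ValueError("FP rate at chosen LOD must be below fp_max")


def calibrate_lod(
    titration: Mapping[float, Sequence[float]],
    healthy_vafs: Sequence[float],
    candidates: Sequence[float],
    fp_max: float = 0.01,
) -> LODCalibration:
    """Choose the LOD from healthy-panel false-positive behaviour.

    Parameters
    ----------
    titration
        Map titration level (expected VAF) -> observed VAFs; used to
        report per-level detection at the chosen LOD.
    healthy_vafs
        Observed VAFs of every tracked-site measurement across the
        healthy-donor panel (per-measurement false-positive basis).
    candidates
        Candidate thresholds, sorted ascending.
    fp_max
        Maximum tolerated per-measurement false-positive rate.

    The chosen LOD is the smallest candidate ``t`` with
    ``fp_rate(t) = mean(healthy >= t) < fp_max``; if none qualifies
    the full FP table is raised in the error.
    """
    candidates = [float(c) for c in candidates]
    if candidates != sorted(candidates):
        raise ValueError("candidates must be sorted ascending")
    healthy = np.asarray(healthy_vafs, dtype=float)
    if healthy.size == 0:
        raise ValueError("healthy panel must be non-empty")
    fp_table = {t: float(np.mean(healthy >= t)) for t in candidates}
    chosen = next((t for t in candidates if fp_table[t] < fp_max), None)
    if chosen is None:
        raise ValueError(
            f"no candidate keeps the false-positive rate below {fp_max}; "
            f"fp_table={fp_table}"
        )
    per_level = {
        float(level): (
            float(np.mean(np.asarray(obs, dtype=float) >= chosen))
            if len(obs)
            else float("nan")
        )
        for level, obs in titration.items()
    }
    return LODCalibration(
        candidate_thresholds=tuple(candidates),
        chosen_lod=chosen,
        fp_rate_at_lod=fp_table[chosen],
        fp_max=fp_max,
        fp_table=fp_table,
        per_level_detection=per_level,
    )


def sample_level_fp_rate(
    healthy_samples: Iterable[Sequence[float]], threshold: float
) -> float:
    """Fraction of healthy samples with any tracked site >= threshold.

    Companion to the per-measurement rate used for calibration: a
    sample-level false positive is a healthy sample that would be
    called ctDNA-positive.
    """
    samples = [np.asarray(s, dtype=float) for s in healthy_samples]
    if not samples:
        raise ValueError("no healthy samples")
    return float(np.mean([bool(np.any(s >= threshold)) for s in samples]))


class CallStatus(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class CtdnaCall:
    """Per-sample ctDNA positivity verdict."""

    sample_id: str
    status: CallStatus
    tracked: tuple[AmpliconMeasurement, ...]
    positive_mutations: tuple[AmpliconMeasurement, ...]
    mean_vaf: float | None
    n_failed_amplicons: int
    lod: float

    @property
    def positive(self) -> bool:
        return self.status is CallStatus.POSITIVE


def call_sample(
    measurements: Sequence[AmpliconMeasurement],
    lod: float = DEFAULT_LOD,
    min_depth: int = MIN_AMPLICON_DEPTH,
) -> CtdnaCall:
    """Call one plasma sample.

    Positivity: any QC-retained tracked mutation with VAF >= LOD
    (inclusive).  Mean VAF: mean of positive mutations when positive,
    else mean of all retained tracked mutations.  All amplicons
    failing QC yields an indeterminate call with ``mean_vaf=None``.
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    sample_ids = {m.sample_id for m in measurements}
    if len(sample_ids) != 1:
        raise ValueError(f"measurements from multiple samples: {sample_ids}")
    retained, failed = qc_amplicons(measurements, min_depth=min_depth)
    sample_id = measurements[0].sample_id
    if not retained:
        return CtdnaCall(
            sample_id=sample_id,
            status=CallStatus.INDETERMINATE,
            tracked=tuple(measurements),
            positive_mutations=(),
            mean_vaf=None,
            n_failed_amplicons=len(failed),
            lod=lod,
        )
    positives = tuple(m for m in retained if m.vaf >= lod)
    if positives:
        mean_vaf = float(np.mean([m.vaf for m in positives]))
        status = CallStatus.POSITIVE
    else:
        mean_vaf = float(np.mean([m.vaf for m in retained]))
        status = CallStatus.NEGATIVE
    return CtdnaCall(
        sample_id=sample_id,
        status=status,
        tracked=tuple(measurements),
        positive_mutations=positives,
        mean_vaf=mean_vaf,
        n_failed_amplicons=len(failed),
        lod=lod,
    )


def cfdna_input_check(concentration_ng_per_ul: float, total_ng: float) -> bool:
    """cfDNA input sufficiency: >= 0.1 ng/uL concentration OR >= 3 ng total."""
    if concentration_ng_per_ul < 0 or total_ng < 0:
        raise ValueError("cfDNA quantities must be non-negative")
    return concentration_ng_per_ul >= 0.1 or total_ng >= 3.0


# ---------------------------------------------------------------------------
# table I/O

_PLASMA_COLUMNS = (
    "sample_id",
    "patient_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_reads",
)


def read_plasma_table(path: str | Path) -> list[AmpliconMeasurement]:
    """Read a plasma read-count TSV (one row per tracked site per sample)."""
    df = pd.read_csv(path, sep="\t", dtype="object", comment="#")
    missing = [c for c in _PLASMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            out.append(
                AmpliconMeasurement(
                    patient_id=str(row["patient_id"]),
                    sample_id=str(row["sample_id"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    depth=int(row["depth"]),
                    alt_reads=int(row["alt_reads"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {i + 1}: {exc}") from None
    return out


def measurements_to_frame(
    measurements: Iterable[AmpliconMeasurement],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "patient_id": m.patient_id,
                "chrom": m.chrom,
                "pos": m.pos,
                "ref": m.ref,
                "alt": m.alt,
                "depth": m.depth,
                "alt_reads": m.alt_reads,
            }
            for m in measurements
        ],
        columns=list(_PLASMA_COLUMNS),
    )


def calls_to_frame(calls: Iterable[CtdnaCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "status": c.status.value,
                "n_tracked": len(c.tracked),
                "n_positive": len(c.positive_mutations),
                "n_failed_amplicons": c.n_failed_amplicons,
                "mean_vaf": math.nan if c.mean_vaf is None else c.mean_vaf,
                "lod": c.lod,
            }
            for c in calls
        ]
    )
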