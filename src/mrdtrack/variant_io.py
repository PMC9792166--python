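"""Reading, validation and filtering of tumor somatic-variant tables.

Tumor profiles arrive downstream of alignment, somatic calling and
functional annotation: either as a single-sample somatic VCF or as a
flat MAF-style TSV (one row per mutation).  This module turns those
tables into validated :class:`SomaticVariant` records, applies the
tumor-sample sequencing QC gate, and applies the FFPE VAF floor used
for mutational-spectrum summaries.

The TSV dialect is tab-separated UTF-8 with a fixed header::

    patient_id  gene  chrom  pos  ref  alt  consequence  protein_change
    ffpe_vaf  cosmic_count  clinvar_pathogenic  predicted_deleterious
    gene_role  in_house_validated  in_low_complexity

Only the first nine columns are required; missing annotation columns
default to the least-favorable value for downstream ranking (``false``
/ ``0``), so absent evidence never inflates a tracking score.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Consequence",
    "GeneRole",
    "SomaticVariant",
    "TumorQCMetrics",
    "parse_protein_change",
    "read_variant_table",
    "write_variant_table",
    "variants_to_frame",
    "qc_tumor_sample",
    "filter_spectrum",
]


class Consequence(str, enum.Enum):
    """Coding consequence class of a somatic mutation."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: common annotation-pipeline spellings (Sequence Ontology terms, MAF
#: Variant_Classification values) mapped onto the internal enum
_CONSEQUENCE_ALIASES = {
    "missense": Consequence.MISSENSE,
    "missense_variant": Consequence.MISSENSE,
    "missense_mutation": Consequence.MISSENSE,
    "nonsense": Consequence.NONSENSE,
    "nonsense_mutation": Consequence.NONSENSE,
    "stop_gained": Consequence.NONSENSE,
    "stopgain": Consequence.NONSENSE,
    "frameshift": Consequence.FRAMESHIFT,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "frame_shift_del": Consequence.FRAMESHIFT,
    "frame_shift_ins": Consequence.FRAMESHIFT,
    "splice": Consequence.SPLICE,
    "splice_site": Consequence.SPLICE,
    "splice_acceptor_variant": Consequence.SPLICE,
    "splice_donor_variant": Consequence.SPLICE,
    "inframe_indel": Consequence.INFRAME_INDEL,
    "inframe_insertion": Consequence.INFRAME_INDEL,
    "inframe_deletion": Consequence.INFRAME_INDEL,
    "in_frame_del": Consequence.INFRAME_INDEL,
    "in_frame_ins": Consequence.INFRAME_INDEL,
    "synonymous": Consequence.SYNONYMOUS,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "silent": Consequence.SYNONYMOUS,
}


class GeneRole(str, enum.Enum):
    """COSMIC-style cancer-gene role."""

    ONCOGENE = "oncogene"
    TUMOR_SUPPRESSOR = "tumor_suppressor"
    OTHER = "other"


_ROLE_ALIASES = {
    "oncogene": GeneRole.ONCOGENE,
    "og": GeneRole.ONCOGENE,
    "tumor_suppressor": GeneRole.TUMOR_SUPPRESSOR,
    "tsg": GeneRole.TUMOR_SUPPRESSOR,
    "tumour_suppressor": GeneRole.TUMOR_SUPPRESSOR,
    "other": GeneRole.OTHER,
    "": GeneRole.OTHER,
}


def consequence_from_string(value: str) -> Consequence:
    """Map an annotation-pipeline consequence string to the enum.

    Unknown strings map to :attr:`Consequence.OTHER` with a logged
    warning rather than failing the whole table.
    """
    key = str(value).strip().lower()
    try:
        return _CONSEQUENCE_ALIASES[key]
    except KeyError:
        logger.warning("unknown consequence %r mapped to 'other'", value)
        return Consequence.OTHER


def gene_role_from_string(value: str) -> GeneRole:
    key = str(value).strip().lower()
    try:
        return _ROLE_ALIASES[key]
    except KeyError:
        logger.warning("unknown gene role %r mapped to 'other'", value)
        return GeneRole.OTHER


_PROTEIN_RE = re.compile(r"^(?:p\.)?([A-Za-z\*])(\d+)(.*)$")


def parse_protein_change(change: str) -> tuple[str, int, str]:
    """Parse a short protein change like ``"G12D"`` or ``"p.V600E"``.

    Returns ``(reference_aa, residue_number, suffix)``; e.g. ``"G12D"``
    gives ``("G", 12, "D")`` and ``"Q61*"`` gives ``("Q", 61, "*")``.
    Raises ``ValueError`` on strings that do not follow the
    letter/number/suffix convention.
    """
    m = _PROTEIN_RE.match(change.strip())
    if m is None:
        raise ValueError(f"unparseable protein change: {change!r}")
    return m.group(1).upper(), int(m.group(2)), m.group(3)


@dataclass(frozen=True)
class SomaticVariant:
    """One tumor-derived somatic mutation with its annotation evidence.

    Coordinates are 1-based (VCF convention).  ``ffpe_vaf`` is the
    variant allele fraction observed in the FFPE tumor tissue, in
    [0, 1].
    """

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    ffpe_vaf: float
    protein_change: str | None = None
    cosmic_count: int = 0
    clinvar_pathogenic: bool = False
    predicted_deleterious: bool = False
    gene_role: GeneRole = GeneRole.OTHER
    in_house_validated: bool = False
    in_low_complexity: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.ffpe_vaf <= 1.0:
            raise ValueError(
                f"ffpe_vaf must be in [0, 1], got {self.ffpe_vaf!r}"
            )
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.cosmic_count < 0:
            raise ValueError("cosmic_count must be non-negative")
        if not isinstance(self.consequence, Consequence):
            raise ValueError(f"invalid consequence: {self.consequence!r}")
        if not isinstance(self.gene_role, GeneRole):
            raise ValueError(f"invalid gene_role: {self.gene_role!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Genomic variant key ``(chrom, pos, ref, alt)``."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_nonsynonymous(self) -> bool:
        return self.consequence is not Consequence.SYNONYMOUS


@dataclass(frozen=True)
class TumorQCMetrics:
    """Tumor-sample sequencing QC summary.

    frac_bases_ge_20x
        Fraction of all target bases reaching >= 20X coverage.
    frac_targets_zero_coverage
        Fraction of target regions with at least one uncovered base.
    """

    frac_bases_ge_20x: float
    frac_targets_zero_coverage: float

    def __post_init__(self) -> None:
        for name in ("frac_bases_ge_20x", "frac_targets_zero_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")


def qc_tumor_sample(metrics: TumorQCMetrics) -> bool:
    """Tumor sequencing QC gate.

    Passes when strictly more than 98% of target bases reach 20X and
    strictly fewer than 1% of target regions have any uncovered base.
    """
    return (
        metrics.frac_bases_ge_20x > 0.98
        and metrics.frac_targets_zero_coverage < 0.01
    )


def filter_spectrum(
    variants: Sequence[SomaticVariant], min_vaf: float = 0.05
) -> list[SomaticVariant]:
    """Apply the FFPE VAF floor used for mutational-spectrum summaries.

    Retains exactly the variants with ``ffpe_vaf >= min_vaf``
    (inclusive boundary: a 5% variant survives the default 5% floor);
    input order is preserved.
    """
    return [v for v in variants if v.ffpe_vaf >= min_vaf]


# ---------------------------------------------------------------------------
# table I/O

_REQUIRED_COLUMNS = (
    "patient_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "ffpe_vaf",
)

_TSV_COLUMNS = _REQUIRED_COLUMNS + (
    "protein_change",
    "cosmic_count",
    "clinvar_pathogenic",
    "predicted_deleterious",
    "gene_role",
    "in_house_validated",
    "in_low_complexity",
)

_TRUE_STRINGS = {"true", "1", "yes", "t", "y"}
_FALSE_STRINGS = {"false", "0", "no", "f", "n", ""}


def _parse_bool(value, row: int, column: str) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    key = str(value).strip().lower()
    if key in _TRUE_STRINGS:
        return True
    if key in _FALSE_STRINGS:
        return False
    raise ValueError(f"row {row}, column {column!r}: bad boolean {value!r}")


def _cell(row_values, row: int, column: str):
    value = row_values.get(column)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"row {row}, column {column!r}: missing value")
    return value


def _variant_from_row(values: dict, row: int) -> SomaticVariant:
    try:
        pos = int(_cell(values, row, "pos"))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row {row}, column 'pos': {exc}") from None
    try:
        vaf = float(_cell(values, row, "ffpe_vaf"))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row {row}, column 'ffpe_vaf': {exc}") from None

    protein_change = values.get("protein_change")
    if protein_change is not None and (
        (isinstance(protein_change, float) and math.isnan(protein_change))
        or str(protein_change).strip() == ""
    ):
        protein_change = None

    cosmic = values.get("cosmic_count", 0)
    if cosmic is None or (isinstance(cosmic, float) and math.isnan(cosmic)):
        cosmic = 0

    try:
        return SomaticVariant(
            patient_id=str(_cell(values, row, "patient_id")),
            gene=str(_cell(values, row, "gene")),
            chrom=str(_cell(values, row, "chrom")),
            pos=pos,
            ref=str(_cell(values, row, "ref")).upper(),
            alt=str(_cell(values, row, "alt")).upper(),
            consequence=consequence_from_string(
                _cell(values, row, "consequence")
            ),
            ffpe_vaf=vaf,
            protein_change=None
            if protein_change is None
            else str(protein_change),
            cosmic_count=int(cosmic),
            clinvar_pathogenic=_parse_bool(
                values.get("clinvar_pathogenic"), row, "clinvar_pathogenic"
            ),
            predicted_deleterious=_parse_bool(
                values.get("predicted_deleterious"),
                row,
                "predicted_deleterious",
            ),
            gene_role=gene_role_from_string(values.get("gene_role") or ""),
            in_house_validated=_parse_bool(
                values.get("in_house_validated"), row, "in_house_validated"
            ),
            in_low_complexity=_parse_bool(
                values.get("in_low_complexity"), row, "in_low_complexity"
            ),
        )
    except ValueError as exc:
        if str(exc).startswith("row "):
            raise
        raise ValueError(f"row {row}: {exc}") from None


def _read_maf_tsv(path: Path) -> list[SomaticVariant]:
    df = pd.read_csv(path, sep="\t", dtype="object", comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for i, rec in enumerate(df.to_dict("records")):
        out.append(_variant_from_row(rec, row=i + 1))
    return out


def _vcf_vaf(variant, record_info) -> float:
    """Allele fraction of the first ALT: FORMAT AF, then AD/DP, then INFO AF."""
    import numpy as np

    try:
        af = variant.format("AF")
        if af is not None:
            return float(np.ravel(af)[0])
    except KeyError:
        pass
    try:
        ad = variant.format("AD")
        if ad is not None:
            ad = np.ravel(ad)
            depth = float(ad[0]) + float(ad[1])
            if depth > 0:
                return float(ad[1]) / depth
    except KeyError:
        pass
    af = record_info.get("AF")
    if af is not None:
        return float(af[0] if isinstance(af, tuple) else af)
    raise ValueError("no AF/AD information on record")


def _read_vcf(path: Path, patient_id: str | None) -> list[SomaticVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if patient_id is None:
        patient_id = vcf.samples[0] if vcf.samples else path.stem
    out = []
    for i, v in enumerate(vcf):
        info = dict(v.INFO)
        gene = info.get("GENE")
        if gene is None:
            raise ValueError(f"row {i + 1}, field 'GENE': missing in INFO")
        try:
            vaf = _vcf_vaf(v, info)
        except ValueError as exc:
            raise ValueError(f"row {i + 1}: {exc}") from None
        pchange = info.get("PCHANGE")
        out.append(
            SomaticVariant(
                patient_id=patient_id,
                gene=str(gene),
                chrom=str(v.CHROM),
                pos=int(v.POS),
                ref=str(v.REF),
                alt=str(v.ALT[0]),
                consequence=consequence_from_string(
                    info.get("CONSEQUENCE", "other")
                ),
                ffpe_vaf=vaf,
                protein_change=None if pchange is None else str(pchange),
                cosmic_count=int(info.get("COSMIC_N", 0)),
                clinvar_pathogenic=bool(info.get("CLNPATH", False)),
                predicted_deleterious=bool(info.get("DELETERIOUS", False)),
                gene_role=gene_role_from_string(info.get("ROLE", "")),
                in_house_validated=bool(info.get("INHOUSE", False)),
                in_low_complexity=bool(info.get("LOWCOMPLEX", False)),
            )
        )
    return out


def read_variant_table(
    path: str | Path,
    format: str | None = None,
    patient_id: str | None = None,
) -> list[SomaticVariant]:
    """Read a tumor somatic-variant table.

    Parameters
    ----------
    path
        File to read.
    format
        ``"vcf"`` or ``"maf_tsv"``; inferred from the suffix when
        omitted (``.vcf``/``.vcf.gz`` vs everything else).
    patient_id
        Patient identifier for VCF input (defaults to the VCF sample
        name); ignored for TSV input, which carries its own column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "maf_tsv"
    if format == "vcf":
        return _read_vcf(path, patient_id)
    if format == "maf_tsv":
        return _read_maf_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def variants_to_frame(variants: Iterable[SomaticVariant]) -> pd.DataFrame:
    """Render variants as a DataFrame in the canonical TSV column order."""
    rows = []
    for v in variants:
        rows.append(
            {
                "patient_id": v.patient_id,
                "gene": v.gene,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "consequence": v.consequence.value,
                "ffpe_vaf": v.ffpe_vaf,
                "protein_change": v.protein_change or "",
                "cosmic_count": v.cosmic_count,
                "clinvar_pathogenic": str(v.clinvar_pathogenic).lower(),
                "predicted_deleterious": str(v.predicted_deleterious).lower(),
                "gene_role": v.gene_role.value,
                "in_house_validated": str(v.in_house_validated).lower(),
                "in_low_complexity": str(v.in_low_complexity).lower(),
            }
        )
    return pd.DataFrame(rows, columns=list(_TSV_COLUMNS))


def write_variant_table(
    variants: Iterable[SomaticVariant], path: str | Path
) -> None:
    """Write variants as the canonical MAF-style TSV."""
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)
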