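"""Synthetic cohort, plasma, titration and timeline generators.

Every pipeline stage is testable without access to patient-level data:
this module generates tumor mutation profiles, ultra-deep amplicon
read counts, titration/healthy-donor calibration panels and serial
clinical timelines with the statistical structure the pipeline
assumes.

Model summary
-------------
* Tumor profiles: each *driver* gene is mutated independently per
  patient with its cohort frequency (so per-gene patient frequencies
  are exact config marginals); additional *passenger* mutations come
  from a disjoint background gene pool with a negative-binomial count
  whose mean tops the total up to the configured mutations-per-patient
  mean.  Mutation classes are i.i.d. from the class probabilities.
  Hotspot protein changes (KRAS G12/G13/Q61, NRAS Q61, BRAF V600E)
  are assigned without altering the drawn class.
* Read counts: per tracked site, depth ~ Normal around 100,000X with
  a configurable fraction drawn under the 10,000X QC floor; alt reads
  ~ beta-binomial with success probability
  ``tumor_fraction x heterozygosity + site background error``, the
  background error beta-distributed (overdispersed) around its mean.
* Shedding: per-patient tumor fraction is log10-normal with
  stage-specific offsets (stage I lowest); a single global location
  parameter is solved numerically so the marginal pre-operative
  detection probability equals the config target.
* Timelines: pre-op draw within 14 days before surgery, post-op at 1
  month then every 6 months; relapsing patients get ramping shedding
  so a molecular-relapse sample precedes the clinical relapse date by
  a uniform 4-10.5 month lead; CEA is elevated pre-op at a configured
  marginal rate and stays normal in relapsers.

All generators are fully deterministic under the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .longitudinal import DAYS_PER_MONTH, PatientTimeline, TimelineSample
from .plasma_mrd import (
    DEFAULT_LOD,
    MIN_AMPLICON_DEPTH,
    AmpliconMeasurement,
    call_sample,
)
from .tracking_panel import TrackingPanel, build_panel
from .variant_io import Consequence, GeneRole, SomaticVariant

__all__ = [
    "SimConfig",
    "SimCohort",
    "LongitudinalDataset",
    "generate_cohort",
    "generate_tumor_cohort",
    "generate_plasma_sample",
    "generate_healthy_panel",
    "generate_titration_panel",
    "generate_timelines",
    "generate_longitudinal_dataset",
    "simulate_preop_samples",
    "detection_probability",
    "sample_tumor_fraction",
]

# ---------------------------------------------------------------------------
# cohort structure defaults
#
# Only APC/TP53/KRAS/FAT4 frequencies, the class split, the KRAS-G12
# hotspot share and the actionability marginals are cohort-reported
# quantities; the remaining driver frequencies and the passenger gene
# pool are plausible colorectal-panel inventions (see docs/methods.md).

DEFAULT_STAGE_DISTRIBUTION = {
    "I": 0.126,
    "II": 0.399,
    "III": 0.388,
    "IV": 0.029,
}

#: driver gene -> (patient frequency, role, chrom, locus base)
DEFAULT_DRIVER_GENES: dict[str, tuple[float, GeneRole, str, int]] = {
    "APC": (0.699, GeneRole.TUMOR_SUPPRESSOR, "5", 112707498),
    "TP53": (0.631, GeneRole.TUMOR_SUPPRESSOR, "17", 7668402),
    "KRAS": (0.398, GeneRole.ONCOGENE, "12", 25205246),
    "FAT4": (0.272, GeneRole.TUMOR_SUPPRESSOR, "4", 125316279),
    "PIK3CA": (0.250, GeneRole.ONCOGENE, "3", 179148114),
    "TRRAP": (0.160, GeneRole.OTHER, "7", 98878532),
    "RNF213": (0.150, GeneRole.OTHER, "17", 80260857),
    "TCF7L2": (0.120, GeneRole.OTHER, "10", 112950247),
    "SMAD4": (0.120, GeneRole.TUMOR_SUPPRESSOR, "18", 50997869),
    "FBXW7": (0.110, GeneRole.TUMOR_SUPPRESSOR, "4", 152320544),
    "ATR": (0.100, GeneRole.TUMOR_SUPPRESSOR, "3", 142449235),
    "BRAF": (0.100, GeneRole.ONCOGENE, "7", 140713328),
    "NF1": (0.090, GeneRole.TUMOR_SUPPRESSOR, "17", 31094927),
    "AMER1": (0.080, GeneRole.TUMOR_SUPPRESSOR, "X", 64185117),
    "RNF43": (0.080, GeneRole.TUMOR_SUPPRESSOR, "17", 58352516),
    "NRAS": (0.040, GeneRole.ONCOGENE, "1", 114704469),
}

#: passenger pool, disjoint from the drivers so passengers never
#: inflate driver-gene patient frequencies
DEFAULT_BACKGROUND_GENES = (
    "ATM", "ARID1A", "BRCA1", "BRCA2", "CDKN2A", "CREBBP", "CTNNB1",
    "EGFR", "EP300", "ERBB2", "ERBB3", "FAT1", "FLT4", "GNAS",
    "GRIN2A", "KDR", "KMT2A", "KMT2C", "KMT2D", "LRP1B", "MET",
    "MSH2", "MSH6", "MTOR", "NOTCH1", "NOTCH2", "PDGFRA", "PIK3R1",
    "POLE", "PTEN", "PTPRT", "RB1", "RET", "ROS1", "SETD2", "SMAD2",
    "SMARCA4", "SOX9", "SPEN", "TGFBR2", "TSC2", "ZFHX3",
)

DEFAULT_CLASS_PROBABILITIES = {
    Consequence.MISSENSE: 0.723,
    Consequence.FRAMESHIFT: 0.135,
    Consequence.NONSENSE: 0.123,
    Consequence.SPLICE: 0.010,
    Consequence.INFRAME_INDEL: 0.009,
}

DEFAULT_SHEDDING_STAGE_OFFSETS = {"I": -1.0, "II": 0.0, "III": 0.1, "IV": 0.5}

_AA = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"

# RNG stream labels, spawned from the config seed
_STREAM_COHORT = 1
_STREAM_TITRATION = 2
_STREAM_TIMELINES = 3
_STREAM_PREOP = 4


@dataclass
class SimConfig:
    """All knobs of the simulator; the seed fully determines output."""

    seed: int = 0
    n_patients: int = 103
    stage_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_DISTRIBUTION)
    )
    gene_frequencies: dict[str, float] = field(
        default_factory=lambda: {
            g: f for g, (f, _, _, _) in DEFAULT_DRIVER_GENES.items()
        }
    )
    class_probabilities: dict[Consequence, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBABILITIES)
    )
    mutations_per_patient_mean: float = 7.0
    zero_mutation_rate: float = 0.01
    driver_second_hit_rate: float = 0.2
    passenger_dispersion: float = 0.9
    # FFPE VAF ~ Beta(alpha, beta); mean 1/3 mimics clonal heterozygous
    # mutations at >=60% tumor cellularity
    ffpe_vaf_alpha: float = 2.0
    ffpe_vaf_beta: float = 4.0
    low_complexity_rate: float = 0.02
    # hotspot / actionability structure
    kras_g12_fraction: float = 0.568
    nras_q61_fraction: float = 0.8
    braf_v600e_fraction: float = 0.26
    # plasma counting model
    panel_size: int = 5
    amplicon_depth_mean: int = 100_000
    amplicon_depth_sd: float = 15_000.0
    amplicon_fail_rate: float = 0.038
    background_error_mean: float = 1.5e-4
    background_error_shape: float = 5.0
    het_factor: float = 0.5
    lod: float = DEFAULT_LOD
    # shedding / detection
    target_preop_detection: float = 0.905
    shedding_sigma_log10: float = 0.8
    shedding_stage_offsets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SHEDDING_STAGE_OFFSETS)
    )
    # calibration panels
    titration_levels: tuple[float, ...] = (0.03, 0.005, 0.001, 0.0005, 0.0)
    titration_replicates: int = 50
    n_healthy_donors: int = 150
    # timelines
    relapse_probability: float = 2 / 19
    lead_time_months_range: tuple[float, float] = (4.0, 10.5)
    relapse_tumor_fraction_log10_range: tuple[float, float] = (-2.8, -2.2)
    relapse_doubling_months: float = 1.0
    follow_up_months: float = 18.0
    cea_preop_elevated_rate: float = 0.413

    _shedding_mu0: float | None = field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for name, probs in (
            ("stage_distribution", self.stage_distribution),
            ("class_probabilities", self.class_probabilities),
        ):
            vals = np.array(list(probs.values()), dtype=float)
            if np.any(vals < 0):
                raise ValueError(f"{name} has negative probabilities")
            if vals.sum() <= 0:
                raise ValueError(f"{name} sums to zero")
        for g, f in self.gene_frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"gene frequency {g}={f} outside [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if 0.0 not in self.titration_levels:
            raise ValueError("titration levels must include 0")
        if not 0 < self.background_error_mean < 1:
            raise ValueError("background_error_mean must be in (0, 1)")
        if not 0 < self.target_preop_detection < 1:
            raise ValueError("target_preop_detection must be in (0, 1)")

    # -- derived quantities -------------------------------------------------

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), int(stream)])
        )

    @property
    def stage_probs(self) -> tuple[list[str], np.ndarray]:
        stages = sorted(self.stage_distribution)
        p = np.array([self.stage_distribution[s] for s in stages], dtype=float)
        return stages, p / p.sum()

    @property
    def class_probs(self) -> tuple[list[Consequence], np.ndarray]:
        classes = list(self.class_probabilities)
        p = np.array(
            [self.class_probabilities[c] for c in classes], dtype=float
        )
        return classes, p / p.sum()

    @property
    def background_error_beta(self) -> tuple[float, float]:
        """(a, b) of the per-site background-error Beta distribution."""
        a = self.background_error_shape
        return a, a * (1.0 / self.background_error_mean - 1.0)

    @property
    def expected_driver_mutations(self) -> float:
        return sum(self.gene_frequencies.values()) * (
            1.0 + self.driver_second_hit_rate
        )

    @property
    def passenger_mean(self) -> float:
        return max(
            0.2, self.mutations_per_patient_mean - self.expected_driver_mutations
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_shedding_mu0", None)
        d["class_probabilities"] = {
            c.value: p for c, p in self.class_probabilities.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "class_probabilities" in d:
            d["class_probabilities"] = {
                Consequence(k): v for k, v in d["class_probabilities"].items()
            }
        for key in ("titration_levels", "lead_time_months_range",
                    "relapse_tumor_fraction_log10_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# shedding calibration


def detection_probability(
    tumor_fraction: float, config: SimConfig, n_sites: int | None = None
) -> float:
    """Closed-form pre-op detection probability for one patient.

    A site detects when its alt count reaches ``lod x depth`` at the
    mean depth; the sample detects when any of the (failure-adjusted)
    tracked sites does.  Background error enters at its mean; the
    full beta-binomial dispersion matters for false positives, not
    for the signal regime this calibrates.
    """
    depth = config.amplicon_depth_mean
    threshold = math.ceil(config.lod * depth)
    p = min(
        1.0, config.het_factor * tumor_fraction + config.background_error_mean
    )
    per_site = stats.binom.sf(threshold - 1, depth, p)
    k = (n_sites or config.panel_size) * (1.0 - config.amplicon_fail_rate)
    return float(1.0 - (1.0 - per_site) ** k)


_HERMITE_NODES = 64


def _marginal_detection(mu0: float, config: SimConfig) -> float:
    stages, stage_p = config.stage_probs
    x, w = np.polynomial.hermite.hermgauss(_HERMITE_NODES)
    z = math.sqrt(2.0) * x
    w = w / math.sqrt(math.pi)
    total = 0.0
    for s, ps in zip(stages, stage_p):
        mu = mu0 + config.shedding_stage_offsets[s]
        tfs = 10.0 ** (mu + config.shedding_sigma_log10 * z)
        det = np.array(
            [detection_probability(min(tf, 1.0), config) for tf in tfs]
        )
        total += ps * float(np.dot(w, det))
    return total


def shedding_location(config: SimConfig) -> float:
    """Global log10 tumor-fraction location, solved so the marginal
    pre-op detection probability equals the config target.

    Deterministic (quadrature + Brent root finding); cached per config.
    """
    if config._shedding_mu0 is None:
        config._shedding_mu0 = float(
            optimize.brentq(
                lambda m: _marginal_detection(m, config)
                - config.target_preop_detection,
                -7.0,
                0.0,
                xtol=1e-6,
            )
        )
    return config._shedding_mu0


def sample_tumor_fraction(
    stage: str, config: SimConfig, rng: np.random.Generator
) -> float:
    mu = shedding_location(config) + config.shedding_stage_offsets[stage]
    tf = 10.0 ** (mu + config.shedding_sigma_log10 * rng.standard_normal())
    return float(min(tf, 1.0))


# ---------------------------------------------------------------------------
# tumor cohort


@dataclass(frozen=True)
class SimCohort:
    """Generated tumor profiles plus the per-patient TNM stage."""

    variants: dict[str, list[SomaticVariant]]
    stages: dict[str, str]

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.variants)


def _gene_locus(gene: str) -> tuple[str, int]:
    if gene in DEFAULT_DRIVER_GENES:
        _, _, chrom, base = DEFAULT_DRIVER_GENES[gene]
        return chrom, base
    idx = DEFAULT_BACKGROUND_GENES.index(gene)
    return str(idx % 22 + 1), 10_000_000 + idx * 1_000_000


def _gene_role(gene: str) -> GeneRole:
    if gene in DEFAULT_DRIVER_GENES:
        return DEFAULT_DRIVER_GENES[gene][1]
    return GeneRole.OTHER


_HOTSPOT_MISSENSE_SUFFIX = "DVCAS"


def _protein_change(
    rng: np.random.Generator,
    consequence: Consequence,
    hotspot: tuple[str, int] | None,
) -> str | None:
    if hotspot is not None:
        aa, residue = hotspot
        if consequence is Consequence.MISSENSE:
            suffix = _HOTSPOT_MISSENSE_SUFFIX[
                rng.integers(len(_HOTSPOT_MISSENSE_SUFFIX))
            ]
        elif consequence is Consequence.NONSENSE:
            suffix = "*"
        elif consequence is Consequence.INFRAME_INDEL:
            suffix = "del"
        else:  # frameshift / splice near the hotspot codon
            suffix = "fs"
        return f"{aa}{residue}{suffix}"
    residue = int(rng.integers(1, 1200))
    ref_aa = _AA[rng.integers(len(_AA))]
    if consequence is Consequence.MISSENSE:
        alt_aa = _AA[rng.integers(len(_AA))]
        while alt_aa == ref_aa:
            alt_aa = _AA[rng.integers(len(_AA))]
        return f"{ref_aa}{residue}{alt_aa}"
    if consequence is Consequence.NONSENSE:
        return f"{ref_aa}{residue}*"
    if consequence is Consequence.FRAMESHIFT:
        return f"{ref_aa}{residue}fs"
    if consequence is Consequence.INFRAME_INDEL:
        return f"{ref_aa}{residue}del"
    return None  # splice


def _ref_alt(
    rng: np.random.Generator, consequence: Consequence
) -> tuple[str, str]:
    b = _BASES[rng.integers(4)]
    if consequence is Consequence.FRAMESHIFT:
        return b + _BASES[rng.integers(4)], b  # 1-bp deletion
    if consequence is Consequence.INFRAME_INDEL:
        tail = "".join(_BASES[rng.integers(4)] for _ in range(3))
        return b + tail, b  # 3-bp deletion
    alt = _BASES[rng.integers(4)]
    while alt == b:
        alt = _BASES[rng.integers(4)]
    return b, alt


def _make_variant(
    rng: np.random.Generator,
    patient_id: str,
    gene: str,
    consequence: Consequence,
    hotspot: tuple[str, int] | None,
    is_driver: bool,
    config: SimConfig,
) -> SomaticVariant:
    chrom, base = _gene_locus(gene)
    role = _gene_role(gene)
    ref, alt = _ref_alt(rng, consequence)
    truncating = consequence in (Consequence.NONSENSE, Consequence.FRAMESHIFT)

    # documented conditional annotation rules
    if hotspot is not None:
        p_clinvar = 0.9
    elif is_driver and truncating:
        p_clinvar = 0.7
    elif is_driver:
        p_clinvar = 0.35
    else:
        p_clinvar = 0.1
    p_delet = {
        Consequence.MISSENSE: 0.6 if is_driver else 0.3,
        Consequence.NONSENSE: 0.7 if is_driver else 0.4,
        Consequence.FRAMESHIFT: 0.7 if is_driver else 0.4,
        Consequence.SPLICE: 0.5,
        Consequence.INFRAME_INDEL: 0.3,
    }[consequence]
    if hotspot is not None and role is GeneRole.ONCOGENE:
        cosmic = int(rng.integers(100, 20001))
    elif is_driver and role is GeneRole.ONCOGENE:
        cosmic = int(rng.geometric(0.25))
    elif is_driver:
        cosmic = int(rng.geometric(0.3))
    else:
        cosmic = int(rng.geometric(0.6)) - 1

    return SomaticVariant(
        patient_id=patient_id,
        gene=gene,
        chrom=chrom,
        pos=base + int(rng.integers(0, 50_000)),
        ref=ref,
        alt=alt,
        consequence=consequence,
        ffpe_vaf=float(rng.beta(config.ffpe_vaf_alpha, config.ffpe_vaf_beta)),
        protein_change=_protein_change(rng, consequence, hotspot),
        cosmic_count=cosmic,
        clinvar_pathogenic=bool(rng.random() < p_clinvar),
        predicted_deleterious=bool(rng.random() < p_delet),
        gene_role=role,
        in_house_validated=bool(rng.random() < (0.3 if is_driver else 0.05)),
        in_low_complexity=bool(rng.random() < config.low_complexity_rate),
    )


def _hotspot_for(
    rng: np.random.Generator, gene: str, first_in_gene: bool,
    consequence: Consequence, config: SimConfig,
) -> tuple[str, int] | None:
    """Hotspot codon assignment for the first mutation in select genes."""
    if not first_in_gene:
        return None
    if gene == "KRAS":
        if rng.random() < config.kras_g12_fraction:
            return ("G", 12)
        return ("G", 13) if rng.random() < 0.5 else ("Q", 61)
    if gene == "NRAS" and rng.random() < config.nras_q61_fraction:
        return ("Q", 61)
    if (
        gene == "BRAF"
        and consequence is Consequence.MISSENSE
        and rng.random() < config.braf_v600e_fraction
    ):
        return ("V", 600)
    return None


def generate_cohort(config: SimConfig) -> SimCohort:
    """Generate tumor profiles and stages for ``config.n_patients``."""
    rng = config.rng(_STREAM_COHORT)
    classes, class_p = config.class_probs
    stages, stage_p = config.stage_probs
    n_digits = max(3, len(str(config.n_patients)))
    variants: dict[str, list[SomaticVariant]] = {}
    stage_map: dict[str, str] = {}
    r = config.passenger_dispersion
    m = config.passenger_mean
    nb_p = r / (r + m)
    for i in range(config.n_patients):
        pid = f"SIM{i + 1:0{n_digits}d}"
        stage_map[pid] = stages[rng.choice(len(stages), p=stage_p)]
        profile: list[SomaticVariant] = []
        if rng.random() < config.zero_mutation_rate:
            variants[pid] = profile
            continue
        for gene, freq in config.gene_frequencies.items():
            if rng.random() >= freq:
                continue
            n_hits = 1 + int(rng.random() < config.driver_second_hit_rate)
            for hit in range(n_hits):
                consequence = classes[rng.choice(len(classes), p=class_p)]
                hotspot = _hotspot_for(
                    rng, gene, hit == 0, consequence, config
                )
                profile.append(
                    _make_variant(
                        rng, pid, gene, consequence, hotspot, True, config
                    )
                )
        n_passengers = int(rng.negative_binomial(r, nb_p))
        for _ in range(n_passengers):
            gene = DEFAULT_BACKGROUND_GENES[
                rng.integers(len(DEFAULT_BACKGROUND_GENES))
            ]
            consequence = classes[rng.choice(len(classes), p=class_p)]
            profile.append(
                _make_variant(rng, pid, gene, consequence, None, False, config)
            )
        if not profile:
            gene = DEFAULT_BACKGROUND_GENES[
                rng.integers(len(DEFAULT_BACKGROUND_GENES))
            ]
            consequence = classes[rng.choice(len(classes), p=class_p)]
            profile.append(
                _make_variant(rng, pid, gene, consequence, None, False, config)
            )
        variants[pid] = profile
    return SimCohort(variants=variants, stages=stage_map)


def generate_tumor_cohort(config: SimConfig) -> dict[str, list[SomaticVariant]]:
    """Plain-mapping view of :func:`generate_cohort`: patient -> variants."""
    return generate_cohort(config).variants


# ---------------------------------------------------------------------------
# plasma read counts


def _draw_depth(config: SimConfig, rng: np.random.Generator) -> int:
    if rng.random() < config.amplicon_fail_rate:
        return int(rng.integers(1_000, MIN_AMPLICON_DEPTH))
    d = rng.normal(config.amplicon_depth_mean, config.amplicon_depth_sd)
    return max(MIN_AMPLICON_DEPTH, int(d))


def _draw_measurement(
    config: SimConfig,
    rng: np.random.Generator,
    patient_id: str,
    sample_id: str,
    key: tuple[str, int, str, str],
    signal_vaf: float,
) -> AmpliconMeasurement:
    a, b = config.background_error_beta
    depth = _draw_depth(config, rng)
    p = min(1.0, signal_vaf + float(rng.beta(a, b)))
    alt = int(rng.binomial(depth, p))
    chrom, pos, ref, alt_allele = key
    return AmpliconMeasurement(
        patient_id=patient_id,
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt_allele,
        depth=depth,
        alt_reads=alt,
    )


def generate_plasma_sample(
    panel: TrackingPanel,
    tumor_fraction: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "S1",
) -> list[AmpliconMeasurement]:
    """Simulate one plasma draw over a patient's tracking panel.

    Per-site signal is ``tumor_fraction x het_factor`` (one mutant
    allele per shed diploid genome by default) on top of a
    beta-distributed background error.
    """
    if not panel.members:
        raise ValueError("empty panel")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    if rng is None:
        rng = config.rng(_STREAM_PREOP)
    signal = tumor_fraction * config.het_factor
    return [
        _draw_measurement(
            config, rng, panel.patient_id, sample_id, m.variant.key, signal
        )
        for m in panel.members
    ]


_NULL_KEY = ("1", 1_000_000, "A", "T")


def generate_healthy_panel(
    config: SimConfig,
    n_samples: int | None = None,
    n_sites: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[list[float]]:
    """Healthy-donor plasma: per-sample lists of QC-passing VAFs.

    Healthy donors carry no tumor DNA; every observation is pure
    background error through the same counting model.
    """
    if rng is None:
        rng = config.rng(_STREAM_TITRATION)
    n_samples = n_samples if n_samples is not None else config.n_healthy_donors
    n_sites = n_sites if n_sites is not None else config.panel_size
    out = []
    for i in range(n_samples):
        vafs = []
        for j in range(n_sites):
            m = _draw_measurement(
                config, rng, f"HD{i + 1:04d}", f"HD{i + 1:04d}", _NULL_KEY, 0.0
            )
            if m.qc_pass:
                vafs.append(m.vaf)
        out.append(vafs)
    return out


def generate_titration_panel(
    config: SimConfig,
    levels: Sequence[float] | None = None,
    replicates: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[float, list[float]], list[list[float]]]:
    """Titration observations plus the healthy-donor panel.

    Returns ``(titration, healthy)`` where ``titration`` maps each
    expected-VAF level to its observed QC-passing VAFs and ``healthy``
    is the per-sample VAF lists from :func:`generate_healthy_panel`
    (150 donors by default).  Titration mixtures carry the mutation at
    the stated VAF directly (reference-standard DNA, no ploidy
    factor).
    """
    if rng is None:
        rng = config.rng(_STREAM_TITRATION)
    levels = list(config.titration_levels if levels is None else levels)
    if 0.0 not in levels:
        raise ValueError("titration levels must include 0")
    replicates = (
        config.titration_replicates if replicates is None else replicates
    )
    titration: dict[float, list[float]] = {}
    for level in levels:
        obs = []
        for i in range(replicates):
            m = _draw_measurement(
                config, rng, "TITR", f"TITR_L{level}", _NULL_KEY, float(level)
            )
            if m.qc_pass:
                obs.append(m.vaf)
        titration[float(level)] = obs
    healthy = generate_healthy_panel(config, rng=rng)
    return titration, healthy


# ---------------------------------------------------------------------------
# pre-operative pipeline and timelines


def _patient_panels(
    cohort: SimCohort, config: SimConfig
) -> dict[str, TrackingPanel]:
    panels = {}
    for pid in cohort.patient_ids:
        try:
            panels[pid] = build_panel(
                cohort.variants[pid], n=config.panel_size
            )
        except ValueError:
            continue  # no trackable mutations; patient is unassayable
    return panels


def simulate_preop_samples(
    cohort: SimCohort,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, list[AmpliconMeasurement]]:
    """One pre-operative plasma sample per panel-eligible patient."""
    if rng is None:
        rng = config.rng(_STREAM_PREOP)
    panels = _patient_panels(cohort, config)
    out = {}
    for pid in sorted(panels):
        tf = sample_tumor_fraction(cohort.stages[pid], config, rng)
        out[pid] = generate_plasma_sample(
            panels[pid], tf, config, rng=rng, sample_id=f"{pid}_T0"
        )
    return out


@dataclass(frozen=True)
class LongitudinalDataset:
    """Timelines plus the raw per-sample read counts behind the calls."""

    timelines: list[PatientTimeline]
    measurements: dict[str, list[AmpliconMeasurement]]
    panels: dict[str, TrackingPanel]


def _cea_value(
    rng: np.random.Generator, elevated: bool
) -> float:
    if elevated:
        return float(5.0 + rng.gamma(2.0, 5.0))
    return float(rng.uniform(0.5, 4.9))


def generate_longitudinal_dataset(
    cohort: SimCohort | Mapping[str, Sequence[SomaticVariant]],
    config: SimConfig,
) -> LongitudinalDataset:
    """Serial plasma monitoring for every panel-eligible patient.

    Pre-op draw 0-13 days before surgery, post-op draws at 1 month
    then every 6 months until the follow-up horizon (or until
    clinical relapse for relapsers).  Relapsing patients get a
    ctDNA-positive sample a uniform 4-10.5 month lead ahead of the
    clinical relapse date by construction.
    """
    if not isinstance(cohort, SimCohort):
        stage_rng = config.rng(_STREAM_TIMELINES + 1000)
        stages, stage_p = config.stage_probs
        cohort = SimCohort(
            variants={p: list(v) for p, v in cohort.items()},
            stages={
                p: stages[stage_rng.choice(len(stages), p=stage_p)]
                for p in cohort
            },
        )
    rng = config.rng(_STREAM_TIMELINES)
    panels = _patient_panels(cohort, config)
    lead_lo, lead_hi = config.lead_time_months_range
    tf_lo, tf_hi = config.relapse_tumor_fraction_log10_range
    timelines = []
    measurements: dict[str, list[AmpliconMeasurement]] = {}
    base = date(2021, 6, 1)
    for pid in sorted(panels):
        panel = panels[pid]
        surgery = base + timedelta(days=int(rng.integers(0, 365)))

        relapse = bool(rng.random() < config.relapse_probability)
        postop_months = [1.0]
        while postop_months[-1] + 6.0 <= config.follow_up_months + 1e-9:
            postop_months.append(postop_months[-1] + 6.0)
        clinical_relapse: date | None = None
        onset_month = math.inf
        relapse_tf0 = 0.0
        if relapse:
            candidates = [m for m in postop_months if m > 1.0] or [7.0]
            detect_month = candidates[int(rng.integers(len(candidates)))]
            lead = float(rng.uniform(lead_lo, lead_hi))
            clinical_month = detect_month + lead
            clinical_relapse = surgery + timedelta(
                days=round(clinical_month * DAYS_PER_MONTH)
            )
            onset_month = detect_month - float(rng.uniform(0.0, 3.0))
            relapse_tf0 = 10.0 ** float(rng.uniform(tf_lo, tf_hi))
            # monitoring stops at clinical diagnosis; extend the grid so
            # every scheduled visit before it is drawn
            postop_months = [1.0]
            while postop_months[-1] + 6.0 < clinical_month:
                postop_months.append(postop_months[-1] + 6.0)

        samples = []
        # pre-operative draw (counts as pre-op up to the surgery day)
        preop_date = surgery - timedelta(days=int(rng.integers(0, 14)))
        preop_tf = sample_tumor_fraction(cohort.stages[pid], config, rng)
        sid = f"{pid}_T0"
        meas = generate_plasma_sample(
            panel, preop_tf, config, rng=rng, sample_id=sid
        )
        measurements[sid] = meas
        samples.append(
            TimelineSample(
                date=preop_date,
                call=call_sample(meas, lod=config.lod),
                cea_ng_per_ml=_cea_value(
                    rng, rng.random() < config.cea_preop_elevated_rate
                ),
            )
        )
        for k, month in enumerate(postop_months, start=1):
            if month >= onset_month:
                tf = relapse_tf0 * 2.0 ** (
                    (month - onset_month) / config.relapse_doubling_months
                )
                tf = min(tf, 0.5)
            else:
                tf = 0.0
            sid = f"{pid}_T{k}"
            meas = generate_plasma_sample(
                panel, tf, config, rng=rng, sample_id=sid
            )
            measurements[sid] = meas
            samples.append(
                TimelineSample(
                    date=surgery + timedelta(days=round(month * DAYS_PER_MONTH)),
                    call=call_sample(meas, lod=config.lod),
                    cea_ng_per_ml=_cea_value(rng, False),
                )
            )
        timelines.append(
            PatientTimeline(
                patient_id=pid,
                surgery_date=surgery,
                samples=tuple(samples),
                clinical_relapse_date=clinical_relapse,
            )
        )
    return LongitudinalDataset(
        timelines=timelines, measurements=measurements, panels=panels
    )


def generate_timelines(
    cohort: SimCohort | Mapping[str, Sequence[SomaticVariant]],
    config: SimConfig,
) -> list[PatientTimeline]:
    """Timeline-only view of :func:`generate_longitudinal_dataset`."""
    return generate_longitudinal_dataset(cohort, config).timelines
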