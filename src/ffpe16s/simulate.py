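"""Synthetic paired FF/FFPE cohorts with contamination ground truth.

The generator emulates the statistical structure of a paired fresh-frozen /
FFPE colorectal-tissue 16S study: FF gut communities dominated by
Bacteroidales and Clostridiales with a minor *Fusobacterium* marker and a
trace of methanogenic archaea; FFPE profiles derived from the matched FF
community by taxon dropout (archaea lost entirely, the marker depleted)
plus a spike of reagent/environmental contaminants (*Rhizobium*,
*Acinetobacter*, *Paracoccus*, *Sphingomonas*, ...); eukaryotic host reads
layered on top of both; and a no-template control (NTC) drawn purely from
the contaminant pool.

Only part of the contaminant pool is drawable by the NTC (reagent-type
ASVs); the rest (environment-type ASVs) appears exclusively in FFPE
tissue. In-silico subtraction of NTC ASVs therefore reduces, but does not
erase, the planted contamination gradient — the situation the downstream
comparability index is designed to detect.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    RANKS,
    UNASSIGNED,
    AsvTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)
from .ish import IshCountTable

ROLES = ("core_crc", "crc_marker", "archaeal", "contaminant", "eukaryote")


@dataclasses.dataclass(frozen=True)
class Taxon:
    """A genus with its full ranked lineage and its role in the simulation."""

    genus: str
    lineage: tuple[str, str, str, str, str, str]  # kingdom..genus
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if len(self.lineage) != len(RANKS):
            raise ValidationError(f"lineage for {self.genus!r} must have 6 ranks")

    @property
    def order(self) -> str:
        return self.lineage[3]


class CommunityProfile:
    """Relative-abundance profile over taxa; abundances sum to one."""

    def __init__(self, taxa: Sequence[Taxon], abundances: Sequence[float]):
        abundances = np.asarray(abundances, dtype=float)
        if len(taxa) != len(abundances):
            raise ValidationError("taxa/abundance length mismatch")
        if (abundances < 0).any():
            raise ValidationError("negative abundance")
        if abs(abundances.sum() - 1.0) > 1e-9:
            raise ValidationError(f"abundances sum to {abundances.sum()}, not 1")
        names = [t.genus for t in taxa]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate genus in profile")
        self.taxa = list(taxa)
        self.abundances = abundances

    def abundance(self, genus: str) -> float:
        for t, a in zip(self.taxa, self.abundances):
            if t.genus == genus:
                return float(a)
        raise KeyError(genus)

    def mass_of_role(self, role: str) -> float:
        return float(
            sum(a for t, a in zip(self.taxa, self.abundances) if t.role == role)
        )

    def order_totals(self) -> pd.Series:
        out: dict[str, float] = {}
        for t, a in zip(self.taxa, self.abundances):
            out[t.order] = out.get(t.order, 0.0) + float(a)
        return pd.Series(out).sort_values(ascending=False)


def _bact(phylum: str, cls: str, order: str, family: str, genus: str) -> tuple:
    return ("Bacteria", phylum, cls, order, family, genus)


def make_default_profiles() -> tuple[CommunityProfile, CommunityProfile]:
    """Default FF gut community and reagent/environmental contaminant pool.

    The FF baseline is a colorectal-tissue community with Bacteroidales and
    Clostridiales as the two dominant orders, minor Fusobacteriales /
    Enterobacteriales / Coriobacteriales components, and a 0.2% archaeal
    trace. The contaminant pool follows the genus proportions observed in
    no-template sequencing controls (Rhizobium 56%, Acinetobacter 11%,
    Lysinibacillus 7%, Delftia 5%, remainder split among Paracoccus,
    Sphingomonas, Pseudomonas and Aquipuribacter).
    """
    ff_taxa = [
        (Taxon("Bacteroides", _bact("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"), "core_crc"), 0.300),
        (Taxon("Prevotella", _bact("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"), "core_crc"), 0.060),
        (Taxon("Alistipes", _bact("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae", "Alistipes"), "core_crc"), 0.050),
        (Taxon("Parabacteroides", _bact("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Tannerellaceae", "Parabacteroides"), "core_crc"), 0.040),
        (Taxon("Odoribacter", _bact("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Marinifilaceae", "Odoribacter"), "core_crc"), 0.020),
        (Taxon("Faecalibacterium", _bact("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Faecalibacterium"), "core_crc"), 0.110),
        (Taxon("Blautia", _bact("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Blautia"), "core_crc"), 0.070),
        (Taxon("Roseburia", _bact("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Roseburia"), "core_crc"), 0.060),
        (Taxon("Ruminococcus", _bact("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminococcus"), "core_crc"), 0.050),
        (Taxon("Dorea", _bact("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Dorea"), "core_crc"), 0.040),
        (Taxon("Lachnoclostridium", _bact("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Lachnoclostridium"), "core_crc"), 0.031),
        (Taxon("Fusobacterium", _bact("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium"), "crc_marker"), 0.022),
        (Taxon("Escherichia", _bact("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", "Escherichia"), "core_crc"), 0.050),
        (Taxon("Collinsella", _bact("Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "Collinsella"), "core_crc"), 0.030),
        (Taxon("Propionibacterium", _bact("Actinobacteria", "Actinobacteria", "Propionibacteriales", "Propionibacteriaceae", "Propionibacterium"), "core_crc"), 0.025),
        (Taxon("Streptococcus", _bact("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"), "core_crc"), 0.020),
        (Taxon("Romboutsia", _bact("Firmicutes", "Clostridia", "Clostridiales", "Peptostreptococcaceae", "Romboutsia"), "core_crc"), 0.020),
        (Taxon("Methanobrevibacter", ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanobrevibacter"), "archaeal"), 0.002),
    ]
    contaminant_taxa = [
        (Taxon("Rhizobium", _bact("Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Rhizobiaceae", "Rhizobium"), "contaminant"), 0.56),
        (Taxon("Acinetobacter", _bact("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae", "Acinetobacter"), "contaminant"), 0.11),
        (Taxon("Lysinibacillus", _bact("Firmicutes", "Bacilli", "Bacillales", "Planococcaceae", "Lysinibacillus"), "contaminant"), 0.07),
        (Taxon("Delftia", _bact("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Comamonadaceae", "Delftia"), "contaminant"), 0.05),
        (Taxon("Paracoccus", _bact("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae", "Paracoccus"), "contaminant"), 0.06),
        (Taxon("Sphingomonas", _bact("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas"), "contaminant"), 0.06),
        (Taxon("Pseudomonas", _bact("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas"), "contaminant"), 0.05),
        (Taxon("Aquipuribacter", _bact("Actinobacteria", "Actinobacteria", "Micrococcales", "Intrasporangiaceae", "Aquipuribacter"), "contaminant"), 0.04),
    ]
    ff = CommunityProfile([t for t, _ in ff_taxa], [a for _, a in ff_taxa])
    pool = CommunityProfile(
        [t for t, _ in contaminant_taxa], [a for _, a in contaminant_taxa]
    )
    return ff, pool


#: Host (eukaryotic) pseudo-taxon used for injected non-microbial reads.
HOST_TAXON = Taxon(
    "Homo",
    ("Eukaryota", UNASSIGNED, UNASSIGNED, UNASSIGNED, UNASSIGNED, UNASSIGNED),
    "eukaryote",
)


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the cohort generator; the seed fixes every draw.

    Defaults reproduce the study design being emulated: 10 FF/FFPE pairs
    plus one NTC, ~16,000 microbial reads per tissue sample and ~25,000 for
    the NTC, eukaryote read fractions of 15.6% (FF) and 18% (FFPE), archaea
    absent from FFPE, and a contamination-fraction gradient across pairs.
    """

    n_pairs: int = 10
    depth: int = 16_000
    ntc_depth: int = 25_000
    dirichlet_concentration: float = 200.0
    contamination: tuple[float, ...] | None = None  # default: linspace(.05, .8)
    dropout: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"archaeal": 0.0, "crc_marker": 0.25}
    )
    eukaryote_fraction_ff: float = 0.156
    eukaryote_fraction_ffpe: float = 0.18
    singleton_rate: float = 3.0  # expected injected singleton ASVs per sample
    asvs_per_taxon: int = 16
    seed: int = 0

    def contamination_gradient(self) -> np.ndarray:
        if self.contamination is not None:
            grid = np.asarray(self.contamination, dtype=float)
            if len(grid) != self.n_pairs:
                raise ValidationError("contamination grid length != n_pairs")
        else:
            grid = np.linspace(0.05, 0.8, self.n_pairs)
        if ((grid < 0) | (grid > 1)).any():
            raise ValidationError("contamination fractions must lie in [0, 1]")
        return grid

    def validate(self) -> None:
        if self.depth <= 0 or self.ntc_depth <= 0:
            raise ValidationError("depth must be positive")
        for frac in (self.eukaryote_fraction_ff, self.eukaryote_fraction_ffpe):
            if not 0 <= frac < 1:
                raise ValidationError("eukaryote fractions must lie in [0, 1)")
        for mult in self.dropout.values():
            if not 0 <= mult <= 1:
                raise ValidationError("dropout multipliers must lie in [0, 1]")
        self.contamination_gradient()


@dataclasses.dataclass
class GroundTruth:
    """Everything a recovery test needs, keyed to sample/patient ids."""

    contamination: dict[str, float]  # patient -> planted c
    ff_profiles: dict[str, np.ndarray]  # patient -> taxon-level FF profile
    euk_reads: dict[str, int]  # sample -> injected eukaryote reads
    singleton_asvs: dict[str, list[str]]  # sample -> injected singleton ids
    contaminant_asvs: list[str]  # all ASVs of contaminant-role taxa
    ntc_shared_asvs: list[str]  # contaminant ASVs drawable by the NTC
    ff_favoured_taxa: list[str]  # planted FF-discriminant genera
    ffpe_favoured_taxa: list[str]  # planted FFPE-discriminant genera
    true_comparability: dict[str, str]  # patient -> "high" | "low"

    #: Generator convention: a pair is truly "high" comparability when its
    #: planted contamination fraction is at most this value.
    COMPARABILITY_C_MAX = 0.4

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for patient in sorted(self.contamination):
            rows.append(
                {
                    "patient_id": patient,
                    "contamination": self.contamination[patient],
                    "true_comparability": self.true_comparability[patient],
                }
            )
        return pd.DataFrame(rows).set_index("patient_id")


@dataclasses.dataclass
class PairedCohort:
    """Simulated cohort plus the ground truth it was generated from."""

    table: AsvTable
    taxonomy: TaxonomyTable
    metadata: SampleMetadata
    ground_truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# ASV-level expansion of taxon profiles
# ---------------------------------------------------------------------------

def _n_asvs(taxon: Taxon, default: int) -> int:
    # Trace archaeal lineages are represented by a couple of variants only;
    # a long rare tail there would sit below one expected read and blur the
    # boundary between real rare ASVs and injected singletons.
    return 2 if taxon.role == "archaeal" else default


def _asv_ids_for(taxon: Taxon, n: int) -> list[str]:
    return [f"ASV_{taxon.genus}_{k:02d}" for k in range(1, n + 1)]


def _within_taxon_split(n: int, ratio: float = 0.78) -> np.ndarray:
    # Geometric split: a dominant ASV plus a long tail of minor variants,
    # fixed (not random) so ASV identity is stable across seeds. The tail
    # puts several ASVs per genus near the detection limit, so membership
    # (and hence binary Jaccard) responds to dilution of the FF community.
    w = ratio ** np.arange(n)
    return w / w.sum()


def _expand_to_asvs(
    profile: CommunityProfile, abundances: np.ndarray, n_asvs: int
) -> tuple[list[str], np.ndarray, list[Taxon]]:
    """Spread taxon-level abundances over per-taxon ASVs."""
    ids: list[str] = []
    probs: list[float] = []
    owners: list[Taxon] = []
    for taxon, mass in zip(profile.taxa, abundances):
        n = _n_asvs(taxon, n_asvs)
        split = _within_taxon_split(n)
        for asv, w in zip(_asv_ids_for(taxon, n), split):
            ids.append(asv)
            probs.append(float(mass) * float(w))
            owners.append(taxon)
    return ids, np.asarray(probs), owners


def _ntc_shared_mask(pool: CommunityProfile, n_asvs: int) -> np.ndarray:
    """Reagent-type ASVs of each contaminant genus (drawable by the NTC).

    Within each genus, ASVs are shared with the NTC up to roughly half the
    genus's mass (the dominant ASV under the default geometric split); the
    remaining environment-type ASVs occur only in FFPE tissue.
    """
    split = _within_taxon_split(n_asvs)
    cum = np.cumsum(split)
    k = int(np.argmin(np.abs(cum - 0.5))) + 1  # prefix mass closest to half
    per_taxon = np.zeros(n_asvs, dtype=bool)
    per_taxon[:k] = True
    return np.tile(per_taxon, len(pool.taxa))


def simulate_pair(
    ff_base: CommunityProfile,
    contaminant_pool: CommunityProfile,
    c: float,
    config: SimulationConfig | None = None,
    seed: int | np.random.Generator = 0,
    dropout: Mapping[str, float] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Draw one FF/FFPE count pair at contamination fraction ``c``.

    The FF community is a Dirichlet perturbation of ``ff_base`` (patient
    effect) sampled multinomially at the configured depth. The FFPE profile
    mixes the dropout-scaled, renormalised FF profile with the contaminant
    pool as ``(1-c) * ff + c * pool``, so the expected contaminant-role
    relative abundance equals ``c`` exactly.
    """
    if not 0.0 <= c <= 1.0:
        raise ValidationError(f"contamination fraction {c} outside [0, 1]")
    config = config or SimulationConfig()
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dropout = config.dropout if dropout is None else dropout

    base = ff_base.abundances
    patient = rng.dirichlet(config.dirichlet_concentration * base)

    ff_ids, ff_probs, _ = _expand_to_asvs(ff_base, patient, config.asvs_per_taxon)
    ff_counts = pd.Series(
        rng.multinomial(config.depth, ff_probs), index=ff_ids, name="FF"
    )

    mult = np.array([dropout.get(t.role, 1.0) for t in ff_base.taxa])
    scaled = patient * mult
    if scaled.sum() <= 0:
        raise ValidationError("dropout removed all FF mass")
    scaled = scaled / scaled.sum()
    pool_ids, pool_probs, _ = _expand_to_asvs(
        contaminant_pool, contaminant_pool.abundances, config.asvs_per_taxon
    )
    _, ffpe_ff_probs, _ = _expand_to_asvs(ff_base, scaled, config.asvs_per_taxon)
    ids = ff_ids + pool_ids
    probs = np.concatenate([(1.0 - c) * ffpe_ff_probs, c * pool_probs])
    ffpe_counts = pd.Series(
        rng.multinomial(config.depth, probs), index=ids, name="FFPE"
    )
    return ff_counts, ffpe_counts


def simulate_cohort(config: SimulationConfig | None = None) -> PairedCohort:
    """Generate the full paired cohort: tissue pairs, NTC, host reads,
    singletons, taxonomy, metadata and ground truth."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    ff_base, pool = make_default_profiles()
    gradient = config.contamination_gradient()

    n_asv = config.asvs_per_taxon
    pool_ids, pool_probs, pool_owners = _expand_to_asvs(
        pool, pool.abundances, n_asv
    )
    shared_mask = _ntc_shared_mask(pool, n_asv)

    columns: dict[str, pd.Series] = {}
    meta_rows = []
    truth = GroundTruth(
        contamination={},
        ff_profiles={},
        euk_reads={},
        singleton_asvs={},
        contaminant_asvs=list(pool_ids),
        ntc_shared_asvs=[a for a, m in zip(pool_ids, shared_mask) if m],
        ff_favoured_taxa=sorted(
            t.genus for t in ff_base.taxa if t.role in ("crc_marker", "archaeal")
        ),
        ffpe_favoured_taxa=sorted(t.genus for t in pool.taxa),
        true_comparability={},
    )

    euk_ids = [f"ASV_{HOST_TAXON.genus}_{k:02d}" for k in range(1, 6)]
    euk_split = _within_taxon_split(len(euk_ids))

    for i, c in enumerate(gradient, start=1):
        patient = f"P{i:02d}"
        ff_sample, ffpe_sample = f"{patient}-FF", f"{patient}-FFPE"
        base = ff_base.abundances
        patient_profile = rng.dirichlet(config.dirichlet_concentration * base)
        ff_ids, ff_probs, _ = _expand_to_asvs(ff_base, patient_profile, n_asv)
        ff_counts = pd.Series(rng.multinomial(config.depth, ff_probs), index=ff_ids)

        mult = np.array([config.dropout.get(t.role, 1.0) for t in ff_base.taxa])
        scaled = patient_profile * mult
        scaled = scaled / scaled.sum()
        _, ffpe_ff_probs, _ = _expand_to_asvs(ff_base, scaled, n_asv)
        probs = np.concatenate([(1.0 - c) * ffpe_ff_probs, c * pool_probs])
        ffpe_counts = pd.Series(
            rng.multinomial(config.depth, probs), index=ff_ids + pool_ids
        )

        for sample, counts, frac in (
            (ff_sample, ff_counts, config.eukaryote_fraction_ff),
            (ffpe_sample, ffpe_counts, config.eukaryote_fraction_ffpe),
        ):
            n_euk = int(round(config.depth * frac / (1.0 - frac)))
            euk_counts = pd.Series(
                rng.multinomial(n_euk, euk_split), index=euk_ids
            )
            counts = pd.concat([counts, euk_counts])
            n_single = int(rng.poisson(config.singleton_rate))
            singles = [f"ASV_singleton_{sample}_{j:02d}" for j in range(1, n_single + 1)]
            counts = pd.concat(
                [counts, pd.Series(np.ones(n_single, dtype=np.int64), index=singles)]
            )
            columns[sample] = counts
            truth.euk_reads[sample] = n_euk
            truth.singleton_asvs[sample] = singles

        meta_rows.append({"sample_id": ff_sample, "patient_id": patient, "preservation": "FF"})
        meta_rows.append({"sample_id": ffpe_sample, "patient_id": patient, "preservation": "FFPE"})
        truth.contamination[patient] = float(c)
        truth.ff_profiles[patient] = patient_profile
        truth.true_comparability[patient] = (
            "high" if c <= GroundTruth.COMPARABILITY_C_MAX else "low"
        )

    # No-template control: reagent-type contaminant ASVs only.
    ntc_probs = np.where(shared_mask, pool_probs, 0.0)
    ntc_probs = ntc_probs / ntc_probs.sum()
    columns["NTC"] = pd.Series(
        rng.multinomial(config.ntc_depth, ntc_probs), index=pool_ids
    )
    meta_rows.append({"sample_id": "NTC", "patient_id": "", "preservation": "NTC"})

    counts = pd.DataFrame(columns).fillna(0).astype(np.int64)
    table = AsvTable(counts).sorted()

    lineage_rows: dict[str, tuple] = {}
    for taxon in list(ff_base.taxa) + list(pool.taxa):
        for asv in _asv_ids_for(taxon, _n_asvs(taxon, n_asv)):
            lineage_rows[asv] = taxon.lineage
    for asv in euk_ids:
        lineage_rows[asv] = HOST_TAXON.lineage
    unknown = ("Bacteria",) + (UNASSIGNED,) * 5
    for singles in truth.singleton_asvs.values():
        for asv in singles:
            lineage_rows[asv] = unknown
    taxonomy = TaxonomyTable(
        pd.DataFrame.from_dict(dict(lineage_rows), orient="index", columns=list(RANKS))
    ).sorted()

    metadata = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id")).sorted()
    return PairedCohort(table, taxonomy, metadata, truth, config)


# ---------------------------------------------------------------------------
# RNA-ISH counts
# ---------------------------------------------------------------------------

#: Default negative-binomial means (tumor, normal) per probe. Tumor-associated
#: probes have tumor mean far above the mucosal background; the contaminant-
#: mode Propionibacterium signal is region-independent.
DEFAULT_ISH_MEANS: dict[str, tuple[float, float]] = {
    "total_bacteria": (600.0, 40.0),
    "Fusobacterium": (300.0, 5.0),
    "Bacteroides": (250.0, 5.0),
    "Propionibacterium": (150.0, 150.0),
}

ISH_DISPERSION = 10.0  # NB size parameter; smaller = noisier sections


def simulate_ish_counts(
    cohort: PairedCohort,
    seed: int = 0,
    means: Mapping[str, tuple[float, float]] | None = None,
    low_biomass_samples: Sequence[str] = (),
    dispersion: float = ISH_DISPERSION,
) -> IshCountTable:
    """Draw per-probe tumor/normal ISH signal counts for each FFPE sample.

    Counts are negative-binomial around the configured region means.
    Samples listed in ``low_biomass_samples`` are drawn with suppressed
    signal and capped so their whole-section total-bacteria count stays
    below 100, guaranteeing they fail ISH quality control.
    """
    means = dict(DEFAULT_ISH_MEANS if means is None else means)
    rng = np.random.default_rng(seed)
    low = set(low_biomass_samples)
    rows = []
    for sample in cohort.metadata.samples_of("FFPE"):
        for probe, (mu_t, mu_n) in means.items():
            if sample in low:
                # Suppressed section: tiny means, hard cap keeps total < 100.
                tumor = min(int(rng.poisson(15)), 60)
                normal = min(int(rng.poisson(5)), 39)
            else:
                tumor = int(rng.negative_binomial(dispersion, dispersion / (dispersion + mu_t)))
                normal = int(rng.negative_binomial(dispersion, dispersion / (dispersion + mu_n)))
            rows.append(
                {
                    "sample_id": sample,
                    "probe": probe,
                    "tumor": tumor,
                    "normal": normal,
                    "total": tumor + normal,
                }
            )
    frame = pd.DataFrame(rows).set_index(["sample_id", "probe"])
    return IshCountTable(frame)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    truth.to_frame().to_csv(path, sep="\t")
    return path
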