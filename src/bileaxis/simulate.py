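"""Synthetic two-group cohort generator with planted, recoverable ground truth.

Every input the analysis pipeline consumes — gene-catalogue relative
abundances, enzyme alignment hits, per-gene taxonomy hits, the targeted
faecal bile-acid panel and the clinical covariate table — can be generated
here with known effects, so that each downstream stage can be checked
against the planted truth rather than against unavailable patient data.

The statistical model is deliberately simple and mirrors what the analysis
assumes: heavy-tailed log-normal abundances closed to a compositional sum
of one, multiplicative (log-scale) group effects applied to atrial
fibrillation (AF) samples, a log-normal bile-acid panel, and a log-normal
FGF19 with a controlled negative correlation to left atrial diameter (LAD).

Group coding is AF = 1, control = 0 throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .vocab import (
    BA_PANEL,
    BAI_GENES,
    ENZYMES,
    HSDH_ALPHA,
    HSDH_BETA,
    RANKS,
    genus_lineage,
    genus_pool,
)

AF_LABEL = "AF"
CONTROL_LABEL = "control"

# Planted log2 effects sized so the matched downstream test detects each of
# them with comfortably more than 80% power at the default cohort sizes
# (50/50 for the metagenome, 23/23 for the BA panel).  Directions follow the
# observed biology: microbial BA-transforming genes are depleted in AF,
# while most panel BAs rise and the LCA family falls.
DEFAULT_ENZYME_EFFECTS: Mapping[str, float] = {
    HSDH_ALPHA: -1.5,
    HSDH_BETA: -1.0,
    "BaiA": -1.0,
    "BaiA2": -1.0,
    "BaiH": -2.0,
    "BaiCD": -2.0,
    "BaiN": -1.5,
}

_BA_UP = (
    "UDCA", "bUDCA", "HCA", "7-KetoLCA", "3-DHCA", "6-KetoLCA",
    "CDCA", "TCA", "CA", "GUDCA", "TCDCA", "TUDCA",
)
_BA_DOWN = ("dehydroLCA", "12-KetoLCA", "LCA", "GDCA")

DEFAULT_BA_EFFECTS: Mapping[str, float] = {
    **{name: 2.0 for name in _BA_UP},
    **{name: -1.5 for name in _BA_DOWN},
}

#: Baseline faecal concentration medians (nmol/g) in the control group.
#: Chosen so the panel is dominated by free secondary BAs (DCA, LCA), as in
#: adult faeces, which makes the planted primary-BA enrichment drive the
#: secondary-proportion decrease in AF.
DEFAULT_BA_BASELINE: Mapping[str, float] = {
    "CA": 250.0, "CDCA": 180.0, "TCA": 25.0, "TCDCA": 18.0,
    "GCA": 20.0, "GCDCA": 15.0,
    "DCA": 450.0, "LCA": 280.0, "UDCA": 35.0, "bUDCA": 8.0,
    "HCA": 12.0, "7-KetoLCA": 15.0, "3-DHCA": 10.0, "6-KetoLCA": 8.0,
    "dehydroLCA": 20.0, "12-KetoLCA": 60.0, "GDCA": 25.0, "GUDCA": 6.0,
    "TUDCA": 4.0, "TDCA": 10.0, "GLCA": 5.0, "TLCA": 4.0,
    "HDCA": 30.0, "7-KetoDCA": 12.0,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Effects are log2 shifts applied multiplicatively to AF samples;
    ``fgf19_effect`` is a natural-log shift of the FGF19 median and
    ``fgf19_lad_rho`` is the target Pearson correlation between raw FGF19
    (pg/mL) and LAD (mm) within group.
    """

    n_af: int = 50
    n_control: int = 50
    n_genes: int = 300
    n_genera: int = 40
    enzyme_effect_map: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENZYME_EFFECTS))
    ba_effect_map: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BA_EFFECTS))
    ba_cv: float = 0.8
    fgf19_effect: float = -0.51
    fgf19_lad_rho: float = -0.3
    seed: int = 0

    # metagenome structure
    gene_log_sigma: float = 1.0
    n_bai_complete_genera: int = 4
    n_hsdh_pair_genera: int = 6
    scatter_genes_per_enzyme: int = 2
    max_decoy_hits: int = 3
    confounder_rate: float = 0.0

    # BA panel
    ba_baseline: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BA_BASELINE))

    # clinical generating parameters
    fgf19_log_median: float = math.log(232.779)
    fgf19_log_sigma: float = 0.70
    lad_mean: float = 37.0
    lad_sd: float = 4.0
    lad_effect: float = 4.0
    lvef_mean: float = 64.0
    lvef_sd: float = 5.0
    lvef_effect: float = -4.0
    dm_prev_control: float = 0.20
    dm_prev_af: float = 0.15
    age_mean: float = 61.0
    age_sd: float = 11.0
    bmi_mean: float = 26.3
    bmi_sd: float = 3.4
    sex_p: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_af", "n_control", "n_genes", "n_genera"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.ba_cv <= 0:
            raise ConfigurationError("ba_cv must be positive")
        if not abs(self.fgf19_lad_rho) < 1:
            raise ConfigurationError("|fgf19_lad_rho| must be < 1")
        unknown = set(self.enzyme_effect_map) - set(ENZYMES)
        if unknown:
            raise ConfigurationError(
                f"effects for unknown enzymes: {sorted(unknown)}")
        unknown = set(self.ba_effect_map) - set(BA_PANEL)
        if unknown:
            raise ConfigurationError(f"effects for unknown BAs: {sorted(unknown)}")
        missing = set(BA_PANEL) - set(self.ba_baseline)
        if missing:
            raise ConfigurationError(f"baseline missing for BAs: {sorted(missing)}")
        if self.confounder_rate < 0 or self.confounder_rate > 1:
            raise ConfigurationError("confounder_rate must be in [0, 1]")

    # stage-specific cohort sizes used by the end-to-end pipeline
    @classmethod
    def metagenome_default(cls, seed: int = 0, **kw) -> "SimulationConfig":
        return cls(n_af=50, n_control=50, seed=seed, **kw)

    @classmethod
    def ba_panel_default(cls, seed: int = 0, **kw) -> "SimulationConfig":
        return cls(n_af=23, n_control=23, seed=seed, **kw)

    @classmethod
    def clinical_default(cls, seed: int = 0, **kw) -> "SimulationConfig":
        return cls(n_af=36, n_control=24, seed=seed, **kw)


@dataclass
class SimulationTruth:
    """Planted ground truth; the recovery oracle for every pipeline stage."""

    gene_enzyme: dict[str, str] = field(default_factory=dict)
    gene_genus: dict[str, str] = field(default_factory=dict)
    genus_enzymes: dict[str, list[str]] = field(default_factory=dict)
    affected_enzymes: dict[str, str] = field(default_factory=dict)
    affected_bas: dict[str, str] = field(default_factory=dict)
    clinical_params: dict[str, float] = field(default_factory=dict)

    def producer_counts(
        self,
        pathways: Mapping[str, frozenset[str] | set[str]],
        bai_min_count: int = 5,
    ) -> dict[str, int]:
        """Producer-set sizes implied by the planted genus/enzyme layout."""
        counts = {}
        for pw, enzymes in pathways.items():
            counts[pw] = sum(
                1 for present in self.genus_enzymes.values()
                if set(present) & set(enzymes))
        counts["hsdh_pair"] = sum(
            1 for present in self.genus_enzymes.values()
            if {HSDH_ALPHA, HSDH_BETA} <= set(present))
        counts["bai_complete"] = sum(
            1 for present in self.genus_enzymes.values()
            if len(set(present) & set(BAI_GENES)) >= bai_min_count)
        return counts

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["genus_enzymes"] = {
            g: sorted(es) for g, es in self.genus_enzymes.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


@dataclass
class GeneAbundanceTable:
    """Relative gene abundances (genes x samples) with group labels."""

    abundance: pd.DataFrame
    groups: pd.Series


@dataclass
class BAPanelTable:
    """Faecal BA concentrations (samples x BAs, nmol/g) with group labels."""

    values: pd.DataFrame
    groups: pd.Series


def _sample_ids(config: SimulationConfig) -> tuple[list[str], pd.Series]:
    ids = [f"AF{i + 1:03d}" for i in range(config.n_af)]
    ids += [f"CTL{i + 1:03d}" for i in range(config.n_control)]
    groups = pd.Series(
        [AF_LABEL] * config.n_af + [CONTROL_LABEL] * config.n_control,
        index=ids, name="group")
    return ids, groups


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _allocate_genes(config: SimulationConfig, rng: np.random.Generator):
    """Lay out enzyme genes over genera with exactly known producer sets.

    Genus roles are disjoint: a few genera carry a 5-6 gene bai operon, a
    few carry both HSDHs, and each enzyme additionally gets dedicated
    single-enzyme "scatter" genera.  Disjoint roles make the pathway,
    HSDH-pair and bai-complete counts exact functions of the configuration.
    """
    k, m = config.n_bai_complete_genera, config.n_hsdh_pair_genera
    need = k + m + len(ENZYMES)
    if config.n_genera < need + 1:
        raise ConfigurationError(
            f"n_genera={config.n_genera} too small for the planted layout "
            f"(needs at least {need + 1})")
    genera = genus_pool(config.n_genera)
    complete = genera[:k]
    pairs = genera[k:k + m]
    scatter = genera[k + m:k + m + len(ENZYMES)]

    plan: list[tuple[str, str]] = []  # (enzyme, genus)
    for i, genus in enumerate(complete):
        n_bai = 5 + (i % 2)
        for enz in rng.choice(BAI_GENES, size=n_bai, replace=False):
            plan.append((str(enz), genus))
    for genus in pairs:
        plan.append((HSDH_ALPHA, genus))
        plan.append((HSDH_BETA, genus))
    for enz, genus in zip(ENZYMES, scatter):
        for _ in range(config.scatter_genes_per_enzyme):
            plan.append((enz, genus))

    if config.n_genes < len(plan) + 10:
        raise ConfigurationError(
            f"n_genes={config.n_genes} too small; the enzyme layout uses "
            f"{len(plan)} genes")

    gene_ids = [f"gene_{i + 1:05d}" for i in range(config.n_genes)]
    gene_enzyme: dict[str, str] = {}
    gene_genus: dict[str, str] = {}
    for gid, (enz, genus) in zip(gene_ids, plan):
        gene_enzyme[gid] = enz
        gene_genus[gid] = genus
    for gid in gene_ids[len(plan):]:
        gene_genus[gid] = str(rng.choice(genera))
    return gene_ids, gene_enzyme, gene_genus


def simulate_metagenome(config: SimulationConfig):
    """Generate gene abundances, enzyme hits, taxonomy hits and their truth.

    Returns
    -------
    (GeneAbundanceTable, hits, taxhits, SimulationTruth)
        ``hits`` has columns gene_id, enzyme, pident, evalue, bitscore;
        ``taxhits`` has gene_id, evalue and the seven rank columns.
    """
    rng_alloc = _rng(config.seed, 10)
    rng_abund = _rng(config.seed, 11)
    rng_hits = _rng(config.seed, 12)
    rng_tax = _rng(config.seed, 13)

    gene_ids, gene_enzyme, gene_genus = _allocate_genes(config, rng_alloc)
    samples, groups = _sample_ids(config)
    n = len(samples)

    base = rng_abund.normal(0.0, 1.0, size=config.n_genes)
    z = rng_abund.standard_normal((config.n_genes, n))
    raw = np.exp(base[:, None] + config.gene_log_sigma * z)

    af_mask = (groups.values == AF_LABEL)
    log2_eff = np.array([
        config.enzyme_effect_map.get(gene_enzyme.get(g, ""), 0.0)
        for g in gene_ids])
    raw[:, af_mask] *= np.exp2(log2_eff)[:, None]
    abundance = pd.DataFrame(
        raw / raw.sum(axis=0, keepdims=True), index=gene_ids, columns=samples)

    # enzyme hits: true enzyme is always the top hit; off-target hits sit
    # either far outside the 10x e-value window or (sometimes) inside it but
    # with a worse e-value, so best-hit assignment recovers the truth.
    hit_rows = []
    other = {e: [x for x in ENZYMES if x != e] for e in ENZYMES}
    for gid in gene_ids:
        enz = gene_enzyme.get(gid)
        if enz is None:
            continue
        top_e = 10.0 ** rng_hits.uniform(-180, -30)
        top_bits = rng_hits.uniform(300, 900)
        hit_rows.append((gid, enz, rng_hits.uniform(80, 100), top_e, top_bits))
        n_off = int(rng_hits.integers(0, 3))
        for _ in range(n_off):
            decoy = str(rng_hits.choice(other[enz]))
            if rng_hits.random() < 0.3:  # within the 10x window, still worse
                e_off = top_e * 10.0 ** rng_hits.uniform(0.2, 0.9)
            else:
                e_off = top_e * 10.0 ** rng_hits.uniform(1.5, 8.0)
            hit_rows.append((
                gid, decoy, rng_hits.uniform(40, 80), min(e_off, 1e-5),
                top_bits * rng_hits.uniform(0.3, 0.8)))
    hits = pd.DataFrame(
        hit_rows, columns=["gene_id", "enzyme", "pident", "evalue", "bitscore"])

    # taxonomy hits: top hit carries the planted genus; decoys are strictly
    # beyond the 10x rule, optional confounders sit inside it.
    genera = genus_pool(config.n_genera)
    tax_rows = []
    for gid in gene_ids:
        genus = gene_genus[gid]
        top_e = 10.0 ** rng_tax.uniform(-100, -10)
        tax_rows.append((gid, top_e) + genus_lineage(genus))
        if config.confounder_rate and rng_tax.random() < config.confounder_rate:
            decoy = str(rng_tax.choice([g for g in genera if g != genus]))
            e_in = top_e * 10.0 ** rng_tax.uniform(0.1, 0.9)
            tax_rows.append((gid, e_in) + genus_lineage(decoy))
        for _ in range(int(rng_tax.integers(0, config.max_decoy_hits + 1))):
            decoy = str(rng_tax.choice([g for g in genera if g != genus]))
            e_out = min(top_e * 10.0 ** rng_tax.uniform(1.1, 5.0), 1.0)
            tax_rows.append((gid, e_out) + genus_lineage(decoy))
    taxhits = pd.DataFrame(tax_rows, columns=["gene_id", "evalue", *RANKS])

    genus_enzymes: dict[str, set[str]] = {}
    for gid, enz in gene_enzyme.items():
        genus_enzymes.setdefault(gene_genus[gid], set()).add(enz)
    truth = SimulationTruth(
        gene_enzyme=dict(gene_enzyme),
        gene_genus=dict(gene_genus),
        genus_enzymes={g: sorted(es) for g, es in genus_enzymes.items()},
        affected_enzymes={
            e: ("up-in-AF" if eff > 0 else "down-in-AF")
            for e, eff in config.enzyme_effect_map.items() if eff != 0},
    )
    return GeneAbundanceTable(abundance, groups), hits, taxhits, truth


def simulate_ba_panel(config: SimulationConfig):
    """Generate the samples x 24 faecal BA concentration table (nmol/g)."""
    rng = _rng(config.seed, 21)
    samples, groups = _sample_ids(config)
    sigma = math.sqrt(math.log1p(config.ba_cv ** 2))
    mu = np.log([config.ba_baseline[ba] for ba in BA_PANEL])
    z = rng.standard_normal((len(samples), len(BA_PANEL)))
    values = np.exp(mu[None, :] + sigma * z)
    eff = np.array([config.ba_effect_map.get(ba, 0.0) for ba in BA_PANEL])
    af_mask = (groups.values == AF_LABEL)
    values[af_mask, :] *= np.exp2(eff)[None, :]
    panel = pd.DataFrame(values, index=samples, columns=list(BA_PANEL))
    truth = SimulationTruth(
        affected_bas={
            ba: ("up-in-AF" if e > 0 else "down-in-AF")
            for ba, e in config.ba_effect_map.items() if e != 0})
    return BAPanelTable(panel, groups), truth


def _latent_rho(rho_target: float, sigma: float) -> float:
    """Gaussian-copula correlation giving Pearson rho_target between
    exp(sigma*Z1) and Z2 (lognormal marker vs normal covariate)."""
    inflation = math.sqrt(math.expm1(sigma ** 2)) / sigma
    latent = rho_target * inflation
    if abs(latent) >= 1:
        raise ConfigurationError(
            f"fgf19_lad_rho={rho_target} unattainable with "
            f"fgf19_log_sigma={sigma} (needs latent correlation {latent:.3f})")
    return latent


def simulate_clinical(config: SimulationConfig):
    """Generate the clinical covariate table.

    FGF19 is log-normal with a negative AF shift; LAD is normal with a
    controlled negative correlation to FGF19 and a positive AF shift; LVEF,
    age and BMI are normal; DM and sex are Bernoulli.
    """
    rng = _rng(config.seed, 31)
    subjects, groups = _sample_ids(config)
    n = len(subjects)
    af = (groups.values == AF_LABEL)

    latent = _latent_rho(config.fgf19_lad_rho, config.fgf19_log_sigma)
    z_f = rng.standard_normal(n)
    z_e = rng.standard_normal(n)
    log_fgf19 = (config.fgf19_log_median + config.fgf19_effect * af
                 + config.fgf19_log_sigma * z_f)
    z_lad = latent * z_f + math.sqrt(1 - latent ** 2) * z_e
    lad = config.lad_mean + config.lad_effect * af + config.lad_sd * z_lad

    table = pd.DataFrame({
        "group": groups.values,
        "FGF19": np.exp(log_fgf19),
        "LAD": lad,
        "LVEF": (config.lvef_mean + config.lvef_effect * af
                 + config.lvef_sd * rng.standard_normal(n)),
        "DM": (rng.random(n) < np.where(
            af, config.dm_prev_af, config.dm_prev_control)).astype(int),
        "age": config.age_mean + config.age_sd * rng.standard_normal(n),
        "sex": (rng.random(n) < config.sex_p).astype(int),
        "BMI": config.bmi_mean + config.bmi_sd * rng.standard_normal(n),
    }, index=pd.Index(subjects, name="subject_id"))

    truth = SimulationTruth(clinical_params={
        "fgf19_log_median": config.fgf19_log_median,
        "fgf19_effect": config.fgf19_effect,
        "fgf19_log_sigma": config.fgf19_log_sigma,
        "fgf19_lad_rho": config.fgf19_lad_rho,
        "lad_mean": config.lad_mean,
        "lad_effect": config.lad_effect,
        "lvef_effect": config.lvef_effect,
    })
    return table, truth
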