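"""End-to-end orchestration: simulate -> profile -> producers -> metabolome
-> clinical, with a consolidated machine-readable report.

Every stage either consumes files written by an earlier run (or an external
provider of the same dialects) or regenerates them from the synthetic
cohort.  Any stage failure aborts with an error naming the stage; outputs
written so far are left in place.  Reports carry the seed and every
threshold for provenance and contain no timestamps, so a rerun with the
same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .vocab import ENZYMES
from .simulate import (
    AF_LABEL,
    SimulationConfig,
    simulate_ba_panel,
    simulate_clinical,
    simulate_metagenome,
)
from .profiling import (
    assign_enzyme,
    compute_enzyme_profile,
    differential_features,
    filter_significant_hits,
    genus_of,
    lca_assign,
)
from .producers import (
    PathwayMap,
    build_genus_enzyme_matrix,
    classify_producers,
    correlation_network,
    network_to_graphml,
)
from .metabolomics import differential_bas, pca_scores, summarize_composition
from .opls import fit_oplsda, vip_select
from .roc import roc_analysis
from .clinical import (
    baseline_table,
    fit_logistic,
    pearson_correlation,
    univariate_screen,
)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    With ``simulate=True`` all inputs are generated from ``seed`` at the
    configured cohort sizes; otherwise the ``*_path`` fields must point at
    existing files in the documented dialects.
    """

    outdir: str = "bileaxis_out"
    seed: int = 0
    simulate: bool = True

    # input paths (used when simulate is False)
    abundance_path: str | None = None
    hits_path: str | None = None
    refmap_path: str | None = None
    taxhits_path: str | None = None
    groups_path: str | None = None
    panel_path: str | None = None
    panel_groups_path: str | None = None
    clinical_path: str | None = None

    # analysis thresholds
    hit_factor: float = 10.0
    vip_threshold: float = 1.0
    network_p: float = 0.05
    screen_alpha: float = 0.100
    bai_min_count: int = 5
    n_orthogonal: int = 1
    forced_covariates: tuple[str, ...] = ("DM",)

    # simulation overrides applied to every stage config
    simulation_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "forced_covariates" in raw:
            raw["forced_covariates"] = tuple(raw["forced_covariates"])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
        return [_jsonable(v) for v in seq]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (pd.Series,)):
        return _jsonable(obj.to_dict())
    return obj


def _stage(name):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as err:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineStageError(name, err) from err
        return wrapped
    return decorator


@_stage("inputs")
def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate:
        meta_cfg = SimulationConfig.metagenome_default(
            seed=config.seed, **config.simulation_overrides)
        ba_cfg = SimulationConfig.ba_panel_default(
            seed=config.seed, **config.simulation_overrides)
        clin_cfg = SimulationConfig.clinical_default(
            seed=config.seed, **config.simulation_overrides)
        gene_table, hits, taxhits, meta_truth = simulate_metagenome(meta_cfg)
        panel_table, ba_truth = simulate_ba_panel(ba_cfg)
        clinical, clin_truth = simulate_clinical(clin_cfg)

        sim_dir = io.ensure_dir(outdir / "inputs")
        io.write_abundance(gene_table.abundance, sim_dir / "gene_abundance.tsv")
        io.write_groups(gene_table.groups, sim_dir / "metagenome_groups.tsv")
        io.write_enzyme_hits(
            hits, sim_dir / "enzyme_hits.tsv", sim_dir / "enzyme_refmap.tsv")
        io.write_taxhits(taxhits, sim_dir / "taxonomy_hits.tsv")
        io.write_ba_panel(panel_table.values, sim_dir / "ba_panel.csv")
        io.write_groups(panel_table.groups, sim_dir / "ba_groups.tsv")
        io.write_clinical(clinical, sim_dir / "clinical.csv")
        meta_truth.to_json(sim_dir / "metagenome_truth.json")
        ba_truth.to_json(sim_dir / "ba_truth.json")
        clin_truth.to_json(sim_dir / "clinical_truth.json")
        return (gene_table.abundance, gene_table.groups, hits, taxhits,
                panel_table.values, panel_table.groups, clinical)

    required = {
        "abundance_path": config.abundance_path,
        "hits_path": config.hits_path,
        "refmap_path": config.refmap_path,
        "taxhits_path": config.taxhits_path,
        "groups_path": config.groups_path,
        "panel_path": config.panel_path,
        "panel_groups_path": config.panel_groups_path,
        "clinical_path": config.clinical_path,
    }
    missing = [k for k, v in required.items() if v is None or not Path(v).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    return (
        io.read_abundance(config.abundance_path),
        io.read_groups(config.groups_path),
        io.read_enzyme_hits(config.hits_path, config.refmap_path),
        io.read_taxhits(config.taxhits_path),
        io.read_ba_panel(config.panel_path),
        io.read_groups(config.panel_groups_path),
        io.read_clinical(config.clinical_path),
    )


@_stage("profile")
def _run_profile(config, outdir, abundance, groups, hits, taxhits):
    retained = filter_significant_hits(hits, factor=config.hit_factor)
    assignments = assign_enzyme(retained)
    profile = compute_enzyme_profile(assignments, abundance, enzymes=ENZYMES)
    diff_enzymes = differential_features(profile, groups)
    lineages = lca_assign(taxhits, factor=config.hit_factor)

    stage_dir = io.ensure_dir(outdir / "profile")
    profile.rename_axis("enzyme").to_csv(stage_dir / "enzyme_profile.tsv", sep="\t")
    diff_enzymes.to_csv(stage_dir / "differential_enzymes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, ";".join(lin)) for g, lin in sorted(lineages.items())],
        columns=["gene_id", "lineage"],
    ).to_csv(stage_dir / "gene_lca.tsv", sep="\t", index=False)
    return assignments, profile, diff_enzymes, lineages


@_stage("producers")
def _run_producers(config, outdir, assignments, lineages, abundance,
                   profile, groups):
    matrix = build_genus_enzyme_matrix(assignments, lineages, abundance)
    pathway_map = PathwayMap(bai_min_count=config.bai_min_count)
    report = classify_producers(matrix, pathway_map)

    genus_rows = {}
    for gene, lineage in lineages.items():
        genus = genus_of(lineage)
        if genus is not None and gene in abundance.index:
            genus_rows.setdefault(genus, []).append(gene)
    genus_abundance = pd.DataFrame(
        {g: abundance.loc[genes].sum(axis=0) for g, genes in sorted(genus_rows.items())}
    ).T
    genus_abundance.columns = abundance.columns
    diff_genera = differential_features(genus_abundance, groups)

    producer_genera = sorted(set().union(*report.pathway_sets.values()))
    edges = correlation_network(
        genus_abundance.loc[[g for g in producer_genera if g in genus_abundance.index]],
        profile, p_threshold=config.network_p)

    stage_dir = io.ensure_dir(outdir / "producers")
    with open(stage_dir / "producer_report.json", "w") as fh:
        json.dump(_jsonable({
            "pathway_sets": report.pathway_sets,
            "venn_counts": report.venn_counts,
            "hsdh_pair_set": report.hsdh_pair_set,
            "bai_complete_set": report.bai_complete_set,
            "counts": report.counts(),
        }), fh, indent=2, sort_keys=True)
    matrix.counts.rename_axis("genus").to_csv(stage_dir / "genus_enzyme_counts.tsv", sep="\t")
    diff_genera.to_csv(stage_dir / "differential_genera.tsv", sep="\t", index=False)
    edges.to_csv(stage_dir / "network_edges.tsv", sep="\t", index=False)
    network_to_graphml(edges, stage_dir / "network.graphml")
    return report, diff_genera, edges


@_stage("metabolome")
def _run_metabolome(config, outdir, panel, groups):
    composition = summarize_composition(panel, groups)
    diff_bas = differential_bas(panel, groups)
    pca = pca_scores(panel)
    model = fit_oplsda(panel, groups, n_orthogonal=config.n_orthogonal)
    selected = vip_select(model, threshold=config.vip_threshold, p_table=diff_bas)

    roc_results = {}
    labels = (groups.reindex(panel.index) == AF_LABEL).to_numpy()
    for ba in selected["variable"]:
        curve = roc_analysis(panel[ba].to_numpy(), labels)
        roc_results[ba] = {
            "auc": curve.auc, "ci95": list(curve.ci95),
            "cutpoint": curve.optimal_cutpoint,
            "sensitivity": curve.sens_at_cut,
            "specificity": curve.spec_at_cut,
            "orientation": curve.orientation,
        }

    stage_dir = io.ensure_dir(outdir / "metabolome")
    composition.per_sample.rename_axis("sample_id").to_csv(
        stage_dir / "composition.tsv", sep="\t")
    diff_bas.to_csv(stage_dir / "differential_bas.tsv", sep="\t", index=False)
    pca.scores.rename_axis("sample_id").to_csv(stage_dir / "pca_scores.tsv", sep="\t")
    selected.to_csv(stage_dir / "vip_selected.tsv", sep="\t", index=False)
    with open(stage_dir / "roc.json", "w") as fh:
        json.dump(_jsonable(roc_results), fh, indent=2, sort_keys=True)
    return composition, diff_bas, model, selected, roc_results


@_stage("clinical")
def _run_clinical(config, outdir, clinical):
    baseline = baseline_table(clinical)
    r, p = pearson_correlation(clinical["FGF19"], clinical["LAD"])
    screen = univariate_screen(
        clinical, alpha=config.screen_alpha, forced=config.forced_covariates)
    chosen = list(screen.loc[screen["selected"], "variable"])
    model = fit_logistic(clinical, chosen)

    stage_dir = io.ensure_dir(outdir / "clinical")
    baseline.to_csv(stage_dir / "baseline_table.tsv", sep="\t", index=False)
    screen.to_csv(stage_dir / "univariate_screen.tsv", sep="\t", index=False)
    model.table().rename_axis("term").to_csv(
        stage_dir / "multivariable_model.tsv", sep="\t")
    return baseline, (r, p), screen, model


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the consolidated report under ``outdir``."""
    outdir = io.ensure_dir(config.outdir)
    (abundance, groups, hits, taxhits,
     panel, panel_groups, clinical) = _load_inputs(config, outdir)

    assignments, profile, diff_enzymes, lineages = _run_profile(
        config, outdir, abundance, groups, hits, taxhits)
    producer_report, diff_genera, edges = _run_producers(
        config, outdir, assignments, lineages, abundance, profile, groups)
    composition, diff_bas, opls_model, selected, roc_results = _run_metabolome(
        config, outdir, panel, panel_groups)
    baseline, (r, p_corr), screen, logit_model = _run_clinical(
        config, outdir, clinical)

    sig_enzymes = diff_enzymes[diff_enzymes["p_value"] < 0.05]
    sig_genera = diff_genera[diff_genera["p_value"] < 0.05]
    sig_bas = diff_bas[diff_bas["p_value"] < 0.05]
    fgf19_af = clinical.loc[clinical["group"] == AF_LABEL, "FGF19"]
    fgf19_ctl = clinical.loc[clinical["group"] != AF_LABEL, "FGF19"]

    report = {
        "seed": config.seed,
        "thresholds": {
            "hit_factor": config.hit_factor,
            "vip_threshold": config.vip_threshold,
            "network_p": config.network_p,
            "screen_alpha": config.screen_alpha,
            "bai_min_count": config.bai_min_count,
            "n_orthogonal": config.n_orthogonal,
        },
        "profile": {
            "n_assigned_genes": len(assignments),
            "significant_enzymes": {
                row.feature: {"p": row.p_value, "direction": row.direction}
                for row in sig_enzymes.itertuples()},
        },
        "producers": {
            "counts": producer_report.counts(),
            "venn": producer_report.venn_counts,
            "n_significant_genera": int(len(sig_genera)),
            "n_network_edges": int(len(edges)),
        },
        "metabolome": {
            "secondary_prop_p": composition.p_value,
            "secondary_prop_median_AF": composition.median_prop_af,
            "secondary_prop_median_control": composition.median_prop_control,
            "n_bas_up": int((sig_bas["direction"] == "up").sum()),
            "n_bas_down": int((sig_bas["direction"] == "down").sum()),
            "opls_r2y": opls_model.r2y,
            "opls_q2": opls_model.q2,
            "vip_selected": list(selected["variable"]),
            "roc": roc_results,
        },
        "clinical": {
            "fgf19_median_AF": float(fgf19_af.median()),
            "fgf19_median_control": float(fgf19_ctl.median()),
            "fgf19_lad_pearson_r": r,
            "fgf19_lad_pearson_p": p_corr,
            "screen_selected": list(screen.loc[screen["selected"], "variable"]),
            "multivariable": _jsonable(logit_model.table().to_dict(orient="index")),
            "converged": logit_model.converged,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)

    import bileaxis

    with open(outdir / "run_log.json", "w") as fh:
        json.dump({
            "bileaxis_version": bileaxis.__version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "simulate": config.simulate,
            "thresholds": report["thresholds"],
        }, fh, indent=2, sort_keys=True)
    return report
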