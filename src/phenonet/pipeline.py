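"""End-to-end analysis pipeline with provenance.

Stages run in the prescribed order: zero-heavy descriptor filter ->
zero-heavy subject filter -> zeros-to-missing -> missing-heavy filter ->
redundancy filter (pairwise-complete polychorics) -> multiple imputation ->
rater-independence screen -> low-variation screen -> per-group polychoric
matrices -> joint gamma selection (most conservative value keeping every
group's network non-empty) -> per-group EBIC-glasso networks -> centrality
-> bootstrap group comparison -> node-wise and subject-wise stability.

All randomness flows from one master seed split per stage, so a run can be
replayed bit-identically from its manifest.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cleaning as cl
from .centrality import centrality_table
from .datasets import SurveyDataset, read_survey, write_survey
from .ggm import edge_density, select_gamma, select_network
from .impute import em_impute, pool_and_round
from .polychoric import polychoric_matrix
from .resampling import (
    bootstrap_networks,
    compare_groups,
    node_wise_stability,
    subject_wise_stability,
)
from .simulate import working_dog_survey

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "run_full",
           "replay", "summarize"]

logger = logging.getLogger(__name__)

_STAGES = [
    "cleaning", "imputation", "rater_filter", "gamma", "bootstrap_a",
    "bootstrap_b", "node_stability_a", "node_stability_b",
    "subject_stability_a", "subject_stability_b",
]


@dataclass
class PipelineConfig:
    """Every numeric choice of the analysis, serializable to YAML."""

    seed: int = 0
    # cleaning thresholds
    zero_heavy_threshold: float = 0.10
    subject_zero_threshold: float = 0.15
    missing_threshold: float = 0.05
    redundancy_threshold: float = 0.8
    variation_floor: float = 0.15
    rater_permutations: int = 500
    rater_percentile: float = 99.0
    # imputation
    m_imputations: int = 15
    em_tol: float = 1e-4
    em_max_iter: int = 200
    em_ridge: float = 1e-3
    # network estimation
    gamma: Optional[float] = None  # None: select jointly over the grid
    gamma_grid_step: float = 0.05
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    # resampling
    B_compare: int = 2000
    B_stability: int = 2000
    node_sizes: Optional[list] = None  # default: 3 .. p-1
    subject_fractions: Optional[list] = None  # default: 10 levels 0.25-0.95
    standardize_centrality: bool = False
    # data schema
    group_column: str = "group"
    rater_column: str = "rater"
    output_dir: str = "phenonet_run"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically."""

    config: dict
    data_source: dict  # {"path": ...} or {"fixture_seed": ...}
    stage_shapes: dict = field(default_factory=dict)
    gamma: float = np.nan
    per_group: dict = field(default_factory=dict)
    cleaning_report: str = ""
    version: str = ""
    started: str = ""
    finished: str = ""

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    manifest: RunManifest
    pooled: SurveyDataset
    report: cl.CleaningReport
    matrices: dict
    networks: dict
    centralities: dict
    effect_sizes: pd.DataFrame
    node_stability: dict
    subject_stability: dict


def _stage_seeds(master: int) -> dict:
    """Deterministic per-stage integer seeds below 2**31."""
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def run_full(
    config: PipelineConfig,
    data: Optional[SurveyDataset] = None,
    input_path: Optional[str] = None,
    fixture_seed: Optional[int] = None,
    write: bool = True,
) -> PipelineResult:
    """Execute the whole analysis; returns all stage outputs plus manifest."""
    from . import __version__

    if data is None:
        if input_path is not None:
            data = read_survey(input_path, config.group_column,
                               config.rater_column)
            source = {"path": str(input_path)}
        else:
            fixture_seed = config.seed if fixture_seed is None else fixture_seed
            data = working_dog_survey(fixture_seed)
            source = {"fixture_seed": int(fixture_seed)}
    else:
        source = {"path": input_path} if input_path else {"in_memory": True}

    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        data_source=source,
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    shapes = manifest.stage_shapes
    shapes["input"] = list(data.responses.shape)
    report = cl.CleaningReport()

    # -- cleaning ---------------------------------------------------------
    step_data, step = cl.filter_zero_heavy(data, config.zero_heavy_threshold)
    report.add(step)
    step_data, step = cl.filter_zero_heavy_subjects(
        step_data, config.subject_zero_threshold
    )
    report.add(step)
    step_data = cl.zeros_to_missing(step_data)
    step_data, step = cl.filter_missing_heavy(
        step_data, config.missing_threshold
    )
    report.add(step)
    step_data, step = cl.filter_redundant_pairs(
        step_data, config.redundancy_threshold
    )
    report.add(step)
    shapes["after_cleaning"] = list(step_data.responses.shape)

    # -- imputation -------------------------------------------------------
    imp = em_impute(
        step_data, m=config.m_imputations, seed=seeds["imputation"],
        tol=config.em_tol, max_iter=config.em_max_iter,
        ridge=config.em_ridge,
    )
    pooled = pool_and_round(imp)
    shapes["after_imputation"] = list(pooled.responses.shape)

    # -- post-imputation screens ------------------------------------------
    pooled, step = cl.filter_rater_dependent(
        pooled, n_permutations=config.rater_permutations,
        percentile=config.rater_percentile, seed=seeds["rater_filter"],
    )
    report.add(step)
    pooled, step = cl.filter_low_variation(pooled, config.variation_floor)
    report.add(step)
    shapes["final"] = list(pooled.responses.shape)
    manifest.cleaning_report = report.to_text()

    # -- per-group networks -----------------------------------------------
    group_names = pooled.group_names
    group_data = {g: pooled.subset_group(g) for g in group_names}
    matrices = {g: polychoric_matrix(d) for g, d in group_data.items()}
    if config.gamma is None:
        gamma = select_gamma(
            [matrices[g].rho for g in group_names],
            [group_data[g].n_subjects for g in group_names],
            gamma_grid=np.round(
                np.arange(0.0, 1.0 + 1e-9, config.gamma_grid_step), 10
            ),
            n_lambda=config.n_lambda, min_ratio=config.lambda_min_ratio,
        )
    else:
        gamma = float(config.gamma)
    manifest.gamma = gamma
    networks = {
        g: select_network(
            matrices[g].rho, group_data[g].n_subjects, gamma=gamma,
            labels=pooled.descriptor_labels, n_lambda=config.n_lambda,
            min_ratio=config.lambda_min_ratio,
        )
        for g in group_names
    }
    centralities = {
        g: centrality_table(networks[g], source=f"group={g}")
        for g in group_names
    }
    for g in group_names:
        m = networks[g]
        manifest.per_group[str(g)] = {
            "n": int(m.n), "p": int(m.p), "lambda": float(m.lambda_),
            "edges": int(m.E), "density_pct": float(edge_density(m)),
        }
        logger.info("group %s: %d edges (%.2f%%), lambda=%.4f", g, m.E,
                    edge_density(m), m.lambda_)

    # -- comparison bootstrap ---------------------------------------------
    ga, gb = group_names[0], group_names[1] if len(group_names) > 1 else None
    boot_a = bootstrap_networks(
        group_data[ga], B=config.B_compare, gamma=gamma,
        seed=seeds["bootstrap_a"], n_lambda=config.n_lambda,
        min_ratio=config.lambda_min_ratio,
    )
    effect_sizes = pd.DataFrame()
    if gb is not None:
        boot_b = bootstrap_networks(
            group_data[gb], B=config.B_compare, gamma=gamma,
            seed=seeds["bootstrap_b"], n_lambda=config.n_lambda,
            min_ratio=config.lambda_min_ratio,
        )
        effect_sizes = compare_groups(
            boot_a, boot_b, standardize=config.standardize_centrality
        )
        manifest.per_group[str(ga)]["edge_count_sd"] = boot_a.edge_count_sd()
        manifest.per_group[str(gb)]["edge_count_sd"] = boot_b.edge_count_sd()

    # -- stability ---------------------------------------------------------
    p = pooled.n_descriptors
    node_sizes = config.node_sizes or list(range(3, p))
    # cleaning may have shrunk p below configured subset sizes
    node_sizes = sorted({min(int(k), p - 1) for k in node_sizes if k >= 3})
    fractions = config.subject_fractions  # None -> module default
    node_stab, subj_stab = {}, {}
    for g, tag in zip(group_names[:2], ("a", "b")):
        node_stab[g] = node_wise_stability(
            group_data[g], sizes=node_sizes, B=config.B_stability,
            gamma=gamma, seed=seeds[f"node_stability_{tag}"],
            n_lambda=config.n_lambda, min_ratio=config.lambda_min_ratio,
        )
        subj_stab[g] = subject_wise_stability(
            group_data[g], fractions=fractions, B=config.B_stability,
            gamma=gamma, seed=seeds[f"subject_stability_{tag}"],
            n_lambda=config.n_lambda, min_ratio=config.lambda_min_ratio,
        )

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    result = PipelineResult(
        manifest=manifest, pooled=pooled, report=report, matrices=matrices,
        networks=networks, centralities=centralities,
        effect_sizes=effect_sizes, node_stability=node_stab,
        subject_stability=subj_stab,
    )
    if write:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_survey(result.pooled, outdir / "pooled_dataset.csv")
    (outdir / "cleaning_report.txt").write_text(result.report.to_text())
    for g, pm in result.matrices.items():
        pm.to_frame().to_csv(outdir / f"polychoric_{g}.csv")
    for g, m in result.networks.items():
        pd.DataFrame(m.W, index=m.labels, columns=m.labels).to_csv(
            outdir / f"network_{g}.csv"
        )
        pd.DataFrame(
            m.edge_list(), columns=["node1", "node2", "weight"]
        ).to_csv(outdir / f"edges_{g}.csv", index=False)
        pd.DataFrame(
            {"lambda": m.lambda_path, "ebic": m.ebic_path}
        ).to_csv(outdir / f"ebic_path_{g}.csv", index=False)
    for g, t in result.centralities.items():
        t.to_frame().to_csv(outdir / f"centrality_{g}.csv", index=False)
    if len(result.effect_sizes):
        result.effect_sizes.to_csv(outdir / "effect_sizes.csv", index=False)
    for g, c in result.node_stability.items():
        c.table.to_csv(outdir / f"stability_node_{g}.csv", index=False)
    for g, c in result.subject_stability.items():
        c.table.to_csv(outdir / f"stability_subject_{g}.csv", index=False)
    result.manifest.to_yaml(outdir / "manifest.yaml")
    (outdir / "summary.txt").write_text(summarize(result))


def replay(manifest_path, output_dir: Optional[str] = None) -> PipelineResult:
    """Re-execute a run from its manifest (same config, seeds and input)."""
    manifest = RunManifest.from_yaml(manifest_path)
    config = PipelineConfig(**manifest.config)
    if output_dir is not None:
        config.output_dir = output_dir
    src = manifest.data_source
    if "path" in src:
        return run_full(config, input_path=src["path"])
    if "fixture_seed" in src:
        return run_full(config, fixture_seed=src["fixture_seed"])
    raise ValueError("manifest does not record a replayable data source")


def summarize(result: PipelineResult) -> str:
    """Human-readable per-group and cross-group summary."""
    lines = []
    for g, m in result.networks.items():
        dens = edge_density(m)
        lines.append(
            f"group {g}: n={m.n}, p={m.p}, lambda={m.lambda_:.4f}, "
            f"E={m.E} edges ({dens:.2f}% of possible edges)"
        )
        t = result.centralities[g].to_frame()
        top_b = t.nlargest(3, "betweenness")["node"].tolist()
        top_s = t.nlargest(3, "strength")["node"].tolist()
        lines.append(f"  top betweenness: {', '.join(top_b)}")
        lines.append(f"  top strength:    {', '.join(top_s)}")
    if len(result.effect_sizes):
        es = result.effect_sizes.reindex(
            result.effect_sizes["delta"].abs().sort_values(
                ascending=False
            ).index
        )
        lines.append("Cliff's delta (|delta| descending; |d|<0.25 negligible):")
        for _, r in es.iterrows():
            flag = " (negligible)" if r["negligible"] else ""
            lines.append(
                f"  {r['descriptor']}: delta={r['delta']:+.3f} "
                f"[{r['ci_low']:+.3f}, {r['ci_high']:+.3f}]{flag}"
            )
    for kind, curves in (("node-wise", result.node_stability),
                         ("subject-wise", result.subject_stability)):
        for g, c in curves.items():
            lines.append(f"{kind} stability, group {g}:")
            for _, r in c.table.iterrows():
                lines.append(
                    f"  level {r['level']:g} [{r['metric']}]: "
                    f"r={r['pearson']:.3f}, rho={r['spearman']:.3f} "
                    f"({int(r['n_success'])} replicates)"
                )
    return "\n".join(lines) + "\n"
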