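"""Pipeline orchestration: chain the analysis stages and write their outputs.

Stages: physiology (indices + drought-period classification) -> differential
expression (per genotype, with the development-dependent exclusion) ->
metabolome (normalization, per-period OPLS-DA, DM calls) -> integration
(correlation layers, enrichment, key metabolites, candidate mining).
Outputs are a pure function of (inputs, config); a run log records the
config, seed and library versions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from . import deg, integrate, io, metabolome, physiology

logger = logging.getLogger(__name__)

INPUT_KEYS = ("expression", "metabolites", "traits", "annotation", "metadata")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def bundle_paths(bundle_dir: str | Path) -> dict[str, Path]:
    d = Path(bundle_dir)
    return {
        "expression": d / "expression.tsv",
        "metabolites": d / "metabolites.csv",
        "traits": d / "traits.csv",
        "annotation": d / "annotations.gmt",
        "metadata": d / "samples.csv",
    }


@dataclass
class Inputs:
    expression: pd.DataFrame
    metabolites: pd.DataFrame
    traits: pd.DataFrame
    annotation: dict[str, tuple[str, frozenset[str]]]
    metadata: pd.DataFrame

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.metadata["genotype"].unique())


def load_inputs(paths: Mapping[str, str | Path]) -> Inputs:
    missing = [k for k in INPUT_KEYS if k not in paths or not Path(paths[k]).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    metadata = io.read_sample_metadata(paths["metadata"])
    return Inputs(
        expression=io.read_expression_matrix(paths["expression"], metadata),
        metabolites=io.read_metabolite_table(paths["metabolites"], metadata),
        traits=io.read_trait_table(paths["traits"]),
        annotation=io.read_annotation_gmt(paths["annotation"]),
        metadata=metadata,
    )


def stage_physiology(inputs: Inputs, config: AnalysisConfig) -> dict:
    index_table = physiology.physiology_index_table(inputs.traits, config)
    swc = physiology.drought_swc_by_timepoint(inputs.traits)
    rewatered = physiology.rewatered_timepoints(inputs.metadata)
    period_map = physiology.classify_drought_periods(swc, rewatered, config)
    swc_values = inputs.traits.loc[
        inputs.traits["condition"] == "drought", "soil_water_content"
    ].dropna()
    cv = physiology.soil_water_cv(swc_values.to_numpy()) if len(swc_values) > 1 else np.nan
    return {"index_table": index_table, "period_map": period_map, "swc_cv": cv}


def stage_deg(inputs: Inputs, config: AnalysisConfig, period_map: Mapping[str, str]) -> dict:
    tables: dict[str, pd.DataFrame] = {}
    profiles: dict[str, pd.DataFrame] = {}
    flags_by_genotype: dict[str, set[str]] = {}
    for genotype in inputs.genotypes:
        per_tp = [
            deg.call_degs(inputs.expression, inputs.metadata, genotype, tp, config)
            for tp in io.timepoint_order(inputs.metadata)
        ]
        tables[genotype] = pd.concat(per_tp, ignore_index=True)
        flags_by_genotype[genotype] = deg.flag_development_dependent(
            inputs.expression, inputs.metadata, genotype, config
        )
    if config.dev_dependent_scope == "global":
        merged = set().union(*flags_by_genotype.values())
        flags_by_genotype = {g: merged for g in flags_by_genotype}
    for genotype in inputs.genotypes:
        tables[genotype] = deg.apply_development_filter(
            tables[genotype], flags_by_genotype[genotype]
        )
        prof = deg.log2fc_profile(inputs.expression, inputs.metadata, genotype, config)
        profiles[genotype] = deg.cap_profile(prof, config.heatmap_cap_genes)
    summary = deg.summarize_deg_counts(tables, period_map)
    return {
        "tables": tables,
        "profiles": profiles,
        "development_dependent": flags_by_genotype,
        "summary": summary,
    }


def stage_metabolome(
    inputs: Inputs, config: AnalysisConfig, period_map: Mapping[str, str]
) -> dict:
    table = inputs.metabolites
    if config.metabolite_missing_policy == "drop":
        table = table.dropna(axis=0, how="any")
    normalized = metabolome.normalize_sum_intensity(table)
    shared = metabolome.shared_metabolites(normalized, inputs.metadata)
    detection = metabolome.detection_flags(normalized, inputs.metadata)
    dm_parts, models = [], {}
    for genotype in inputs.genotypes:
        dm, genotype_models = metabolome.call_differential_metabolites(
            normalized, inputs.metadata, genotype, period_map, config, restrict_to=shared
        )
        dm_parts.append(dm)
        models[genotype] = genotype_models
    dm_table = pd.concat(dm_parts, ignore_index=True) if dm_parts else pd.DataFrame(
        columns=metabolome.DM_COLUMNS
    )
    model_summary = pd.DataFrame(
        [
            (g, per, m.r2x, m.r2y, m.n_orthogonal)
            for g, ms in models.items() for per, m in ms.items()
        ],
        columns=["genotype", "period", "r2x", "r2y", "n_orthogonal"],
    )
    return {
        "normalized": normalized,
        "shared": shared,
        "detection": detection,
        "dm_table": dm_table,
        "models": models,
        "model_summary": model_summary,
    }


def stage_integrate(
    inputs: Inputs,
    config: AnalysisConfig,
    deg_results: dict,
    metab_results: dict,
    period_map: Mapping[str, str],
) -> dict:
    edges_parts = []
    gene_flags: dict[str, pd.DataFrame] = {}
    met_flags_parts = []
    candidates_parts = []
    enrichment_parts = []
    energy: dict[str, set[str]] = {}
    dm_table = metab_results["dm_table"]
    normalized = metab_results["normalized"]
    universe = set(inputs.expression.index.astype(str))

    for genotype in inputs.genotypes:
        table = deg_results["tables"][genotype]
        deg_ids = sorted(set(table.loc[table["is_deg"], "gene_id"]))
        drought_cols = io.select_samples(
            inputs.metadata, genotype=genotype, condition="drought"
        ).index.tolist()
        # correlations run on the log2 scale: FPKM and peak intensities are
        # heavily right-skewed, and Pearson on raw values is dominated by
        # the few largest observations
        gene_frame = np.log2(
            inputs.expression.loc[inputs.expression.index.isin(deg_ids), drought_cols]
            + config.fpkm_pseudocount
        )
        profiles = deg_results["profiles"][genotype].loc[
            deg_results["profiles"][genotype].index.isin(deg_ids)
        ]
        g_edges, g_flags = integrate.build_trait_correlation_layer(
            gene_frame, inputs.traits, inputs.metadata, genotype, config,
            layer="gene-trait", profiles=profiles,
        )
        g_edges = g_edges.assign(genotype=genotype)
        gene_flags[genotype] = g_flags
        edges_parts.append(g_edges)

        shared_norm = normalized.loc[normalized.index.isin(metab_results["shared"])]
        log_norm = np.log2(shared_norm)
        met_frame = log_norm[
            [c for c in drought_cols if c in log_norm.columns]
        ]
        met_profiles = None
        if config.trait_corr_mode == "profile":
            met_profiles = _metabolite_profiles(shared_norm, inputs.metadata, genotype, period_map)
        m_edges, m_flags = integrate.build_trait_correlation_layer(
            met_frame, inputs.traits, inputs.metadata, genotype, config,
            layer="metabolite-trait", profiles=met_profiles,
        )
        m_edges = m_edges.assign(genotype=genotype)
        edges_parts.append(m_edges)
        met_flags_parts.append(
            m_flags.reset_index(names="metabolite_id").assign(genotype=genotype)
        )

        dm_ids = sorted(set(dm_table.loc[
            (dm_table["is_dm"]) & (dm_table["genotype"] == genotype), "metabolite_id"
        ]))
        gm_edges = integrate.build_feature_correlation_layer(
            gene_frame, log_norm.loc[log_norm.index.isin(dm_ids), met_frame.columns],
            config,
        ).assign(genotype=genotype)
        edges_parts.append(gm_edges)

        energy[genotype] = integrate.classify_energy_related(deg_ids, inputs.annotation)
        unions = deg_results["summary"].get("period_unions", {}).get(genotype, {})
        for period, genes in sorted(unions.items()):
            for namespace, ann in _split_namespaces(inputs.annotation).items():
                enr = integrate.hypergeometric_enrichment(genes, ann, universe)
                enr.insert(0, "namespace", namespace)
                enr.insert(0, "period", period)
                enr.insert(0, "genotype", genotype)
                enrichment_parts.append(enr)

    edges = pd.concat(edges_parts, ignore_index=True) if edges_parts else pd.DataFrame(
        columns=integrate.EDGE_COLUMNS + ["genotype"]
    )
    met_flags = pd.concat(met_flags_parts, ignore_index=True) if met_flags_parts \
        else pd.DataFrame(columns=["metabolite_id", "genotype"])
    key_table = integrate.select_key_metabolites(
        dm_table, metab_results["detection"], met_flags, config
    )
    key_ids = key_table.loc[key_table["is_key"], "metabolite_id"].tolist()

    for genotype in inputs.genotypes:
        gm = edges[(edges["layer"] == "gene-metabolite") & (edges["genotype"] == genotype)]
        mined = integrate.mine_candidate_genes(
            key_ids,
            {genotype: deg_results["tables"][genotype]},
            {genotype: gene_flags[genotype]},
            gm,
            inputs.annotation,
            config,
            period_map,
        )
        candidates_parts.append(mined)
    candidates_parts = [p for p in candidates_parts if len(p)]
    candidates = (
        pd.concat(candidates_parts, ignore_index=True) if candidates_parts else pd.DataFrame()
    )
    if len(candidates):
        candidates = candidates.sort_values(
            by=["log2fc", "pathway_id", "gene_id", "genotype"],
            key=lambda s: -s.abs() if s.name == "log2fc" else s,
            kind="stable",
        ).reset_index(drop=True)

    enrichment = (
        pd.concat(enrichment_parts, ignore_index=True) if enrichment_parts else pd.DataFrame()
    )
    return {
        "edges": edges,
        "gene_flags": gene_flags,
        "metabolite_flags": met_flags,
        "key_metabolites": key_table,
        "candidates": candidates,
        "enrichment": enrichment,
        "energy_related": energy,
    }


def _metabolite_profiles(
    normalized: pd.DataFrame,
    metadata: pd.DataFrame,
    genotype: str,
    period_map: Mapping[str, str],
) -> pd.DataFrame:
    cols = {}
    for tp in sorted(period_map):
        d = io.select_samples(metadata, genotype, "drought", tp).index
        w = io.select_samples(metadata, genotype, "well_watered", tp).index
        d = [c for c in d if c in normalized.columns]
        w = [c for c in w if c in normalized.columns]
        if d and w:
            cols[tp] = metabolome.metabolite_log2fc(normalized, d, w)
    return pd.DataFrame(cols)


def _split_namespaces(
    annotation: Mapping[str, tuple[str, frozenset[str]]]
) -> dict[str, dict]:
    out: dict[str, dict] = {"GO": {}, "KEGG": {}}
    for set_id, value in annotation.items():
        namespace = "GO" if set_id.upper().startswith("GO:") else "KEGG"
        out[namespace][set_id] = value
    return {k: v for k, v in out.items() if v}


def run_pipeline(
    config: AnalysisConfig,
    input_paths: Mapping[str, str | Path],
    out_dir: str | Path,
) -> dict:
    """Run every stage and write per-stage outputs plus a run log.

    Outputs under ``out_dir``: physiology_indices.csv, period_map.csv,
    deg_<genotype>.tsv, profile_<genotype>.tsv, deg_counts.csv,
    dm_table.csv, opls_summary.csv, edges.csv, enrichment.csv,
    key_metabolites.csv, candidates.csv, run_log.json.
    Identical (inputs, config) produce byte-identical outputs.
    """
    out = Path(out_dir)

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    inputs = _stage("load", load_inputs, input_paths)
    out.mkdir(parents=True, exist_ok=True)
    phys = _stage("physiology", stage_physiology, inputs, config)
    degr = _stage("differential_expression", stage_deg, inputs, config, phys["period_map"])
    met = _stage("metabolome", stage_metabolome, inputs, config, phys["period_map"])
    integ = _stage("integration", stage_integrate, inputs, config, degr, met, phys["period_map"])

    io.write_table(phys["index_table"], out / "physiology_indices.csv", index=False)
    period_df = pd.DataFrame(
        sorted(phys["period_map"].items()), columns=["timepoint", "period"]
    )
    io.write_table(period_df, out / "period_map.csv", index=False)
    for genotype in inputs.genotypes:
        io.write_table(degr["tables"][genotype], out / f"deg_{genotype}.tsv", index=False)
        prof = degr["profiles"][genotype].copy()
        prof.index.name = "gene_id"
        io.write_table(prof, out / f"profile_{genotype}.tsv")
    io.write_table(degr["summary"]["counts"], out / "deg_counts.csv", index=False)
    io.write_table(met["dm_table"], out / "dm_table.csv", index=False)
    io.write_table(met["model_summary"], out / "opls_summary.csv", index=False)
    io.write_table(integ["edges"], out / "edges.csv", index=False)
    io.write_table(integ["enrichment"], out / "enrichment.csv", index=False)
    io.write_table(integ["key_metabolites"], out / "key_metabolites.csv", index=False)
    io.write_table(integ["candidates"], out / "candidates.csv", index=False)

    import droughtmine

    log = {
        "config": config.to_dict(),
        "seed": config.rng_seed,
        "versions": {
            "droughtmine": droughtmine.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {k: str(v) for k, v in input_paths.items()},
        "soil_water_cv_percent": None if np.isnan(phys["swc_cv"]) else round(phys["swc_cv"], 4),
        "stages": ["load", "physiology", "differential_expression", "metabolome", "integration"],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return {"inputs": inputs, "physiology": phys, "deg": degr, "metabolome": met,
            "integration": integ}
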