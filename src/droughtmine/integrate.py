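"""Correlation layers, pathway enrichment and metabolite-anchored gene mining.

The integrative step links three layers with Pearson correlation
(edge kept iff |r| > 0.6 and p < 0.05): gene-trait, metabolite-trait and
gene-metabolite.  Pathway enrichment of DEG sets uses the upper-tail
hypergeometric test with BH control within each annotation namespace.

Candidate mining is metabolite-centered.  A *key metabolite* must be
(a) detected in both genotypes, (b) a differential metabolite in at least
one genotype, (c) correlated with osmolality or total antioxidant capacity,
and (d) divergently regulated between genotypes (|difference of mean
log2FC| above a threshold in some drought period).  A *candidate gene*
must (i) be a surviving DEG, (ii) share an annotated pathway with a key
metabolite's compound id, (iii) be osmolality- or AOC-correlated, and
(iv) be correlated with that key metabolite.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .config import AnalysisConfig
from .deg import bh_adjust
from . import io

logger = logging.getLogger(__name__)

#: KEGG pathways defining energy-related DEGs: photosynthesis-antenna
#: proteins, carbon fixation (photosynthetic organisms and prokaryotes),
#: photosynthesis, oxidative phosphorylation.
ENERGY_PATHWAYS = ("ko00196", "ko00710", "ko00720", "ko00195", "ko00190")

EDGE_COLUMNS = ["source_id", "target_id", "layer", "r", "p_value", "n"]


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson r with two-sided p (t-transform); missing pairs dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"pearson needs >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson is undefined for a zero-variance variable")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(n)


def _corr_with_p(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise correlations of X (n x a) against Y (n x b), with p.

    Requires complete data; returns (a x b) r and p matrices.  Zero-variance
    columns yield NaN (skipped by callers with a log entry).
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = Xc.std(axis=0, ddof=1)
    sy = Yc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ Yc) / ((n - 1) * np.outer(sx, sy))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return r, p


def correlate_features_with_series(
    features: pd.DataFrame,
    series: pd.Series,
    layer: str,
    config: AnalysisConfig,
    target_id: str,
) -> pd.DataFrame:
    """Correlate every feature row against one aligned series.

    ``features`` is feature x observation; ``series`` must be indexed by the
    same observations.  Pairs with missing values are dropped per feature.
    Returns retained edges only (|r| > r_threshold and p < p_threshold).
    """
    obs = [c for c in features.columns if c in series.index and np.isfinite(series[c])]
    if len(obs) < 3:
        raise ValueError(
            f"trait layer {layer!r}: only {len(obs)} observations align with the "
            f"feature frame; unmatched: {sorted(set(features.columns) - set(obs))[:5]}"
        )
    y = series[obs].to_numpy(dtype=float)
    rows = []
    block = features[obs]
    complete = block.notna().all(axis=1)
    # vectorized path for complete rows, per-row fallback with NA dropping
    if complete.any():
        X = block.loc[complete].to_numpy(dtype=float).T
        r_mat, p_mat = _corr_with_p(X, y[:, None])
        for fid, r, p in zip(block.index[complete], r_mat[:, 0], p_mat[:, 0]):
            rows.append((str(fid), target_id, layer, r, p, len(obs)))
    for fid in block.index[~complete]:
        vals = block.loc[fid]
        mask = vals.notna()
        if mask.sum() < 3 or vals[mask].std() == 0:
            logger.info("layer %s: skipping %s (insufficient or constant data)", layer, fid)
            continue
        r, p, n = pearson(vals[mask].to_numpy(), y[mask.to_numpy()])
        rows.append((str(fid), target_id, layer, r, p, n))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    keep = (edges["r"].abs() > config.corr_r_threshold) & (
        edges["p_value"] < config.corr_p_threshold
    )
    return edges[keep].reset_index(drop=True)


def replicate_trait_series(
    traits: pd.DataFrame,
    metadata: pd.DataFrame,
    genotype: str,
    trait_col: str,
    condition: str = "drought",
) -> pd.Series:
    """Trait value per sample_id, matched on (genotype, condition, timepoint, replicate)."""
    sub = traits[(traits["genotype"] == genotype) & (traits["condition"] == condition)]
    lookup = sub.set_index(["timepoint", "replicate"])[trait_col]
    meta = io.select_samples(metadata, genotype=genotype, condition=condition)
    values = {}
    for sid, row in meta.iterrows():
        key = (row["timepoint"], row["replicate"])
        if key in lookup.index:
            values[sid] = float(lookup.loc[key])
    return pd.Series(values, dtype=float)


def profile_trait_series(
    traits: pd.DataFrame, genotype: str, trait_col: str
) -> pd.Series:
    """Per-timepoint trait fold change (drought / well-watered replicate means)."""
    sub = traits[traits["genotype"] == genotype]
    means = sub.groupby(["timepoint", "condition"])[trait_col].mean().unstack("condition")
    fc = means["drought"] / means["well_watered"]
    return fc.dropna()


def build_trait_correlation_layer(
    features: pd.DataFrame,
    traits: pd.DataFrame,
    metadata: pd.DataFrame,
    genotype: str,
    config: AnalysisConfig,
    layer: str,
    trait_cols: Sequence[str] = ("osmolality", "aoc"),
    profiles: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait-correlation edges and per-feature flags for one genotype.

    In the default ``replicate`` mode each feature's values across the
    genotype's drought samples are correlated against the replicate-level
    trait values of the matching plots (n = timepoints x replicates).  In
    ``profile`` mode each feature's per-timepoint log2FC profile
    (``profiles``, feature x timepoint) is correlated against the trait's
    per-timepoint drought/well-watered fold change (n = timepoints).

    Returns (edges, flags) where ``flags`` is a boolean feature x trait
    frame (column ``<trait>_correlated``).
    """
    all_edges = []
    flags = pd.DataFrame(
        False, index=features.index if profiles is None else profiles.index,
        columns=[f"{t}_correlated" for t in trait_cols],
    )
    for trait_col in trait_cols:
        if trait_col not in traits.columns:
            continue
        if config.trait_corr_mode == "replicate":
            series = replicate_trait_series(traits, metadata, genotype, trait_col)
            frame = features
        else:
            series = profile_trait_series(traits, genotype, trait_col)
            if profiles is None:
                raise ValueError("profile mode requires per-timepoint log2FC profiles")
            frame = profiles
        edges = correlate_features_with_series(frame, series, layer, config, trait_col)
        all_edges.append(edges)
        flags.loc[flags.index.isin(edges["source_id"]), f"{trait_col}_correlated"] = True
    edges = (
        pd.concat(all_edges, ignore_index=True)
        if all_edges else pd.DataFrame(columns=EDGE_COLUMNS)
    )
    return edges, flags


def build_feature_correlation_layer(
    genes: pd.DataFrame,
    metabolites: pd.DataFrame,
    config: AnalysisConfig,
    layer: str = "gene-metabolite",
) -> pd.DataFrame:
    """Gene-metabolite correlation edges over shared sample columns.

    Metabolite rows with missing values in the shared samples are
    correlated pairwise-complete; retained edges follow the |r| / p rule.
    """
    shared = [c for c in genes.columns if c in metabolites.columns]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples between the two layers")
    G = genes[shared]
    M = metabolites[shared]
    rows = []
    complete = M.notna().all(axis=1)
    if complete.any():
        r_mat, p_mat = _corr_with_p(
            G.to_numpy(dtype=float).T, M.loc[complete].to_numpy(dtype=float).T
        )
        mids = M.index[complete]
        keep = (np.abs(r_mat) > config.corr_r_threshold) & (p_mat < config.corr_p_threshold)
        gi, mi = np.nonzero(keep)
        for g, m in zip(gi, mi):
            rows.append((str(G.index[g]), str(mids[m]), layer,
                         float(r_mat[g, m]), float(p_mat[g, m]), len(shared)))
    for mid in M.index[~complete]:
        vals = M.loc[mid]
        mask = vals.notna()
        if mask.sum() < 3 or vals[mask].std() == 0:
            continue
        y = vals[mask].to_numpy(dtype=float)
        X = G.loc[:, mask.to_numpy()].to_numpy(dtype=float).T
        if X.shape[0] < 3:
            continue
        r_mat, p_mat = _corr_with_p(X, y[:, None])
        for g in range(r_mat.shape[0]):
            r, p = float(r_mat[g, 0]), float(p_mat[g, 0])
            if abs(r) > config.corr_r_threshold and p < config.corr_p_threshold:
                rows.append((str(G.index[g]), str(mid), layer, r, p, int(mask.sum())))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def hypergeometric_enrichment(
    selected: Iterable[str],
    annotation: Mapping[str, tuple[str, frozenset[str]]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``selected`` within ``universe``.

    Every annotation set is intersected with the universe first; p is
    P(overlap >= observed) under sampling |selected| ids without
    replacement; q is BH across the tested sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    rows = []
    for set_id, (description, members) in annotation.items():
        members_in = members & universe
        if not members_in:
            continue
        overlap = len(members_in & selected)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members_in), len(selected)))
        rows.append((set_id, description, overlap, len(members_in), len(selected),
                     len(universe), p))
    df = pd.DataFrame(rows, columns=[
        "set_id", "description", "overlap", "set_size", "selected_size",
        "universe_size", "p_value",
    ])
    df["q_value"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def classify_energy_related(
    deg_ids: Iterable[str],
    annotation: Mapping[str, tuple[str, frozenset[str]]],
    pathway_ids: Sequence[str] = ENERGY_PATHWAYS,
) -> set[str]:
    """DEGs annotated to any of the five energy-related KEGG pathways."""
    missing = [pid for pid in pathway_ids if pid not in annotation]
    if missing:
        logger.warning("energy pathway id(s) absent from the annotation: %s", missing)
    members: set[str] = set()
    for pid in pathway_ids:
        if pid in annotation:
            members |= set(annotation[pid][1])
    return set(deg_ids) & members


def select_key_metabolites(
    dm_table: pd.DataFrame,
    detection: pd.DataFrame,
    trait_flags: pd.DataFrame,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Apply the four key-metabolite criteria.

    Parameters
    ----------
    dm_table
        Concatenated DM table over genotypes and periods (columns of
        :data:`droughtmine.metabolome.DM_COLUMNS`).
    detection
        Boolean metabolite x genotype detection frame.
    trait_flags
        Long frame (metabolite_id, genotype, osmolality_correlated,
        aoc_correlated).

    Returns one row per metabolite with boolean columns for each criterion
    (``shared``, ``dm_any``, ``trait_correlated``, ``divergent``), the
    maximal between-genotype |log2FC difference| over periods
    (``divergence``), and the conjunction ``is_key``.
    """
    genotypes = sorted(detection.columns)
    mets = detection.index
    shared = detection.all(axis=1)

    dm_any = pd.Series(False, index=mets)
    hits = dm_table[dm_table["is_dm"]]
    dm_any[dm_any.index.isin(hits["metabolite_id"])] = True

    tflags = pd.Series(False, index=mets)
    if len(trait_flags):
        corr_cols = [c for c in trait_flags.columns if c.endswith("_correlated")]
        any_corr = trait_flags[trait_flags[corr_cols].any(axis=1)]["metabolite_id"]
        tflags[tflags.index.isin(any_corr)] = True

    lfc = dm_table.pivot_table(
        index=["metabolite_id", "period"], columns="genotype", values="log2fc",
        aggfunc="mean",
    )
    divergence = pd.Series(0.0, index=mets)
    if len(genotypes) >= 2 and len(lfc):
        diff = (lfc[genotypes[0]] - lfc[genotypes[1]]).abs()
        per_met = diff.groupby(level="metabolite_id").max()
        divergence.loc[per_met.index.intersection(mets)] = per_met
    divergent = divergence >= config.divergence_lfc_threshold

    out = pd.DataFrame({
        "metabolite_id": mets.astype(str),
        "shared": shared.to_numpy(),
        "dm_any": dm_any.to_numpy(),
        "trait_correlated": tflags.to_numpy(),
        "divergence": divergence.to_numpy(),
        "divergent": divergent.to_numpy(),
    })
    out["is_key"] = out[["shared", "dm_any", "trait_correlated", "divergent"]].all(axis=1)
    return out.reset_index(drop=True)


def mine_candidate_genes(
    key_metabolites: Iterable[str],
    deg_tables: Mapping[str, pd.DataFrame],
    gene_trait_flags: Mapping[str, pd.DataFrame],
    gene_metabolite_edges: pd.DataFrame,
    annotation: Mapping[str, tuple[str, frozenset[str]]],
    config: AnalysisConfig,
    period_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Metabolite-centered candidate-gene mining.

    For each key metabolite, pathways containing its compound id are looked
    up in the annotation; genes of those pathways become candidates when
    they (i) are surviving DEGs, (ii) carry an osmolality or AOC
    correlation flag, and (iii) are correlated with the anchoring
    metabolite.  The reported fold change is the gene's median log2FC over
    drought timepoints (periods I and II when a period map is given).
    Output is sorted by |fold change|, one row per
    (pathway, metabolite, gene, genotype).
    """
    edge_pairs = set(
        zip(gene_metabolite_edges["source_id"], gene_metabolite_edges["target_id"])
    )
    edge_r = {
        (s, t): r for s, t, r in zip(
            gene_metabolite_edges["source_id"],
            gene_metabolite_edges["target_id"],
            gene_metabolite_edges["r"],
        )
    }
    rows = []
    for metabolite in sorted(set(key_metabolites)):
        pathways = [pid for pid, (_, members) in annotation.items() if metabolite in members]
        if not pathways:
            logger.info("key metabolite %s has no pathway membership; no candidates", metabolite)
            continue
        for genotype, table in deg_tables.items():
            survivors = table[table["is_deg"]]
            if period_map is not None:
                drought_tps = [tp for tp, per in period_map.items() if per in ("I", "II")]
                fc_base = table[table["timepoint"].isin(drought_tps)]
            else:
                fc_base = table
            fc = fc_base.groupby("gene_id")["log2fc"].median()
            flags = gene_trait_flags.get(genotype)
            if flags is None or flags.empty:
                continue
            corr_cols = [c for c in flags.columns if c.endswith("_correlated")]
            trait_ok = set(flags.index[flags[corr_cols].any(axis=1)].astype(str))
            deg_ids = set(survivors["gene_id"])
            for pid in pathways:
                members = annotation[pid][1]
                for gene in sorted(members & deg_ids & trait_ok):
                    if (gene, metabolite) not in edge_pairs:
                        continue
                    osm = bool(flags.loc[gene, "osmolality_correlated"]) \
                        if "osmolality_correlated" in flags.columns else False
                    aoc = bool(flags.loc[gene, "aoc_correlated"]) \
                        if "aoc_correlated" in flags.columns else False
                    rows.append((
                        pid, annotation[pid][0], metabolite, gene, genotype,
                        float(fc.get(gene, np.nan)), edge_r[(gene, metabolite)],
                        osm, aoc,
                    ))
    out = pd.DataFrame(rows, columns=[
        "pathway_id", "pathway_description", "metabolite_id", "gene_id", "genotype",
        "log2fc", "gene_metabolite_r", "osmolality_correlated", "aoc_correlated",
    ])
    if len(out):
        out = out.sort_values(
            by=["log2fc", "pathway_id", "gene_id", "genotype"],
            key=lambda s: -s.abs() if s.name == "log2fc" else s,
            kind="stable",
        ).reset_index(drop=True)
    return out


def cluster_profiles(
    profiles: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[list[str], np.ndarray]:
    """Agglomerative clustering of (capped) log2FC profiles.

    Returns (leaf order as profile ids, scipy linkage matrix).  Identical
    profiles merge at height 0; the tree is deterministic for a fixed row
    order.
    """
    if len(profiles) < 2:
        raise ValueError("cluster_profiles needs >= 2 profiles")
    X = profiles.to_numpy(dtype=float)
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    order = hierarchy.leaves_list(Z)
    return [str(profiles.index[i]) for i in order], Z
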