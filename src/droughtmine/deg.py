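"""Per-timepoint differential expression on FPKM matrices.

Two calling modes mirror the study design: libraries with biological
replicates are tested per gene with a two-sample t-test on
log2(FPKM + pseudocount) and Benjamini-Hochberg control (DEG iff
q < 0.05 and |log2FC| >= 1); unreplicated libraries cannot support a
per-gene test, so a variance-trend stand-in converts each gene's log2FC
into a z-score against the local null spread (DEG iff p < 0.05 and
|log2FC| >= 1).

Drought delays development, so a gene differing between two drought
timepoints may simply be at a different developmental stage than its
well-watered contemporary.  Any gene called differential between ANY pair
of well-watered timepoints is flagged development-dependent and excluded
from the final DEG tables.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from . import io

#: Median of the chi-square(1) distribution; scales a median of squared
#: z-values back to a variance estimate.
_CHI2_1_MEDIAN = 0.45493642311957174

DEG_COLUMNS = [
    "gene_id", "timepoint", "log2fc", "p_value", "q_value",
    "direction", "is_deg", "development_dependent",
]


def log2_fold_change(
    fpkm_drought: float | np.ndarray,
    fpkm_watered: float | np.ndarray,
    pseudocount: float = 0.00001,
) -> float | np.ndarray:
    """log2[(FPKM_D + pseudocount) / (FPKM_W + pseudocount)].

    The shared pseudocount keeps the ratio finite for zero expression and
    makes the fold change exactly 0 when both means are 0.
    """
    d = np.asarray(fpkm_drought, dtype=float)
    w = np.asarray(fpkm_watered, dtype=float)
    if (d < 0).any() or (w < 0).any():
        raise ValueError("FPKM values must be non-negative")
    out = np.log2(d + pseudocount) - np.log2(w + pseudocount)
    return float(out) if out.ndim == 0 else out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _condition_columns(
    metadata: pd.DataFrame, genotype: str, timepoint: str
) -> tuple[list[str], list[str]]:
    d = io.select_samples(metadata, genotype, "drought", timepoint).index.tolist()
    w = io.select_samples(metadata, genotype, "well_watered", timepoint).index.tolist()
    return d, w


def _welch_rows(
    a: np.ndarray, b: np.ndarray, variant: str
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test; constant equal rows get (0, 1)."""
    res = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "student"))
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(stat)
    stat[degenerate] = 0.0
    p[degenerate] = 1.0
    return stat, p


def call_degs_replicated(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    genotype: str,
    timepoint: str,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """DEG records at one timepoint for a genotype with replicates.

    DEG iff BH-adjusted q < ``deg_fdr_threshold`` and
    |log2FC| >= ``deg_lfc_threshold``.  Every tested gene receives p and q.
    """
    d_cols, w_cols = _condition_columns(metadata, genotype, timepoint)
    if len(d_cols) < 2 or len(w_cols) < 2:
        raise ValueError(
            f"replicated DEG calling needs >= 2 replicates per condition at "
            f"timepoint {timepoint!r} (got {len(d_cols)} drought, {len(w_cols)} "
            f"well-watered); use call_degs_unreplicated instead"
        )
    d = matrix[d_cols].to_numpy(dtype=float)
    w = matrix[w_cols].to_numpy(dtype=float)
    lfc = log2_fold_change(d.mean(axis=1), w.mean(axis=1), config.fpkm_pseudocount)
    log_d = np.log2(d + config.fpkm_pseudocount)
    log_w = np.log2(w + config.fpkm_pseudocount)
    _, p = _welch_rows(log_d, log_w, config.ttest_variant)
    q = bh_adjust(p)
    is_deg = (q < config.deg_fdr_threshold) & (np.abs(lfc) >= config.deg_lfc_threshold)
    return _records(matrix.index, timepoint, lfc, p, q, is_deg)


def fit_variance_trend(
    lfc: np.ndarray, mean_log_abundance: np.ndarray, n_bins: int = 20
) -> np.ndarray:
    """Per-gene null SD of log2FC from a robust local trend.

    Genes are grouped into ``n_bins`` equal-count bins over mean log2
    abundance; within each bin the null variance is estimated as
    median(log2FC^2) / median(chi-square_1), which stays calibrated when a
    minority of genes carry real effects.  Returns an SD per gene.
    """
    n = lfc.size
    n_bins = max(1, min(n_bins, n // 10)) if n >= 10 else 1
    order = np.argsort(mean_log_abundance, kind="stable")
    bin_of = np.empty(n, dtype=int)
    bin_of[order] = np.minimum((np.arange(n) * n_bins) // n, n_bins - 1)
    sd = np.empty(n)
    for b in range(n_bins):
        mask = bin_of == b
        var = np.median(lfc[mask] ** 2) / _CHI2_1_MEDIAN
        sd[mask] = np.sqrt(max(var, 1e-12))
    return sd


def call_degs_unreplicated(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    genotype: str,
    timepoint: str,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """DEG records at one timepoint without biological replicates.

    A per-gene test is impossible with one library per condition, so each
    gene's log2FC is z-scored against the abundance-dependent null spread
    estimated across all genes (see :func:`fit_variance_trend`), giving a
    two-sided normal p.  DEG iff p < ``deg_p_threshold`` and
    |log2FC| >= ``deg_lfc_threshold``.
    """
    d_cols, w_cols = _condition_columns(metadata, genotype, timepoint)
    if not d_cols or not w_cols:
        raise ValueError(
            f"no samples for genotype {genotype!r} at timepoint {timepoint!r}"
        )
    d = matrix[d_cols].to_numpy(dtype=float).mean(axis=1)
    w = matrix[w_cols].to_numpy(dtype=float).mean(axis=1)
    lfc = log2_fold_change(d, w, config.fpkm_pseudocount)
    mean_abund = 0.5 * (
        np.log2(d + config.fpkm_pseudocount) + np.log2(w + config.fpkm_pseudocount)
    )
    sd = fit_variance_trend(np.asarray(lfc), mean_abund)
    z = np.asarray(lfc) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    is_deg = (p < config.deg_p_threshold) & (np.abs(lfc) >= config.deg_lfc_threshold)
    return _records(matrix.index, timepoint, np.asarray(lfc), p, np.full(len(p), np.nan), is_deg)


def _records(
    genes: pd.Index,
    timepoint: str,
    lfc: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    is_deg: np.ndarray,
) -> pd.DataFrame:
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    return pd.DataFrame({
        "gene_id": genes.astype(str),
        "timepoint": timepoint,
        "log2fc": lfc,
        "p_value": p,
        "q_value": q,
        "direction": direction,
        "is_deg": is_deg,
        "development_dependent": False,
    }).reset_index(drop=True)


def call_degs(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    genotype: str,
    timepoint: str,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Dispatch to the replicated or unreplicated caller by replicate count."""
    d_cols, w_cols = _condition_columns(metadata, genotype, timepoint)
    if len(d_cols) >= 2 and len(w_cols) >= 2:
        return call_degs_replicated(matrix, metadata, genotype, timepoint, config)
    return call_degs_unreplicated(matrix, metadata, genotype, timepoint, config)


def flag_development_dependent(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    genotype: str,
    config: AnalysisConfig,
) -> set[str]:
    """Genes differential between ANY pair of well-watered timepoints.

    Each of the C(T, 2) timepoint pairs is tested with the same machinery
    and thresholds as a drought-vs-watered contrast (replicated test when
    both timepoints have >= 2 replicates, the variance-trend stand-in
    otherwise); no extra correction across pairs.
    """
    w = io.select_samples(metadata, genotype, "well_watered")
    tps = sorted(w["timepoint"].unique())
    if len(tps) < 2:
        raise ValueError(
            f"development-dependent flagging needs >= 2 well-watered timepoints "
            f"for genotype {genotype!r}, got {len(tps)}"
        )
    flagged: set[str] = set()
    for tp_a, tp_b in itertools.combinations(tps, 2):
        a_cols = w[w["timepoint"] == tp_a].index.tolist()
        b_cols = w[w["timepoint"] == tp_b].index.tolist()
        a = matrix[a_cols].to_numpy(dtype=float)
        b = matrix[b_cols].to_numpy(dtype=float)
        lfc = np.asarray(log2_fold_change(a.mean(axis=1), b.mean(axis=1), config.fpkm_pseudocount))
        if len(a_cols) >= 2 and len(b_cols) >= 2:
            _, p = _welch_rows(
                np.log2(a + config.fpkm_pseudocount),
                np.log2(b + config.fpkm_pseudocount),
                config.ttest_variant,
            )
            q = bh_adjust(p)
            hit = (q < config.deg_fdr_threshold) & (np.abs(lfc) >= config.deg_lfc_threshold)
        else:
            mean_abund = 0.5 * (
                np.log2(a.mean(axis=1) + config.fpkm_pseudocount)
                + np.log2(b.mean(axis=1) + config.fpkm_pseudocount)
            )
            sd = fit_variance_trend(lfc, mean_abund)
            p = 2.0 * stats.norm.sf(np.abs(lfc / sd))
            hit = (p < config.deg_p_threshold) & (np.abs(lfc) >= config.deg_lfc_threshold)
        flagged.update(matrix.index[hit].astype(str))
    return flagged


def apply_development_filter(
    deg_table: pd.DataFrame, flagged: set[str]
) -> pd.DataFrame:
    """Mark flagged genes and strip their DEG status.

    The returned table keeps every tested gene (with the
    ``development_dependent`` column set) but no flagged gene remains
    ``is_deg``.
    """
    out = deg_table.copy()
    mask = out["gene_id"].isin(flagged)
    out["development_dependent"] = mask
    out.loc[mask, "is_deg"] = False
    return out


def log2fc_profile(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    genotype: str,
    config: AnalysisConfig,
    timepoints: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gene x timepoint log2FC (drought vs well-watered means) profile."""
    if timepoints is None:
        timepoints = io.timepoint_order(metadata)
    cols = {}
    for tp in timepoints:
        d_cols, w_cols = _condition_columns(metadata, genotype, tp)
        if not d_cols or not w_cols:
            continue
        d = matrix[d_cols].to_numpy(dtype=float).mean(axis=1)
        w = matrix[w_cols].to_numpy(dtype=float).mean(axis=1)
        cols[tp] = log2_fold_change(d, w, config.fpkm_pseudocount)
    return pd.DataFrame(cols, index=matrix.index)


def cap_profile(profile: pd.DataFrame, cap: float) -> pd.DataFrame:
    """Clamp log2FC values to [-cap, +cap] for heatmap display; idempotent."""
    if cap <= 0:
        raise ValueError(f"cap must be positive, got {cap}")
    return profile.clip(lower=-cap, upper=cap)


def deg_sets_by_timepoint(deg_table: pd.DataFrame) -> dict[str, set[str]]:
    hits = deg_table[deg_table["is_deg"]]
    return {
        tp: set(sub["gene_id"]) for tp, sub in hits.groupby("timepoint")
    }


def summarize_deg_counts(
    tables: Mapping[str, pd.DataFrame],
    period_map: Mapping[str, str] | None = None,
) -> dict:
    """Up/down/total DEG counts plus intersection sets.

    Parameters
    ----------
    tables
        genotype -> concatenated per-timepoint DEG table.
    period_map
        Optional timepoint -> period map; adds period-level DEG unions.

    Returns a dict with:

    * ``counts`` — DataFrame (genotype, timepoint, up, down, total);
    * ``common`` — timepoint -> gene set shared by all genotypes;
    * ``period_unions`` — genotype -> period -> union DEG set (if a period
      map was given);
    * ``pairwise`` — (genotype_a, genotype_b) -> timepoint -> shared set.
    """
    rows = []
    per_tp: dict[str, dict[str, set[str]]] = {}
    for genotype, table in tables.items():
        hits = table[table["is_deg"]]
        for tp in sorted(table["timepoint"].unique()):
            sub = hits[hits["timepoint"] == tp]
            up = int((sub["direction"] == "up").sum())
            down = int((sub["direction"] == "down").sum())
            rows.append((genotype, tp, up, down, up + down))
            per_tp.setdefault(tp, {})[genotype] = set(sub["gene_id"])
    counts = pd.DataFrame(rows, columns=["genotype", "timepoint", "up", "down", "total"])

    common = {
        tp: set.intersection(*sets.values()) if len(sets) == len(tables) else set()
        for tp, sets in per_tp.items()
    }
    pairwise = {}
    genotypes = sorted(tables)
    for ga, gb in itertools.combinations(genotypes, 2):
        pairwise[(ga, gb)] = {
            tp: per_tp[tp].get(ga, set()) & per_tp[tp].get(gb, set()) for tp in per_tp
        }
    result = {"counts": counts, "common": common, "pairwise": pairwise}
    if period_map is not None:
        unions: dict[str, dict[str, set[str]]] = {}
        for genotype, table in tables.items():
            hits = table[table["is_deg"]]
            unions[genotype] = {}
            for tp, sub in hits.groupby("timepoint"):
                period = period_map.get(str(tp))
                if period is None:
                    continue
                unions[genotype].setdefault(period, set()).update(sub["gene_id"])
        result["period_unions"] = unions
    return result
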