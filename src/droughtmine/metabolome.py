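"""GC/MS peak-table statistics: normalization, PCA, OPLS-DA, VIP, DM calls.

Peak tables are normalized to the sum intensity of each sample (so every
sample column sums to 1 over its detected peaks), then mean-centered and
unit-variance scaled before multivariate modelling.  Class discrimination
uses orthogonal partial least squares discriminant analysis (OPLS-DA):
variation orthogonal to the class contrast is removed first, then a single
predictive PLS component is fitted by NIPALS.  Variable importance in the
projection (VIP) ranks each metabolite's contribution; by construction the
root-mean-square VIP over variables is 1.  A metabolite is a differential
metabolite (DM) when it passes the dual criterion VIP > 1.0 (multivariate)
and p < 0.05 (univariate two-sample t-test on normalized intensities).
Cross-genotype comparisons are restricted to metabolites detected in both
genotypes, so detection bias between the two metabolomes cannot masquerade
as regulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from . import io

logger = logging.getLogger(__name__)

DM_COLUMNS = ["metabolite_id", "genotype", "period", "vip", "p_value", "log2fc", "is_dm"]


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge within the iteration budget."""


def normalize_sum_intensity(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by its total peak intensity.

    Sums run over non-missing peaks only; missing peaks stay missing.
    Idempotent up to floating point once columns already sum to 1.
    """
    sums = table.sum(axis=0, skipna=True)
    empty = table.notna().sum(axis=0) == 0
    if empty.any():
        raise ValueError(
            f"sample(s) with no detected peaks: {table.columns[empty].tolist()}"
        )
    if (sums <= 0).any():
        bad = sums.index[sums <= 0].tolist()
        raise ValueError(f"sample(s) with non-positive total intensity: {bad}")
    return table.div(sums, axis=1)


def detection_flags(table: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite, per-genotype detection (any non-missing peak)."""
    flags = {}
    for genotype in sorted(metadata["genotype"].unique()):
        cols = io.select_samples(metadata, genotype=genotype).index
        cols = [c for c in cols if c in table.columns]
        flags[genotype] = table[cols].notna().any(axis=1)
    return pd.DataFrame(flags)


def shared_metabolites(table: pd.DataFrame, metadata: pd.DataFrame) -> pd.Index:
    """Metabolites detected in every genotype (the comparable core)."""
    flags = detection_flags(table, metadata)
    return table.index[flags.all(axis=1)]


def autoscale(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Mean-center and unit-variance scale each variable (column).

    Uses the sample (n-1) standard deviation; statistics are computed over
    non-missing entries.  Zero-variance variables are dropped with a logged
    warning.  Returns (scaled matrix, means, sds).
    """
    means = matrix.mean(axis=0, skipna=True)
    sds = matrix.std(axis=0, ddof=1, skipna=True)
    keep = sds > 0
    if not keep.all():
        dropped = matrix.columns[~keep].tolist()
        logger.warning("autoscale: dropping %d zero-variance variable(s): %s",
                       len(dropped), dropped[:5])
    scaled = (matrix.loc[:, keep] - means[keep]) / sds[keep]
    return scaled, means[keep], sds[keep]


def pca(
    scaled: pd.DataFrame | np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components of a scaled samples x variables matrix.

    Returns (scores n x k, loadings p x k, explained variances length k).
    Loadings are orthonormal; explained variances are the non-increasing
    eigenvalues of the sample covariance matrix.  Sign convention: the
    largest-magnitude loading of each component is positive.
    """
    X = np.asarray(scaled, dtype=float)
    n, p = X.shape
    max_rank = min(n - 1, p)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds the maximal rank {max_rank} "
            f"of a {n}x{p} centered matrix"
        )
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[:n_components].T
    # deterministic sign: largest |loading| entry positive per component
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
    scores = Xc @ loadings
    explained = (s[:n_components] ** 2) / (n - 1)
    return scores, loadings, explained


@dataclass
class DiscriminantModel:
    """Fitted (O)PLS-DA model with one predictive component.

    ``weights`` is the unit-norm predictive weight vector in the space of
    the retained variables, ``scores`` the predictive score vector, and the
    ``ortho_*`` arrays hold the removed class-orthogonal components.
    ``vip`` satisfies sum(vip^2) == number of variables.
    """

    variables: list[str]
    classes: tuple[str, str]
    y: np.ndarray
    weights: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    y_loading: float
    ortho_weights: np.ndarray
    ortho_scores: np.ndarray
    ortho_loadings: np.ndarray
    vip: np.ndarray = field(default=None)  # type: ignore[assignment]
    r2x: float = 0.0
    r2y: float = 0.0
    means: pd.Series | None = None
    sds: pd.Series | None = None

    @property
    def n_orthogonal(self) -> int:
        return self.ortho_scores.shape[1]


def _nipals_component(
    X: np.ndarray, Y: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """One NIPALS PLS component: returns (w unit-norm, t = Xw).

    Convergence is declared when the score vector changes by less than
    ``tol`` (Euclidean norm) between iterations.  With a single response
    column this converges in one pass.
    """
    u = Y[:, 0].copy()
    t_old = None
    for _ in range(max_iter):
        w = X.T @ u / (u @ u)
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("degenerate weight vector (X'y = 0)")
        w /= norm
        t = X @ w
        c = Y.T @ t / (t @ t)
        u = Y @ c / (c @ c)
        if t_old is not None and np.linalg.norm(t - t_old) < tol:
            return w, t
        t_old = t
        if Y.shape[1] == 1:  # single response: fixed point reached immediately
            return w, t
    raise ConvergenceError(
        f"NIPALS did not converge within {max_iter} iterations (tol={tol})"
    )


def encode_classes(labels: Sequence[str]) -> tuple[np.ndarray, tuple[str, str]]:
    """Centered +-1 class coding for a two-class label vector."""
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly 2 classes required, got {uniq}")
    y = np.where(np.asarray(labels) == uniq[1], 1.0, -1.0)
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("each class needs >= 2 samples")
    return y - y.mean(), (uniq[0], uniq[1])


def opls_da(
    scaled: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    n_orthogonal: int = 1,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> DiscriminantModel:
    """Fit OPLS-DA: remove class-orthogonal variation, then one PLS component.

    Orthogonal components are extracted as in O-PLS: the part of each X
    loading not aligned with the predictive weight defines an orthogonal
    weight; its component is deflated from X.  Each orthogonal score is
    uncorrelated with the class vector by construction.  With
    ``n_orthogonal=0`` the model is plain PLS-DA.
    """
    if isinstance(scaled, pd.DataFrame):
        variables = [str(v) for v in scaled.columns]
        X = scaled.to_numpy(dtype=float)
    else:
        X = np.asarray(scaled, dtype=float)
        variables = [f"var_{j}" for j in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("OPLS-DA requires a complete matrix; drop or fill missing values")
    y, classes = encode_classes(labels)
    Y = y[:, None]
    n, p = X.shape
    ssx_total = float((X ** 2).sum())
    ssy_total = float((y ** 2).sum())

    Xd = X.copy()
    w_orths, t_orths, p_orths = [], [], []
    for _ in range(n_orthogonal):
        w, t = _nipals_component(Xd, Y, tol, max_iter)
        p_load = Xd.T @ t / (t @ t)
        w_orth = p_load - (w @ p_load) * w
        norm = np.linalg.norm(w_orth)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_orth /= norm
        t_orth = Xd @ w_orth
        p_orth = Xd.T @ t_orth / (t_orth @ t_orth)
        Xd = Xd - np.outer(t_orth, p_orth)
        w_orths.append(w_orth)
        t_orths.append(t_orth)
        p_orths.append(p_orth)

    w, t = _nipals_component(Xd, Y, tol, max_iter)
    p_load = Xd.T @ t / (t @ t)
    c = float(y @ t / (t @ t))

    ssy_explained = float((c * t) @ (c * t))
    modelled = np.outer(t, p_load)
    for t_o, p_o in zip(t_orths, p_orths):
        modelled = modelled + np.outer(t_o, p_o)
    r2x = float((modelled ** 2).sum() / ssx_total) if ssx_total > 0 else 0.0
    r2y = ssy_explained / ssy_total if ssy_total > 0 else 0.0

    k = len(w_orths)
    model = DiscriminantModel(
        variables=variables,
        classes=classes,
        y=y,
        weights=w,
        scores=t,
        loadings=p_load,
        y_loading=c,
        ortho_weights=np.column_stack(w_orths) if k else np.empty((p, 0)),
        ortho_scores=np.column_stack(t_orths) if k else np.empty((n, 0)),
        ortho_loadings=np.column_stack(p_orths) if k else np.empty((p, 0)),
        r2x=r2x,
        r2y=r2y,
    )
    model.vip = vip_scores(model)
    rms = np.sqrt(np.mean(model.vip ** 2))
    if abs(rms - 1.0) > 1e-6:
        raise AssertionError(f"VIP normalization violated: RMS VIP = {rms}")
    return model


def vip_scores(model: DiscriminantModel) -> np.ndarray:
    """Variable importance in the projection over predictive components.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),
    where SSY_a is the y-variance explained by predictive component a.
    With one predictive component this reduces to sqrt(p) * |w_j|, so
    sum(VIP^2) equals the number of variables.
    """
    if model.weights is None:
        raise ValueError("model is not fitted")
    p = len(model.variables)
    # single predictive component: SSY weighting cancels
    w = model.weights / np.linalg.norm(model.weights)
    ssy = float((model.y_loading * model.scores) @ (model.y_loading * model.scores))
    vip = np.sqrt(p * ssy * w ** 2 / ssy)
    return vip


def univariate_p(
    table: pd.DataFrame,
    class_a_cols: Sequence[str],
    class_b_cols: Sequence[str],
    variant: str = "welch",
) -> pd.Series:
    """Row-wise two-sided t-test p between two sample groups (NaN-aware)."""
    a = table[list(class_a_cols)].to_numpy(dtype=float)
    b = table[list(class_b_cols)].to_numpy(dtype=float)
    res = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "student"), nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    p[np.isnan(np.asarray(res.statistic, dtype=float))] = 1.0
    return pd.Series(p, index=table.index)


def metabolite_log2fc(
    table: pd.DataFrame,
    drought_cols: Sequence[str],
    watered_cols: Sequence[str],
) -> pd.Series:
    """log2 of mean normalized intensity, drought over well-watered."""
    d = table[list(drought_cols)].mean(axis=1, skipna=True)
    w = table[list(watered_cols)].mean(axis=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(d / w)
    return pd.Series(lfc, index=table.index)


def call_differential_metabolites(
    normalized: pd.DataFrame,
    metadata: pd.DataFrame,
    genotype: str,
    period_map: Mapping[str, str],
    config: AnalysisConfig,
    restrict_to: pd.Index | None = None,
) -> tuple[pd.DataFrame, dict[str, DiscriminantModel]]:
    """Call DMs per drought period for one genotype.

    For each period an OPLS-DA model contrasts drought against well-watered
    samples of that genotype (all timepoints in the period pooled); a
    metabolite is a DM when VIP > ``vip_threshold`` and the univariate
    t-test p < ``dm_p_threshold``.  ``restrict_to`` (typically the
    metabolites detected in both genotypes) limits the tested set.
    Metabolites with missing values among the modelled samples are dropped
    from the multivariate model with a warning.

    Returns (DM table, period -> fitted model).
    """
    table = normalized
    if restrict_to is not None:
        table = table.loc[table.index.intersection(restrict_to)]
    meta = io.select_samples(metadata, genotype=genotype)
    periods = sorted(set(period_map.values()))
    rows = []
    models: dict[str, DiscriminantModel] = {}
    for period in periods:
        tps = [tp for tp, per in period_map.items() if per == period]
        sub = meta[meta["timepoint"].isin(tps)]
        d_cols = sub[sub["condition"] == "drought"].index.tolist()
        w_cols = sub[sub["condition"] == "well_watered"].index.tolist()
        if len(d_cols) < 2 or len(w_cols) < 2:
            logger.warning("period %s: fewer than 2 samples per class for %s; skipped",
                           period, genotype)
            continue
        cols = d_cols + w_cols
        block = table[cols]
        complete = block.notna().all(axis=1)
        if not complete.all():
            logger.warning(
                "period %s (%s): dropping %d metabolite(s) with missing values "
                "from the OPLS-DA model", period, genotype, int((~complete).sum()),
            )
        block = block.loc[complete]
        X = block.T  # samples x metabolites
        scaled, means, sds = autoscale(X)
        labels = ["drought"] * len(d_cols) + ["well_watered"] * len(w_cols)
        model = opls_da(
            scaled, labels,
            n_orthogonal=config.n_orthogonal,
            tol=config.opls_tol,
            max_iter=config.opls_max_iter,
        )
        model.means, model.sds = means, sds
        models[period] = model
        vip = pd.Series(model.vip, index=pd.Index(model.variables))
        pvals = univariate_p(table, d_cols, w_cols, config.ttest_variant)
        lfc = metabolite_log2fc(table, d_cols, w_cols)
        for met in table.index:
            v = float(vip.get(met, np.nan))
            p = float(pvals.get(met, np.nan))
            is_dm = bool(
                np.isfinite(v) and np.isfinite(p)
                and v > config.vip_threshold and p < config.dm_p_threshold
            )
            rows.append((met, genotype, period, v, p, float(lfc.get(met, np.nan)), is_dm))
    return pd.DataFrame(rows, columns=DM_COLUMNS), models


def cap_metabolite_profile(profile: pd.DataFrame, cap: float = 10.0) -> pd.DataFrame:
    """Clamp metabolite log2FC profiles to [-cap, +cap]; idempotent."""
    if cap <= 0:
        raise ValueError(f"cap must be positive, got {cap}")
    return profile.clip(lower=-cap, upper=cap)
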