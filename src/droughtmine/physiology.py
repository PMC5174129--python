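"""Drought-physiology indices and the drought-period classification.

The drought experiment is summarised by a handful of leaf- and plot-level
indices: relative water content RWC = (fresh - dry) / (saturated - dry),
the drought-tolerance coefficient GY_D / GY_W (grain yield under drought
over grain yield well-watered), per-timepoint trait fold changes
(drought / well-watered, used for total antioxidant capacity, AOC), and
relative gas-exchange ratios (drought / control for CO2 assimilation and
stomatal conductance).  Sampling timepoints are assigned to drought periods
from soil water content: period I (mild) while SWC stays above the mild
threshold (18% by default), period II (severe) once it falls below the
severe threshold (15%), period III after re-watering.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig

logger = logging.getLogger(__name__)

PERIOD_MILD = "I"
PERIOD_SEVERE = "II"
PERIOD_REWATERING = "III"


def relative_water_content(fresh: float, dry: float, saturated: float) -> float:
    """Leaf relative water content, (fresh - dry) / (saturated - dry)."""
    if saturated <= dry:
        raise ValueError(
            f"saturated weight must exceed dry weight (got saturated={saturated}, dry={dry})"
        )
    return (fresh - dry) / (saturated - dry)


def drought_tolerance_coefficient(gy_drought: float, gy_watered: float) -> float:
    """Grain yield under drought divided by grain yield well-watered."""
    if gy_watered <= 0:
        raise ValueError(f"well-watered grain yield must be positive, got {gy_watered}")
    if gy_drought < 0:
        raise ValueError(f"grain yield cannot be negative, got {gy_drought}")
    return gy_drought / gy_watered


def trait_fold_change(drought_value: float, watered_value: float) -> float:
    """Per-timepoint trait fold change, drought / well-watered."""
    if watered_value <= 0:
        raise ValueError(f"well-watered trait value must be positive, got {watered_value}")
    return drought_value / watered_value


def relative_gas_exchange(ds_value: float, ck_value: float) -> float:
    """Relative gas-exchange rate, drought-stress value over control value."""
    if ck_value <= 0:
        raise ValueError(f"control value must be positive, got {ck_value}")
    return ds_value / ck_value


def soil_water_cv(values: Sequence[float]) -> float:
    """Coefficient of variation (%) of a soil-water-content series.

    Sample (n-1) standard deviation over the mean, times 100.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("soil_water_cv needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("soil_water_cv is undefined for a zero-mean series")
    return float(arr.std(ddof=1) / mean * 100.0)


def per_timepoint_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "welch",
) -> tuple[float, float]:
    """Two-sided independent two-sample t-test between replicate groups.

    ``variant`` is "welch" (unequal variances, default) or "student".
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("per_timepoint_ttest needs >= 2 replicates per group")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    stat = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(stat):  # both groups constant and equal
        stat, p = 0.0, 1.0
    return stat, p


def classify_drought_periods(
    swc_series: Mapping[str, float],
    rewatered: Iterable[str],
    config: AnalysisConfig,
) -> dict[str, str]:
    """Map each timepoint to drought period I, II or III.

    Re-watered timepoints are period III regardless of soil water content.
    Otherwise SWC >= the mild threshold is period I and SWC below the severe
    threshold is period II.  SWC inside the ambiguous band between the two
    thresholds is assigned to period II with a logged warning: the
    conservative call, since the band is crossed quickly in a drying field.
    """
    rewatered = set(rewatered)
    periods: dict[str, str] = {}
    for tp in sorted(set(swc_series) | rewatered):
        if tp in rewatered:
            periods[tp] = PERIOD_REWATERING
            continue
        swc = swc_series[tp]
        if swc < 0:
            raise ValueError(f"negative soil water content at timepoint {tp!r}: {swc}")
        if swc >= config.swc_mild_threshold:
            periods[tp] = PERIOD_MILD
        else:
            if swc >= config.swc_severe_threshold:
                logger.warning(
                    "timepoint %s: SWC %.2f%% lies between the severe (%.1f%%) and mild "
                    "(%.1f%%) thresholds; classified as period II",
                    tp, swc, config.swc_severe_threshold, config.swc_mild_threshold,
                )
            periods[tp] = PERIOD_SEVERE
    return periods


def drought_swc_by_timepoint(traits: pd.DataFrame) -> dict[str, float]:
    """Mean drought-condition soil water content per timepoint."""
    sub = traits[traits["condition"] == "drought"].dropna(subset=["soil_water_content"])
    return sub.groupby("timepoint")["soil_water_content"].mean().to_dict()


def rewatered_timepoints(metadata: pd.DataFrame) -> set[str]:
    return set(metadata.loc[metadata["rewatered"], "timepoint"].unique())


def physiology_index_table(traits: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Per-genotype, per-timepoint physiological index table.

    For each genotype and timepoint the table reports the replicate-mean
    index together with the two-sided p-value of the drought vs well-watered
    t-test on the underlying replicate values:

    * ``rwc_drought`` / ``rwc_well_watered`` — mean leaf RWC per condition;
      p from the test on replicate RWC values.
    * ``osmolality_drought`` / ``osmolality_well_watered`` — mean leaf
      osmolality; p as above.
    * ``aoc_fold_change`` — replicate-mean AOC drought / replicate-mean AOC
      well-watered; p from the test on replicate AOC values.
    * ``relative_co2_assimilation`` and ``relative_stomatal_conductance`` —
      replicate-mean drought rate over replicate-mean control rate.
    """
    rows = []
    variant = config.ttest_variant
    for (genotype, timepoint), sub in traits.groupby(["genotype", "timepoint"], sort=True):
        d = sub[sub["condition"] == "drought"]
        w = sub[sub["condition"] == "well_watered"]

        def _vals(frame: pd.DataFrame, col: str) -> np.ndarray:
            if col not in frame.columns:
                return np.array([])
            return frame[col].dropna().to_numpy(dtype=float)

        def _p(a: np.ndarray, b: np.ndarray) -> float:
            if a.size >= 2 and b.size >= 2:
                return per_timepoint_ttest(a, b, variant)[1]
            return float("nan")

        if all(c in sub.columns for c in ("fresh_weight", "dry_weight", "saturated_weight")):
            rwc_d = np.array([
                relative_water_content(f, dr, s)
                for f, dr, s in d[["fresh_weight", "dry_weight", "saturated_weight"]]
                .dropna().to_numpy()
            ])
            rwc_w = np.array([
                relative_water_content(f, dr, s)
                for f, dr, s in w[["fresh_weight", "dry_weight", "saturated_weight"]]
                .dropna().to_numpy()
            ])
            p = _p(rwc_d, rwc_w)
            if rwc_d.size:
                rows.append((genotype, timepoint, "rwc_drought", rwc_d.mean(), p))
            if rwc_w.size:
                rows.append((genotype, timepoint, "rwc_well_watered", rwc_w.mean(), p))

        osm_d, osm_w = _vals(d, "osmolality"), _vals(w, "osmolality")
        p = _p(osm_d, osm_w)
        if osm_d.size:
            rows.append((genotype, timepoint, "osmolality_drought", osm_d.mean(), p))
        if osm_w.size:
            rows.append((genotype, timepoint, "osmolality_well_watered", osm_w.mean(), p))

        aoc_d, aoc_w = _vals(d, "aoc"), _vals(w, "aoc")
        if aoc_d.size and aoc_w.size and aoc_w.mean() > 0:
            rows.append((
                genotype, timepoint, "aoc_fold_change",
                trait_fold_change(aoc_d.mean(), aoc_w.mean()), _p(aoc_d, aoc_w),
            ))

        for col, name in (
            ("co2_assimilation", "relative_co2_assimilation"),
            ("stomatal_conductance", "relative_stomatal_conductance"),
        ):
            ds, ck = _vals(d, col), _vals(w, col)
            if ds.size and ck.size and ck.mean() > 0:
                rows.append((
                    genotype, timepoint, name,
                    relative_gas_exchange(ds.mean(), ck.mean()), _p(ds, ck),
                ))

    return pd.DataFrame(rows, columns=["genotype", "timepoint", "index", "value", "p_value"])
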