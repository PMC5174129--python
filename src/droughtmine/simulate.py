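"""Synthetic multi-omics drought study with a machine-readable ground truth.

The generator emulates the field design the pipeline targets: two rice
genotypes of contrasting drought tolerance ("tolerant", "susceptible"),
drought-stressed and well-watered plots, six sampling timepoints A-F
(A, B mild drought period I; C, D, E severe period II; F after re-watering,
period III), three biological replicates.

Planted structure, recorded in a :class:`SyntheticTruth` ledger so every
downstream stage is testable by recovery:

* *drought-responsive genes* shift by ``effect_size_lfc`` log2 units under
  drought only (periods I and II);
* *development-dependent genes* drift linearly across timepoints under
  BOTH conditions, so they are invisible to the drought contrast but light
  up between well-watered timepoints;
* *key metabolites* are linearly coupled (on the log2 scale) to a
  physiological trait (leaf osmolality or total antioxidant capacity) at
  replicate level, which makes them differential, trait-correlated and
  divergently regulated between genotypes, because the tolerant genotype
  mounts the stronger osmotic/antioxidant response;
* *candidate genes* are drought-responsive genes additionally co-regulated
  with a key metabolite (they track the same replicate-level trait signal)
  and share an annotated pathway with it.

Expression noise is log-normal (normal on the log2 scale) around the
genotype/condition/timepoint mean; metabolite peak intensities are
log-normal and each sample carries a random global intensity factor, which
sum normalization must remove.  Everything is a pure function of the spec
and its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io

GENOTYPES = ("tolerant", "susceptible")
DEFAULT_TIMEPOINTS = (
    ("A", "I"), ("B", "I"), ("C", "II"), ("D", "II"), ("E", "II"), ("F", "III"),
)

# Deterministic trait trajectories (before replicate noise).
_OSMOLALITY_BASE = 400.0          # mmol/kg, well-watered level
_OSMOLALITY_SCALE = 150.0         # divisor turning a rise into log2-coupling units
_OSM_RISE = {
    "tolerant": {"A": 0.0, "B": 50.0, "C": 200.0, "D": 300.0, "E": 350.0, "F": 50.0},
    "susceptible": {"A": 0.0, "B": 20.0, "C": 50.0, "D": 80.0, "E": 100.0, "F": 20.0},
}
_AOC_BASE = 10.0                  # assay units
_AOC_SCALE = 10.0
_AOC_MULT = {
    "tolerant": {"A": 1.0, "B": 1.3, "C": 2.5, "D": 3.0, "E": 2.5, "F": 1.2},
    "susceptible": {"A": 1.0, "B": 1.1, "C": 1.3, "D": 1.4, "E": 1.2, "F": 1.0},
}
_SWC_DROUGHT = {"A": 19.5, "B": 18.6, "C": 14.0, "D": 13.0, "E": 12.0, "F": 24.0}
_SWC_WATERED = 25.0
_CO2_WATERED = 20.0               # umol m-2 s-1
_CO2_DROUGHT_MULT = {
    "tolerant": {"A": 0.95, "B": 0.9, "C": 0.7, "D": 0.6, "E": 0.55, "F": 0.85},
    "susceptible": {"A": 0.7, "B": 0.6, "C": 0.4, "D": 0.3, "E": 0.3, "F": 0.8},
}
_GS_WATERED = 0.5                 # mol m-2 s-1
_GS_DROUGHT_MULT = {"A": 0.9, "B": 0.8, "C": 0.5, "D": 0.4, "E": 0.35, "F": 0.85}
# Grain yield / biomass anchors (t/ha-scale field means).
_YIELD = {
    "tolerant": {"well_watered": 10.65, "drought": 7.89},
    "susceptible": {"well_watered": 8.90, "drought": 1.84},
}
_BIOMASS = {
    "tolerant": {"well_watered": 28.35, "drought": 19.64},
    "susceptible": {"well_watered": 15.97, "drought": 7.90},
}

#: Replicate-level coupling of a candidate gene to its anchor trait signal
#: (log2 units per SD of the trait).
_GENE_TRAIT_COUPLING = 0.5
#: log2 intensity change of a key metabolite per scaled trait unit; at the
#: default trajectories the genotypes' planted log2FC differ by ~2 units in
#: the severe period, an unambiguous regulatory divergence.
_MET_TRAIT_COUPLING = 1.5
_FILLER_GENES_PER_PATHWAY = 8


class SpecError(ValueError):
    """Raised for an infeasible SimulationSpec."""


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study; defaults are the study conditions."""

    n_genes: int = 2000
    n_metabolites: int = 120
    timepoints: tuple[tuple[str, str], ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    effect_size_lfc: float = 2.0
    noise_sd_log_expression: float = 0.25
    noise_sd_log_metabolite: float = 0.25
    trait_noise_sd: float = 0.05          # relative SD of replicate trait values
    fraction_responsive: float = 0.05
    fraction_developmental: float = 0.05
    n_key_metabolites: int = 6
    n_candidate_genes: int = 12
    n_single_genotype_metabolites: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_metabolites < 1 or self.n_replicates < 1:
            raise SpecError("n_genes, n_metabolites and n_replicates must be >= 1")
        for name in ("noise_sd_log_expression", "noise_sd_log_metabolite", "trait_noise_sd"):
            if not getattr(self, name) > 0:
                raise SpecError(f"{name} must be > 0")
        if self.effect_size_lfc <= 0:
            raise SpecError("effect_size_lfc must be > 0")
        for name in ("fraction_responsive", "fraction_developmental"):
            if not 0 <= getattr(self, name) <= 1:
                raise SpecError(f"{name} must be a proportion")
        if self.fraction_responsive + self.fraction_developmental > 1:
            raise SpecError("planted gene fractions must sum to <= 1")
        if self.n_candidate_genes > self.n_responsive:
            raise SpecError(
                f"n_candidate_genes={self.n_candidate_genes} exceeds the "
                f"{self.n_responsive} planted responsive genes"
            )
        if self.n_key_metabolites == 0 and self.n_candidate_genes > 0:
            raise SpecError("candidate genes need at least one key metabolite to anchor to")
        if self.n_key_metabolites + 2 * self.n_single_genotype_metabolites > self.n_metabolites:
            raise SpecError("more planted metabolites than metabolites")
        labels = [tp for tp, _ in self.timepoints]
        if len(set(labels)) != len(labels):
            raise SpecError("timepoint labels must be unique")

    @property
    def n_responsive(self) -> int:
        return int(round(self.fraction_responsive * self.n_genes))

    @property
    def n_developmental(self) -> int:
        return int(round(self.fraction_developmental * self.n_genes))


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of every planted feature."""

    responsive_effects: dict[str, dict[str, float]]
    developmental_effects: dict[str, dict[str, float]]
    key_metabolites: dict[str, dict]
    candidate_genes: dict[str, dict]
    null_genes: set[str]
    null_metabolites: set[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, effects in self.responsive_effects.items():
            role = "candidate" if gene in self.candidate_genes else "responsive"
            anchor = self.candidate_genes.get(gene, {})
            rows.append((
                gene, "gene", role,
                anchor.get("metabolite", ""), anchor.get("pathway", ""), "",
                ";".join(f"{tp}:{eff:.4g}" for tp, eff in sorted(effects.items())),
            ))
        for gene, effects in self.developmental_effects.items():
            rows.append((
                gene, "gene", "developmental", "", "", "",
                ";".join(f"{tp}:{eff:.4g}" for tp, eff in sorted(effects.items())),
            ))
        for met, info in self.key_metabolites.items():
            rows.append((
                met, "metabolite", "key", "", info.get("pathway", ""),
                info["trait"], f"coupling:{info['coupling']:.4g}",
            ))
        return pd.DataFrame(rows, columns=[
            "feature_id", "feature_type", "role", "anchor_metabolite",
            "pathway", "trait", "planted_effects",
        ])


@dataclass
class Bundle:
    """One complete synthetic input set plus its truth."""

    expression: pd.DataFrame
    metabolites: pd.DataFrame
    traits: pd.DataFrame
    annotation: dict[str, tuple[str, frozenset[str]]]
    metadata: pd.DataFrame
    truth: SyntheticTruth


def _trait_tables(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Replicate-level physiological trait table for all conditions."""
    rows = []
    for genotype in GENOTYPES:
        gy = {c: _YIELD[genotype][c] for c in io.CONDITIONS}
        bim = {c: _BIOMASS[genotype][c] for c in io.CONDITIONS}
        for condition in io.CONDITIONS:
            for tp, period in spec.timepoints:
                for rep in range(1, spec.n_replicates + 1):
                    rel = lambda: 1.0 + rng.normal(0.0, spec.trait_noise_sd)
                    if condition == "drought":
                        osm = (_OSMOLALITY_BASE + _OSM_RISE[genotype][tp]) * rel()
                        aoc = _AOC_BASE * _AOC_MULT[genotype][tp] * rel()
                        swc = _SWC_DROUGHT[tp] + rng.normal(0.0, 0.3)
                        fresh = {"I": 0.93, "II": 0.88, "III": 0.94}[period]
                        co2 = _CO2_WATERED * _CO2_DROUGHT_MULT[genotype][tp] * rel()
                        gs = _GS_WATERED * _GS_DROUGHT_MULT[tp] * rel()
                    else:
                        osm = _OSMOLALITY_BASE * rel()
                        aoc = _AOC_BASE * rel()
                        swc = _SWC_WATERED + rng.normal(0.0, 0.3)
                        fresh = 0.95
                        co2 = _CO2_WATERED * rel()
                        gs = _GS_WATERED * rel()
                    fresh = float(np.clip(fresh + rng.normal(0.0, 0.005), 0.21, 0.999))
                    rows.append((
                        genotype, condition, tp, rep,
                        fresh, 0.2, 1.0, osm, aoc, swc, co2, gs,
                        gy[condition] * rel(), bim[condition] * rel(),
                    ))
    return pd.DataFrame(rows, columns=[
        "genotype", "condition", "timepoint", "replicate",
        "fresh_weight", "dry_weight", "saturated_weight",
        "osmolality", "aoc", "soil_water_content",
        "co2_assimilation", "stomatal_conductance", "grain_yield", "biomass",
    ])


def _sample_sheet(spec: SimulationSpec) -> pd.DataFrame:
    samples = []
    for genotype in GENOTYPES:
        for condition in io.CONDITIONS:
            short = "D" if condition == "drought" else "W"
            for tp, period in spec.timepoints:
                for rep in range(1, spec.n_replicates + 1):
                    samples.append(io.SampleMetadata(
                        sample_id=f"{genotype}_{short}_{tp}_r{rep}",
                        genotype=genotype,
                        condition=condition,
                        timepoint=tp,
                        replicate=rep,
                        rewatered=(period == "III"),
                    ))
    return io.metadata_frame(samples)


def _trait_lookup(traits: pd.DataFrame, col: str) -> dict[tuple, float]:
    return {
        (r.genotype, r.condition, r.timepoint, r.replicate): getattr(r, col)
        for r in traits.itertuples(index=False)
    }


def generate_dataset(spec: SimulationSpec) -> Bundle:
    """Generate a complete input bundle; a pure function of the spec."""
    rng = np.random.default_rng(spec.rng_seed)
    tp_labels = [tp for tp, _ in spec.timepoints]
    periods = dict(spec.timepoints)
    T = len(tp_labels)

    metadata = _sample_sheet(spec)
    traits = _trait_tables(spec, rng)
    osm_lookup = _trait_lookup(traits, "osmolality")
    aoc_lookup = _trait_lookup(traits, "aoc")

    genes = [f"gene_{i:04d}" for i in range(spec.n_genes)]
    roles = rng.permutation(spec.n_genes)
    responsive_idx = roles[: spec.n_responsive]
    developmental_idx = roles[spec.n_responsive: spec.n_responsive + spec.n_developmental]
    candidate_idx = responsive_idx[: spec.n_candidate_genes]

    mets = [f"met_{i:04d}" for i in range(spec.n_metabolites)]
    met_roles = rng.permutation(spec.n_metabolites)
    key_idx = met_roles[: spec.n_key_metabolites]
    s = spec.n_key_metabolites
    only_a_idx = met_roles[s: s + spec.n_single_genotype_metabolites]
    only_b_idx = met_roles[
        s + spec.n_single_genotype_metabolites: s + 2 * spec.n_single_genotype_metabolites
    ]

    # --- planted gene effects ------------------------------------------------
    gene_sign = rng.choice([-1.0, 1.0], size=spec.n_genes)
    responsive_effects: dict[str, dict[str, float]] = {}
    for gi in responsive_idx:
        eff = {
            tp: (gene_sign[gi] * spec.effect_size_lfc if periods[tp] in ("I", "II") else 0.0)
            for tp in tp_labels
        }
        responsive_effects[genes[gi]] = eff
    developmental_effects: dict[str, dict[str, float]] = {}
    for gi in developmental_idx:
        developmental_effects[genes[gi]] = {
            tp: gene_sign[gi] * spec.effect_size_lfc * k / (T - 1) if T > 1 else 0.0
            for k, tp in enumerate(tp_labels)
        }

    # --- key metabolites and candidate anchoring -----------------------------
    key_metabolites: dict[str, dict] = {}
    for k, mi in enumerate(key_idx):
        trait = "osmolality" if k % 2 == 0 else "aoc"
        key_metabolites[mets[mi]] = {
            "trait": trait,
            "coupling": _MET_TRAIT_COUPLING,
            "pathway": f"osa009{40 + k:02d}",
        }
    key_ids = list(key_metabolites)
    candidate_genes: dict[str, dict] = {}
    for j, gi in enumerate(candidate_idx):
        met = key_ids[j % len(key_ids)]
        candidate_genes[genes[gi]] = {
            "metabolite": met,
            "pathway": key_metabolites[met]["pathway"],
            "trait": key_metabolites[met]["trait"],
            "coupling": _GENE_TRAIT_COUPLING,
        }
        # candidate drought effects follow the anchor trait's trajectory
        # (full planted strength at the trait's peak), so the gene is
        # co-regulated with its anchoring metabolite across timepoints
        trait = key_metabolites[met]["trait"]
        traj = _OSM_RISE["tolerant"] if trait == "osmolality" else {
            tp: (_AOC_MULT["tolerant"][tp] - 1.0) for tp in tp_labels
        }
        peak = max(traj.values()) or 1.0
        responsive_effects[genes[gi]] = {
            tp: gene_sign[gi] * spec.effect_size_lfc * (0.5 + 0.5 * traj[tp] / peak)
            for tp in tp_labels
        }

    # --- replicate-level trait signals per sample ----------------------------
    sample_ids = metadata.index.tolist()
    n_samples = len(sample_ids)
    meta_rows = metadata.loc[sample_ids]
    # standardized drought-trait deviation per genotype (0 for watered samples)
    z_trait: dict[str, np.ndarray] = {}
    for trait, lookup, base, scale in (
        ("osmolality", osm_lookup, _OSMOLALITY_BASE, _OSMOLALITY_SCALE),
        ("aoc", aoc_lookup, _AOC_BASE, _AOC_SCALE),
    ):
        scaled = np.array([
            (lookup[(r.genotype, r.condition, r.timepoint, r.replicate)] - base) / scale
            for r in meta_rows.itertuples()
        ])
        z_trait[trait] = scaled

    def standardized(trait: str, genotype: str) -> np.ndarray:
        """Trait z-scored within the genotype's drought samples; 0 elsewhere."""
        mask = (meta_rows["genotype"] == genotype) & (meta_rows["condition"] == "drought")
        out = np.zeros(n_samples)
        vals = z_trait[trait][mask.to_numpy()]
        sd = vals.std(ddof=1)
        if sd > 0:
            out[mask.to_numpy()] = (vals - vals.mean()) / sd
        return out

    z_std = {
        (trait, genotype): standardized(trait, genotype)
        for trait in ("osmolality", "aoc") for genotype in GENOTYPES
    }

    # --- expression matrix ---------------------------------------------------
    mu = rng.uniform(2.0, 10.0, size=spec.n_genes)
    E = np.zeros((spec.n_genes, n_samples))
    is_drought = (meta_rows["condition"] == "drought").to_numpy()
    tp_of = meta_rows["timepoint"].to_numpy()
    for gene, eff in responsive_effects.items():
        gi = genes.index(gene)
        per_sample = np.array([eff[tp] for tp in tp_of])
        E[gi] += per_sample * is_drought
    for gene, eff in developmental_effects.items():
        gi = genes.index(gene)
        E[gi] += np.array([eff[tp] for tp in tp_of])
    for gene, info in candidate_genes.items():
        gi = genes.index(gene)
        coupling = np.zeros(n_samples)
        for genotype in GENOTYPES:
            coupling += z_std[(info["trait"], genotype)]
        E[gi] += gene_sign[gi] * _GENE_TRAIT_COUPLING * coupling
    log2x = mu[:, None] + E + rng.normal(0.0, spec.noise_sd_log_expression,
                                         size=(spec.n_genes, n_samples))
    expression = pd.DataFrame(2.0 ** log2x, index=pd.Index(genes, name="gene_id"),
                              columns=sample_ids)

    # --- metabolite table ----------------------------------------------------
    log2base = rng.uniform(10.0, 20.0, size=spec.n_metabolites)
    # key metabolites are moderate-abundance peaks: a dominating peak that
    # rises under drought would drag the per-sample sum with it and closure
    # after sum normalization would erase the planted log2FC divergence
    if len(key_idx):
        log2base[np.asarray(key_idx, dtype=int)] = rng.uniform(10.0, 14.0, size=len(key_idx))
    B = np.zeros((spec.n_metabolites, n_samples))
    for met, info in key_metabolites.items():
        mi = mets.index(met)
        B[mi] += info["coupling"] * z_trait[info["trait"]]
    log2m = log2base[:, None] + B + rng.normal(0.0, spec.noise_sd_log_metabolite,
                                               size=(spec.n_metabolites, n_samples))
    sample_factor = rng.uniform(0.5, 2.0, size=n_samples)
    intensities = (2.0 ** log2m) * sample_factor[None, :]
    metabolites = pd.DataFrame(intensities, index=pd.Index(mets, name="metabolite_id"),
                               columns=sample_ids)
    geno_of = meta_rows["genotype"].to_numpy()
    for mi in only_a_idx:   # detected only in the tolerant genotype
        metabolites.iloc[mi, geno_of == GENOTYPES[1]] = np.nan
    for mi in only_b_idx:   # detected only in the susceptible genotype
        metabolites.iloc[mi, geno_of == GENOTYPES[0]] = np.nan

    # --- annotation sets -----------------------------------------------------
    planted_gene_ids = set(responsive_effects) | set(developmental_effects)
    null_gene_pool = [g for g in genes if g not in planted_gene_ids]
    annotation: dict[str, tuple[str, frozenset[str]]] = {}
    for met, info in key_metabolites.items():
        members = {met} | {
            g for g, c in candidate_genes.items() if c["metabolite"] == met
        }
        n_fill = min(_FILLER_GENES_PER_PATHWAY, len(null_gene_pool))
        if n_fill:
            members |= set(rng.choice(null_gene_pool, size=n_fill, replace=False))
        annotation[info["pathway"]] = (f"Anchor pathway for {met}", frozenset(members))
    for pid, desc in zip(
        ("ko00196", "ko00710", "ko00720", "ko00195", "ko00190"),
        ("Photosynthesis - antenna proteins",
         "Carbon fixation in photosynthetic organisms",
         "Carbon fixation pathways in prokaryotes",
         "Photosynthesis", "Oxidative phosphorylation"),
    ):
        size = min(30, spec.n_genes)
        annotation[pid] = (desc, frozenset(rng.choice(genes, size=size, replace=False)))
    for k in range(4):
        size = min(25, spec.n_genes)
        annotation[f"GO:00069{70 + k:02d}"] = (
            f"synthetic GO term {k}", frozenset(rng.choice(genes, size=size, replace=False)),
        )

    truth = SyntheticTruth(
        responsive_effects=responsive_effects,
        developmental_effects=developmental_effects,
        key_metabolites=key_metabolites,
        candidate_genes=candidate_genes,
        null_genes=set(null_gene_pool),
        null_metabolites={
            m for i, m in enumerate(mets)
            if i not in set(key_idx) | set(only_a_idx) | set(only_b_idx)
        },
    )
    return Bundle(expression, metabolites, traits, annotation, metadata, truth)


def scaled_spec(n_genes: int, n_metabolites: int, rng_seed: int = 0, **overrides) -> SimulationSpec:
    """A feasible spec at a requested size, keeping the default proportions."""
    n_resp = int(round(SimulationSpec.__dataclass_fields__["fraction_responsive"].default * n_genes))
    n_key = min(6, max(1, n_metabolites // 8))
    defaults = dict(
        n_genes=n_genes,
        n_metabolites=n_metabolites,
        n_key_metabolites=n_key,
        n_candidate_genes=min(12, n_resp),
        n_single_genotype_metabolites=min(10, max(0, (n_metabolites - n_key) // 6)),
        rng_seed=rng_seed,
    )
    defaults.update(overrides)
    return SimulationSpec(**defaults)


def null_spec(rng_seed: int = 0, **overrides) -> SimulationSpec:
    """A spec with no planted structure (for null calibration)."""
    defaults = dict(
        fraction_responsive=0.0, fraction_developmental=0.0,
        n_key_metabolites=0, n_candidate_genes=0,
        n_single_genotype_metabolites=0, rng_seed=rng_seed,
    )
    defaults.update(overrides)
    return SimulationSpec(**defaults)


def write_bundle(bundle: Bundle, out_dir: str | Path, include_truth: bool = True) -> dict[str, Path]:
    """Write the bundle in the dialects the readers consume.

    The truth ledger is written alongside but is never read by the
    pipeline; it exists for recovery tests only.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metabolites": out / "metabolites.csv",
        "traits": out / "traits.csv",
        "annotation": out / "annotations.gmt",
        "metadata": out / "samples.csv",
    }
    io.write_expression_matrix(bundle.expression, paths["expression"])
    io.write_metabolite_table(bundle.metabolites, paths["metabolites"])
    io.write_table(bundle.traits, paths["traits"], sep=",", index=False)
    io.write_annotation_gmt(bundle.annotation, paths["annotation"])
    io.write_sample_metadata(bundle.metadata, paths["metadata"])
    if include_truth:
        paths["truth"] = out / "truth.csv"
        bundle.truth.to_frame().to_csv(paths["truth"], index=False)
    return paths


#: Seed of the hand-auditable worked fixture (fixed; part of the fixture).
WORKED_FIXTURE_SEED = 20140825


def worked_fixture_spec() -> SimulationSpec:
    return SimulationSpec(
        n_genes=20,
        n_metabolites=10,
        n_replicates=2,
        noise_sd_log_expression=0.01,
        noise_sd_log_metabolite=0.01,
        trait_noise_sd=0.01,
        fraction_responsive=0.2,      # 4 responsive genes, 2 of them candidates
        fraction_developmental=0.1,   # 2 development-dependent genes
        n_key_metabolites=2,
        n_candidate_genes=2,
        n_single_genotype_metabolites=1,
        rng_seed=WORKED_FIXTURE_SEED,
    )


def make_worked_fixture() -> Bundle:
    """Miniature, near-noise-free bundle for hand tracing.

    20 genes x 10 metabolites, 6 timepoints, 2 replicates, noise SDs of
    0.01 so every planted effect is visually obvious in the written files.
    Deterministic: the same bundle on every call.
    """
    return generate_dataset(worked_fixture_spec())
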