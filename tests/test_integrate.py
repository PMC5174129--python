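"""Correlation layers, enrichment and the metabolite-centered mining."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import droughtmine as dm
from droughtmine import integrate


def hypergeom_oracle(overlap, universe, set_size, selected):
    """P(X >= overlap) by exhaustive enumeration of all selected-size draws."""
    members = set(range(set_size))
    total = hits = 0
    for draw in itertools.combinations(range(universe), selected):
        total += 1
        if len(members & set(draw)) >= overlap:
            hits += 1
    return hits / total


class TestPearson:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [6, 4, 2], -1.0),
        ([1, 2, 3], [1, 3, 2], 0.5),
    ])
    def test_values(self, x, y, expected):
        r, p, n = dm.pearson(x, y)
        assert r == pytest.approx(expected)
        assert n == 3

    def test_missing_pairs_dropped(self):
        r, p, n = dm.pearson([1, 2, 3, np.nan], [2, 4, 6, 100])
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            dm.pearson([1, 1, 1], [1, 2, 3])

    @settings(derandomize=True, max_examples=30)
    @given(
        scale=st.floats(0.01, 50.0), shift=st.floats(-100.0, 100.0),
        seed=st.integers(0, 100),
    )
    def test_affine_invariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r1, p1, _ = dm.pearson(x, y)
        r2, p2, _ = dm.pearson(scale * x + shift, y)
        assert r1 == pytest.approx(r2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-9)


class TestHypergeometric:
    def test_worked_example(self):
        ann = {"s": ("d", frozenset(f"g{i}" for i in range(4)))}
        universe = [f"g{i}" for i in range(10)]
        selected = [f"g{i}" for i in range(5)]   # overlap 4
        res = dm.hypergeometric_enrichment(selected, ann, universe)
        assert res.loc[0, "p_value"] == pytest.approx(6 / 252)

    def test_degenerate_cases(self):
        universe = ["a", "b", "c"]
        ann = {"all": ("d", frozenset(universe))}
        res = dm.hypergeometric_enrichment(universe, ann, universe)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)
        res_empty = dm.hypergeometric_enrichment([], ann, universe)
        assert res_empty.loc[0, "p_value"] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            dm.hypergeometric_enrichment([], ann, [])

    def test_small_enumeration_sweep(self):
        for universe in (5, 8):
            for set_size in (2, 4):
                for selected in (2, 3):
                    ann = {"s": ("d", frozenset(f"g{i}" for i in range(set_size)))}
                    ids = [f"g{i}" for i in range(universe)]
                    res = dm.hypergeometric_enrichment(ids[:selected], ann, ids)
                    overlap = res.loc[0, "overlap"]
                    assert res.loc[0, "p_value"] == pytest.approx(
                        hypergeom_oracle(overlap, universe, set_size, selected), abs=1e-12
                    )


class TestEnergyClassification:
    def test_membership_rules(self):
        ann = {
            "ko00195": ("Photosynthesis", frozenset({"g1", "g3"})),
            "ko00190": ("Oxidative phosphorylation", frozenset({"g3"})),
            "osa00940": ("unrelated", frozenset({"g2"})),
        }
        result = dm.classify_energy_related(["g1", "g2", "g3", "g4"], ann)
        assert result == {"g1", "g3"}   # g3 counted once, g2 not energy, g4 unannotated

    def test_missing_pathways_warn_but_proceed(self, caplog):
        ann = {"ko00195": ("Photosynthesis", frozenset({"g1"}))}
        with caplog.at_level("WARNING"):
            result = dm.classify_energy_related(["g1"], ann)
        assert result == {"g1"}
        assert "absent" in caplog.text


class TestTraitLayer:
    def _feature_frame(self, rows, cols):
        return pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))], columns=cols)

    def test_feature_equal_to_trait_flagged(self, default_config):
        cols = [f"s{i}" for i in range(6)]
        trait = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=cols)
        features = self._feature_frame([trait.to_numpy(), [1, 1, 2, 1, 1, 2]], cols)
        edges = integrate.correlate_features_with_series(
            features, trait, "gene-trait", default_config, "osmolality"
        )
        assert "f0" in set(edges["source_id"])
        assert edges.set_index("source_id").loc["f0", "r"] == pytest.approx(1.0)

    def test_anticorrelation_flagged_two_sided(self, default_config):
        cols = [f"s{i}" for i in range(8)]
        rng = np.random.default_rng(0)
        trait = pd.Series(np.arange(8.0), index=cols)
        anti = -trait.to_numpy() + rng.normal(0, 0.5, 8)
        edges = integrate.correlate_features_with_series(
            self._feature_frame([anti], cols), trait, "gene-trait",
            default_config, "osmolality",
        )
        assert len(edges) == 1 and edges.loc[0, "r"] < -0.6

    def test_null_flag_rate_small(self, default_config):
        cols = [f"s{i}" for i in range(18)]
        trait = pd.Series(np.linspace(0, 5, 18), index=cols)
        flagged = total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            features = self._feature_frame(rng.normal(size=(50, 18)), cols)
            edges = integrate.correlate_features_with_series(
                features, trait, "gene-trait", default_config, "osmolality"
            )
            flagged += len(edges)
            total += 50
        assert flagged / total < 0.05


class TestKeyMetabolitesAndMining:
    def test_criteria_columns(self, worked_results, worked_bundle):
        key = worked_results["integration"]["key_metabolites"]
        planted = set(worked_bundle.truth.key_metabolites)
        assert set(key.loc[key["is_key"], "metabolite_id"]) == planted
        # a metabolite missing in one genotype fails the shared criterion
        assert not key.loc[~key["shared"], "is_key"].any()

    def test_gene_without_metabolite_edge_excluded(self, default_config):
        ann = {"pw": ("d", frozenset({"metX", "g1", "g2"}))}
        degs = pd.DataFrame({
            "gene_id": ["g1", "g2"], "timepoint": "A", "log2fc": [2.0, 2.0],
            "p_value": 0.01, "q_value": 0.01, "direction": "up",
            "is_deg": True, "development_dependent": False,
        })
        flags = pd.DataFrame(
            {"osmolality_correlated": [True, True], "aoc_correlated": [False, False]},
            index=["g1", "g2"],
        )
        edges = pd.DataFrame({
            "source_id": ["g1"], "target_id": ["metX"], "layer": "gene-metabolite",
            "r": [0.9], "p_value": [0.001], "n": [18],
        })
        mined = dm.mine_candidate_genes(
            ["metX"], {"G": degs}, {"G": flags}, edges, ann, default_config
        )
        assert set(mined["gene_id"]) == {"g1"}

    def test_empty_compound_pathway_map_gives_no_candidates(self, default_config):
        mined = dm.mine_candidate_genes(
            ["metX"], {"G": pd.DataFrame(columns=[
                "gene_id", "timepoint", "log2fc", "p_value", "q_value",
                "direction", "is_deg", "development_dependent"])},
            {"G": pd.DataFrame()},
            pd.DataFrame(columns=integrate.EDGE_COLUMNS),
            {}, default_config,
        )
        assert mined.empty

    def test_candidates_shrink_as_r_threshold_tightens(self, worked_bundle, default_config):
        import dataclasses
        import droughtmine.pipeline as pl
        paths = None
        inputs = pl.Inputs(
            worked_bundle.expression, worked_bundle.metabolites, worked_bundle.traits,
            worked_bundle.annotation, worked_bundle.metadata,
        )
        results = {}
        for r_thr in (0.6, 0.9):
            cfg = dataclasses.replace(default_config, corr_r_threshold=r_thr)
            phys = pl.stage_physiology(inputs, cfg)
            degr = pl.stage_deg(inputs, cfg, phys["period_map"])
            met = pl.stage_metabolome(inputs, cfg, phys["period_map"])
            integ = pl.stage_integrate(inputs, cfg, degr, met, phys["period_map"])
            results[r_thr] = set(integ["candidates"].get("gene_id", []))
        assert results[0.9] <= results[0.6]

    def test_worked_fixture_candidates_exact(self, worked_results, worked_bundle):
        mined = set(worked_results["integration"]["candidates"]["gene_id"])
        assert mined == set(worked_bundle.truth.candidate_genes)


class TestClustering:
    def test_duplicate_profiles_merge_at_zero(self):
        profiles = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]], index=["a", "b", "c"])
        order, Z = dm.cluster_profiles(profiles)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_two_groups_recovered_at_top_split(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal(0, 0.1, (5, 4))
        g2 = rng.normal(8, 0.1, (5, 4))
        profiles = pd.DataFrame(np.vstack([g1, g2]),
                                index=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)])
        order, _ = dm.cluster_profiles(profiles)
        first_half = {name[0] for name in order[:5]}
        assert first_half in ({"a"}, {"b"})

    def test_single_pair_merges_at_distance(self):
        profiles = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        _, Z = dm.cluster_profiles(profiles)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(5.0)
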