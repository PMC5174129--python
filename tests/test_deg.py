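"""Differential-expression calling, the development filter and profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import droughtmine as dm
from droughtmine import deg, io


def bh_oracle(pvals):
    """Sorting-based Benjamini-Hochberg: q_i = min over j>=rank(i) of p_j*m/j."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestLog2FoldChange:
    @pytest.mark.parametrize("d,w,expected", [
        (0.0, 0.0, 0.0),
        (5.0, 5.0, 0.0),
        (4.0, 1.0, np.log2(4.00001 / 1.00001)),
    ])
    def test_values(self, d, w, expected):
        assert dm.log2_fold_change(d, w) == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dm.log2_fold_change(-1.0, 2.0)


class TestBenjaminiHochberg:
    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=80))
    def test_matches_sorting_oracle(self, pvals):
        np.testing.assert_allclose(dm.bh_adjust(pvals), bh_oracle(pvals), atol=1e-12)

    def test_bounded_and_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = dm.bh_adjust(p)
        assert (q <= 1.0).all() and (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


def _two_condition_matrix(effects, n_rep=3, noise=0.05, seed=0):
    """Matrix with one timepoint, len(effects) genes, planted drought effects."""
    rng = np.random.default_rng(seed)
    samples = [io.SampleMetadata(f"d{r}", "g", "drought", "A", r + 1) for r in range(n_rep)]
    samples += [io.SampleMetadata(f"w{r}", "g", "well_watered", "A", r + 1) for r in range(n_rep)]
    meta = io.metadata_frame(samples)
    base = 6.0
    rows = []
    for eff in effects:
        d = 2.0 ** (base + eff + rng.normal(0, noise, n_rep))
        w = 2.0 ** (base + rng.normal(0, noise, n_rep))
        rows.append(np.concatenate([d, w]))
    matrix = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(effects))],
                          columns=meta.index)
    return matrix, meta


class TestReplicatedCalling:
    def test_dual_threshold_respected(self, default_config):
        matrix, meta = _two_condition_matrix([3.0, 0.5, 0.0] + [0.0] * 20)
        table = dm.call_degs_replicated(matrix, meta, "g", "A", default_config)
        by_gene = table.set_index("gene_id")
        assert bool(by_gene.loc["g0", "is_deg"])          # large effect
        assert not bool(by_gene.loc["g1", "is_deg"])      # |lfc| < 1 despite small p
        hits = table[table["is_deg"]]
        assert (hits["q_value"] < default_config.deg_fdr_threshold).all()
        assert (hits["log2fc"].abs() >= default_config.deg_lfc_threshold).all()
        assert (table["q_value"] >= table["p_value"] - 1e-12).all()

    def test_direction_consistent_with_sign(self, default_config):
        matrix, meta = _two_condition_matrix([2.0, -2.0] + [0.0] * 10)
        table = dm.call_degs_replicated(matrix, meta, "g", "A", default_config)
        by_gene = table.set_index("gene_id")
        assert by_gene.loc["g0", "direction"] == "up"
        assert by_gene.loc["g1", "direction"] == "down"

    def test_replicate_order_invariance(self, default_config):
        matrix, meta = _two_condition_matrix([2.0] + [0.0] * 10)
        shuffled = matrix[list(matrix.columns[::-1])]
        a = dm.call_degs_replicated(matrix, meta, "g", "A", default_config)
        b = dm.call_degs_replicated(shuffled, meta, "g", "A", default_config)
        pd.testing.assert_series_equal(a["is_deg"], b["is_deg"])

    def test_too_few_replicates_directs_to_unreplicated(self, default_config):
        matrix, meta = _two_condition_matrix([1.0], n_rep=1)
        with pytest.raises(ValueError, match="unreplicated"):
            dm.call_degs_replicated(matrix, meta, "g", "A", default_config)


class TestUnreplicatedCalling:
    def test_zero_fold_change_never_deg(self, default_config):
        matrix, meta = _two_condition_matrix([0.0] * 50, n_rep=1, noise=0.3)
        matrix.iloc[0] = [4.0, 4.0]  # exactly equal -> lfc 0
        table = dm.call_degs_unreplicated(matrix, meta, "g", "A", default_config)
        assert not bool(table.set_index("gene_id").loc["g0", "is_deg"])

    def test_null_p_roughly_uniform(self, default_config):
        rates = []
        for seed in range(3):
            spec = dm.null_spec(rng_seed=seed, n_genes=500, n_metabolites=10, n_replicates=1)
            bundle = dm.generate_dataset(spec)
            table = dm.call_degs_unreplicated(
                bundle.expression, bundle.metadata, "tolerant", "C", default_config
            )
            rates.append((table["p_value"] < 0.05).mean())
        assert np.mean(rates) < 0.075   # 1.5x nominal

    def test_planted_effect_detected(self, default_config):
        spec = dm.SimulationSpec(
            n_genes=400, n_metabolites=10, n_key_metabolites=2, n_candidate_genes=2,
            n_single_genotype_metabolites=0, n_replicates=1, rng_seed=3,
        )
        bundle = dm.generate_dataset(spec)
        table = dm.call_degs_unreplicated(
            bundle.expression, bundle.metadata, "tolerant", "C", default_config
        )
        hits = set(table.loc[table["is_deg"], "gene_id"])
        planted = set(bundle.truth.responsive_effects)
        assert len(hits & planted) / len(planted) >= 0.9


class TestDevelopmentFilter:
    def test_planted_wellwatered_shift_flagged(self, default_config):
        # gene 0 quadruples between well-watered timepoints A and C
        rng = np.random.default_rng(1)
        samples = []
        for tp in "ABC":
            for r in range(3):
                samples.append(io.SampleMetadata(f"w_{tp}{r}", "g", "well_watered", tp, r + 1))
                samples.append(io.SampleMetadata(f"d_{tp}{r}", "g", "drought", tp, r + 1))
        meta = io.metadata_frame(samples)
        base = np.full(len(meta), 6.0)
        shift = np.array([2.0 if meta.loc[s, "timepoint"] == "C" else 0.0 for s in meta.index])
        rows = [2.0 ** (base + shift + rng.normal(0, 0.05, len(meta)))]
        for _ in range(15):
            rows.append(2.0 ** (base + rng.normal(0, 0.05, len(meta))))
        matrix = pd.DataFrame(rows, index=[f"g{i}" for i in range(16)], columns=meta.index)
        flagged = dm.flag_development_dependent(matrix, meta, "g", default_config)
        assert "g0" in flagged

    def test_constant_gene_not_flagged(self, worked_bundle, default_config):
        flagged = dm.flag_development_dependent(
            worked_bundle.expression, worked_bundle.metadata, "tolerant", default_config
        )
        assert flagged == set(worked_bundle.truth.developmental_effects)

    def test_final_table_excludes_flagged_genes(self, worked_results, worked_bundle):
        for table in worked_results["deg"]["tables"].values():
            hits = table[table["is_deg"]]
            assert not set(hits["gene_id"]) & set(worked_bundle.truth.developmental_effects)
            flagged_rows = table[table["development_dependent"]]
            assert not flagged_rows["is_deg"].any()


class TestProfilesAndCounts:
    @pytest.mark.parametrize("value,expected", [(7.3, 6.0), (-8.0, -6.0), (5.9, 5.9)])
    def test_capping(self, value, expected):
        profile = pd.DataFrame({"A": [value]})
        capped = dm.cap_profile(profile, 6.0)
        assert capped.iloc[0, 0] == pytest.approx(expected)
        pd.testing.assert_frame_equal(dm.cap_profile(capped, 6.0), capped)

    def test_mean_abs_fc_unchanged_when_within_cap(self):
        profile = pd.DataFrame(np.random.default_rng(0).uniform(-5, 5, (20, 6)))
        capped = dm.cap_profile(profile, 6.0)
        assert capped.abs().mean().mean() == pytest.approx(profile.abs().mean().mean())

    def test_summary_set_arithmetic(self):
        def table(genes, tp="A"):
            return pd.DataFrame({
                "gene_id": genes, "timepoint": tp, "log2fc": 2.0, "p_value": 0.01,
                "q_value": 0.01, "direction": "up", "is_deg": True,
                "development_dependent": False,
            })
        summary = dm.summarize_deg_counts(
            {"g1": table(["a", "b", "c"]), "g2": table(["b", "c", "d"])},
            period_map={"A": "I"},
        )
        assert summary["common"]["A"] == {"b", "c"}
        union = summary["period_unions"]["g1"]["I"] | summary["period_unions"]["g2"]["I"]
        assert len(union) == 4
        counts = summary["counts"].set_index("genotype")
        assert counts.loc["g1", "total"] == 3

    def test_disjoint_and_identical_sets(self):
        def table(genes):
            return pd.DataFrame({
                "gene_id": genes, "timepoint": "A", "log2fc": 2.0, "p_value": 0.01,
                "q_value": 0.01, "direction": "up", "is_deg": True,
                "development_dependent": False,
            })
        disjoint = dm.summarize_deg_counts({"g1": table(["a"]), "g2": table(["b"])})
        assert disjoint["common"]["A"] == set()
        same = dm.summarize_deg_counts({"g1": table(["a", "b"]), "g2": table(["a", "b"])})
        assert same["common"]["A"] == {"a", "b"}
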