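"""Generator contracts: conservation, neutral limits, redundancy effects,
determinism, and the numba kernel against its pure-python mirror."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from phycosphere.diversity import beta_diversity
from phycosphere.io import AbundanceTable, to_relative
from phycosphere.partition import partition_taxa
from phycosphere.synthetic import (
    GuildMap,
    Metacommunity,
    NeutralSimConfig,
    _moran_python,
    attach_functions,
    effective_dispersal,
    generate_redundant_strains,
    sample_metacommunity,
    simulate_local_communities,
)


def shannon_evenness(p):
    return -(p * np.log(p)).sum() / np.log(len(p))


class TestMetacommunity:
    def test_single_taxon_is_unit_mass(self):
        meta = sample_metacommunity(1, shape=2.0, seed=0)
        np.testing.assert_allclose(meta.p, [1.0])

    def test_normalized_and_sorted(self):
        meta = sample_metacommunity(100, shape=1.0, seed=5)
        assert abs(meta.p.sum() - 1.0) < 1e-9
        assert (np.diff(meta.p) <= 0).all()
        assert len(set(meta.taxon_ids)) == 100

    def test_larger_sigma_more_dominance(self):
        even = sample_metacommunity(100, shape=0.5, seed=7)
        skewed = sample_metacommunity(100, shape=2.0, seed=7)
        assert shannon_evenness(skewed.p) < shannon_evenness(even.p)

    @pytest.mark.parametrize("n,shape", [(0, 1.0), (5, 0.0), (5, -1.0)])
    def test_invalid_arguments(self, n, shape):
        with pytest.raises(ValueError):
            sample_metacommunity(n, shape)

    def test_deterministic_per_seed(self):
        a = sample_metacommunity(50, 1.0, seed=3)
        b = sample_metacommunity(50, 1.0, seed=3)
        np.testing.assert_array_equal(a.p, b.p)


class TestNeutralSimulation:
    def test_rows_sum_to_n_exactly(self):
        meta = sample_metacommunity(30, 1.0, seed=1)
        cfg = NeutralSimConfig(N=257, m=0.3, n_samples=12, seed=2)
        t = simulate_local_communities(meta, cfg)
        assert (t.values.sum(axis=1) == 257).all()

    def test_m_zero_rejected(self):
        with pytest.raises(ValueError):
            NeutralSimConfig(N=100, m=0.0, n_samples=5)

    def test_numba_kernel_matches_python_mirror(self):
        meta = sample_metacommunity(20, 1.0, seed=9)
        cfg = NeutralSimConfig(N=50, m=0.2, n_samples=4, burn_in=500, seed=9)
        fast = simulate_local_communities(meta, cfg)
        slow = simulate_local_communities(meta, cfg, _kernel=_moran_python)
        np.testing.assert_array_equal(fast.values, slow.values)

    def test_full_immigration_is_multinomial(self):
        """m=1: every sample is a fresh multinomial(N, p) draw; the mean
        relative abundance tracks p within sampling error."""
        meta = sample_metacommunity(25, 1.0, seed=4)
        cfg = NeutralSimConfig(N=500, m=1.0, n_samples=200, burn_in=500, seed=5)
        t = simulate_local_communities(meta, cfg)
        rel = t.values / 500
        mean = rel.mean(axis=0)
        se = np.sqrt(meta.p * (1 - meta.p) / 500 / 200)
        assert (np.abs(mean - meta.p) <= 3 * se + 1e-12).mean() > 0.9

    def test_multinomial_chisquare_across_seeds(self):
        """m=1 pooled counts pass a goodness-of-fit test against p for at
        least 19/20 seeds at alpha=0.01."""
        meta = sample_metacommunity(15, 0.8, seed=0)
        ok = 0
        for seed in range(20):
            cfg = NeutralSimConfig(N=2000, m=1.0, n_samples=5, burn_in=2000,
                                   seed=1000 + seed)
            t = simulate_local_communities(meta, cfg)
            pooled = t.values.sum(axis=0)
            pval = chisquare(pooled, f_exp=pooled.sum() * meta.p).pvalue
            ok += pval > 0.01
        assert ok >= 19

    def test_low_immigration_reduces_richness(self):
        meta = sample_metacommunity(100, 1.0, seed=6)
        drift = simulate_local_communities(
            meta, NeutralSimConfig(N=100, m=0.001, n_samples=50,
                                   burn_in=100_000, seed=7))
        mixed = simulate_local_communities(
            meta, NeutralSimConfig(N=100, m=1.0, n_samples=50,
                                   burn_in=100_000, seed=7))
        rich_drift = (drift.values > 0).sum(axis=1).mean()
        rich_mixed = (mixed.values > 0).sum(axis=1).mean()
        assert rich_drift < rich_mixed

    def test_deterministic_per_seed(self):
        meta = sample_metacommunity(20, 1.0, seed=8)
        cfg = NeutralSimConfig(N=100, m=0.5, n_samples=5, burn_in=1000, seed=11)
        a = simulate_local_communities(meta, cfg)
        b = simulate_local_communities(meta, cfg)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_effective_dispersal_formula(self):
        assert effective_dispersal(10_000, 0.1) == pytest.approx(
            0.1 * 9999 / 0.9)


class TestAttachFunctions:
    def test_identity_map_is_identity(self, small_table):
        gm = GuildMap(
            guild_of={t: t for t in small_table.taxon_ids},
            functions_of={t: {t: 1.0} for t in small_table.taxon_ids},
        )
        out = attach_functions(small_table, gm)
        np.testing.assert_allclose(
            out.data[small_table.taxon_ids].to_numpy(), small_table.values)

    def test_within_guild_swap_invisible_to_functions(self):
        x = np.array([[5.0, 2.0, 1.0], [2.0, 5.0, 1.0]])
        t = AbundanceTable(pd.DataFrame(
            x, index=["s1", "s2"], columns=["a", "b", "c"]))
        gm = GuildMap(guild_of={"a": "g1", "b": "g1", "c": "g2"},
                      functions_of={"g1": {"F1": 1.0}, "g2": {"F2": 1.0}})
        out = attach_functions(t, gm)
        np.testing.assert_allclose(out.data.loc["s1"], out.data.loc["s2"])

    def test_matrix_product_oracle(self, rng, small_table):
        taxa = small_table.taxon_ids
        guilds = [f"g{j % 4}" for j in range(len(taxa))]
        gm = GuildMap(
            guild_of=dict(zip(taxa, guilds)),
            functions_of={g: {f"F{g}": 1.0, "Fshared": 0.5}
                          for g in set(guilds)},
        )
        out = attach_functions(small_table, gm)
        w = gm.weight_matrix(taxa)
        expected = small_table.values @ w.to_numpy()
        np.testing.assert_allclose(
            out.data[w.columns].to_numpy(), expected)

    def test_unmapped_taxon_error(self, small_table):
        gm = GuildMap(guild_of={"t0": "g"}, functions_of={"g": {"F": 1.0}})
        with pytest.raises(KeyError, match="t1"):
            attach_functions(small_table, gm)


class TestRedundantStrains:
    def test_redundancy_one_collapses_taxa_onto_functions(self):
        ds = generate_redundant_strains(
            n_strains=3, n_guilds=12, redundancy=1,
            samples_per_strain=4, depth=5000, seed=0)
        bc_taxa = beta_diversity(to_relative(ds.abundance), "bray_curtis")
        bc_func = beta_diversity(to_relative(ds.function_table), "bray_curtis")
        np.testing.assert_allclose(
            np.asarray(bc_taxa.data), np.asarray(bc_func.data), atol=1e-12)

    def test_redundancy_decouples_function_from_taxonomy(self):
        ds = generate_redundant_strains(seed=1)
        g = ds.metadata["group"].to_numpy()
        iu = np.triu_indices(len(g), 1)
        between = g[iu[0]] != g[iu[1]]
        bt = np.asarray(beta_diversity(
            to_relative(ds.abundance), "bray_curtis").data)[iu][between]
        bf = np.asarray(beta_diversity(
            to_relative(ds.function_table), "bray_curtis").data)[iu][between]
        assert bf.mean() < bt.mean()

    def test_function_distance_non_increasing_in_redundancy(self):
        for seed in (0, 1, 2):
            means = []
            for r in (1, 2, 8):
                ds = generate_redundant_strains(redundancy=r, seed=seed)
                g = ds.metadata["group"].to_numpy()
                iu = np.triu_indices(len(g), 1)
                between = g[iu[0]] != g[iu[1]]
                bc = np.asarray(beta_diversity(
                    to_relative(ds.function_table), "bray_curtis").data)
                means.append(bc[iu][between].mean())
            assert means[0] >= means[1] >= means[2]

    def test_single_strain_all_core(self):
        ds = generate_redundant_strains(
            n_strains=1, n_guilds=10, redundancy=3,
            samples_per_strain=4, depth=5000, seed=2)
        part = partition_taxa(ds.abundance, ds.metadata["group"].to_dict())
        assert part.accessory == set()
        assert all(not s for s in part.specific.values())
        assert part.core == part.detected

    def test_zero_redundancy_rejected(self):
        with pytest.raises(ValueError):
            generate_redundant_strains(redundancy=0)

    def test_deterministic_per_seed(self):
        a = generate_redundant_strains(n_strains=2, n_guilds=6, redundancy=2,
                                       samples_per_strain=4, depth=1000, seed=9)
        b = generate_redundant_strains(n_strains=2, n_guilds=6, redundancy=2,
                                       samples_per_strain=4, depth=1000, seed=9)
        pd.testing.assert_frame_equal(a.abundance.data, b.abundance.data)
        pd.testing.assert_frame_equal(a.function_table.data, b.function_table.data)

    def test_metadata_structure_and_truth(self):
        ds = generate_redundant_strains(n_strains=2, n_guilds=6, redundancy=2,
                                        samples_per_strain=8, depth=1000, seed=3)
        assert set(ds.metadata.columns) >= {"group", "timepoint", "replicate"}
        assert ds.metadata.index.tolist() == ds.abundance.sample_ids
        assert ds.truth["redundancy"] == 2
        assert ds.truth["guild_map"].redundancy("G001") == 2

    def test_write_round_trip(self, tmp_path):
        from phycosphere.io import read_abundance_table
        ds = generate_redundant_strains(n_strains=2, n_guilds=4, redundancy=2,
                                        samples_per_strain=4, depth=500, seed=4)
        ds.write(tmp_path)
        back = read_abundance_table(tmp_path / "abundance.tsv")
        np.testing.assert_array_equal(back.values, ds.abundance.values)
        assert (tmp_path / "truth.json").exists()


class TestValidation:
    def test_metacommunity_invariants(self):
        with pytest.raises(ValueError):
            Metacommunity(["a", "b"], np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            Metacommunity(["a", "a"], np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            Metacommunity(["a", "b"], np.array([1.0, 0.0]))

    def test_guild_map_invariants(self):
        with pytest.raises(ValueError):
            GuildMap(guild_of={"t": "g"}, functions_of={"g": {}})
        with pytest.raises(ValueError):
            GuildMap(guild_of={"t": "g"}, functions_of={"h": {"F": 1.0}})
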