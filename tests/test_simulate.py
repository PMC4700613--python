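"""Synthetic genotypes, causal-set selection and phenotype simulation."""

import numpy as np
import pytest
from scipy import stats

from gfblup.io_qc import qc_filter
from gfblup.kinship import build_grm, center_scale
from gfblup.simulate import (
    PopulationStructure,
    SimScenario,
    make_dilution_and_null_sets,
    scenario_grid,
    select_causal,
    simulate_dataset,
    simulate_genotypes,
    simulate_phenotypes,
    variance_split,
)


class TestGenotypeSimulation:
    def test_deterministic_under_seed(self):
        a = simulate_genotypes(10, 20, seed=123)
        b = simulate_genotypes(10, 20, seed=123)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.pos, b.pos)

    def test_counts_in_range_and_polymorphic_after_qc(self):
        g = simulate_genotypes(200, 300, seed=5)
        assert set(np.unique(g.counts)) <= {0, 1, 2}
        filtered, _ = qc_filter(g)
        assert (filtered.maf() > 0).all()

    def test_cohort_labels_present(self):
        structure = PopulationStructure(n_sires=2, n_dams_per_sire=5,
                                n_offspring_per_dam=3)
        g = simulate_genotypes(120, 50, structure=structure, seed=1)
        assert g.meta is not None and "cohort" in g.meta
        assert g.meta["cohort"].nunique() > 1

    def test_map_sorted_within_chromosomes(self):
        g = simulate_genotypes(20, 100, seed=2)
        for c in np.unique(g.chrom.astype(str)):
            p = g.pos[g.chrom == c]
            assert (np.diff(p) > 0).all()

    def test_adjacent_ld_matches_founder_oracle(self):
        """Mean adjacent-marker genotype correlation on a simulated panel
        agrees (within 0.1) with a Monte-Carlo estimate from the founder
        haplotype equations (latent AR(1) copula at rho = 0.7)."""
        structure = PopulationStructure()
        g = simulate_genotypes(500, 2000, structure=structure, seed=42)
        same_chrom = g.chrom[:-1] == g.chrom[1:]
        X = g.counts.astype(float)
        X -= X.mean(axis=0)
        sd = X.std(axis=0)
        ok = (sd[:-1] > 0) & (sd[1:] > 0) & same_chrom
        corr = (X[:, :-1] * X[:, 1:]).mean(axis=0) / (sd[:-1] * sd[1:])
        observed = corr[ok].mean()

        rng = np.random.default_rng(7)
        n_mc = 200_000
        p1 = rng.uniform(0.05, 0.5, n_mc)
        p2 = rng.uniform(0.05, 0.5, n_mc)
        rho = structure.rho
        cors = []
        for _ in range(2):  # two haplotypes per genotype
            z1 = rng.standard_normal(n_mc)
            z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n_mc)
            h1 = (z1 < stats.norm.ppf(p1)).astype(float)
            h2 = (z2 < stats.norm.ppf(p2)).astype(float)
            cors.append((h1, h2))
        g1 = cors[0][0] + cors[1][0]
        g2 = cors[0][1] + cors[1][1]
        oracle = np.corrcoef(g1, g2)[0, 1]
        assert observed == pytest.approx(oracle, abs=0.1)


class TestCausalSelection:
    @pytest.mark.parametrize("model", ["random", "cluster"])
    def test_sizes_and_disjointness(self, model):
        C1, C2 = select_causal(5000, model=model, seed=3)
        assert C1.n_markers == 100 and C2.n_markers == 900
        assert set(C1.indices).isdisjoint(C2.indices)

    def test_cluster_markers_inside_regions(self):
        C1, _ = select_causal(5000, model="cluster", seed=9)
        regions = {idx // 50 for idx in C1.indices}
        assert len(regions) == 20
        counts = np.bincount([idx // 50 for idx in C1.indices])
        assert counts[counts > 0].tolist() == [5] * 20

    def test_seed_reproducibility(self):
        a = select_causal(3000, model="cluster", seed=11)
        b = select_causal(3000, model="cluster", seed=11)
        np.testing.assert_array_equal(a[0].indices, b[0].indices)

    def test_insufficient_markers_rejected(self):
        with pytest.raises(ValueError):
            select_causal(500, model="cluster")


class TestVarianceSplit:
    @pytest.mark.parametrize(
        "h2, h2f, expected",
        [
            (0.2, 0.5, (10.0, 10.0, 80.0)),
            (0.3, 0.1, (3.0, 27.0, 70.0)),
        ],
    )
    def test_arithmetic(self, h2, h2f, expected):
        assert variance_split(h2, h2f, 100.0) == pytest.approx(expected)

    def test_components_sum_to_total(self, rng):
        for _ in range(20):
            h2, h2f = rng.uniform(0, 1, 2)
            assert sum(variance_split(h2, h2f, 100.0)) == pytest.approx(100.0)


class TestPhenotypeSimulation:
    def test_pure_noise_limit(self, panel_ctx):
        sc = SimScenario(h2=0.0, h2_f=0.5, n_obs=150, n_markers=400)
        C1, C2 = select_causal(panel_ctx.n_markers, model="random", n_c1=40, n_c2=100, seed=1)
        ds = simulate_phenotypes(panel_ctx.genotypes, C1, C2, sc, rng=5, w=panel_ctx.w)
        np.testing.assert_array_equal(ds.truth["g1"], 0.0)
        assert ds.y == pytest.approx(ds.truth["e"])

    def test_truth_identity_and_zero_mean(self, panel_ctx):
        sc = SimScenario(h2=0.3, h2_f=0.2, n_obs=150, n_markers=400)
        C1, C2 = select_causal(panel_ctx.n_markers, model="random", n_c1=40, n_c2=100, seed=2)
        ds = simulate_phenotypes(panel_ctx.genotypes, C1, C2, sc, rng=6, w=panel_ctx.w)
        np.testing.assert_allclose(
            ds.y, ds.truth["g1"] + ds.truth["g2"] + ds.truth["e"]
        )
        assert abs(ds.y.mean()) < 3 * 10.0 / np.sqrt(len(ds.y))

    def test_variance_share_recovery(self, medium_ctx):
        """Across replicates the realized share var(g1)/(var(g1)+var(g2))
        tracks the configured h_f^2."""
        sc = SimScenario(h2=0.5, h2_f=0.3, n_obs=300, n_markers=1200)
        rng = np.random.default_rng(8)
        shares = []
        for _ in range(30):
            C1, C2 = select_causal(medium_ctx.n_markers, seed=rng.integers(2**31))
            ds = simulate_phenotypes(medium_ctx.genotypes, C1, C2, sc, rng=rng,
                                     w=medium_ctx.w)
            v1, v2 = ds.truth["g1"].var(), ds.truth["g2"].var()
            shares.append(v1 / (v1 + v2))
        shares = np.asarray(shares)
        se = shares.std(ddof=1) / np.sqrt(len(shares))
        assert abs(shares.mean() - 0.3) < max(2 * se, 0.02)


class TestDilutionAndNullSets:
    def test_construction_contracts(self):
        C1, C2 = select_causal(5000, seed=4)
        diluted, nulls = make_dilution_and_null_sets(
            C1, C2, 5000, dilution_grid=(100, 500), null_sizes=(100, 500),
            n_null=3, seed=5,
        )
        assert diluted[100].n_markers == 200
        assert set(diluted[100].indices) >= set(C1.indices)
        assert set(diluted[500].indices).isdisjoint(C2.indices)
        assert len(nulls) == 6
        causal = set(C1.indices) | set(C2.indices)
        for fs in nulls:
            assert causal.isdisjoint(fs.indices)

    def test_flanking_mode_adds_adjacent_markers(self):
        C1 = select_causal(400, model="random", n_c1=5, n_c2=0, seed=0)[0]
        from gfblup.features import FeatureSet

        C1 = FeatureSet("C1", np.arange(100, 105))
        C2 = FeatureSet("C2", np.array([300]))
        diluted, _ = make_dilution_and_null_sets(
            C1, C2, 400, dilution_grid=(4,), null_sizes=(), mode="flanking", seed=1
        )
        added = set(diluted[4].indices) - set(C1.indices)
        assert added == {98, 99, 105, 106}

    def test_excessive_dilution_rejected(self):
        C1, C2 = select_causal(1200, seed=4)
        with pytest.raises(ValueError, match="exceeds"):
            make_dilution_and_null_sets(C1, C2, 1200, dilution_grid=(500,),
                                        null_sizes=())


class TestScenarioGridAndOrchestration:
    def test_grid_has_72_cells(self):
        grid = scenario_grid()
        assert len(grid) == 72
        coords = {(s.n_obs, s.h2, s.h2_f, s.causal_model) for s in grid}
        assert len(coords) == 72

    def test_simulate_dataset_end_to_end(self):
        sc = SimScenario(h2=0.2, h2_f=0.5, dilution=100, n_obs=150,
                         n_markers=1500, seed=7)
        ds = simulate_dataset(sc, with_sets=True, n_null=2)
        assert ds.y.shape == (150,)
        assert ds.C1.n_markers == 100 and ds.C2.n_markers == 900
        assert 100 in ds.diluted_sets
        assert len(ds.null_sets) > 0
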