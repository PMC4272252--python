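"""Ploidy-aware diversity, FST, fixed differences and LD statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from parscout import popgen as pg


def make_panel(site_positions, alleles, species=None, sexes=None, scaffold="s"):
    """alleles: (n_ind, 2, n_sites) list/array; -1 for absent copies."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_ind = alleles.shape[0]
    individuals = pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(n_ind)],
            "species": species or ["A"] * n_ind,
            "sex": sexes or ["M"] * n_ind,
        }
    )
    sites = pd.DataFrame(
        {"scaffold": scaffold, "position": site_positions, "ref": "A", "alt": "T"}
    )
    ploidy = pd.DataFrame({scaffold: [1 if (alleles[k, 1] == -1).all() else 2 for k in range(n_ind)]},
                          index=individuals["id"])
    return pg.HaplotypePanel(sites=sites, alleles=alleles, individuals=individuals, ploidy=ploidy)


class TestPi:
    def test_identical_haplotypes_zero(self):
        panel = make_panel([10, 20], [[[0, 0], [0, 0]], [[0, 0], [0, 0]]])
        assert pg.nucleotide_diversity(panel, callable_length=100) == 0.0

    def test_single_half_frequency_site(self):
        """4 haplotypes, one 2/2 site, 10 callable bp: pi = (4/3 * 0.5)/10."""
        panel = make_panel([5], [[[0], [0]], [[1], [1]]])
        pi = pg.nucleotide_diversity(panel, callable_length=10)
        assert pi == pytest.approx((4 / 3) * 0.5 / 10)

    def test_relabeling_invariance(self):
        alleles = [[[0, 1], [1, 0]], [[1, 0], [0, 0]], [[0, 1], [1, 1]]]
        p1 = make_panel([10, 20], alleles)
        p2 = make_panel([10, 20], alleles[::-1])
        assert pg.nucleotide_diversity(p1, callable_length=50) == pytest.approx(
            pg.nucleotide_diversity(p2, callable_length=50)
        )

    def test_haploid_bookkeeping_differs_from_fake_diploid(self):
        """pi counts each sampled chromosome once; doubling a haploid changes it."""
        # 2 males (diploid) + 2 hemizygous females at one site: alleles 1,0 | 1 | 0
        hap = [[[1], [0]], [[1], [1]], [[1], [-1]], [[0], [-1]]]
        panel = make_panel([5], hap, sexes=["M", "M", "F", "F"])
        # hand enumeration: n=6 alleles, 4 alt -> h = 6/5 * 2*(4/6)*(2/6)
        expected = (6 / 5) * 2 * (4 / 6) * (2 / 6)
        assert pg.nucleotide_diversity(panel, callable_length=1) == pytest.approx(expected)
        fake = [[[1], [0]], [[1], [1]], [[1], [1]], [[0], [0]]]
        panel_fake = make_panel([5], fake, sexes=["M", "M", "F", "F"])
        assert pg.nucleotide_diversity(panel_fake, callable_length=1) != pytest.approx(expected)

    def test_empty_window_flagged_not_zero(self):
        panel = make_panel([5], [[[0], [0]], [[1], [1]]])
        with pytest.raises(pg.UndefinedStatistic):
            pg.nucleotide_diversity(panel, callable_length=0)


class TestFst:
    def two_group_panel(self, a_alleles, b_alleles):
        alleles = np.array(a_alleles + b_alleles, dtype=np.int8)
        species = ["A"] * len(a_alleles) + ["B"] * len(b_alleles)
        return make_panel(list(range(10, 10 * (alleles.shape[2] + 1), 10)), alleles, species=species)

    def test_fixed_difference_hudson_one(self):
        panel = self.two_group_panel([[[0], [0]], [[0], [0]]], [[[1], [1]], [[1], [1]]])
        assert pg.fst(panel, {"species": "A"}, {"species": "B"}, estimator="hudson") == pytest.approx(1.0)

    def test_identical_frequencies_zero(self):
        block = [[[0], [1]], [[0], [1]]]
        panel = self.two_group_panel(block, block)
        assert pg.fst(panel, {"species": "A"}, {"species": "B"}, estimator="hudson") == pytest.approx(0.0, abs=1e-12)
        wc = pg.fst(panel, {"species": "A"}, {"species": "B"}, estimator="weir-cockerham")
        # identical sample frequencies give the small negative finite-sample
        # value -1/(nc - 1), never a positive signal
        assert -0.5 < wc <= 0.0

    def test_symmetry(self):
        panel = self.two_group_panel([[[0], [1]], [[1], [1]]], [[[0], [0]], [[0], [1]]])
        for est in ("hudson", "weir-cockerham"):
            ab = pg.fst(panel, {"species": "A"}, {"species": "B"}, estimator=est)
            ba = pg.fst(panel, {"species": "B"}, {"species": "A"}, estimator=est)
            assert ab == pytest.approx(ba)

    def test_monomorphic_union_flagged(self):
        panel = self.two_group_panel([[[0], [0]]], [[[0], [0]]])
        with pytest.raises(pg.UndefinedStatistic):
            pg.fst(panel, {"species": "A"}, {"species": "B"}, estimator="hudson")


class TestFixedDifferences:
    def test_counts_and_shared_allele_exclusion(self):
        # site 1: fixed difference; site 2: shared allele in B -> not fixed
        a = [[[0, 0], [0, 0]], [[0, 0], [0, 0]]]
        b = [[[1, 1], [1, 1]], [[1, 0], [1, 1]]]
        panel = make_panel([10, 20], np.array(a + b, dtype=np.int8), species=["A", "A", "B", "B"])
        df = pg.fixed_difference_density(panel, {"species": "A"}, {"species": "B"}, callable_length=100_000)
        assert df == pytest.approx(1 / 100_000)

    def test_no_fixed_sites_zero(self):
        block = [[[0], [1]], [[0], [1]]]
        panel = make_panel([10], np.array(block + block, dtype=np.int8), species=["A", "A", "B", "B"])
        assert pg.fixed_difference_density(panel, {"species": "A"}, {"species": "B"}, callable_length=10) == 0.0


class TestR2:
    def test_perfect_ld(self):
        panel = make_panel([10, 20], [[[1, 1], [1, 1]], [[0, 0], [0, 0]]])
        assert pg.pairwise_r2(panel, 0, 1) == pytest.approx(1.0)

    def test_independence(self):
        panel = make_panel([10, 20], [[[1, 1], [1, 0]], [[0, 1], [0, 0]]])
        assert pg.pairwise_r2(panel, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_six_haplotype_enumeration_oracle(self):
        """r^2 equals the squared Pearson correlation of allele indicators."""
        h1, h2 = [1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 1]
        alleles = np.stack([np.array(h1).reshape(3, 2), np.array(h2).reshape(3, 2)], axis=2)
        panel = make_panel([10, 20], alleles)
        oracle = np.corrcoef(h1, h2)[0, 1] ** 2
        assert pg.pairwise_r2(panel, 0, 1) == pytest.approx(oracle)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=4, max_size=20))
    def test_r2_matches_squared_correlation(self, haps):
        h1 = np.array([a for a, _ in haps])
        h2 = np.array([b for _, b in haps])
        if len(set(h1)) < 2 or len(set(h2)) < 2:
            return
        rows = np.stack([h1, h2], axis=1)
        r2 = pg.r2_matrix_pairs(rows, np.array([0]), np.array([1]))[0]
        assert r2 == pytest.approx(np.corrcoef(h1, h2)[0, 1] ** 2, abs=1e-12)
        assert 0.0 <= r2 <= 1.0 + 1e-12

    def test_monomorphic_flagged(self):
        # site 0 carries only the alt allele; site 1 segregates
        panel = make_panel([10, 20], [[[1, 1], [1, 0]], [[1, 1], [1, 0]]])
        with pytest.raises(pg.UndefinedStatistic):
            pg.pairwise_r2(panel, 0, 1)


class TestLDFit:
    def test_noiseless_alpha_recovered_exactly(self):
        d = np.linspace(1, 20_000, 400)
        for alpha in (0.2, 0.005776):
            fit = pg.ld_decay_fit(d, 1.0 / (1.0 + alpha * d))
            assert abs(fit.alpha - alpha) / alpha < 1e-6
        fit = pg.ld_decay_fit(d, 1.0 / (1.0 + 0.2 * d))
        assert fit.d01 == pytest.approx(45.0, rel=1e-6)

    def test_decay_distance_closed_form(self):
        assert pg.ld_decay_distance(0.2) == pytest.approx(45.0)
        assert pg.ld_decay_distance(0.005776) == pytest.approx(1558.17, abs=0.01)
        with pytest.raises(ValueError):
            pg.ld_decay_distance(0.2, r2=1.5)

    def test_constant_r2_hits_zero_boundary(self):
        d = np.linspace(1, 1000, 50)
        fit = pg.ld_decay_fit(d, np.ones_like(d))
        assert fit.at_boundary and fit.alpha == 0.0 and np.isinf(fit.d01)


class TestWindowScan:
    def test_concatenation_identity_and_empty_windows(self):
        from parscout.sim import SimConfig, simulate_haplotypes
        from parscout.sim.config import Scaffold

        cfg = SimConfig(seed=9, genome_plan=(Scaffold("par_1", 100_000, "PAR"),
                                             Scaffold("zdiff_1", 50_000, "Z_diff")))
        panel = simulate_haplotypes(cfg)
        stats = pg.window_scan(
            panel, {"par_1": 100_000}, window_sizes=(20_000, 100_000),
            focal_group={"species": "A"},
            species_pair=({"species": "A"}, {"species": "B"}),
        )
        small = stats[stats["window_size"] == 20_000]
        big = stats[stats["window_size"] == 100_000].iloc[0]
        weighted = (small["pi"] * small["callable_sites"]).sum() / small["callable_sites"].sum()
        assert big["pi"] == pytest.approx(weighted)
        # df pools the same way
        weighted_df = (small["df"] * small["callable_sites"]).sum() / small["callable_sites"].sum()
        assert big["df"] == pytest.approx(weighted_df)

    def test_uncovered_scaffold_windows_are_undefined(self):
        panel = make_panel([10], [[[0], [1]], [[1], [0]]])
        stats = pg.window_scan(panel, {"s": 100, "absent": 100}, window_sizes=(100,),
                               focal_group=None)
        absent = stats[stats["scaffold"] == "absent"]
        assert len(absent) == 1 and np.isnan(absent["pi"].iloc[0])
        present = stats[stats["scaffold"] == "s"]
        assert present["pi"].iloc[0] > 0

    def test_windowed_df_recovers_target(self):
        from parscout.sim import SimConfig, simulate_haplotypes
        from parscout.sim.config import Scaffold

        cfg = SimConfig(seed=10, genome_plan=(Scaffold("par_1", 100_000, "PAR"),
                                              Scaffold("zdiff_1", 500_000, "Z_diff")))
        panel = simulate_haplotypes(cfg)
        df = pg.fixed_difference_density(panel, {"species": "A"}, {"species": "B"}, "zdiff_1", 0, 500_000)
        target = 0.0011
        se = np.sqrt(target * 500_000) / 500_000  # Poisson count s.e. per bp
        assert abs(df - target) < 3 * se
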