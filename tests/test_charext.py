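"""Composition windows, gene content, expression indices, bootstrap test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from parscout import charext as ce


class TestComposition:
    @pytest.mark.parametrize(
        "seq,gc,repeat",
        [("GCGC", 1.0, 0.0), ("ATAT", 0.0, 0.0), ("ACGT", 0.5, 0.0), ("acgtACGT", 0.5, 0.5)],
    )
    def test_gc_and_softmask_fractions(self, seq, gc, repeat):
        comp = ce.gc_repeat_windows({"s": seq}, window_size=len(seq))
        assert comp["gc_fraction"].iloc[0] == pytest.approx(gc)
        assert comp["repeat_fraction"].iloc[0] == pytest.approx(repeat)

    def test_gc_over_non_n_bases_and_complement(self):
        comp = ce.gc_repeat_windows({"s": "GGNNAA"}, window_size=6)
        row = comp.iloc[0]
        assert row["gc_fraction"] == pytest.approx(0.5)  # 2 GC of 4 non-N
        assert row["n_fraction"] == pytest.approx(2 / 6)
        # GC + AT fractions over non-N bases sum to 1
        at = 1 - row["gc_fraction"]
        assert at == pytest.approx(0.5)

    def test_window_beyond_scaffold_truncated(self):
        comp = ce.gc_repeat_windows({"s": "ACGT" * 5}, windows=[("s", 10, 50)])
        assert comp.iloc[0]["truncated"] and comp.iloc[0]["end"] == 20

    def test_bed_mask_overrides_softmask(self):
        mask = pd.DataFrame({"scaffold": ["s"], "start": [0], "end": [2]})
        comp = ce.gc_repeat_windows({"s": "ACGT"}, window_size=4, mask=mask)
        assert comp.iloc[0]["repeat_fraction"] == pytest.approx(0.5)


class TestGeneSummary:
    def ann(self, genes):
        rows = []
        for gid, scaf, start, end in genes:
            rows.append(dict(scaffold=scaf, type="gene", start=start, end=end, feature_id=gid))
        return pd.DataFrame(rows)

    def test_gene_density_identity(self):
        ann = self.ann([(f"g{i}", "par", 1000 * i + 1, 1000 * i + 500) for i in range(22)])
        gs = ce.gene_summary(ann, [("par", 0, 630_500)])
        assert gs.n_genes == 22
        assert gs.genes_per_mb * gs.region_bp * 1e-6 == pytest.approx(gs.n_genes)

    def test_empty_region(self):
        gs = ce.gene_summary(self.ann([]), [("par", 0, 1000)])
        assert gs.n_genes == 0 and gs.genes_per_mb == 0.0

    def test_gene_start_decides_membership(self):
        ann = self.ann([("g1", "par", 900, 1500), ("g2", "par", 1100, 1600)])
        gs = ce.gene_summary(ann, [("par", 0, 1000)])
        assert gs.n_genes == 1

    def test_overlapping_cds_union(self):
        ann = pd.DataFrame(
            [
                dict(scaffold="par", type="gene", start=1, end=200, feature_id="g"),
                dict(scaffold="par", type="CDS", start=1, end=100, feature_id="c1"),
                dict(scaffold="par", type="CDS", start=1, end=100, feature_id="c2"),
            ]
        )
        gs = ce.gene_summary(ann, [("par", 0, 1000)])
        assert gs.coding_bp == 100


class TestTau:
    def test_uniform_zero_single_one(self):
        assert ce.tau_specificity([5, 5, 5, 5]) == 0.0
        assert ce.tau_specificity([7, 0, 0, 0]) == 1.0

    def test_hand_computed_example(self):
        assert ce.tau_specificity([8, 2, 2, 2, 2]) == pytest.approx(0.75)

    def test_unexpressed_flagged(self):
        with pytest.raises(ce.UndefinedStatistic):
            ce.tau_specificity([0, 0, 0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.1, 100), min_size=3, max_size=8), st.data())
    def test_concentrating_mass_never_decreases_tau(self, values, data):
        """Moving expression from a non-max tissue onto the max tissue raises tau."""
        x = np.array(values)
        i_max = int(np.argmax(x))
        donors = [i for i in range(len(x)) if i != i_max and x[i] > 0]
        if not donors:
            return
        i_donor = data.draw(st.sampled_from(donors))
        shift = data.draw(st.floats(0.0, float(x[i_donor])))
        y = x.copy()
        y[i_donor] -= shift
        y[i_max] += shift
        assert ce.tau_specificity(y) >= ce.tau_specificity(x) - 1e-9

    def test_tau_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            tau = ce.tau_specificity(rng.uniform(0, 10, 6) + 1e-6)
            assert 0.0 <= tau <= 1.0


class TestMFRatio:
    def make(self, male_factor):
        samples = pd.DataFrame(
            [
                {"sample": f"{t}_{s}{r}", "tissue": t, "sex": s}
                for t in ("brain", "liver", "testis")
                for s in ("M", "F")
                for r in (1, 2)
            ]
        )
        base = {"brain": 10.0, "liver": 20.0, "testis": 5.0}
        values = {
            row["sample"]: base[row["tissue"]] * (male_factor if row["sex"] == "M" else 1.0)
            for _, row in samples.iterrows()
        }
        matrix = pd.DataFrame([values], index=["g1"])
        return matrix, samples

    def test_identical_expression_unit_ratio(self):
        matrix, samples = self.make(1.0)
        assert ce.mf_expression_ratio(matrix, samples)["mf_ratio"].iloc[0] == pytest.approx(1.0)

    def test_constant_fold_change_recovered_and_gonads_excluded(self):
        matrix, samples = self.make(1.4)
        out = ce.mf_expression_ratio(matrix, samples)
        assert out["mf_ratio"].iloc[0] == pytest.approx(1.40)
        assert out["n_tissues"].iloc[0] == 2  # testis excluded

    def test_zero_female_tissue_skipped(self):
        matrix, samples = self.make(1.0)
        matrix.loc["g1", ["brain_F1", "brain_F2"]] = 0.0
        out = ce.mf_expression_ratio(matrix, samples)
        assert out["n_tissues"].iloc[0] == 1


class TestSpecificity:
    def test_binomial_chance_probability(self):
        p = ce.specificity_by_chance(20, 1, 0.0072)
        from scipy.stats import binom

        assert p == pytest.approx(float(binom.sf(0, 20, 0.0072)))


class TestBootstrap:
    def test_smallest_p_on_19_resamples(self):
        res = ce.bootstrap_window_test(np.arange(100.0), 1e9, n_resamples=19, tail="high", rng=0)
        assert res.p_value == pytest.approx(0.05)

    def test_beyond_all_resamples_reports_floor(self):
        res = ce.bootstrap_window_test(np.arange(100.0), 1e9, n_resamples=100_000, tail="high", rng=0)
        assert res.n_extreme == 0
        assert res.p_value < 1e-5
        assert res.display.startswith("<")

    def test_central_value_has_large_two_sided_p(self):
        rng = np.random.default_rng(3)
        background = rng.normal(0, 1, 500)
        res = ce.bootstrap_window_test(background, float(np.median(background)),
                                       n_resamples=999, tail="two", rng=1)
        assert res.p_value > 0.5

    def test_null_p_values_uniform(self):
        """Region drawn from the background gives uniform P on the (k+1)/(B+1) grid."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(1000):
            background = rng.normal(0, 1, 60)
            region = rng.normal(0, 1)
            pvals.append(
                ce.bootstrap_window_test(background, region, n_resamples=199, tail="high", rng=rng).p_value
            )
        assert kstest(pvals, "uniform").pvalue > 0.01
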