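"""Two-point likelihood, HWE/Mendelian screens, maps, rates and boundary."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist

from parscout import linkage as lk
from parscout.sim.genotypes import GenotypeTable
from parscout.sim.pedigree import Pedigree


def make_gt(markers: list[tuple[str, str, int, str]], calls: dict[str, list[str]]) -> GenotypeTable:
    """markers: (id, scaffold, position, role); calls: individual -> per-marker strings."""
    meta = pd.DataFrame(markers, columns=["marker", "scaffold", "position", "role"])
    meta["chrom"] = np.where(meta["role"] == "autosome", meta["scaffold"], "Z")
    meta["chrom_pos"] = meta["position"] - 1
    frame = pd.DataFrame(calls, index=meta["marker"])
    frame.index.name = "marker"
    return GenotypeTable(meta, frame)


def make_ped(rows: list[tuple[str, str, str, str, int]]) -> Pedigree:
    return Pedigree(
        pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation"]).assign(family="f1")[
            ["id", "family", "sire", "dam", "sex", "generation"]
        ]
    )


def phase_known_fixture(n_recombinant: int):
    """A dam heterozygous at two markers, phase resolved through her parents.

    Grandsire AA/AA x granddam BB/BB make the dam AB/AB with known phase
    (both A alleles grandpaternal).  Her mate is AA/AA, so each child reads
    out the maternal allele directly: 'AA' = A transmitted, 'AB' = B.
    """
    markers = [("m1", "s1", 100, "autosome"), ("m2", "s1", 200, "autosome")]
    ped_rows = [
        ("gs", "0", "0", "M", 1),
        ("gd", "0", "0", "F", 1),
        ("dam", "gs", "gd", "F", 2),
        ("sire", "0", "0", "M", 2),
    ]
    calls = {"gs": ["AA", "AA"], "gd": ["BB", "BB"], "dam": ["AB", "AB"], "sire": ["AA", "AA"]}
    for k in range(10):
        child = f"c{k}"
        ped_rows.append((child, "sire", "dam", "M", 3))
        maternal_m1 = "A" if k < 5 else "B"
        maternal_m2 = maternal_m1
        if k < n_recombinant:  # make the first k children recombinant
            maternal_m2 = "B" if maternal_m1 == "A" else "A"
        calls[child] = ["AA" if maternal_m1 == "A" else "AB", "AA" if maternal_m2 == "A" else "AB"]
    return make_gt(markers, calls), make_ped(ped_rows)


class TestTwoPoint:
    def test_ten_meioses_no_recombinant(self):
        gt, ped = phase_known_fixture(0)
        res = lk.twopoint(gt, ped, "m1", "m2")
        assert res.theta_female == 0.0
        assert res.lod_female == pytest.approx(10 * math.log10(2), abs=1e-6)
        assert res.n_informative_f == 10 and res.n_informative_m == 0

    def test_one_recombinant_closed_form(self):
        gt, ped = phase_known_fixture(1)
        res = lk.twopoint(gt, ped, "m1", "m2")
        assert res.theta_female == pytest.approx(0.1)  # r/n exactly, phase known
        expected = math.log10((0.1 * 0.9**9) / 0.5**10)
        assert res.lod_female == pytest.approx(expected, abs=1e-6)

    def test_half_recombinant_is_null(self):
        gt, ped = phase_known_fixture(5)
        res = lk.twopoint(gt, ped, "m1", "m2")
        assert res.theta_female == pytest.approx(0.5)
        assert res.lod_female == pytest.approx(0.0, abs=1e-9)

    def test_lod_at_half_is_zero_and_nonnegative(self):
        for fam in (lk._ParentFamily(3, 10, True), lk._ParentFamily(3, 10, False)):
            assert fam.loglik(0.5) == pytest.approx(10 * math.log(0.5))
            _, lod = lk._maximize([fam])
            assert lod >= 0.0

    def test_pooled_theta_between_sex_thetas(self):
        fam_f = lk._ParentFamily(r=1, n=10, phase_known=True)
        fam_m = lk._ParentFamily(r=3, n=10, phase_known=True)
        theta, _ = lk._maximize([fam_f, fam_m])
        assert theta == pytest.approx(0.2)
        assert 0.1 <= theta <= 0.3


class TestHWE:
    def test_perfect_proportions(self):
        res = lk.hwe_test(25, 50, 25)
        assert res.chi2 == pytest.approx(0.0)

    def test_no_heterozygotes_extreme(self):
        res = lk.hwe_test(50, 0, 50)
        assert res.chi2 == pytest.approx(100.0)  # 25 + 50 + 25

    def test_monomorphic_flag(self):
        res = lk.hwe_test(0, 0, 100)
        assert res.monomorphic and math.isnan(res.chi2)

    def test_p_value_matches_chi2_oracle(self):
        res = lk.hwe_test(90, 10, 0)
        assert res.p_value == pytest.approx(float(chi2_dist.sf(res.chi2, 1)))
        assert not res.monomorphic


class TestMendel:
    def test_impossible_and_obligate_heterozygote(self):
        markers = [("m1", "s1", 100, "autosome")]
        ped = make_ped([
            ("f", "0", "0", "M", 1), ("m", "0", "0", "F", 1),
            ("c1", "f", "m", "M", 2),
        ])
        err = lk.mendelian_check(make_gt(markers, {"f": ["AA"], "m": ["AA"], "c1": ["AB"]}), ped)
        assert err["mendel_errors"].iloc[0] == 1
        ok = lk.mendelian_check(make_gt(markers, {"f": ["AA"], "m": ["BB"], "c1": ["AB"]}), ped)
        assert ok["mendel_errors"].iloc[0] == 0

    def test_heterozygous_daughter_at_differentiated_marker(self):
        """A hemizygous dam cannot yield a heterozygous daughter on the Z."""
        markers = [("z1", "zs", 100, "Z_diff")]
        ped = make_ped([
            ("f", "0", "0", "M", 1), ("m", "0", "0", "F", 1),
            ("d1", "f", "m", "F", 2),
        ])
        err = lk.mendelian_check(make_gt(markers, {"f": ["AA"], "m": ["A"], "d1": ["AB"]}), ped)
        assert err["mendel_errors"].iloc[0] == 1
        ok = lk.mendelian_check(make_gt(markers, {"f": ["AA"], "m": ["A"], "d1": ["A"]}), ped)
        assert ok["mendel_errors"].iloc[0] == 0

    def test_simulated_cohort_is_mendel_clean(self, linkage_cohort):
        _, ped, gt, _, _ = linkage_cohort
        assert lk.mendelian_check(gt, ped)["mendel_errors"].sum() == 0


class TestCandidateFilter:
    def make_cohort_calls(self):
        markers = [("m1", "s1", 100, "autosome"), ("m2", "s1", 200, "autosome"),
                   ("z1", "zs", 100, "Z_diff")]
        calls = {}
        ped_rows = []
        for k in range(40):
            ind = f"i{k}"
            sex = "M" if k < 20 else "F"
            ped_rows.append((ind, "0", "0", sex, 1))
            m1 = ["AA", "AB", "BB", "AB"][k % 4]
            m2 = ["AA", "AA", "BB", "BB"][k % 4]  # no heterozygote anywhere
            z1 = ("AB" if k % 2 else "AA") if sex == "M" else "A"
            calls[ind] = [m1, m2, z1]
        return make_gt(markers, calls), make_ped(ped_rows)

    def test_filter_reasons(self):
        gt, ped = self.make_cohort_calls()
        out = lk.filter_candidate_pseudoautosomal(gt, sex_of={i: ("M" if int(i[1:]) < 20 else "F") for i in gt.calls.columns}).set_index("marker")
        assert out.at["m1", "retained"]
        assert not out.at["m2", "retained"] and out.at["m2", "reason"] == "no_heterozygote_males"
        assert not out.at["z1", "retained"] and out.at["z1", "reason"] == "no_heterozygote_females"

    def test_hwe_violating_marker_excluded(self):
        markers = [("m1", "s1", 100, "autosome")]
        calls = {}
        sex_of = {}
        for k in range(100):
            ind = f"i{k}"
            sex_of[ind] = "M" if k % 2 else "F"
            calls[ind] = ["AA" if k < 49 else ("BB" if k >= 51 else "AB")]  # 49/2/49
        out = lk.filter_candidate_pseudoautosomal(make_gt(markers, calls), sex_of=sex_of)
        assert not out["retained"].iloc[0] and out["reason"].iloc[0] == "hwe_fail"


class TestAssignment:
    def test_simulated_par_markers_assigned_autosomes_not(self, linkage_cohort):
        """At ~500 meioses every true PAR marker reaches LOD>3 to a Z anchor; no autosome does."""
        _, ped, gt, _, ts = linkage_cohort
        markers = gt.markers
        anchors = markers.loc[markers["role"] == "Z_diff", "marker"].tolist()
        candidates = markers.loc[markers["role"] != "Z_diff", "marker"].tolist()
        table = lk.assign_by_lod(gt, ped, candidates, anchors, threshold=3.0, ts=ts)
        merged = table.merge(markers[["marker", "role"]], on="marker")
        assert merged.loc[merged["role"] == "PAR", "assigned"].all()
        assert not merged.loc[merged["role"] == "autosome", "assigned"].any()


class TestMapFunctions:
    def test_closed_forms(self):
        assert lk.map_distance_cm(0.0) == 0.0
        assert lk.map_distance_cm(0.2, "haldane") == pytest.approx(-50 * math.log(0.6), abs=1e-9)
        assert lk.map_distance_cm(0.2, "haldane") == pytest.approx(25.54, abs=0.01)
        assert lk.map_distance_cm(0.2, "kosambi") == pytest.approx(25 * math.log(1.4 / 0.6), abs=1e-9)
        assert lk.map_distance_cm(0.2, "kosambi") == pytest.approx(21.18, abs=0.01)

    @pytest.mark.parametrize("theta", [0.001, 0.005, 0.02])
    def test_haldane_kosambi_agree_to_first_order(self, theta):
        h = lk.map_distance_cm(theta, "haldane")
        k = lk.map_distance_cm(theta, "kosambi")
        assert abs(h - k) / h < 10 * theta  # both ~100*theta as theta -> 0


class TestBuildMap:
    def test_zero_theta_interval_adds_no_length(self):
        gt, ped = phase_known_fixture(1)
        # duplicate m2 as a fully linked third marker
        gt2 = make_gt(
            [("m1", "s1", 100, "autosome"), ("m2", "s1", 200, "autosome"), ("m3", "s1", 201, "autosome")],
            {ind: [gt.calls.at["m1", ind], gt.calls.at["m2", ind], gt.calls.at["m2", ind]] for ind in gt.calls.columns},
        )
        short = lk.build_map(gt, ped, ["m1", "m2"])
        long = lk.build_map(gt2, ped, ["m1", "m2", "m3"])
        assert long.female_length() == pytest.approx(short.female_length())

    def test_interval_thetas_recover_truth(self, linkage_cohort):
        """theta_f within 3 binomial s.e. of the realized gamete counts."""
        _, ped, gt, truth, ts = linkage_cohort
        z_order = gt.markers[gt.markers["chrom"] == "Z"].sort_values("chrom_pos")["marker"].tolist()
        gmap = lk.build_map(gt, ped, z_order, ts=ts)
        merged = gmap.table.merge(truth[["marker", "theta_f", "n_f"]], on="marker", suffixes=("", "_truth"))
        checked = 0
        for _, row in merged.iterrows():
            est, true = row["theta_f"], row["theta_f_truth"]
            if np.isnan(est) or np.isnan(true):
                continue
            n = row["n_f"]
            tol = 3 * math.sqrt(max(true * (1 - true), 0.0) / n) + 3 / n
            assert abs(est - true) <= tol, f"{row['marker']}: {est} vs {true}"
            checked += 1
        assert checked >= 5

    def test_unknown_marker_rejected(self, linkage_cohort):
        _, ped, gt, _, ts = linkage_cohort
        with pytest.raises(lk.InputError):
            lk.build_map(gt, ped, ["nope:1"], ts=ts)

    def test_female_map_spans_half_morgan_across_par(self):
        """~1000 female meioses: end-to-end PAR recombinant fraction near 0.5."""
        from parscout.sim import SimConfig, simulate_pedigree, simulate_zw_genotypes
        from parscout.sim.config import Scaffold

        cfg = SimConfig(
            seed=37, n_families=20, offspring_per_family=50, n_generations=2,
            genome_plan=(Scaffold("par_1", 400_000, "PAR"), Scaffold("zdiff_1", 400_000, "Z_diff")),
            marker_spacing=20_000,
        )
        ped = simulate_pedigree(cfg)
        gt, truth = simulate_zw_genotypes(ped, cfg)
        first, last = "par_1:10000", "par_1:390000"
        res = lk.twopoint(gt, ped, first, last)
        n = res.n_informative_f
        # crossovers below the first / above the last marker escape detection
        p_covered = (390_000 - 10_000) / 400_000
        se = math.sqrt(0.25 / n)
        assert abs(res.theta_female - 0.5 * p_covered) < 3 * se + 0.02


class TestRatesHotspotsBoundary:
    def test_physical_distance_same_and_cross_scaffold(self):
        lengths = {"s1": 1_000, "s2": 500}
        assert lk.physical_distance("s1:100", "s1:350", lengths, ["s1", "s2"]) == 250
        assert lk.physical_distance("s1:900", "s2:100", lengths, ["s1", "s2"], gap_padding=5000) == 5200
        assert lk.physical_distance("s2:100", "s1:900", lengths, ["s1", "s2"], gap_padding=5000) == 5200

    def test_zero_genetic_length_zero_rate(self):
        gmap = lk.GeneticMap.from_positions(
            pd.DataFrame({"marker": ["s1:100", "s1:200"], "cum_sexavg": [0, 0],
                          "cum_female": [0, 0], "cum_male": [0, 0]})
        )
        rates = lk.interval_rates(gmap, {"s1": 1_000})
        assert rates["rate_cm_per_mb"].iloc[0] == 0.0

    def test_hotspot_fold_threshold_arithmetic(self):
        rates = pd.DataFrame({"rate_cm_per_mb": [1.0, 1.0, 50.0, 1.0]})
        assert not lk.detect_hotspots(rates, fold=10)["hotspot"].any()  # 50 < 132.5
        assert lk.detect_hotspots(rates, fold=3)["hotspot"].tolist() == [False, False, True, False]
        uniform = pd.DataFrame({"rate_cm_per_mb": [2.0, 2.0, 2.0]})
        assert not lk.detect_hotspots(uniform, fold=1.5)["hotspot"].any()

    def test_boundary_cases(self):
        flat = lk.GeneticMap.from_positions(
            pd.DataFrame({"marker": ["s:1", "s:2"], "cum_sexavg": [0, 1],
                          "cum_female": [0, 0], "cum_male": [0, 2]})
        )
        res = lk.detect_par_boundary(flat)
        assert res.boundary_marker is None and res.z_diff_markers == ["s:1", "s:2"]
        rising = lk.GeneticMap.from_positions(
            pd.DataFrame({"marker": ["s:1", "s:2", "s:3"], "cum_sexavg": [0, 1, 2],
                          "cum_female": [0, 5, 9], "cum_male": [0, 1, 2]})
        )
        res = lk.detect_par_boundary(rising)
        assert res.boundary_marker == "s:3" and res.par_markers == ["s:1", "s:2", "s:3"]

    def test_simulated_boundary_within_one_interval_of_truth(self, linkage_cohort):
        _, ped, gt, _, ts = linkage_cohort
        z_order = gt.markers[gt.markers["chrom"] == "Z"].sort_values("chrom_pos")["marker"].tolist()
        gmap = lk.build_map(gt, ped, z_order, ts=ts)
        res = lk.detect_par_boundary(gmap)
        # true boundary: last PAR marker (par_1:375000); next marker starts Z_diff
        boundary_idx = z_order.index(res.boundary_marker)
        true_idx = z_order.index("par_1:375000")
        assert abs(boundary_idx - true_idx) <= 1
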