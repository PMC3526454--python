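"""Background estimation, measurement filtering, outlier and distribution checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from probelint.measurement_qc import (
    BackgroundEstimate,
    SampleMeta,
    apply_measurement_filter,
    detect_sample_outliers,
    distribution_checks,
    estimate_background,
    select_background_candidates,
)
from probelint.probe_filters import FilterVerdict
from probelint.synthetic import simulate_intensities

from conftest import make_matrix


def verdict(pid, flags=()):
    return FilterVerdict(probe_id=pid, flags=set(flags))


class TestSelectCandidates:
    def test_selection_rules(self):
        verdicts = [
            verdict("stable_unexpr"),
            verdict("stable_expr"),
            verdict("weak_unexpr"),
            verdict("flagged", {"cross_hyb"}),
            verdict("stable_polyg", {"poly_g"}),  # poly_g is not a uniqueness flag
        ]
        dgs = {
            "stable_unexpr": -12.0,
            "stable_expr": -12.0,
            "weak_unexpr": -3.0,
            "flagged": -12.0,
            "stable_polyg": -12.0,
        }
        genes = {p: f"gene_{p}" for p in dgs}
        out = select_background_candidates(
            verdicts, dgs, genes, ["gene_stable_unexpr", "gene_weak_unexpr",
                                   "gene_flagged", "gene_stable_polyg"]
        )
        assert out == ["stable_polyg", "stable_unexpr"]

    def test_strict_cutoff_boundary(self):
        verdicts = [verdict("at_cutoff"), verdict("below")]
        dgs = {"at_cutoff": -10.0, "below": -10.0001}
        genes = {"at_cutoff": "g1", "below": "g2"}
        out = select_background_candidates(verdicts, dgs, genes, ["g1", "g2"])
        assert out == ["below"]

    def test_empty_candidate_set_is_error(self):
        with pytest.raises(ValueError, match="relax"):
            select_background_candidates([verdict("p")], {"p": -3.0}, {"p": "g"}, ["g"])


class TestEstimateBackground:
    def test_constant_candidates_all_methods(self):
        m = make_matrix(np.full((3, 6), 2.5), ["control"] * 3 + ["disease"] * 3)
        for method in ("stable_unexpressed_mean", "stable_unexpressed_median"):
            bg = estimate_background(m, m.probe_ids, method)
            assert bg.cutoffs == {"control": 2.5, "disease": 2.5}

    def test_simple_arithmetic(self):
        vals = np.array([[2.0, 2.0, 5.0], [3.0, 3.0, 5.0], [4.0, 4.0, 5.0]])
        m = make_matrix(vals, ["control", "control", "disease"])
        bg = estimate_background(m, m.probe_ids, "stable_unexpressed_mean")
        assert bg.cutoffs["control"] == pytest.approx(3.0)
        bg = estimate_background(m, m.probe_ids, "stable_unexpressed_median")
        assert bg.cutoffs["control"] == pytest.approx(3.0)

    def test_planted_floor_recovered(self):
        truth = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(500)],
                "category": ["background"] * 200 + ["clean"] * 300,
                "unexpressed_gene": [True] * 200 + [False] * 300,
            },
            index=[f"p{i:04d}" for i in range(500)],
        )
        sim = simulate_intensities(truth, n_control=6, n_disease=6,
                                   floor_mean=2.5, floor_sd=0.1, seed=11)
        candidates = list(truth.index[:200])
        bg = estimate_background(sim.matrix, candidates)
        for cls in ("control", "disease"):
            assert abs(bg.cutoffs[cls] - 2.5) < 0.05

    def test_cutoffs_within_candidate_range(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(2.5, 0.2, (50, 6)), ["control"] * 3 + ["disease"] * 3)
        for method in ("stable_unexpressed_mean", "stable_unexpressed_median"):
            bg = estimate_background(m, m.probe_ids, method)
            block = m.values.to_numpy()
            assert block.min() <= bg.cutoffs["control"] <= block.max()

    def test_missing_class_is_error(self):
        m = make_matrix(np.full((2, 3), 2.5), ["control"] * 3)
        with pytest.raises(ValueError, match="zero arrays"):
            estimate_background(m, m.probe_ids)

    def test_lowess_floor_tracks_stable_end(self):
        rng = np.random.default_rng(4)
        n = 120
        dgs = {f"p{i:03d}": float(-14 + 12 * i / n) for i in range(n)}
        # intensity rises away from the stable-folding end
        base = np.array([2.5 if dgs[f"p{i:03d}"] < -10 else 4.0 for i in range(n)])
        vals = base[:, None] + rng.normal(0, 0.05, (n, 6))
        m = make_matrix(vals, ["control"] * 3 + ["disease"] * 3)
        candidates = [p for p, g in dgs.items() if g < -10]
        bg = estimate_background(m, candidates, "lowess_floor", monomer_dg=dgs)
        assert abs(bg.cutoffs["control"] - 2.5) < 0.3


class TestMeasurementFilter:
    def bg(self, control=2.5, disease=2.5):
        return BackgroundEstimate(
            cutoffs={"control": control, "disease": disease},
            method="stable_unexpressed_mean",
            candidate_probe_ids=["x"],
        )

    def test_cutoff_below_minimum_retains_all(self):
        m = make_matrix(np.full((4, 6), 3.0), ["control"] * 3 + ["disease"] * 3)
        retained, filtered, removed = apply_measurement_filter(m, self.bg(0.0, 0.0))
        assert retained == m.probe_ids and removed.empty
        assert filtered.values.equals(m.values)

    def test_single_failing_array_removes_probe(self):
        vals = np.full((2, 6), 3.0)
        vals[1, 0] = 2.0  # below cutoff in one control array
        m = make_matrix(vals, ["control"] * 3 + ["disease"] * 3)
        retained, _, removed = apply_measurement_filter(m, self.bg())
        assert retained == ["p000"]
        assert set(removed["probe_id"]) == {"p001"}
        row = removed.iloc[0]
        assert row["class"] == "control" and row["sample"] == "s00"

    def test_strictly_above_required(self):
        vals = np.full((1, 6), 2.5)  # exactly at the cutoff everywhere
        m = make_matrix(vals, ["control"] * 3 + ["disease"] * 3)
        retained, _, _ = apply_measurement_filter(m, self.bg())
        assert retained == []

    def test_either_mode_accepts_one_valid_class(self):
        vals = np.array([[3.0, 3.0, 3.0, 1.0, 1.0, 1.0]])
        m = make_matrix(vals, ["control"] * 3 + ["disease"] * 3)
        assert apply_measurement_filter(m, self.bg(), mode="both")[0] == []
        assert apply_measurement_filter(m, self.bg(), mode="either")[0] == ["p000"]

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(3, 0.5, (40, 6)), ["control"] * 3 + ["disease"] * 3)
        previous = None
        for cutoff in (2.0, 2.5, 3.0, 3.5):
            retained, _, _ = apply_measurement_filter(m, self.bg(cutoff, cutoff))
            if previous is not None:
                assert set(retained) <= set(previous)
            previous = retained

    def test_nan_is_never_valid(self):
        vals = np.full((1, 6), 3.0)
        vals[0, 2] = np.nan
        m = make_matrix(vals, ["control"] * 3 + ["disease"] * 3)
        assert apply_measurement_filter(m, self.bg())[0] == []


class TestOutlierDetection:
    def test_identical_samples_have_no_outliers(self):
        m = make_matrix(np.full((5, 8), 3.0), ["control"] * 4 + ["disease"] * 4)
        outliers, diag = detect_sample_outliers(m)
        assert outliers == [] and not diag["outlier"].any()

    def test_planted_three_sd_sample_flagged(self):
        truth = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(100)],
                "category": ["clean"] * 100,
                "unexpressed_gene": [False] * 100,
            },
            index=[f"p{i:03d}" for i in range(100)],
        )
        sim = simulate_intensities(
            truth, n_control=8, n_disease=8, outlier_sd_multiple=3.0, seed=21
        )
        outliers, diag = detect_sample_outliers(sim.matrix)
        # detection is guaranteed; other samples may occasionally exceed the
        # leave-one-out threshold, which the diagnostics table exposes
        assert sim.outlier_sample in outliers
        z = diag.set_index("sample").at[sim.outlier_sample, "z_mean_signal"]
        assert z == pytest.approx(3.0, abs=1e-6)

    def test_exactly_two_sd_not_flagged_strict(self):
        # others: mean 0, population SD exactly 1; candidate sits at 2.0 SD
        others = [-1.0, -1.0, -1.0, -1.0, 1.0, 1.0, 1.0, 1.0]
        vals = np.array([others + [2.0] + [5.0, 5.0, 5.0]])
        m = make_matrix(vals, ["control"] * 9 + ["disease"] * 3)
        outliers, diag = detect_sample_outliers(m)
        assert outliers == []
        cand = diag.loc[diag["sample"] == "s08"].iloc[0]
        assert cand["z_mean_signal"] == pytest.approx(2.0)
        # nudged above the boundary it flags
        vals[0, 8] = 2.0 + 1e-4
        outliers, _ = detect_sample_outliers(make_matrix(
            vals, ["control"] * 9 + ["disease"] * 3))
        assert outliers == ["s08"]

    def test_invariant_to_order_and_constant_shift(self):
        rng = np.random.default_rng(31)
        vals = rng.normal(3, 0.3, (20, 8))
        classes = ["control"] * 4 + ["disease"] * 4
        m = make_matrix(vals, classes)
        base, _ = detect_sample_outliers(m)
        perm = [3, 1, 0, 2, 7, 5, 6, 4]
        m2 = make_matrix(vals[:, perm], [classes[i] for i in perm])
        shifted, _ = detect_sample_outliers(m2)
        name_map = {f"s{j:02d}": f"s{perm[j]:02d}" for j in range(8)}
        assert sorted(name_map[s] for s in shifted) == base
        plus, _ = detect_sample_outliers(make_matrix(vals + 7.0, classes))
        assert plus == base

    def test_small_class_is_error(self):
        m = make_matrix(np.full((2, 5), 3.0), ["control"] * 2 + ["disease"] * 3)
        with pytest.raises(ValueError, match=">= 3"):
            detect_sample_outliers(m)

    def test_include_self_option(self):
        others = [-1.0, -1.0, -1.0, -1.0, 1.0, 1.0, 1.0, 1.0]
        vals = np.array([others + [2.5] + [5.0, 5.0, 5.0]])
        m = make_matrix(vals, ["control"] * 9 + ["disease"] * 3)
        loo, _ = detect_sample_outliers(m, leave_one_out=True)
        incl, _ = detect_sample_outliers(m, leave_one_out=False)
        assert loo == ["s08"]
        # including the candidate inflates the SD, weakening detection
        assert set(incl) <= set(loo)


class TestDistributionChecks:
    def test_equal_variance_gives_unit_f(self):
        rng = np.random.default_rng(41)
        a = rng.normal(0, 1, 20)
        rep = distribution_checks(a, a + 5.0)
        assert rep.f_statistic == pytest.approx(1.0)
        assert rep.f_pvalue == pytest.approx(1.0)

    def test_tenfold_variance_ratio_rejected(self):
        rng = np.random.default_rng(42)
        base = rng.normal(0, 1, 20)
        a = base * np.sqrt(10.0)
        b = rng.normal(0, 1, 20)
        # scale a so the sample variance ratio is exactly 10
        a = a / a.std(ddof=1) * np.sqrt(10.0) * b.std(ddof=1)
        rep = distribution_checks(a, b)
        assert rep.f_statistic == pytest.approx(10.0)
        crit = stats.f.ppf(0.975, 19, 19)
        assert rep.f_statistic > crit and rep.f_pvalue < 0.05

    def test_shapiro_rejects_exponential(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            rep = distribution_checks(rng.exponential(1.0, 50), rng.normal(0, 1, 50))
            w, p = rep.shapiro["A"]
            rejections += p < 0.05
        assert rejections >= 19  # >= 95% of seeded replicates

    def test_constant_group_reported_undefined(self):
        rep = distribution_checks([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert rep.shapiro["A"] is None and rep.shapiro["B"] is not None

    def test_qq_pairs_are_plottable(self):
        rng = np.random.default_rng(43)
        rep = distribution_checks(rng.normal(0, 1, 30), rng.normal(0, 1, 30))
        osm, osr = rep.qq["A"]
        assert len(osm) == len(osr) == 30
        assert np.all(np.diff(osm) >= 0)


class TestSampleMeta:
    def test_rin_gate(self):
        assert SampleMeta("s", "control", rin=7.0).passes_rin()
        assert not SampleMeta("s", "control", rin=5.0).passes_rin()
        assert not SampleMeta("s", "control").passes_rin()
        with pytest.raises(ValueError):
            SampleMeta("s", "control", rin=11.0)
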