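import math

import numpy as np
import pytest

from ervkit import expression_analysis as ea
from ervkit.core_io import AlignmentRecord, GenomicInterval, ProvirusRecord
from ervkit.quantification import ElementExpression
from ervkit.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_peaks,
    simulate_transcript_reads,
)

from conftest import make_element, make_peaks


def expr(eid, rpkm):
    return ElementExpression(element_id=eid, family="ERVF", length_kb=5.0,
                             n_reads=rpkm, rpkm=rpkm, r_s=rpkm, r_c=0.0,
                             u_s=0.0, t_s=rpkm, specificity=1.0)


def element_with_regions(start=10_000, strand="+"):
    length = 5_000
    iv = GenomicInterval("chr1", start, start + length, strand)
    fractions = [("5LTR", 0.0, 0.1), ("gag", 0.1, 0.35), ("pro", 0.35, 0.5),
                 ("pol", 0.5, 0.75), ("env", 0.75, 0.9), ("3LTR", 0.9, 1.0)]
    if strand == "-":
        fractions = [(lbl, 1 - b, 1 - a) for lbl, a, b in reversed(fractions)]
    regions = {
        lbl: GenomicInterval("chr1", start + int(a * length),
                             start + int(b * length), strand)
        for lbl, a, b in fractions
    }
    return ProvirusRecord("e0", "ERVF", iv, regions=regions)


def reads_in(iv, n, rng, length=50, prefix="r"):
    out = []
    for k in range(n):
        s = int(rng.integers(iv.start, max(iv.start + 1, iv.end - length)))
        out.append(AlignmentRecord(f"{prefix}{k}",
                                   [GenomicInterval(iv.chrom, s, s + length)]))
    return out


class TestRegionCoverage:
    def test_normalization_by_5ltr(self, rng):
        el = element_with_regions()
        counts = {"5LTR": 100, "gag": 80, "pro": 60, "pol": 2, "env": 1,
                  "3LTR": 90}
        records = []
        for i, (label, n) in enumerate(counts.items()):
            records += reads_in(el.regions[label], n, rng, prefix=label)
        prof = ea.region_coverage(records, el)
        assert prof.defined
        assert prof.normalized["5LTR"] == 1.0
        for label, n in counts.items():
            assert prof.normalized[label] == pytest.approx(n / 100)

    def test_all_reads_in_5ltr(self, rng):
        el = element_with_regions()
        prof = ea.region_coverage(reads_in(el.regions["5LTR"], 20, rng), el)
        assert prof.normalized["5LTR"] == 1.0
        assert all(prof.normalized[r] == 0.0 for r in prof.normalized
                   if r != "5LTR")

    def test_transcript_structure_recovered(self, rng):
        # reads from a 5LTR-gag-pro-3LTR transcript leave pol/env empty
        el = element_with_regions()
        records = simulate_transcript_reads(
            el, ["5LTR", "gag", "pro", "3LTR"], 2_000, rng)
        prof = ea.region_coverage(records, el)
        assert prof.normalized["pol"] < 0.05
        assert prof.normalized["env"] < 0.05
        assert prof.normalized["gag"] > 0.5

    def test_scale_invariance(self, rng):
        el = element_with_regions()
        records = simulate_transcript_reads(el, ["5LTR", "gag"], 500, rng)
        p1 = ea.region_coverage(records, el)
        doubled = records + [
            AlignmentRecord(r.read_id + "_dup", list(r.hits)) for r in records
        ]
        p2 = ea.region_coverage(doubled, el)
        for label in p1.normalized:
            assert p2.normalized[label] == pytest.approx(p1.normalized[label])

    def test_zero_5ltr_flagged_undefined(self, rng):
        el = element_with_regions()
        prof = ea.region_coverage(reads_in(el.regions["gag"], 5, rng), el)
        assert not prof.defined
        assert math.isnan(prof.normalized["gag"])

    def test_missing_region_map_rejected(self):
        with pytest.raises(ValueError):
            ea.region_coverage([], make_element(0, 100))

    def test_multiread_uniform_split(self):
        el = element_with_regions()
        hit_in = el.regions["5LTR"]
        multi = AlignmentRecord("m", [
            GenomicInterval("chr1", hit_in.start, hit_in.start + 50),
            GenomicInterval("chr1", 500_000 // 2, 500_000 // 2 + 50)])
        prof = ea.region_coverage([multi], el)
        assert prof.counts["5LTR"] == pytest.approx(0.5)


class TestTopK:
    def test_hand_fraction(self):
        exprs = [expr("a", 50), expr("b", 30), expr("c", 20)]
        top, frac = ea.top_k_concentration(exprs, 2)
        assert [e.element_id for e in top] == ["a", "b"]
        assert frac == pytest.approx(0.8)

    def test_k_all_is_one(self):
        exprs = [expr(f"e{i}", 10 * i + 1) for i in range(5)]
        _, frac = ea.top_k_concentration(exprs, 5)
        assert frac == pytest.approx(1.0)

    def test_all_equal_half(self):
        exprs = [expr(f"e{i}", 7.0) for i in range(10)]
        _, frac = ea.top_k_concentration(exprs, 5)
        assert frac == pytest.approx(0.5)

    def test_monotone_in_k(self, rng):
        exprs = [expr(f"e{i}", float(v)) for i, v in
                 enumerate(rng.uniform(0, 100, 20))]
        fracs = [ea.top_k_concentration(exprs, k)[1] for k in range(1, 21)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == pytest.approx(1.0)

    def test_tie_break_by_id(self):
        exprs = [expr("z", 10), expr("a", 10), expr("m", 10)]
        top, _ = ea.top_k_concentration(exprs, 2)
        assert [e.element_id for e in top] == ["a", "m"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ea.top_k_concentration([], 1)


class TestTrajectories:
    def test_constant_normalizer(self):
        s = ea.StageSeries(["N0", "N1", "N2", "N3"], [10, 5, 2, 1],
                           [4, 4, 4, 4])
        np.testing.assert_allclose(ea.normalize_trajectory(s),
                                   [1.0, 0.5, 0.2, 0.1])

    def test_proportional_series_is_flat(self):
        s = ea.StageSeries(["N0", "N1", "N2"], [8, 4, 2], [16, 8, 4])
        np.testing.assert_allclose(ea.normalize_trajectory(s), [1, 1, 1])

    def test_decreasing_input_stays_decreasing(self):
        s = ea.StageSeries(["N0", "N1", "N2", "N3"], [16, 8, 4, 2],
                           [2, 2, 2, 2])
        vals = ea.normalize_trajectory(s)
        assert np.all(np.diff(vals) < 0)

    def test_zero_normalizer_rejected(self):
        s = ea.StageSeries(["N0", "N1", "N2"], [1, 1, 1], [1, 0, 1])
        with pytest.raises(ValueError):
            ea.normalize_trajectory(s)

    def test_correlation_identity(self):
        assert ea.correlate_trajectories([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_correlation_reversal(self):
        assert ea.correlate_trajectories([1, 2, 3, 4], [4, 3, 2, 1]) == -1.0

    def test_rank_equality_hand_case(self):
        assert ea.correlate_trajectories(
            [4, 3, 2, 1], [8, 6, 4, 3], method="spearman") == 1.0

    def test_pearson_differs_from_spearman_on_nonlinear(self):
        x = [1, 2, 3, 4]
        y = [1, 10, 100, 1000]
        assert ea.correlate_trajectories(x, y, "spearman") == 1.0
        assert ea.correlate_trajectories(x, y, "pearson") < 1.0

    def test_constant_series_nan_not_crash(self):
        with pytest.warns(UserWarning):
            rho = ea.correlate_trajectories([1, 1, 1], [1, 2, 3],
                                            method="pearson")
        assert math.isnan(rho)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ea.correlate_trajectories([1, 2], [1, 2])


class TestTFProximity:
    def planted(self, rng, d, n=300, sep=30_000):
        elements = []
        peaks = []
        for i in range(n):
            start = 10_000 + sep * i
            el = make_element(start, start + 5_000, eid=f"e{i}")
            elements.append(el)
            peaks.append(el.tss + int(rng.integers(0, d + 1)))
        return elements, make_peaks(sorted(peaks))

    def test_uniform_placement_mean_is_half_window(self, rng):
        elements, peaks = self.planted(rng, 500)
        res = ea.tf_proximity(elements, peaks)
        assert res.mean_distance_bp == pytest.approx(250, rel=0.1)
        assert res.n_bound == len(elements)

    def test_peaks_at_tss_mean_zero(self):
        elements = [make_element(10_000 * i + 1000, 10_000 * i + 3000,
                                 eid=f"e{i}") for i in range(10)]
        peaks = make_peaks([el.tss for el in elements])
        res = ea.tf_proximity(elements, peaks)
        assert res.mean_distance_bp == 0.0

    def test_wide_uniform_placement(self, rng):
        elements, peaks = self.planted(rng, 4000)
        res = ea.tf_proximity(elements, peaks)
        assert res.mean_distance_bp == pytest.approx(2000, rel=0.1)

    def test_subset_filter(self, rng):
        elements, peaks = self.planted(rng, 500, n=50)
        keep = [f"e{i}" for i in range(10)]
        res = ea.tf_proximity(elements, peaks, subset=keep)
        assert res.n_total == 10

    def test_empty_subset_rejected(self, rng):
        elements, peaks = self.planted(rng, 500, n=10)
        with pytest.raises(ValueError):
            ea.tf_proximity(elements, peaks, subset=["nope"])

    def test_f_curve_with_controls(self, rng):
        elements, peaks = self.planted(rng, 500, n=100)
        controls = [("chr1", int(p)) for p in
                    rng.integers(0, 30_000 * 100, 2_000)]
        res = ea.tf_proximity(elements, peaks, controls=controls)
        assert res.max_assoc_window_bp in set(res.windows)
        assert res.half_window_ratio is not None

    def test_monte_carlo_error_shrinks_with_n(self):
        # mean error under uniform [0, D] placement decays ~ 1/sqrt(n)
        errs = []
        for n in (100, 10_000):
            reps = []
            for s in range(10):
                rng = np.random.default_rng(s)
                elements, peaks = self.planted(rng, 1000, n=n)
                res = ea.tf_proximity(elements, peaks)
                reps.append(abs(res.mean_distance_bp - 500))
            errs.append(np.mean(reps))
        assert errs[1] < errs[0]


class TestTFOrder:
    def elements_with_distances(self, dists_per_tf, n=20):
        # plants peaks at fixed distances downstream of each TSS
        elements = [make_element(50_000 * i + 1000, 50_000 * i + 6000,
                                 eid=f"e{i}") for i in range(n)]
        peak_sets = []
        for tf, d in enumerate(dists_per_tf):
            peak_sets.append(make_peaks(
                sorted(el.tss + d for el in elements),
                marker=f"TF{tf}"))
        return elements, peak_sets

    def test_perfect_order(self):
        elements, ps = self.elements_with_distances([100, 800, 1800])
        frac, n_inc, n_exc = ea.tf_order_fraction(elements, ps)
        assert (frac, n_inc, n_exc) == (1.0, 20, 0)

    def test_reversed_order(self):
        elements, ps = self.elements_with_distances([1800, 800, 100])
        frac, _, _ = ea.tf_order_fraction(elements, ps)
        assert frac == 0.0

    def test_ties_violate_strict_order(self):
        elements, ps = self.elements_with_distances([500, 500, 900])
        frac, _, _ = ea.tf_order_fraction(elements, ps)
        assert frac == 0.0

    def test_missing_tf_excluded_with_count(self):
        elements, ps = self.elements_with_distances([100, 800, 20_000])
        frac, n_inc, n_exc = ea.tf_order_fraction(elements, ps, max_bp=10_000)
        assert n_inc == 0 and n_exc == 20

    def test_random_placement_one_sixth(self):
        # independent uniform distances per TF: P(strict order) = 1/3! = 1/6
        rng = np.random.default_rng(0)
        n = 3_000
        elements = [make_element(60_000 * i + 1000, 60_000 * i + 6000,
                                 eid=f"e{i}") for i in range(n)]
        peak_sets = []
        for tf in range(3):
            positions = sorted(
                int(el.tss + rng.integers(1, 5_000)) for el in elements)
            peak_sets.append(make_peaks(positions, marker=f"TF{tf}"))
        frac, n_inc, _ = ea.tf_order_fraction(elements, peak_sets)
        se = math.sqrt((1 / 6) * (5 / 6) / n_inc)
        assert abs(frac - 1 / 6) < 4 * se


class TestBindingFraction:
    def test_all_bound(self):
        elements = [make_element(50_000 * i + 1000, 50_000 * i + 6000,
                                 eid=f"e{i}") for i in range(10)]
        peaks = make_peaks(sorted(el.tss + 100 for el in elements))
        assert ea.binding_fraction(elements, peaks, 500) == 1.0

    def test_none_bound(self):
        elements = [make_element(50_000 * i + 1000, 50_000 * i + 6000,
                                 eid=f"e{i}") for i in range(10)]
        peaks = make_peaks([el.tss + 20_000 for el in elements][:1])
        assert ea.binding_fraction(elements, peaks, 500) == 0.0

    def test_planted_96_percent_recovered_exactly(self, rng):
        n = 50
        elements = [make_element(60_000 * i + 1000, 60_000 * i + 6000,
                                 eid=f"e{i}") for i in range(n)]
        bound_ids = rng.choice(n, size=48, replace=False)  # 96% of 50
        peaks = make_peaks(sorted(
            elements[i].tss + int(rng.integers(0, 400)) for i in bound_ids))
        assert ea.binding_fraction(elements, peaks, 500) == pytest.approx(0.96)

    def test_ltr5_anchor_uses_region(self):
        el = element_with_regions(start=10_000)
        # peak inside the 5'LTR region
        inside = make_peaks([el.regions["5LTR"].start + 10])
        assert ea.binding_fraction([el], inside, 100, anchor="LTR5") == 1.0
        far = make_peaks([el.interval.end + 5_000])
        assert ea.binding_fraction([el], far, 100, anchor="LTR5") == 0.0
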