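import numpy as np
import pandas as pd
import pytest

from roisummary import (
    GridMismatchError,
    MeasureSpec,
    ROIMask,
    ScalarMap,
    SubjectFirstLevel,
    VolumeGrid,
    central_summary,
    default_measure_specs,
    eigen_weighted_mean,
    extract_all,
    extract_measure,
    find_peak,
    peak_cluster_extent,
    peak_cluster_mean,
    peak_correlated_mean,
    peak_sphere_mean,
    top_n_contiguous_mean,
    top_percentile_mean,
)

from conftest import make_random_flm, make_random_roi
from oracles import oracle_measure, oracle_peak


def flm_from(grid, beta, t, series=None, df=38):
    beta = np.asarray(beta, dtype=float).reshape(grid.shape)
    t = np.asarray(t, dtype=float).reshape(grid.shape)
    return SubjectFirstLevel(
        beta=ScalarMap(grid, beta),
        tmap=ScalarMap(grid, t),
        df=df,
        series=None if series is None else np.asarray(series, dtype=float),
    )


def line_grid(n):
    """n voxels along x, 3 mm apart — keeps toy examples one-dimensional."""
    return VolumeGrid((n, 1, 1))


def full_roi(grid):
    return ROIMask(grid, np.ones(grid.shape, dtype=bool))


class TestMeasureSpec:
    def test_variant_availability(self):
        with pytest.raises(ValueError):
            MeasureSpec(5, "B")
        with pytest.raises(ValueError):
            MeasureSpec(9, "A")
        MeasureSpec(9, "B")  # fine

    def test_parameter_presence(self):
        with pytest.raises(ValueError):
            MeasureSpec(4, "A")  # q missing
        with pytest.raises(ValueError):
            MeasureSpec(1, "A", q=10)  # extraneous parameter

    def test_default_specs_cover_table(self):
        specs = default_measure_specs()
        assert len(specs) == 16
        assert len({s.name for s in specs}) == 16


class TestFindPeak:
    def test_unique_maximum(self, grid6, rng):
        flm = make_random_flm(grid6, rng, with_series=False)
        flm.tmap.data[4, 2, 5] = 99.0
        assert find_peak(flm, full_roi(grid6)) == (4, 2, 5)

    def test_tie_breaks_lexicographic(self):
        grid = line_grid(4)
        flm = flm_from(grid, [0, 0, 0, 0], [1, 3, 3, 2])
        assert find_peak(flm, full_roi(grid)) == (1, 0, 0)

    def test_matches_exhaustive_scan(self, grid6, rng):
        for _ in range(20):
            flm = make_random_flm(grid6, rng, with_series=False)
            roi = make_random_roi(grid6, rng)
            assert find_peak(flm, roi) == oracle_peak(flm.tmap.data, roi.data)

    def test_empty_roi_errors(self, grid6, rng):
        flm = make_random_flm(grid6, rng, with_series=False)
        empty = ROIMask(grid6, np.zeros(grid6.shape, dtype=bool), allow_empty=True)
        with pytest.raises(ValueError):
            find_peak(flm, empty)


class TestCentralSummary:
    def test_mean_median_of_four(self):
        grid = line_grid(4)
        flm = flm_from(grid, [1, 2, 3, 4], [1, 1, 1, 1])
        roi = full_roi(grid)
        assert central_summary(flm, roi, "mean").value == pytest.approx(2.5)
        assert central_summary(flm, roi, "median").value == pytest.approx(2.5)

    def test_b_variant_all_subthreshold_missing(self):
        grid = line_grid(4)
        flm = flm_from(grid, [1, 2, 3, 4], [-1, -2, -1, -3], df=20)
        out = central_summary(flm, full_roi(grid), "mean", variant="B")
        assert out.missing and np.isnan(out.value)


class TestEigenWeightedMean:
    def test_shared_timecourse_equal_weights(self):
        # both voxels carry one timecourse -> rank-one, equal weights -> 2
        grid = line_grid(2)
        tc = np.array([1.0, -1.0, 2.0, 0.0, -2.0, 0.5])
        series = np.stack([tc, tc]).reshape(2, 1, 1, -1)
        flm = flm_from(grid, [1, 3], [1, 1], series=series)
        out = eigen_weighted_mean(flm, full_roi(grid))
        assert out.value == pytest.approx(2.0)

    def test_single_voxel_is_its_beta(self, grid6, rng):
        flm = make_random_flm(grid6, rng)
        data = np.zeros(grid6.shape, dtype=bool)
        data[2, 2, 2] = True
        out = eigen_weighted_mean(flm, ROIMask(grid6, data))
        assert out.value == pytest.approx(flm.beta.data[2, 2, 2])

    def test_three_voxel_toy_vs_independent_svd(self):
        grid = line_grid(3)
        series = np.array(
            [
                [1.0, 2.0, 3.0, 4.0, 3.0, 2.0],
                [2.0, 4.1, 5.9, 8.0, 6.1, 4.0],
                [0.5, 0.9, 1.6, 2.1, 1.4, 1.0],
            ]
        ).reshape(3, 1, 1, -1)
        flm = flm_from(grid, [1.0, 2.0, 0.5], [3.0, 4.0, 1.0], series=series)
        roi = full_roi(grid)
        expected = oracle_measure(
            3, flm.beta.data, flm.tmap.data, roi.data, flm.df, grid,
            series=flm.series,
        )
        assert eigen_weighted_mean(flm, roi).value == pytest.approx(expected)

    def test_needs_series(self, grid6, rng):
        flm = make_random_flm(grid6, rng, with_series=False)
        with pytest.raises(ValueError):
            eigen_weighted_mean(flm, full_roi(grid6))


class TestTopPercentile:
    def test_four_voxel_example(self):
        grid = line_grid(4)
        flm = flm_from(grid, [10, 20, 30, 40], [1, 2, 3, 4])
        out = top_percentile_mean(flm, full_roi(grid), q=25)
        assert out.value == pytest.approx(40.0)
        assert out.n_voxels_used == 1

    def test_q100_equals_mean(self, grid6, rng):
        flm = make_random_flm(grid6, rng, with_series=False)
        roi = make_random_roi(grid6, rng)
        full = top_percentile_mean(flm, roi, q=100)
        mean = central_summary(flm, roi, "mean")
        assert full.value == pytest.approx(mean.value)

    def test_tie_at_cut_resolved_lexicographically(self):
        grid = line_grid(4)
        flm = flm_from(grid, [10, 20, 30, 40], [5, 3, 3, 1])
        out = top_percentile_mean(flm, full_roi(grid), q=50)
        # k=2: t=5 first, then the tie at t=3 goes to the smaller index
        assert out.value == pytest.approx((10 + 20) / 2)


class TestTopNContiguous:
    def test_n1_is_peak_beta(self, grid6, rng):
        flm = make_random_flm(grid6, rng, with_series=False)
        roi = make_random_roi(grid6, rng)
        peak = find_peak(flm, roi)
        out = top_n_contiguous_mean(flm, roi, n=1)
        assert out.value == pytest.approx(flm.beta.data[peak])

    def test_n_at_least_roi_is_roi_mean_when_connected(self, grid6, rng):
        data = np.zeros(grid6.shape, dtype=bool)
        data[1:4, 2:5, 1:3] = True  # connected box
        roi = ROIMask(grid6, data)
        flm = make_random_flm(grid6, rng, with_series=False)
        out = top_n_contiguous_mean(flm, roi, n=roi.n_voxels + 5)
        assert out.value == pytest.approx(flm.beta.data[data].mean())

    def test_decreasing_t_gives_global_top_n(self, grid6):
        # t strictly decreasing with distance from the peak: the grown set
        # must equal the N globally highest-t voxels
        centers = grid6.voxel_centers_mm()
        peak_mm = grid6.ijk_to_mm((3, 3, 3))
        dist = np.linalg.norm(centers - peak_mm, axis=-1)
        # tiny unique offsets break the lattice distance-shell ties
        t = 10.0 - dist + np.linspace(0, 1e-6, grid6.n_voxels).reshape(grid6.shape)
        beta = np.arange(grid6.n_voxels, dtype=float).reshape(grid6.shape)
        flm = flm_from(grid6, beta, t)
        roi = full_roi(grid6)
        for n in (5, 17, 40):
            out = top_n_contiguous_mean(flm, roi, n=n)
            top_idx = np.argsort(-t.ravel())[:n]
            expected = beta.ravel()[top_idx].mean()
            assert out.value == pytest.approx(expected)


class TestPeakSphere:
    def test_radius_zero_is_peak_beta(self, grid6, rng):
        flm = make_random_flm(grid6, rng, with_series=False)
        roi = make_random_roi(grid6, rng)
        peak = find_peak(flm, roi)
        out = peak_sphere_mean(flm, roi, radius_mm=0.0)
        assert out.value == pytest.approx(flm.beta.data[peak])

    def test_huge_radius_a_is_roi_mean(self, grid6, rng):
        flm = make_random_flm(grid6, rng, with_series=False)
        roi = make_random_roi(grid6, rng)
        out = peak_sphere_mean(flm, roi, radius_mm=1e4)
        assert out.value == pytest.approx(flm.beta.data[roi.data].mean())

    def test_6mm_toy_matches_enumeration(self, grid6, rng):
        flm = make_random_flm(grid6, rng, with_series=False)
        roi = full_roi(grid6)
        expected = oracle_measure(
            7, flm.beta.data, flm.tmap.data, roi.data, flm.df, grid6,
            radius_mm=6.0,
        )
        assert peak_sphere_mean(flm, roi, radius_mm=6.0).value == pytest.approx(expected)


class TestPeakCorrelated:
    def test_shared_timecourse_whole_component(self, grid6):
        tc = np.array([0.0, 1.0, -1.0, 2.0, 0.5, -0.5])
        data = np.zeros(grid6.shape, dtype=bool)
        data[2:4, 2:4, 2] = True  # connected 2x2 patch
        series = np.zeros(grid6.shape + (6,))
        # positive scalings of one timecourse -> correlation exactly 1
        scales = {(2, 2, 2): 1.0, (2, 3, 2): 2.0, (3, 2, 2): 0.5, (3, 3, 2): 3.0}
        beta = np.zeros(grid6.shape)
        t = np.zeros(grid6.shape)
        for v, s in scales.items():
            series[v] = s * tc
            beta[v] = s
            t[v] = s
        flm = flm_from(grid6, beta, t, series=series)
        out = peak_correlated_mean(flm, ROIMask(grid6, data), corr_r=0.9)
        assert out.value == pytest.approx(np.mean(list(scales.values())))
        assert out.n_voxels_used == 4

    def test_unattainable_threshold_keeps_peak_alone(self, grid6, rng):
        flm = make_random_flm(grid6, rng)
        roi = full_roi(grid6)
        peak = find_peak(flm, roi)
        out = peak_correlated_mean(flm, roi, corr_r=0.9999)
        assert out.n_voxels_used == 1
        assert out.value == pytest.approx(flm.beta.data[peak])

    def test_two_separated_blocks_only_peak_block(self, grid6):
        tc = np.array([0.0, 1.0, -1.0, 2.0, 0.5, -0.5])
        series = np.zeros(grid6.shape + (6,))
        beta = np.zeros(grid6.shape)
        t = np.zeros(grid6.shape)
        near = [(0, 0, 0), (0, 1, 0)]
        far = [(5, 5, 5), (5, 4, 5)]
        for v in near + far:
            series[v] = tc
            beta[v] = 1.0 if v in near else 7.0
        t[(0, 0, 0)] = 5.0  # peak in the near block
        data = np.zeros(grid6.shape, dtype=bool)
        for v in near + far:
            data[v] = True
        flm = flm_from(grid6, beta, t, series=series)
        out = peak_correlated_mean(flm, ROIMask(grid6, data), corr_r=0.9)
        assert out.value == pytest.approx(1.0)
        assert out.n_voxels_used == 2


class TestPeakCluster:
    def _two_cluster_flm(self, grid6):
        t = np.zeros(grid6.shape)
        beta = np.zeros(grid6.shape)
        big = [(1, 1, 1), (1, 2, 1), (2, 2, 1), (2, 1, 1), (1, 1, 2)]
        small = [(5, 5, 5), (5, 4, 5), (4, 5, 5)]
        for v in big:
            t[v] = 5.0
            beta[v] = 2.0
        t[(1, 1, 1)] = 9.0  # global peak inside the 5-cluster
        for v in small:
            t[v] = 4.0
            beta[v] = 100.0
        return flm_from(grid6, beta, t, df=20)

    def test_peak_cluster_mean_and_extent(self, grid6):
        flm = self._two_cluster_flm(grid6)
        roi = full_roi(grid6)
        assert peak_cluster_mean(flm, roi).value == pytest.approx(2.0)
        out = peak_cluster_extent(flm, roi)
        assert out.value == 5 and float(out.value).is_integer()

    def test_none_suprathreshold_missing(self, grid6):
        flm = flm_from(grid6, np.ones(grid6.shape), -np.ones(grid6.shape), df=20)
        assert peak_cluster_mean(flm, full_roi(grid6)).missing
        assert peak_cluster_extent(flm, full_roi(grid6)).missing

    def test_all_supra_connected_roi_full_extent(self, grid6):
        data = np.zeros(grid6.shape, dtype=bool)
        data[1:5, 1:5, 1:3] = True
        roi = ROIMask(grid6, data)
        flm = flm_from(grid6, np.ones(grid6.shape), 10 * np.ones(grid6.shape), df=20)
        assert peak_cluster_extent(flm, roi).value == roi.n_voxels


class TestInvariantsAndComposition:
    def test_limit_chain_measures_6_7_5(self, grid6, rng):
        flm = make_random_flm(grid6, rng, with_series=False)
        roi = make_random_roi(grid6, rng)
        peak_beta = flm.beta.data[find_peak(flm, roi)]
        assert top_n_contiguous_mean(flm, roi, 1).value == pytest.approx(peak_beta)
        assert peak_sphere_mean(flm, roi, 0.0).value == pytest.approx(peak_beta)

    def test_b_uses_no_more_voxels_than_a(self, grid6, rng):
        for _ in range(10):
            flm = make_random_flm(grid6, rng, t_loc=1.0)
            roi = make_random_roi(grid6, rng)
            for spec_a in default_measure_specs():
                if spec_a.variant != "A" or spec_a.measure_id not in (1, 2, 3, 4, 7, 8):
                    continue
                spec_b = MeasureSpec(
                    spec_a.measure_id,
                    "B",
                    q=spec_a.q,
                    n=spec_a.n,
                    radius_mm=spec_a.radius_mm,
                    corr_r=spec_a.corr_r,
                )
                a = extract_measure(flm, roi, spec_a)
                b = extract_measure(flm, roi, spec_b)
                assert b.n_voxels_used <= a.n_voxels_used

    def test_sign_flip_mirrored_oracle(self, grid6, rng):
        """Measures 1-9 negate under a global sign flip of beta and t when the
        one-sided selection rules are applied to the flipped upper tail; the
        cluster extent (10) is invariant.  The mirrored run is checked with
        the independent brute-force oracle (tail=-1 on the flipped maps)."""
        for _ in range(5):
            flm = make_random_flm(grid6, rng, t_loc=1.0)
            roi = make_random_roi(grid6, rng, max_voxels=60)
            for spec in default_measure_specs():
                ours = extract_measure(flm, roi, spec)
                mirrored = oracle_measure(
                    spec.measure_id,
                    -flm.beta.data,
                    -flm.tmap.data,
                    roi.data,
                    flm.df,
                    grid6,
                    variant=spec.variant,
                    p=spec.p_thresh,
                    q=spec.q,
                    n=spec.n,
                    radius_mm=spec.radius_mm,
                    corr_r=spec.corr_r,
                    series=flm.series,
                    tail=-1,
                )
                if ours.missing:
                    assert mirrored is None
                elif spec.measure_id == 10:
                    assert mirrored == pytest.approx(ours.value)
                else:
                    assert mirrored == pytest.approx(-ours.value)

    def test_extract_all_composition(self, grid6, rng):
        specs = default_measure_specs()
        flms = [make_random_flm(grid6, rng, t_loc=1.0) for _ in range(5)]
        roi = make_random_roi(grid6, rng, max_voxels=80)
        table = extract_all(flms, roi, specs)
        for i, flm in enumerate(flms):
            for spec in specs:
                sv = extract_measure(flm, roi, spec)
                cell = table.loc[i, spec.name]
                if sv.missing:
                    assert np.isnan(cell)
                else:
                    assert cell == pytest.approx(sv.value)

    def test_extract_all_empty_specs(self, grid6, rng):
        flms = [make_random_flm(grid6, rng) for _ in range(3)]
        roi = make_random_roi(grid6, rng)
        table = extract_all(flms, roi, [])
        assert list(table.columns) == ["subject_id"] and len(table) == 3

    def test_extract_all_grid_mismatch(self, grid6, rng):
        other = VolumeGrid((6, 6, 6), voxel_size=(2, 2, 2))
        flm = make_random_flm(other, rng)
        roi = make_random_roi(grid6, rng)
        with pytest.raises(GridMismatchError):
            extract_all([flm], roi, default_measure_specs())

    def test_extract_all_meta_alignment(self, grid6, rng):
        flms = [make_random_flm(grid6, rng) for _ in range(2)]
        roi = make_random_roi(grid6, rng)
        meta = pd.DataFrame({"subject_id": ["a"]})
        with pytest.raises(ValueError):
            extract_all(flms, roi, [], meta=meta)
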