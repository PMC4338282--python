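"""Measurement pipeline: shapes, tracks, integrity, sorting, equilibrium."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from segcpm import SimState, TissueSpec, build_gradient_tissue, build_segmented_tissue
from segcpm import metrics
from segcpm.errors import ContractViolation, UndefinedMeasureError
from segcpm.params import GREEN, RED


def solid_rect(height, width, h, w):
    """One rectangular pseudo-cell of h x w sites centred in the field."""
    st = SimState(height, width, 1)
    y0, x0 = (height - h) // 2, (width - w) // 2
    st.sites[y0:y0 + h, x0:x0 + w] = 1
    st.resync()
    st.ctype[1] = RED
    return st


class TestTissueAxes:
    def test_axis_aligned_rectangle(self):
        st = solid_rect(80, 80, 50, 60)
        ax = metrics.tissue_axes(st)
        assert ax.long_axis == pytest.approx(60)
        assert ax.short_axis == pytest.approx(50)
        # long axis along x: reported angle vs the y-axis is pi/2
        assert abs(ax.angle) == pytest.approx(math.pi / 2)

    def test_disc_is_isotropic(self):
        st = SimState(80, 80, 1)
        ys, xs = np.mgrid[0:80, 0:80]
        st.sites[(ys - 40) ** 2 + (xs - 40) ** 2 <= 30 ** 2] = 1
        st.sites[0, :] = -1; st.sites[-1, :] = -1
        st.sites[:, 0] = -1; st.sites[:, -1] = -1
        st.resync()
        ax = metrics.tissue_axes(st)
        assert ax.long_axis / ax.short_axis == pytest.approx(1.0, abs=0.05)

    def test_initial_four_segment_footprint_ratio(self):
        spec = TissueSpec(n_segments=4, segment_rows=3, segment_cols=10)
        st = build_segmented_tissue(spec, field=(100, 80))
        ax = metrics.tissue_axes(st)
        assert ax.long_axis / ax.short_axis == pytest.approx(60 / 50)

    def test_empty_tissue_rejected(self):
        with pytest.raises(UndefinedMeasureError):
            metrics.tissue_axes(SimState(10, 10, 0))


def synthetic_tracks(points, times):
    """tracks frame from {sigma: [(x, y) per time]}"""
    rows = [(t, sig, xy[0], xy[1])
            for sig, tr in points.items() for t, xy in zip(times, tr)]
    return pd.DataFrame(rows, columns=["mcs", "sigma", "x", "y"])


class TestDisplacementVectors:
    def test_known_drift(self):
        # 0.01 sites/MCS drift in x over 1e5 MCS -> vector (1000, 0)
        times = list(range(0, 100_001, 1000))
        tracks = synthetic_tracks(
            {1: [(5 + 0.01 * t, 7.0) for t in times]}, times)
        v = metrics.displacement_vectors(tracks, t_start=5000, t_end=100_000)
        assert v.loc[1, "dx"] == pytest.approx(950.0)  # from MCS 5000
        assert v.loc[1, "dy"] == pytest.approx(0.0)

    def test_translation_invariance(self):
        times = [5000, 10000]
        rng = np.random.default_rng(0)
        pts = {s: [tuple(rng.uniform(0, 50, 2)) for _ in times]
               for s in range(1, 6)}
        tracks = synthetic_tracks(pts, times)
        shifted = tracks.copy()
        shifted.x += 5
        shifted.y -= 3
        v0 = metrics.displacement_vectors(tracks, 5000, 10000)
        v1 = metrics.displacement_vectors(shifted, 5000, 10000)
        assert np.allclose(v0[["dx", "dy"]], v1[["dx", "dy"]])

    def test_retired_cells_excluded_and_counted(self):
        tracks = synthetic_tracks({1: [(0, 0), (1, 1)]}, [5000, 9000])
        tracks = pd.concat([tracks, synthetic_tracks(
            {2: [(3, 3)]}, [5000])])  # cell 2 retired before the end
        v = metrics.displacement_vectors(tracks, 5000, 9000)
        assert list(v.index) == [1]
        assert v.attrs["excluded"] == 1

    def test_missing_sample_rejected(self):
        tracks = synthetic_tracks({1: [(0, 0), (1, 1)]}, [0, 1000])
        with pytest.raises(ContractViolation):
            metrics.displacement_vectors(tracks, t_start=500, t_end=1000)


def shapes_frame(times, angles, cx=0.0, cy=0.0):
    return pd.DataFrame({"mcs": times, "long_axis": 10.0, "short_axis": 5.0,
                         "angle": angles, "cx": cx, "cy": cy})


class TestRotationCorrect:
    def test_zero_rotation_is_identity(self):
        times = [5000, 10000]
        tracks = synthetic_tracks({1: [(1, 2), (4, 6)]}, times)
        v = metrics.displacement_vectors(tracks, *times)
        out = metrics.rotation_correct(v, shapes_frame(times, [0.3, 0.3]))
        assert np.allclose(out[["dx", "dy"]], v[["dx", "dy"]])

    def test_rigid_rotation_cancels(self):
        theta = 0.4
        c = np.array([10.0, 10.0])
        rng = np.random.default_rng(1)
        pts0 = rng.uniform(0, 20, (6, 2))
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        pts1 = (pts0 - c) @ rot.T + c
        times = [5000, 10000]
        tracks = synthetic_tracks(
            {i + 1: [tuple(pts0[i]), tuple(pts1[i])] for i in range(6)},
            times)
        v = metrics.displacement_vectors(tracks, *times)
        shapes = shapes_frame(times, [0.0, theta], cx=c[0], cy=c[1])
        out = metrics.rotation_correct(v, shapes)
        assert np.allclose(out[["dx", "dy"]], 0.0, atol=1e-9)

    def test_angle_unwrap_across_pi(self):
        # principal angle wraps with period pi; a drift through the branch
        # cut must unwrap to a continuous small net rotation
        angles = [1.4, 1.5, -1.5, -1.4]  # pi-periodic: net +0.34, not -2.8
        theta = metrics.unwrap_principal_angle(np.array(angles))
        # steps: +0.1, -3.0 -> +0.1416 (mod pi), +0.1
        assert theta[-1] - theta[0] == pytest.approx(0.2 + math.pi - 3.0)
        times = [0, 1000, 2000, 3000]
        tracks = synthetic_tracks({1: [(0, 0)] * 4, 2: [(3, 1)] * 4}, times)
        v = metrics.displacement_vectors(tracks, 0, 3000)
        out = metrics.rotation_correct(v, shapes_frame(times, angles))
        assert abs(out.attrs["net_rotation"]) < 0.5


class TestNeighbourAngleCoherence:
    def test_parallel_field_scores_zero(self):
        v = pd.DataFrame({"x0": np.arange(5.0), "y0": 0.0,
                          "dx": 1.0, "dy": 1.0})
        out = metrics.neighbour_angle_coherence(v, radius=30)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_antiparallel_pair_scores_pi(self):
        v = pd.DataFrame({"x0": [0.0, 5.0], "y0": [0.0, 0.0],
                          "dx": [1.0, -1.0], "dy": [0.0, 0.0]})
        out = metrics.neighbour_angle_coherence(v, radius=30)
        assert np.allclose(out, math.pi)

    def test_isotropic_field_scores_half_pi(self):
        rng = np.random.default_rng(2)
        n = 400
        ang = rng.uniform(0, 2 * math.pi, n)
        v = pd.DataFrame({"x0": rng.uniform(0, 10, n),
                          "y0": rng.uniform(0, 10, n),
                          "dx": np.cos(ang), "dy": np.sin(ang)})
        out = metrics.neighbour_angle_coherence(v, radius=30)
        assert np.nanmean(out) == pytest.approx(math.pi / 2, rel=0.05)

    def test_isolated_vector_flagged_nan(self):
        v = pd.DataFrame({"x0": [0.0, 500.0, 501.0], "y0": 0.0,
                          "dx": 1.0, "dy": 0.0})
        out = metrics.neighbour_angle_coherence(v, radius=30)
        assert math.isnan(out[0]) and not math.isnan(out[1])


class TestMeanCellSpeed:
    def test_frozen_tissue_speed_zero(self):
        times = list(range(5000, 20001, 1000))
        tracks = synthetic_tracks({1: [(4.0, 4.0)] * len(times)}, times)
        assert metrics.mean_cell_speed(tracks) == 0.0

    def test_one_site_per_interval(self):
        times = list(range(0, 10001, 1000))
        tracks = synthetic_tracks(
            {1: [(float(i), 0.0) for i in range(len(times))]}, times)
        assert metrics.mean_cell_speed(tracks, t_start=0) \
            == pytest.approx(0.001)

    def test_averages_over_cells(self):
        times = [5000, 6000, 7000]
        tracks = synthetic_tracks({1: [(0, 0), (1, 0), (2, 0)],
                                   2: [(0, 0), (3, 0), (6, 0)]}, times)
        assert metrics.mean_cell_speed(tracks) == pytest.approx(0.002)


class TestSegmentIntegrity:
    def test_initial_tissue_has_no_strays(self):
        spec = TissueSpec(n_segments=4, segment_rows=3, segment_cols=10)
        st = build_segmented_tissue(spec, field=(100, 80))
        mixing, strays = metrics.segment_integrity(st)
        assert strays == 0
        assert mixing == 0.0

    def test_relabelled_island_is_a_stray(self):
        spec = TissueSpec(n_segments=2, segment_rows=2, segment_cols=3)
        st = build_segmented_tissue(spec, field=(60, 40))
        # move cell 1 (segment 0) into the far corner of segment 1's space:
        # it keeps its label but loses all same-segment contact
        ys, xs = np.nonzero(st.sites == 1)
        st.sites[ys, xs] = 0
        st.sites[2:7, 2:7] = 0
        st.sites[ys.max() + 3:ys.max() + 8, xs] = 0
        # place cell 1 isolated below the tissue, touching only medium
        st.sites[50:55, 10:15] = 1
        st.resync()
        _, strays = metrics.segment_integrity(st)
        assert strays == 1

    def test_stray_count_matches_bruteforce_on_shuffled_labels(self):
        rng = np.random.default_rng(0)
        spec = TissueSpec(n_segments=4, segment_rows=2, segment_cols=4)
        st = build_segmented_tissue(spec, field=(80, 50))
        st.segment[1:] = rng.permutation(st.segment[1:])
        _, strays = metrics.segment_integrity(st)
        # oracle: scan every cell's Moore neighbourhood site by site
        stray_oracle = 0
        for sigma in range(1, st.n_slots):
            found = False
            ys, xs = np.nonzero(st.sites == sigma)
            for y, x in zip(ys, xs):
                neigh = st.sites[y - 1:y + 2, x - 1:x + 2]
                for other in np.unique(neigh):
                    if other > 0 and other != sigma and \
                            st.segment[other] == st.segment[sigma]:
                        found = True
            stray_oracle += 0 if found else 1
        assert strays == stray_oracle

    def test_non_segmented_tissue_rejected(self):
        spec = TissueSpec(n_segments=1, segment_rows=4, segment_cols=3,
                          pattern="gradient_sorted")
        st = build_gradient_tissue(spec, (60, 40))
        with pytest.raises(UndefinedMeasureError):
            metrics.segment_integrity(st)


class TestSegmentMerging:
    def test_initial_tissue_not_merged(self):
        spec = TissueSpec(n_segments=4, segment_rows=3, segment_cols=10)
        st = build_segmented_tissue(spec, field=(100, 80))
        merged, pairs = metrics.detect_segment_merging(st)
        assert not merged and pairs == []

    def test_bridged_same_type_segments_reported(self):
        # segments 0 and 2 are both red; relabel one green cell between
        # them to segment 0's type so a same-type path connects them
        spec = TissueSpec(n_segments=3, segment_rows=1, segment_cols=3)
        st = build_segmented_tissue(spec, field=(60, 40))
        bridge = 4  # a segment-1 (green) cell in the middle row
        st.ctype[bridge] = RED
        st.segment[bridge] = 0
        merged, pairs = metrics.detect_segment_merging(st)
        assert merged and (0, 2) in pairs

    def test_single_segment_never_merges(self):
        spec = TissueSpec(n_segments=1, segment_rows=2, segment_cols=3)
        st = build_segmented_tissue(spec, field=(50, 40))
        merged, pairs = metrics.detect_segment_merging(st)
        assert not merged


class TestEquilibriumContactLength:
    def test_zero_intersegment_tension_gives_square(self):
        n, A = 4, 3000.0
        L = metrics.equilibrium_contact_length(n, A, 0.0, 6.0)
        assert L == pytest.approx(math.sqrt(n * A))

    def test_matches_numerical_minimisation(self):
        for (n, A, grg, gcm) in [(4, 3000, 10, 6), (8, 1920, 4, 2),
                                 (2, 500, 1, 5), (4, 6000, 12, 8)]:
            energy = lambda L: (n - 1) * grg * L + gcm * (2 * L + 2 * n * A / L)
            opt = minimize_scalar(energy, bounds=(1e-3, 1e4),
                                  method="bounded")
            L = metrics.equilibrium_contact_length(n, A, grg, gcm)
            assert L == pytest.approx(opt.x, rel=1e-5)

    def test_scale_invariance_of_tensions(self):
        a = metrics.equilibrium_contact_length(4, 3000, 10, 6)
        b = metrics.equilibrium_contact_length(4, 3000, 20, 12)
        assert a == pytest.approx(b)

    def test_large_tension_asymptote(self):
        n, A, gcm = 4, 3000.0, 6.0
        grg = 1e7
        L = metrics.equilibrium_contact_length(n, A, grg, gcm)
        assert L == pytest.approx(
            math.sqrt(2 * n * A * gcm / grg) / math.sqrt(n - 1), rel=1e-3)

    def test_degenerate_tensions_rejected(self):
        with pytest.raises(UndefinedMeasureError):
            metrics.equilibrium_contact_length(4, 3000, 0.0, 0.0)


class TestSortingIndex:
    def test_sorted_tissue_scores_one(self):
        spec = TissueSpec(n_segments=1, segment_rows=10, segment_cols=4,
                          cell_target_area=200, pattern="gradient_sorted")
        st = build_gradient_tissue(spec, (120, 60))
        assert metrics.sorting_index(st) == pytest.approx(1.0, abs=0.02)

    def test_random_assignment_scores_low(self):
        spec = TissueSpec(n_segments=1, segment_rows=10, segment_cols=10,
                          cell_target_area=200, pattern="gradient_random")
        vals = []
        for seed in range(5):
            st = build_gradient_tissue(spec, (150, 150), rng=seed)
            vals.append(metrics.sorting_index(st))
        assert np.mean(vals) < 0.25

    def test_matches_bruteforce_rank_correlation(self):
        spec = TissueSpec(n_segments=1, segment_rows=6, segment_cols=3,
                          cell_target_area=200, pattern="gradient_sorted")
        st = build_gradient_tissue(spec, (80, 50))
        # swap the concentrations of two whole rows
        r0 = slice(1, 4)          # row 0 sigmas
        r3 = slice(10, 13)        # row 3 sigmas
        b = st.conc_b.copy()
        st.conc_b[r0], st.conc_b[r3] = b[r3], b[r0]
        # oracle: spearman of B against y-centroid (long axis is vertical)
        alive = st.alive()
        rho, _ = stats.spearmanr(st.conc_b[alive],
                                 st.centroids()[alive][:, 1])
        assert metrics.sorting_index(st) == pytest.approx(abs(rho), abs=1e-9)
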