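"""Migration statistics tests: hand-computed examples, directional
invariants, and the rank test against scipy and exact permutation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oxgradchip.errors import ValidationError
from oxgradchip.track_stats import (
    AngularHistogram,
    GradientFrame,
    Track,
    TrackSet,
    aggregate_conditions,
    com_displacement,
    fmi,
    kruskal_wallis,
    kruskal_wallis_permutation,
    local_response,
    mean_velocity,
    offset_to_origin,
    pairwise_kruskal,
    summarize_tracks,
    weighted_angular_histogram,
)

GX = GradientFrame.from_axis("x", 1)


def track(points, dt=10.0, **kwargs):
    pts = np.asarray(points, dtype=float)
    return Track(
        track_id=kwargs.pop("track_id", "t0"),
        t_min=np.arange(len(pts)) * dt,
        x_um=pts[:, 0],
        y_um=pts[:, 1],
        **kwargs,
    )


#: the worked toy track: (0,0) -> (3,4) -> (6,0), 10-min frames
TOY = track([(0, 0), (3, 4), (6, 0)])


class TestTrackValidation:
    def test_single_frame_rejected(self):
        with pytest.raises(ValidationError):
            Track("a", [0.0], [0.0], [0.0])

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            Track("a", [0.0, 10.0, 10.0], [0, 1, 2], [0, 0, 0])

    def test_non_finite_coordinate_rejected(self):
        with pytest.raises(ValidationError):
            Track("a", [0.0, 10.0], [0.0, np.nan], [0.0, 0.0])


class TestOffsetToOrigin:
    def test_shifts_start_to_origin_preserving_steps(self):
        tr = track([(5, 5), (8, 9), (11, 5)])
        off = offset_to_origin(tr)
        assert off.positions[0] == pytest.approx([0.0, 0.0])
        assert np.allclose(off.steps, tr.steps)
        assert off.path_length == pytest.approx(tr.path_length)

    def test_identity_when_already_at_origin(self):
        off = offset_to_origin(TOY)
        assert np.allclose(off.positions, TOY.positions)


class TestFMI:
    def test_toy_track_hand_values(self):
        """Path 5+5=10 um, net (6,0): FMI = (0.6, 0.0)."""
        assert fmi(TOY, GX) == pytest.approx((0.6, 0.0))

    def test_straight_run_along_gradient_is_maximally_directed(self):
        tr = track([(0, 0), (5, 0), (10, 0)])
        assert fmi(tr, GX) == pytest.approx((1.0, 0.0))

    def test_closed_loop_has_zero_fmi(self):
        tr = track([(0, 0), (4, 0), (4, 4), (0, 4), (0, 0)])
        assert fmi(tr, GX) == pytest.approx((0.0, 0.0))

    def test_zero_path_length_is_missing_with_warning(self):
        tr = track([(1, 1), (1, 1), (1, 1)])
        with pytest.warns(UserWarning, match="zero path length"):
            par, perp = fmi(tr, GX)
        assert math.isnan(par) and math.isnan(perp)

    def test_rotating_frame_90deg_swaps_components(self):
        frame_y = GradientFrame.from_axis("y", 1)  # 90 deg CCW from +x
        par_x, perp_x = fmi(TOY, GX)
        par_y, perp_y = fmi(TOY, frame_y)
        assert par_y == pytest.approx(perp_x)
        assert perp_y == pytest.approx(-par_x)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)
            ),
            min_size=2,
            max_size=12,
        ),
        st.floats(-1e4, 1e4),
        st.floats(-1e4, 1e4),
    )
    def test_bounded_and_translation_invariant(self, points, dx, dy):
        tr = track(points)
        if tr.path_length == 0:
            return
        par, perp = fmi(tr, GX)
        assert abs(par) <= 1 + 1e-9 and abs(perp) <= 1 + 1e-9
        shifted = track([(x + dx, y + dy) for x, y in points])
        assert fmi(shifted, GX) == pytest.approx((par, perp), abs=1e-9)
        # triangle inequality: path length bounds the net displacement
        assert tr.path_length >= np.linalg.norm(tr.net_displacement) - 1e-9


class TestVelocityAndCOM:
    def test_toy_track_velocity(self):
        """10 um over 20 min = 0.5 um/min."""
        assert mean_velocity(TOY) == pytest.approx(0.5)

    def test_stationary_cell_zero_velocity(self):
        assert mean_velocity(track([(2, 2), (2, 2)])) == 0.0

    def test_doubling_timestamps_halves_velocity(self):
        slow = track([(0, 0), (3, 4), (6, 0)], dt=20.0)
        assert mean_velocity(slow) == pytest.approx(mean_velocity(TOY) / 2)

    def test_zero_duration_impossible_by_construction(self):
        with pytest.raises(ValidationError):
            Track("a", [0.0, 0.0], [0, 1], [0, 0])

    def test_com_single_track(self):
        assert com_displacement([TOY]) == pytest.approx([6.0, 0.0])

    def test_com_opposite_tracks_cancel(self):
        a = track([(0, 0), (6, 0)])
        b = track([(0, 0), (-6, 0)])
        assert com_displacement([a, b]) == pytest.approx([0.0, 0.0])

    def test_com_mean_of_nets(self):
        ts = [track([(0, 0), (d, 0)], track_id=i) for i, d in enumerate([1, 2, 3])]
        assert com_displacement(ts) == pytest.approx([2.0, 0.0])

    def test_com_translation_invariant_per_cell(self):
        a = track([(100, 50), (106, 50)])
        b = track([(-20, 7), (-26, 7)])
        assert com_displacement([a, b]) == pytest.approx([0.0, 0.0])

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            com_displacement([])


class TestAngularHistogram:
    def test_all_cells_same_bin_equal_distances(self):
        ts = [
            track([(0, 0), (np.cos(np.radians(10)), np.sin(np.radians(10)))],
                  track_id=i)
            for i in range(5)
        ]
        hist = weighted_angular_histogram(ts, n_bins=8)
        assert hist.weights[0] == pytest.approx(5.0)
        assert hist.weights[1:] == pytest.approx(np.zeros(7))

    def test_distance_weighting_hand_example(self):
        """d=1 at 10 deg and d=3 at 100 deg: weights 0.5 and 1.5 (mean d = 2)."""
        a = track([(0, 0), (np.cos(np.radians(10)), np.sin(np.radians(10)))])
        b = track(
            [(0, 0), (3 * np.cos(np.radians(100)), 3 * np.sin(np.radians(100)))],
            track_id="t1",
        )
        hist = weighted_angular_histogram([a, b], n_bins=8)
        assert hist.weights[0] == pytest.approx(0.5)
        assert hist.weights[2] == pytest.approx(1.5)
        assert hist.weights.sum() == pytest.approx(2.0)

    def test_weights_sum_to_contributing_cells(self):
        rng = np.random.default_rng(3)
        ts = [
            track(np.cumsum(rng.normal(0, 5, (6, 2)), axis=0), track_id=i)
            for i in range(20)
        ]
        ts.append(track([(1, 1), (2, 2), (1, 1)], track_id="loop"))  # d = 0
        hist = weighted_angular_histogram(ts, n_bins=8)
        assert hist.weights.sum() == pytest.approx(hist.n_contributing)
        assert hist.n_contributing == 20

    def test_all_immobile_warns_empty(self):
        ts = [track([(0, 0), (1, 1), (0, 0)], track_id=i) for i in range(3)]
        with pytest.warns(UserWarning, match="immobile"):
            hist = weighted_angular_histogram(ts)
        assert hist.weights.sum() == 0.0


class TestLocalResponse:
    def test_uniform_field_reports_uniform_oxygen(self):
        ts = [track([(i, 0), (i + 3, 4)], track_id=i) for i in range(4)]
        table = local_response(ts, lambda x, y: 5.0)
        assert (table["o2_percent"] == 5.0).all()
        assert len(table) == 4

    def test_linear_profile_interpolated_at_start(self):
        """0-21% over 10 mm: a cell starting mid-chamber reads 10.5%."""
        positions = np.array([0.0, 10000.0])  # um
        o2 = np.array([0.0, 21.0])
        ts = [track([(5000.0, 0), (5003.0, 4)])]
        table = local_response(ts, (positions, o2))
        assert table["o2_percent"].iloc[0] == pytest.approx(10.5)

    def test_outside_support_flagged_missing(self):
        ts = [track([(-5.0, 0), (0, 4)])]
        table = local_response(ts, (np.array([0.0, 100.0]), np.array([0.0, 21.0])))
        assert not table["valid"].iloc[0]
        assert math.isnan(table["o2_percent"].iloc[0])


class TestKruskalWallis:
    def test_hand_computed_h(self):
        """Groups {1,2,3},{4,5,6},{7,8,9}: rank sums 6/15/24 give H = 7.2."""
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.h == pytest.approx(7.2)
        assert res.df == 2

    def test_identical_groups_give_zero_h(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.h == pytest.approx(0.0)

    def test_all_observations_identical_guarded(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5]])
        assert res.h == 0.0 and res.p == 1.0

    def test_matches_scipy_with_ties(self):
        groups = [[1.0, 2.0, 2.0, 3.0], [2.0, 4.0, 4.0], [1.0, 5.0, 6.0, 6.0]]
        res = kruskal_wallis(groups)
        ref = stats.kruskal(*groups)
        assert res.h == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    @pytest.mark.parametrize(
        "groups",
        [
            [[1.2, 3.4, 2.2], [5.1, 4.4], [0.3, 6.0]],
            [[1, 2, 5], [3, 7, 8], [4, 6]],
            [[10, 2], [3, 7, 8], [4, 6, 9]],
        ],
    )
    def test_agrees_with_exact_permutation_on_tiny_sample(self, groups):
        """Chi-square p vs enumerated permutation null (mid-p) at N <= 8,
        to within the granularity of the discrete permutation distribution."""
        res = kruskal_wallis(groups)
        p_mid = kruskal_wallis_permutation(groups, mid_p=True)
        assert res.p == pytest.approx(p_mid, abs=0.06)

    def test_null_rejection_rate_calibrated(self):
        """Chi-square approximation holds its 5% level: 10,000 null
        datasets of 3 groups x 15 continuous observations."""
        rng = np.random.default_rng(19)
        data = rng.normal(size=(10_000, 45))
        rejections = 0
        for row in data:
            res = kruskal_wallis([row[:15], row[15:30], row[30:]])
            rejections += res.p < 0.05
        assert 0.04 <= rejections / 10_000 <= 0.06

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2, 3]])

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2], []])

    def test_pairwise_against_reference(self):
        samples = {
            "ref": [1.0, 2.0, 3.0, 4.0],
            "a": [5.0, 6.0, 7.0, 8.0],
            "b": [1.5, 2.5, 3.5, 4.5],
        }
        table = pairwise_kruskal(samples, "ref")
        assert set(table["condition"]) == {"a", "b"}
        assert (table["df"] == 1).all()


class TestSummariesAndAggregation:
    def _summaries(self):
        rng = np.random.default_rng(8)
        out = {}
        for cond in ("a", "b"):
            ts = TrackSet(
                [
                    track(np.cumsum(rng.normal(0, 5, (6, 2)), axis=0), track_id=i)
                    for i in range(10)
                ]
            )
            out[cond] = summarize_tracks(ts, GX)
        return out

    def test_per_cell_summary_columns_and_bounds(self):
        df = self._summaries()["a"]
        assert len(df) == 10
        assert (df["fmi_parallel"].abs() <= 1).all()
        assert (df["path_length_um"] >= df["net_displacement_um"] - 1e-9).all()

    def test_aggregate_one_row_per_condition(self):
        agg = aggregate_conditions(self._summaries())
        assert list(agg["condition"]) == ["a", "b"]
        assert (agg["n"] == 10).all()

    def test_per_experiment_aggregation_averages_replicates_first(self):
        df = pd.DataFrame(
            {
                "experiment": [1, 1, 2, 2],
                "fmi_parallel": [0.0, 1.0, 0.5, 0.5],
                "fmi_perpendicular": [0.0] * 4,
                "mean_velocity_um_min": [1.0] * 4,
            }
        )
        agg = aggregate_conditions(
            {"c": df}, mode="per_experiment"
        )
        assert agg["fmi_parallel_mean"].iloc[0] == pytest.approx(0.5)
        assert agg["n"].iloc[0] == 2
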