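"""Distance computation, PCoA fidelity and binned disparity curves."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from disparitree.disparity import (
    BinSeries,
    DistanceMatrix,
    disparity_curve,
    make_bins,
    pairwise_distances,
    pcoa,
    rarefied_disparity_curve,
    sum_of_variances,
)
from disparitree.io_formats import MISSING, CharacterMatrix, LineageDuration


def _dm_from_points(points: np.ndarray) -> DistanceMatrix:
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    n = len(points)
    return DistanceMatrix([f"p{i}" for i in range(n)], d, np.full((n, n), 1), [])


def _flat_durations(ids, start=10.0, end=0.0):
    return [LineageDuration(i, start, end, "observed_tip") for i in ids]


class TestPairwiseDistances:
    def test_identical_rows_have_zero_distance(self):
        m = CharacterMatrix(["A", "B"], ["c1", "c2"], [[0, 1], [0, 1]], [False, False])
        assert pairwise_distances(m).values[0, 1] == 0

    def test_unordered_mismatch_count(self):
        m = CharacterMatrix(
            ["A", "B"], list("wxyz"), [[0, 0, 0, 0], [1, 1, 0, 0]], [False] * 4
        )
        assert pairwise_distances(m).values[0, 1] == pytest.approx(np.sqrt(2))

    def test_missing_data_rescaling(self):
        m = CharacterMatrix(
            ["A", "B"], list("wxyz"), [[0, 0, 0, MISSING], [1, 0, 0, 0]], [False] * 4
        )
        assert pairwise_distances(m).values[0, 1] == pytest.approx(np.sqrt(4 / 3))
        assert pairwise_distances(m, rescale=False).values[0, 1] == pytest.approx(1.0)

    def test_ordered_characters_use_linear_steps(self):
        m = CharacterMatrix(["A", "B"], ["c1"], [[0], [3]], [True])
        assert pairwise_distances(m).values[0, 1] == pytest.approx(3.0)

    def test_polymorphism_takes_minimum_cross_difference(self):
        m = CharacterMatrix(
            ["A", "B", "C"], ["c1"],
            [[frozenset({0, 3})], [1], [frozenset({3, 4})]], [True],
        )
        d = pairwise_distances(m).values
        assert d[0, 1] == pytest.approx(1.0)  # |0-1|
        assert d[0, 2] == pytest.approx(0.0)  # shared state 3
        m2 = CharacterMatrix(
            ["A", "B"], ["c1"], [[frozenset({0, 2})], [frozenset({0, 1})]], [False]
        )
        assert pairwise_distances(m2).values[0, 1] == 0.0

    def test_complete_data_equals_plain_euclidean(self, rng):
        states = rng.integers(0, 3, size=(5, 8))
        m = CharacterMatrix(
            [f"t{i}" for i in range(5)], [f"c{j}" for j in range(8)],
            states.tolist(), [True] * 8,
        )
        expected = np.sqrt(((states[:, None, :] - states[None, :, :]) ** 2).sum(-1))
        assert np.allclose(pairwise_distances(m).values, expected)

    def test_incomparable_pair_errors_when_frequent(self):
        m = CharacterMatrix(
            ["A", "B"], ["c1", "c2"], [[0, MISSING], [MISSING, 1]], [False, False]
        )
        with pytest.raises(ValueError):
            pairwise_distances(m)


class TestPcoa:
    def test_collinear_points_give_one_axis(self):
        D = np.array([[0, 3, 5], [3, 0, 2], [5, 2, 0]], dtype=float)
        dm = DistanceMatrix(["a", "b", "c"], D, np.full((3, 3), 1), [])
        ordn = pcoa(dm)
        assert ordn.n_axes == 1
        recon = np.abs(ordn.coords[:, 0][:, None] - ordn.coords[:, 0][None, :])
        assert np.abs(recon - D).max() < 1e-9

    def test_random_plane_points_reconstruct_distances(self, rng):
        pts = rng.normal(size=(4, 2))
        ordn = pcoa(_dm_from_points(pts))
        assert ordn.n_axes == 2
        recon = np.sqrt(
            ((ordn.coords[:, None, :] - ordn.coords[None, :, :]) ** 2).sum(-1)
        )
        assert np.abs(recon - _dm_from_points(pts).values).max() < 1e-9

    def test_zero_distances_degenerate(self):
        dm = DistanceMatrix(["a", "b"], np.zeros((2, 2)), np.full((2, 2), 1), [])
        with pytest.raises(ValueError, match="degenerate"):
            pcoa(dm)

    def test_axis_scores_are_centred_with_eigenvalue_scale(self, rng):
        pts = rng.normal(size=(7, 3))
        ordn = pcoa(_dm_from_points(pts))
        assert np.abs(ordn.coords.mean(axis=0)).max() < 1e-9
        lam = ordn.eigenvalues[: ordn.n_axes]
        assert np.allclose((ordn.coords**2).sum(axis=0), lam)

    def test_sum_of_variances_parseval(self, rng):
        pts = rng.normal(size=(9, 4))
        ordn = pcoa(_dm_from_points(pts))
        lam_pos = ordn.eigenvalues[ordn.eigenvalues > 0]
        assert sum_of_variances(ordn.coords) == pytest.approx(
            lam_pos.sum() / (len(pts) - 1), abs=1e-9
        )

    def test_sum_of_variances_rotation_invariant(self, rng):
        pts = rng.normal(size=(6, 3))
        theta = 0.7
        R = np.eye(3)
        R[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        assert sum_of_variances(pts) == pytest.approx(sum_of_variances(pts @ R))

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(8, 3))
        dm = _dm_from_points(pts)
        ours = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, ids=dm.ids), method="eigh"
        )
        lam_ref = np.asarray(ref.eigvals)
        assert np.allclose(ours.eigenvalues[:3], lam_ref[:3], atol=1e-9)
        for m in range(3):
            ref_axis = np.asarray(ref.samples.iloc[:, m])
            assert np.allclose(np.abs(ours.coords[:, m]), np.abs(ref_axis), atol=1e-8)


class TestDisparityCurve:
    def test_single_bin_hand_example(self):
        # members' scores {0, 2} on one axis -> variance 2
        coords = np.array([[0.0], [2.0]])
        ordn_like = pcoa(_dm_from_points(coords))
        durations = _flat_durations(ordn_like.ids)
        series = disparity_curve(
            ordn_like, durations, [(10.0, 0.0)], k_axes=1, n_boot=50, seed=1
        )
        assert series.values[0] == pytest.approx(2.0)
        assert series.counts[0] == 2

    def test_identical_members_give_zero_with_degenerate_band(self):
        m = CharacterMatrix(
            ["A", "B", "C"], ["c1", "c2"], [[0, 1], [0, 1], [1, 0]], [False] * 2
        )
        ordn = pcoa(pairwise_distances(m))
        durations = _flat_durations(["A", "B"]) + [LineageDuration("C", 30, 20, "observed_tip")]
        series = disparity_curve(ordn, durations, [(10.0, 0.0)], n_boot=100, seed=2)
        assert series.values[0] == pytest.approx(0.0)
        assert series.lower[0] == pytest.approx(0.0, abs=1e-15)
        assert series.upper[0] == pytest.approx(0.0, abs=1e-15)

    def test_bins_with_one_member_are_undefined(self):
        coords = np.array([[0.0], [2.0]])
        ordn = pcoa(_dm_from_points(coords))
        durations = [
            LineageDuration("p0", 10, 6, "observed_tip"),
            LineageDuration("p1", 4, 0, "observed_tip"),
        ]
        series = disparity_curve(ordn, durations, make_bins(10, 0, 5), n_boot=20, seed=3)
        assert not series.defined.any()
        assert list(series.counts) == [1, 1]

    def test_band_brackets_value_and_narrows_with_n(self, rng):
        # homogeneous synthetic scores: CI width shrinks as membership grows
        widths = []
        for n in (10, 100, 1000):
            pts = rng.normal(size=(n, 2))
            ordn = pcoa(_dm_from_points(pts))
            series = disparity_curve(
                ordn, _flat_durations(ordn.ids), [(10.0, 0.0)], k_axes=2,
                n_boot=200, seed=4,
            )
            assert series.lower[0] <= series.values[0] <= series.upper[0]
            widths.append(series.upper[0] - series.lower[0])
        assert widths[0] > widths[1] > widths[2]

    def test_duplicate_row_never_increases_disparity(self, rng):
        pts = rng.normal(size=(6, 2))
        pts_dup = np.vstack([pts, pts[0]])
        v = sum_of_variances(pts)
        v_dup = sum_of_variances(pts_dup)
        assert v_dup <= v + 1e-12


class TestRarefiedCurve:
    def test_bin_with_exactly_n_sub_members_equals_full_value(self, rng):
        pts = rng.normal(size=(8, 2))
        ordn = pcoa(_dm_from_points(pts))
        durations = _flat_durations(ordn.ids)
        full = disparity_curve(
            ordn, durations, [(10.0, 0.0)], k_axes=2, n_boot=10, seed=5
        )
        rare = rarefied_disparity_curve(
            ordn, durations, [(10.0, 0.0)], n_sub=8, n_boot=10, k_axes=2, seed=5
        )
        assert rare.values[0] == pytest.approx(full.values[0])

    def test_underfilled_bin_is_flagged_undefined(self, rng):
        pts = rng.normal(size=(5, 2))
        ordn = pcoa(_dm_from_points(pts))
        rare = rarefied_disparity_curve(
            ordn, _flat_durations(ordn.ids), [(10.0, 0.0)], n_sub=8, n_boot=10, seed=6
        )
        assert not rare.defined[0]
        assert rare.counts[0] == 5


class TestBinSeries:
    def test_tsv_roundtrip_fields(self):
        series = BinSeries(
            [(2.0, 1.0), (1.0, 0.0)],
            np.array([1.5, np.nan]),
            np.array([1.0, np.nan]),
            np.array([2.0, np.nan]),
            np.array([3, 0]),
            "disparity",
        )
        text = series.to_tsv()
        lines = text.strip().split("\n")
        assert lines[0].split("\t") == ["bin_older", "bin_younger", "n", "value", "lo", "hi"]
        assert lines[2].split("\t")[3] == "NA"
        assert series.to_dict()["value"][1] is None

    @given(st.floats(1.0, 50.0), st.integers(1, 7))
    def test_make_bins_covers_range_exactly(self, oldest, nsteps):
        step = oldest / nsteps
        bins = make_bins(oldest, 0.0, step)
        assert len(bins) == nsteps
        assert bins[0][0] == pytest.approx(oldest)
        assert bins[-1][1] == pytest.approx(0.0)
        for (o1, y1), (o2, y2) in zip(bins, bins[1:]):
            assert y1 == pytest.approx(o2)
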