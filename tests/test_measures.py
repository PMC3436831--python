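import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonytrack import measures as M
from colonytrack.image_io import ImageFrame
from conftest import disc_mask


class TestCoveredAreaFraction:
    @pytest.mark.parametrize(
        "mask, expected",
        [
            (np.zeros((10, 10), int), 0.0),
            (np.ones((10, 10), int), 1.0),
        ],
        ids=["empty", "full"],
    )
    def test_edge_cases(self, mask, expected):
        assert M.covered_area_fraction(mask) == expected

    def test_square_in_standard_frame(self):
        mask = np.zeros((480, 640), int)
        mask[100:200, 100:200] = 1
        assert M.covered_area_fraction(mask) == pytest.approx(10000 / 307200)

    def test_consistent_with_per_colony_areas(self):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 4, (50, 50))
        per_colony = sum(
            int((mask == k).sum()) for k in np.unique(mask) if k > 0
        )
        assert M.covered_area_fraction(mask) == per_colony / mask.size


class TestElongation:
    def test_disc_is_round(self):
        assert M.colony_elongation(disc_mask(40), 1) < 0.02

    def test_ellipse_axis_ratio(self):
        # semi-axes 40 and 10: continuous value 1 - 10/40 = 0.75
        n = 101
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        ell = (((rr - 50) / 10.0) ** 2 + ((cc - 50) / 40.0) ** 2 <= 1).astype(int)
        assert M.colony_elongation(ell, 1) == pytest.approx(0.75, abs=0.02)

    def test_line_segment_highly_elongated(self):
        line = np.zeros((5, 60), int)
        line[2, 5:55] = 1
        assert M.colony_elongation(line, 1) >= 0.95

    def test_rotation_by_90_invariant(self):
        n = 101
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        ell = (((rr - 50) / 12.0) ** 2 + ((cc - 50) / 30.0) ** 2 <= 1).astype(int)
        assert M.colony_elongation(ell, 1) == pytest.approx(
            M.colony_elongation(ell.T, 1), abs=1e-12
        )

    def test_arbitrary_rotation_stability(self):
        from scipy import ndimage

        n = 121
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        ell = (((rr - 60) / 12.0) ** 2 + ((cc - 60) / 36.0) ** 2 <= 1).astype(float)
        base = M.colony_elongation(ell.astype(int), 1)
        for deg in (17, 45, 63):
            rot = (ndimage.rotate(ell, deg, reshape=False, order=1) > 0.5).astype(int)
            assert M.colony_elongation(rot, 1) == pytest.approx(base, abs=0.03)

    def test_missing_label(self):
        with pytest.raises(KeyError):
            M.colony_elongation(disc_mask(5), 9)


class TestCircularity:
    def test_disc_near_one(self):
        assert 0.95 <= M.colony_circularity(disc_mask(50), 1) <= 1.05

    def test_rectangle_closed_form(self):
        rect = np.zeros((20, 260), int)
        rect[5:15, 5:255] = 1
        expected = 4 * math.pi * 2500 / 520**2
        assert M.colony_circularity(rect, 1) == pytest.approx(expected, abs=0.02)

    def test_plus_sign_less_circular_than_square(self):
        plus = np.zeros((40, 40), int)
        plus[15:25, 5:35] = 1
        plus[5:35, 15:25] = 1  # area 500
        area = plus.sum()
        side = int(round(math.sqrt(area)))
        square = np.zeros((40, 40), int)
        square[5 : 5 + side, 5 : 5 + side] = 1
        assert M.colony_circularity(plus, 1) < M.colony_circularity(square, 1)

    def test_star_perturbations_decrease_circularity(self):
        # fixed-area shapes with increasingly wiggly boundaries
        n = 161
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        th = np.arctan2(rr - 80, cc - 80)
        d = np.hypot(rr - 80, cc - 80)
        values = []
        for amp in (0, 4, 8, 12):
            r_of_th = 50 + amp * np.cos(8 * th)
            mask = (d <= r_of_th).astype(int)
            values.append(M.colony_circularity(mask, 1))
        assert all(a > b for a, b in zip(values, values[1:]))


class TestEntropy:
    def test_constant_colony_zero(self):
        frame = ImageFrame(pixels=np.full((10, 10), 0.4))
        assert M.colony_entropy(frame, np.ones((10, 10), int), 1) == 0.0

    def test_two_level_log2(self):
        pix = np.zeros((10, 10))
        pix[:5] = 100.5 / 256
        pix[5:] = 200.5 / 256
        h = M.colony_entropy(ImageFrame(pixels=pix), np.ones((10, 10), int), 1)
        assert h == pytest.approx(math.log(2), abs=1e-12)

    def test_uniform_256_levels(self):
        pix = (np.arange(256).reshape(16, 16) + 0.5) / 256
        h = M.colony_entropy(ImageFrame(pixels=pix), np.ones((16, 16), int), 1, 256)
        assert h == pytest.approx(math.log(256), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.permutations(list(range(8))))
    def test_gray_level_permutation_invariant(self, perm):
        # entropy depends only on the histogram, not which levels are used
        base = np.repeat(np.arange(8), [1, 2, 3, 4, 5, 6, 7, 8])
        pix = (base + 0.5) / 8
        ppix = (np.array(perm)[base] + 0.5) / 8
        lab = np.ones((1, base.size), int)
        h1 = M.colony_entropy(ImageFrame(pixels=pix[None]), lab, 1, 8)
        h2 = M.colony_entropy(ImageFrame(pixels=ppix[None]), lab, 1, 8)
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_n_levels_validation(self):
        with pytest.raises(ValueError):
            M.colony_entropy(ImageFrame(pixels=np.zeros((4, 4))),
                             np.ones((4, 4), int), 1, 1)


class TestDisplacementStats:
    def test_uniform_field(self):
        u = np.zeros((2, 10, 10))
        u[0], u[1] = 3.0, 4.0
        assert M.displacement_stats(u, np.ones((10, 10), int), 1) == (5.0, 0.0)

    def test_zero_field(self):
        u = np.zeros((2, 6, 6))
        assert M.displacement_stats(u, np.ones((6, 6), int), 1) == (0.0, 0.0)

    def test_two_valued_field(self):
        u = np.zeros((2, 10, 10))
        u[0, :5], u[0, 5:] = 2.0, 4.0
        assert M.displacement_stats(u, np.ones((10, 10), int), 1) == (3.0, 1.0)

    def test_mean_scales_linearly(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(2, 12, 12))
        lab = np.ones((12, 12), int)
        m1, _ = M.displacement_stats(u, lab, 1)
        m3, _ = M.displacement_stats(3.0 * u, lab, 1)
        assert m3 == pytest.approx(3.0 * m1, rel=1e-12)


class TestMeasureSequence:
    def _inputs(self):
        frames = [ImageFrame(pixels=np.random.default_rng(t).random((40, 40)),
                             time_index=t) for t in range(5)]
        mask = np.zeros((40, 40), int)
        mask[5:15, 5:15] = 1
        mask[25:35, 25:35] = 2
        masks = [mask.copy() for _ in range(5)]
        fields = [np.zeros((2, 40, 40)) for _ in range(4)]
        return frames, masks, fields

    def test_record_counts_and_missing_terminal_displacement(self):
        frames, masks, fields = self._inputs()
        records = M.measure_sequence(frames, masks, fields)
        assert len(records) == 10
        with_disp = [r for r in records if not math.isnan(r.mean_displacement)]
        assert len(with_disp) == 8
        assert all(math.isnan(r.mean_displacement) for r in records
                   if r.frame_index == 4)

    def test_absent_colony_no_record(self):
        frames, masks, fields = self._inputs()
        masks[3] = np.where(masks[3] == 2, 0, masks[3])
        records = M.measure_sequence(frames, masks, fields)
        assert not any(r.frame_index == 3 and r.colony_id == 2 for r in records)

    def test_empty_frame_no_records(self):
        frames, masks, fields = self._inputs()
        masks[2] = np.zeros_like(masks[2])
        records = M.measure_sequence(frames, masks, fields)
        assert not any(r.frame_index == 2 for r in records)
        assert M.covered_area_fraction(masks[2]) == 0.0

    def test_misaligned_inputs(self):
        frames, masks, fields = self._inputs()
        with pytest.raises(ValueError):
            M.measure_sequence(frames, masks, fields[:-2])


class TestSummarizeFrames:
    def _records(self, values_by_frame):
        out = []
        for f, vals in values_by_frame.items():
            for i, v in enumerate(vals):
                out.append(M.ColonyFeatureRecord(
                    frame_index=f, colony_id=i + 1, area_px=1, elongation=0.0,
                    circularity=v, entropy=0.0, mean_displacement=0.0,
                    sd_displacement=0.0, centroid=(0.0, 0.0)))
        return out

    def test_single_colony_all_quantiles_equal(self):
        s = M.summarize_frames(self._records({0: [0.7]}), "circularity")
        assert s[0].median == s[0].q25 == s[0].q75 == 0.7
        assert s[0].n_colonies == 1

    def test_linear_interpolation_quantiles(self):
        (s,) = M.summarize_frames(self._records({0: [1, 2, 3, 4]}), "circularity")
        assert (s.q25, s.median, s.q75) == (1.75, 2.5, 3.25)

    def test_empty_frames_omitted(self):
        s = M.summarize_frames(self._records({0: [1.0], 3: [2.0]}), "circularity")
        assert [x.frame_index for x in s] == [0, 3]

    def test_unknown_feature(self):
        with pytest.raises(KeyError):
            M.summarize_frames(self._records({0: [1.0]}), "sparkliness")


def exact_rank_sum_p(xs, ys):
    """Two-sided p by full enumeration of all group assignments."""
    pooled = sorted(xs + ys)
    ranks = {}
    # midranks for ties
    import collections

    positions = collections.defaultdict(list)
    for i, v in enumerate(pooled, 1):
        positions[v].append(i)
    for v, pos in positions.items():
        ranks[v] = sum(pos) / len(pos)
    w_obs = sum(ranks[v] for v in xs)
    n = len(xs)
    mean_w = sum(ranks[v] for v in pooled) * n / len(pooled)
    count = 0
    total = 0
    all_ranks = [ranks[v] for v in pooled]
    for comb in itertools.combinations(range(len(pooled)), n):
        w = sum(all_ranks[i] for i in comb)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            count += 1
    return count / total


class TestRankSum:
    def test_identical_pools_center(self):
        res = M.rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p_value"] > 0.9

    def test_separated_pools_tiny_p(self):
        res = M.rank_sum_test(list(range(1, 21)), list(range(101, 121)))
        assert res["p_value"] < 1e-6

    def test_singleton_pools(self):
        res = M.rank_sum_test([1.0], [2.0])
        assert res["p_value"] == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 5, 2)
        xs = list(np.round(rng.normal(0, 1, nx), 3))
        ys = list(np.round(rng.normal(0.5, 1, ny), 3))
        res = M.rank_sum_test(xs, ys)
        assert res["p_value"] == pytest.approx(exact_rank_sum_p(xs, ys), abs=1e-9)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            M.rank_sum_test([], [1.0])

    def test_compare_conditions_pools_records(self):
        recs_a = [M.ColonyFeatureRecord(0, 1, 10, 0.0, v, 0.0, 0.0, 0.0, (0, 0))
                  for v in np.linspace(0.8, 0.95, 12)]
        recs_b = [M.ColonyFeatureRecord(0, 1, 10, 0.0, v, 0.0, 0.0, 0.0, (0, 0))
                  for v in np.linspace(0.2, 0.4, 12)]
        res = M.compare_conditions(recs_a, recs_b, "circularity")
        assert res["p_value"] < 0.01
        assert res["n_a"] == res["n_b"] == 12
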