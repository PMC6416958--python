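"""Tests of mask construction, mean-level measurement and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from replidyn import image_quant as iq
from replidyn.synthetic_data import SyntheticCell, gen_nucleus_image
from replidyn.types import RegionMask

from conftest import jaccard


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((7, 9), 4.2)
        np.testing.assert_array_equal(iq.median_filter(img, 1), img)

    def test_single_bright_voxel_removed(self):
        # brute-force oracle: median of the 27-voxel neighbourhood is 0
        img = np.zeros((5, 5, 5))
        img[2, 2, 2] = 100.0
        out = iq.median_filter(img, 1)
        assert out[2, 2, 2] == 0.0

    def test_matches_brute_force_on_random_image(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 10, size=(6, 7))
        out = iq.median_filter(img, 1)
        padded = np.pad(img, 1, mode="symmetric")  # reflection with edge repeat
        for i in range(6):
            for j in range(7):
                assert out[i, j] == np.median(padded[i:i + 3, j:j + 3])

    def test_idempotent_on_interior_plateaus(self):
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 10.0
        once = iq.median_filter(img, 1)
        twice = iq.median_filter(once, 1)
        np.testing.assert_array_equal(once[7:13, 7:13], twice[7:13, 7:13])


class TestMakeMask:
    def test_two_level_disk_recovered_exactly(self):
        yy, xx = np.indices((60, 60))
        disk = (yy - 30) ** 2 + (xx - 30) ** 2 <= 15 ** 2
        img = np.where(disk, 100.0, 10.0)
        for n_steps in (1, 2, 4):
            m = iq.make_mask(img, n_steps=n_steps, kind="nucleus")
            np.testing.assert_array_equal(m.mask, disk)

    def test_blank_image_raises_no_signal(self):
        with pytest.raises(iq.NoSignalError):
            iq.make_mask(np.zeros((30, 30)), kind="nucleus")

    def test_threshold_trace_recorded_and_monotone(self):
        rng = np.random.default_rng(1)
        img = np.where(np.indices((50, 50))[0] < 25, 10.0, 100.0)
        img = img + rng.normal(0, 1, img.shape)
        m = iq.make_mask(img, kind="nucleus", min_area=10)
        assert len(m.threshold_trace) >= 1
        assert m.threshold_trace == sorted(m.threshold_trace)

    def test_raising_final_threshold_never_adds_voxels(self):
        rng = np.random.default_rng(2)
        yy, xx = np.indices((60, 60))
        img = np.where((yy - 30) ** 2 + (xx - 30) ** 2 <= 400, 100.0, 10.0)
        img += rng.normal(0, 3, img.shape)
        m = iq.make_mask(img, kind="nucleus")
        t_final = m.threshold_trace[-1]
        stricter = m.mask & (img > t_final + 5.0)
        assert stricter.sum() <= m.n_voxels

    def test_recovers_synthetic_nucleus(self, untreated_config, early_cell):
        # generator ground truth as the segmentation oracle
        for seed in (21, 22, 23):
            stack, truth = gen_nucleus_image(untreated_config, early_cell, seed=seed)
            dapi = stack.channel("DAPI")
            sec = iq.median_filter(iq.mid_nuclear_section(dapi, dapi=dapi))
            m = iq.make_mask(sec, kind="nucleus", source="DAPI")
            assert jaccard(m.mask, truth["nucleus"].mask[2]) >= 0.9

    def test_recovers_synthetic_blocks_from_marker(self, untreated_config, early_cell):
        stack, truth = gen_nucleus_image(untreated_config, early_cell, seed=24)
        dapi = stack.channel("DAPI")
        for role, kind in (("marker:HP1", "block_X"), ("marker:macroH2A", "block_Xstar")):
            sec = iq.median_filter(iq.mid_nuclear_section(stack.channel(role), dapi=dapi))
            m = iq.make_mask(sec, kind=kind, expected_components=2)
            gt = np.zeros_like(m.mask)
            for b in truth["blocks"]:
                if b.kind == kind:
                    gt |= b.mask[2]
            assert jaccard(m.mask, gt) >= 0.9


class TestExclusionMask:
    def test_no_blocks_equals_nucleus(self):
        nuc = RegionMask(np.ones((10, 10), bool), kind="nucleus")
        excl = iq.make_exclusion_mask(nuc, [])
        np.testing.assert_array_equal(excl.mask, nuc.mask)
        assert excl.kind == "exclusion"

    def test_blocks_covering_nucleus_flagged_empty(self):
        nuc = RegionMask(np.ones((5, 5), bool), kind="nucleus")
        blk = RegionMask(np.ones((5, 5), bool), kind="block_X")
        with pytest.warns(UserWarning, match="empty"):
            excl = iq.make_exclusion_mask(nuc, [blk])
        assert excl.n_voxels == 0

    def test_dimension_mismatch_raises(self):
        nuc = RegionMask(np.ones((5, 5), bool), kind="nucleus")
        blk = RegionMask(np.ones((6, 5), bool), kind="block_X")
        with pytest.raises(ValueError):
            iq.make_exclusion_mask(nuc, [blk])

    @given(data=st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_partition_property(self, data):
        # exclusion + (blocks clipped to nucleus) tile the nucleus disjointly
        nuc_arr = data.draw(arrays(bool, (12, 12)))
        blk_arrs = [data.draw(arrays(bool, (12, 12))) for _ in range(2)]
        nuc = RegionMask(nuc_arr, kind="nucleus")
        blocks = [RegionMask(b, kind="block_X") for b in blk_arrs]
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            excl = iq.make_exclusion_mask(nuc, blocks)
        union_blocks = np.zeros_like(nuc_arr)
        for b in blk_arrs:
            union_blocks |= b
        clipped = union_blocks & nuc_arr
        np.testing.assert_array_equal(excl.mask | clipped, nuc_arr)
        assert not np.any(excl.mask & clipped)


class TestMeanLevel:
    def test_uniform_value(self):
        mask = RegionMask(np.ones((4, 4), bool), kind="nucleus")
        q = iq.mean_level(np.full((4, 4), 5.0), mask)
        assert q.mean == 5.0 and q.n_px == 16
        assert q.total == 80.0

    def test_checkerboard_mean(self):
        img = np.indices((6, 6)).sum(axis=0) % 2 * 10.0
        mask = RegionMask(np.ones((6, 6), bool), kind="nucleus")
        assert iq.mean_level(img, mask).mean == 5.0

    def test_empty_mask_distinct_error(self):
        mask = RegionMask(np.zeros((4, 4), bool), kind="nucleus")
        with pytest.raises(iq.EmptyMaskError):
            iq.mean_level(np.zeros((4, 4)), mask)
        # zero signal over a nonempty mask is NOT an error
        ok = iq.mean_level(np.zeros((4, 4)),
                           RegionMask(np.ones((4, 4), bool), kind="nucleus"))
        assert ok.mean == 0.0

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 50, (9, 9))
        mask = RegionMask(rng.uniform(size=(9, 9)) < 0.4, kind="exclusion")
        q = iq.mean_level(img, mask)
        acc, n = 0.0, 0
        for i in range(9):
            for j in range(9):
                if mask.mask[i, j]:
                    acc += img[i, j]
                    n += 1
        assert q.mean == pytest.approx(acc / n)
        assert q.n_px == n


class TestNormalizeToControl:
    def test_self_normalization_is_one(self):
        vals = [3.0, 4.0, 5.0]
        ratio, ci, _ = iq.normalize_to_control(vals, vals)
        assert ratio == 1.0
        assert ci[0] <= 1.0 <= ci[1]

    def test_doubled_sample(self):
        c = np.array([2.0, 3.0, 4.0])
        ratio, _, _ = iq.normalize_to_control(2 * c, c)
        assert ratio == pytest.approx(2.0)

    def test_gain_invariance(self):
        rng = np.random.default_rng(4)
        s, c = rng.uniform(5, 10, 30), rng.uniform(4, 8, 25)
        r0, _, _ = iq.normalize_to_control(s, c)
        r1, _, _ = iq.normalize_to_control(7.3 * s, 7.3 * c)
        assert r1 == pytest.approx(r0, rel=1e-12)

    def test_zero_control_raises(self):
        with pytest.raises(ZeroDivisionError):
            iq.normalize_to_control([1.0], [0.0, 0.0])

    def test_recovers_configured_fold(self):
        # hyperacetylation fold 1.5 with per-cell lognormal scatter
        rng = np.random.default_rng(5)
        control = 100.0 * rng.lognormal(0, 0.2, 50)
        treated = 150.0 * rng.lognormal(0, 0.2, 50)
        ratio, ci, test = iq.normalize_to_control(treated, control)
        assert ratio == pytest.approx(1.5, abs=0.15)
        assert ci[0] < ratio < ci[1]
        assert test.p_value < 1e-6


class TestLineProfile:
    def test_constant_image(self):
        prof = iq.line_profile(np.full((20, 20), 3.0), (10, 2), (10, 17))
        np.testing.assert_allclose(prof, 3.0)

    def test_column_ramp(self):
        img = np.tile(np.arange(16, dtype=float), (16, 1))
        prof = iq.line_profile(img, (8, 0), (8, 15))
        np.testing.assert_allclose(prof, np.arange(16, dtype=float))

    def test_zero_length_raises(self):
        with pytest.raises(ValueError):
            iq.line_profile(np.zeros((5, 5)), (2, 2), (2, 2))

    def test_block_plateau_flanked_by_background(self, noiseless_config):
        cell = SyntheticCell("c", "untreated", "nonS")
        stack, truth = gen_nucleus_image(noiseless_config, cell, seed=6)
        ch = stack.channel("PTM:H3K9me3")[2]
        xblock = next(b for b in truth["blocks"] if b.kind == "block_X")
        ys, xs = np.nonzero(xblock.mask[2])
        cy, cx = ys.mean(), xs.mean()
        prof = iq.line_profile(ch, (cy, cx - 11), (cy, cx + 11))
        levels = noiseless_config.ptm_levels["H3K9me3"]
        assert prof.max() == pytest.approx(levels["x"])
        assert prof[0] == pytest.approx(levels["euchromatin"])
        assert prof[-1] == pytest.approx(levels["euchromatin"])


class TestQuantifyTranscription:
    def _cells(self, eu_x, eu_xstar, n, rng=None):
        cells = []
        for i in range(n):
            eu = np.zeros((3, 10, 10))
            mx = np.zeros((3, 10, 10), bool)
            mxs = np.zeros((3, 10, 10), bool)
            mx[1, 2:5, 2:5] = True
            mxs[1, 6:9, 6:9] = True
            jx = rng.normal(0, 1) if rng is not None else 0.0
            jxs = rng.normal(0, 1) if rng is not None else 0.0
            eu[mx] = eu_x + jx
            eu[mxs] = eu_xstar + jxs
            cells.append({"eu": eu, "x": RegionMask(mx, "block_X"),
                          "xstar": RegionMask(mxs, "block_Xstar")})
        return cells

    def test_identical_blocks_no_difference(self):
        x, xs, res = iq.quantify_transcription(self._cells(50.0, 50.0, 5))
        assert res.effect == 0.0
        assert res.p_value == 1.0

    def test_constitutive_double_with_noise_significant(self):
        rng = np.random.default_rng(7)
        x, xs, res = iq.quantify_transcription(self._cells(100.0, 50.0, 10, rng))
        assert res.effect > 0  # direction: X above X*
        assert res.p_value < 0.001

    def test_generator_roundtrip_ratio(self, untreated_config):
        # configured EU means X=120, X*=100 -> recovered ratio about 1.2
        x_means, xs_means = [], []
        for seed in range(30, 42):
            cell = SyntheticCell("c", "untreated", "nonS")
            stack, truth = gen_nucleus_image(untreated_config, cell, seed=seed)
            cells = [{"eu": stack.channel("EU"),
                      "x": next(b for b in truth["blocks"] if b.kind == "block_X"),
                      "xstar": next(b for b in truth["blocks"] if b.kind == "block_Xstar")}]
            x, xs, _ = iq.quantify_transcription(cells * 2)
            x_means.append(x[0])
            xs_means.append(xs[0])
        ratio = np.mean(x_means) / np.mean(xs_means)
        assert ratio == pytest.approx(1.2, abs=0.05)

    def test_missing_block_excluded_with_warning(self):
        cells = self._cells(50.0, 50.0, 3)
        cells.append({"eu": np.zeros((3, 10, 10)), "x": None, "xstar": None})
        with pytest.warns(UserWarning, match="excluded 1"):
            x, xs, _ = iq.quantify_transcription(cells)
        assert len(x) == 3
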