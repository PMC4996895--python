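import numpy as np
import pytest

from canopybench import (
    CoRegistrationError,
    GridTransform,
    InvalidParameterError,
    LayerStack,
    Raster,
    SampleSet,
    SamplingError,
    aggregate_mean,
    apply_validity_mask,
    extract_samples,
    read_raster,
    read_stack,
    write_raster,
    write_stack,
)


def brute_force_block_mean(values, mask, factor):
    nr, nc = values.shape
    cr, cc = nr // factor, nc // factor
    out = np.full((cr, cc), np.nan)
    for i in range(cr):
        for j in range(cc):
            block = values[i * factor:(i + 1) * factor,
                           j * factor:(j + 1) * factor]
            ok = mask[i * factor:(i + 1) * factor,
                      j * factor:(j + 1) * factor]
            if ok.any():
                out[i, j] = block[ok].mean()
    return out


class TestAggregateMean:
    def test_constant_block(self):
        r = Raster(np.full((100, 100), 10.0), GridTransform(1.0))
        coarse = aggregate_mean(r, 100)
        assert coarse.shape == (1, 1)
        assert coarse.values[0, 0] == 10.0
        assert coarse.transform.pixel_size == 100.0

    def test_symmetric_block(self):
        r = Raster(np.array([[0.0, 0.0], [20.0, 20.0]]), GridTransform(1.0))
        assert aggregate_mean(r, 2).values[0, 0] == 10.0

    def test_matches_bruteforce_oracle(self, rng):
        vals = rng.normal(size=(8, 8))
        r = Raster(vals, GridTransform(1.0))
        expected = brute_force_block_mean(vals, np.ones((8, 8), bool), 4)
        np.testing.assert_allclose(aggregate_mean(r, 4).values, expected,
                                   rtol=0, atol=1e-12)

    def test_masked_cells_excluded(self, rng):
        vals = rng.normal(size=(6, 6))
        mask = rng.random((6, 6)) < 0.4
        mask[:3, :3] = True  # one block fully masked
        r = Raster(vals, GridTransform(1.0), nodata_mask=mask)
        coarse = aggregate_mean(r, 3)
        expected = brute_force_block_mean(vals, ~mask, 3)
        assert coarse.nodata_mask[0, 0]
        ok = ~coarse.nodata_mask
        np.testing.assert_allclose(coarse.values[ok], expected[ok])

    def test_partial_edge_blocks_dropped(self, rng):
        r = Raster(rng.normal(size=(7, 9)), GridTransform(1.0))
        assert aggregate_mean(r, 2).shape == (3, 4)

    def test_conserves_grand_mean(self, rng):
        vals = rng.normal(size=(12, 12))
        r = Raster(vals, GridTransform(1.0))
        assert aggregate_mean(r, 4).values.mean() == pytest.approx(
            vals.mean(), abs=1e-12)

    @pytest.mark.parametrize("factor", [0, -1])
    def test_invalid_factor(self, factor):
        r = Raster(np.ones((4, 4)), GridTransform(1.0))
        with pytest.raises(InvalidParameterError):
            aggregate_mean(r, factor)


class TestValidityMask:
    def _toy(self):
        vals = np.array([[0.5, 1.0, 1.5], [2.0, 2.5, 3.0], [25.0, 0.0, 4.0]])
        mch = Raster(vals, GridTransform(100.0))
        veg = Raster(np.ones((3, 3)), GridTransform(100.0))
        return mch, veg

    def test_height_rule_strict_threshold(self):
        mch, veg = self._toy()
        out, counts = apply_validity_mask(mch, veg, min_height=1.0)
        # brute-force count of values > 1.0
        expected_kept = int((mch.values > 1.0).sum())
        assert out.valid_mask.sum() == expected_kept
        assert out.nodata_mask[0, 0]       # 0.5 m masked
        assert out.nodata_mask[0, 1]       # exactly 1.0 m is NOT higher than 1
        assert not out.nodata_mask[2, 0]   # 25 m retained
        assert counts.removed_height == 9 - expected_kept
        assert counts.removed_landcover == 0

    def test_landcover_rule_and_counts(self):
        mch, veg = self._toy()
        veg.values[0, :] = 0.0
        out, counts = apply_validity_mask(mch, veg)
        assert counts.removed_landcover == 3
        # height rule now only applies to remaining vegetated pixels
        assert counts.removed_height == int(
            (mch.values[1:] <= 1.0).sum())
        assert out.values[2, 0] == 25.0 and not out.nodata_mask[2, 0]

    def test_idempotent(self):
        mch, veg = self._toy()
        once, _ = apply_validity_mask(mch, veg)
        twice, counts = apply_validity_mask(once, veg)
        np.testing.assert_array_equal(once.nodata_mask, twice.nodata_mask)
        assert counts.removed_landcover == 0 and counts.removed_height == 0

    def test_shape_mismatch(self):
        mch, _ = self._toy()
        veg = Raster(np.ones((2, 2)), GridTransform(100.0))
        with pytest.raises(CoRegistrationError):
            apply_validity_mask(mch, veg)


class TestExtractSamples:
    def test_deterministic_and_distinct(self, small_scene):
        mch, stack = small_scene
        a = extract_samples(stack, mch, 50, rng_seed=9)
        b = extract_samples(stack, mch, 50, rng_seed=9)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.row_col, b.row_col)
        # no duplicated pixel coordinates
        assert len({tuple(rc) for rc in a.row_col}) == 50

    def test_all_pixels_is_permutation(self, small_scene):
        mch, stack = small_scene
        s = extract_samples(stack, mch, None, rng_seed=3)
        n_valid = int((stack.valid_mask & mch.valid_mask).sum())
        assert len(s) == n_valid
        assert len({tuple(rc) for rc in s.row_col}) == n_valid

    def test_train_test_partition_sizes(self, small_scene):
        mch, stack = small_scene
        n_valid = int((stack.valid_mask & mch.valid_mask).sum())
        s = extract_samples(stack, mch, 400, rng_seed=1)
        assert n_valid - len(s) == n_valid - 400  # rest available as test

    def test_oversampling_error_names_counts(self, small_scene):
        mch, stack = small_scene
        n_valid = int((stack.valid_mask & mch.valid_mask).sum())
        with pytest.raises(SamplingError, match=str(n_valid)):
            extract_samples(stack, mch, n_valid + 1)

    def test_values_match_rasters(self, small_scene):
        mch, stack = small_scene
        s = extract_samples(stack, mch, 20, rng_seed=5)
        r, c = s.row_col[:, 0], s.row_col[:, 1]
        np.testing.assert_array_equal(s.y, mch.values[r, c])
        np.testing.assert_array_equal(s.X[:, 0], stack.bands[0].values[r, c])


class TestIO:
    def test_raster_tiff_roundtrip(self, tmp_path, rng):
        vals = rng.normal(size=(10, 12))
        mask = rng.random((10, 12)) < 0.2
        r = Raster(vals, GridTransform(100.0, 5.0, -3.0), mask)
        p = tmp_path / "r.tif"
        write_raster(p, r)
        back = read_raster(p)
        assert back.transform == r.transform
        np.testing.assert_array_equal(back.nodata_mask, r.nodata_mask)
        np.testing.assert_allclose(back.values[back.valid_mask],
                                   vals[~mask])

    def test_stack_tiff_roundtrip(self, tmp_path, small_scene):
        _, stack = small_scene
        p = tmp_path / "s.tif"
        write_stack(p, stack)
        back = read_stack(p)
        assert back.names == stack.names and back.roles == stack.roles
        np.testing.assert_allclose(back.bands[2].values,
                                   stack.bands[2].values)

    def test_sampleset_csv_roundtrip(self, tmp_path, small_scene):
        mch, stack = small_scene
        s = extract_samples(stack, mch, 30, rng_seed=2)
        p = tmp_path / "samples.csv"
        s.to_csv(p)
        back = SampleSet.from_csv(p)
        assert back.names == s.names
        np.testing.assert_allclose(back.X, s.X)
        np.testing.assert_allclose(back.y, s.y)
        np.testing.assert_allclose(back.xy, s.xy)
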