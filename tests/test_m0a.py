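import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aslcalib as asl
from aslcalib import constants as C
from aslcalib.m0a import CalibOptions, RtMaskSpec, masked_median_filter
from aslcalib.phantom import VENTRICLE_LABEL


class TestLambdaMap:
    def test_avg_variant_constant(self, pasl_phantom):
        tissue, _ = pasl_phantom
        lam = asl.lambda_map(tissue, "avg")
        bm = tissue.brain_mask
        assert np.allclose(lam[bm], 0.90)

    def test_pure_csf_pve_variant(self, crisp_phantom):
        tissue, _ = crisp_phantom
        lam = asl.lambda_map(tissue, "pve")
        assert np.allclose(lam[tissue.labels == VENTRICLE_LABEL], 1.15)

    def test_weighted_sum(self):
        assert (0.5 * C.LAMBDA_GM + 0.3 * C.LAMBDA_WM
                + 0.2 * C.LAMBDA_CSF) == pytest.approx(0.966)

    def test_tspec_majority_and_tie_break(self, crisp_phantom):
        tissue, _ = crisp_phantom
        lam = asl.lambda_map(tissue, "tspec")
        assert np.allclose(lam[tissue.pve_gm == 1.0], C.LAMBDA_GM)
        assert np.allclose(lam[tissue.pve_wm == 1.0], C.LAMBDA_WM)

    def test_no_tissue_voxels_are_nan(self, crisp_phantom):
        tissue, _ = crisp_phantom
        lam = asl.lambda_map(tissue, "pve")
        assert np.all(np.isnan(lam[tissue.pve_sum == 0]))

    def test_pve_lambda_within_table_range(self, pasl_phantom):
        tissue, _ = pasl_phantom
        lam = asl.lambda_map(tissue, "pve")
        bm = tissue.brain_mask
        assert lam[bm].min() >= min(C.LAMBDA_TISSUE) - 1e-12
        assert lam[bm].max() <= max(C.LAMBDA_TISSUE) + 1e-12

    def test_unknown_variant(self, pasl_phantom):
        tissue, _ = pasl_phantom
        with pytest.raises(ValueError):
            asl.lambda_map(tissue, "bogus")


class TestRtMask:
    def test_full_pve_mask_is_whole_region(self, crisp_phantom):
        tissue, _ = crisp_phantom
        mask = asl.build_rt_mask(tissue, RtMaskSpec("WM", 0.9, False))
        assert np.array_equal(mask, tissue.pve_wm == 1.0)

    def test_threshold_monotonicity(self, pasl_phantom):
        tissue, _ = pasl_phantom
        restrictive = asl.build_rt_mask(
            tissue, RtMaskSpec("CSF", 0.9, False))
        extensive = asl.build_rt_mask(tissue, RtMaskSpec("CSF", 0.6, False))
        assert restrictive.sum() <= extensive.sum()
        assert np.all(extensive[restrictive])

    def test_ventricle_intersection(self, pasl_phantom):
        tissue, _ = pasl_phantom
        with_vent = asl.build_rt_mask(tissue, RtMaskSpec("CSF", 0.6, True))
        without = asl.build_rt_mask(tissue, RtMaskSpec("CSF", 0.6, False))
        assert with_vent.sum() < without.sum()   # sulcal CSF excluded
        assert np.all(tissue.ventricle_mask[with_vent])

    def test_empty_mask_suggests_extensive(self, pasl_phantom):
        tissue, _ = pasl_phantom
        with pytest.raises(ValueError, match="extensive"):
            asl.build_rt_mask(tissue, RtMaskSpec("CSF", 1.01, False))

    def test_unknown_tissue(self):
        with pytest.raises(ValueError):
            RtMaskSpec("fat", 0.9, False)


class TestReferenceTissueM0a:
    def test_te_zero_lambda_one_is_masked_mean(self, pasl_phantom):
        tissue, truth = pasl_phantom
        m0t = asl.M0Map(truth.m0t_map, "M0t", "SatRec")
        mask = tissue.ventricle_mask
        opts = CalibOptions(te_ms=0.0, lambda_tissue=(1.0, 1.0, 1.0))
        m0a = asl.m0a_reference_tissue(m0t, mask, opts, "CSF")
        assert m0a.values == pytest.approx(truth.m0t_map[mask].mean(),
                                           rel=1e-6)

    def test_equal_t2stars_cancel(self, pasl_phantom):
        tissue, truth = pasl_phantom
        m0t = asl.M0Map(truth.m0t_map, "M0t", "SatRec")
        mask = tissue.ventricle_mask
        opts = CalibOptions(te_ms=19.0, t2star_blood_ms=400.0)
        m0a = asl.m0a_reference_tissue(m0t, mask, opts, "CSF")
        expected = truth.m0t_map[mask].mean() / C.LAMBDA_CSF
        assert m0a.values == pytest.approx(expected, rel=1e-9)

    def test_csf_factor_at_te13(self, pasl_phantom):
        tissue, truth = pasl_phantom
        m0t = asl.M0Map(truth.m0t_map, "M0t", "SatRec")
        mask = tissue.ventricle_mask
        opts = CalibOptions(te_ms=13.0)
        m0a = asl.m0a_reference_tissue(m0t, mask, opts, "CSF")
        factor = np.exp(13.0 * (1 / 400.0 - 1 / 50.0))
        assert factor == pytest.approx(0.7965, abs=2e-4)
        expected = truth.m0t_map[mask].mean() * factor / 1.15
        assert m0a.values == pytest.approx(expected, rel=1e-9)

    def test_te_unit_guard(self):
        with pytest.raises(ValueError, match="milliseconds"):
            CalibOptions(te_ms=0.019)    # TE passed in seconds

    def test_empty_mask_rejected(self, pasl_phantom):
        tissue, truth = pasl_phantom
        m0t = asl.M0Map(truth.m0t_map, "M0t", "SatRec")
        with pytest.raises(ValueError, match="empty"):
            asl.m0a_reference_tissue(
                m0t, np.zeros_like(tissue.ventricle_mask), CalibOptions(),
                "CSF")


class TestBiasField:
    def test_unbiased_input_gives_unit_field(self, satrec_m0t,
                                             pasl_phantom):
        tissue, _ = pasl_phantom
        m0map, _ = satrec_m0t
        bias = asl.estimate_bias_field(m0map, tissue)
        bm = tissue.brain_mask
        assert np.all(np.abs(bias[bm] - 1.0) < 0.02)

    def test_recovers_synthetic_bias(self, biased_bundle):
        tissue, truth, _, _, m0t_map = biased_bundle
        bias = asl.estimate_bias_field(m0t_map, tissue)
        bm = tissue.brain_mask
        r = np.corrcoef(bias[bm], truth.bias_field[bm])[0, 1]
        assert r > 0.95

    def test_degenerate_input_rejected(self, pasl_phantom):
        tissue, _ = pasl_phantom
        with pytest.raises(ValueError):
            asl.estimate_bias_field(np.zeros(tissue.pve_gm.shape), tissue)


class TestMaskedMedianFilter:
    def test_spike_removed_neighbors_unchanged(self):
        vol = np.ones((9, 9, 3))
        mask = np.ones_like(vol, dtype=bool)
        vol[4, 4, 1] = 100.0
        out = masked_median_filter(vol, mask, 3)
        assert out[4, 4, 1] == 1.0
        assert np.allclose(out[:3], 1.0)

    def test_size_zero_is_identity(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(6, 6, 2))
        out = masked_median_filter(vol, np.ones_like(vol, dtype=bool), 0)
        assert np.array_equal(out, vol)

    def test_no_background_bleed(self):
        vol = np.zeros((7, 7, 1))
        mask = np.zeros_like(vol, dtype=bool)
        vol[2:5, 2:5, 0] = 5.0
        mask[2:5, 2:5, 0] = True
        out = masked_median_filter(vol, mask, 3)
        # edge voxels of the masked block keep their value: zeros outside
        # the mask are excluded from the neighborhood
        assert np.allclose(out[mask], 5.0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            masked_median_filter(np.ones((4, 4, 1)),
                                 np.ones((4, 4, 1), dtype=bool), 2)


class TestVoxelwiseM0a:
    def test_identity_configuration(self, crisp_phantom):
        tissue, truth = crisp_phantom
        m0t = asl.M0Map(truth.m0t_map, "M0t", "SatRec")
        opts = CalibOptions(te_ms=0.0, smoothing="none",
                            lambda_tissue=(1.0, 1.0, 1.0),
                            m0a_floor_frac=0.0)
        m0a = asl.m0a_voxelwise(m0t, tissue, opts)
        bm = tissue.brain_mask
        assert np.allclose(np.asarray(m0a.values)[bm], truth.m0t_map[bm],
                           rtol=1e-6)

    def test_recovers_arterial_signal_exactly(self, crisp_phantom):
        # the phantom is built so Eq-style extrapolation is exact
        tissue, truth = crisp_phantom
        m0t = asl.M0Map(truth.m0t_map, "M0t", "SatRec")
        opts = CalibOptions(te_ms=truth.te_ms, smoothing="none")
        m0a = asl.m0a_voxelwise(m0t, tissue, opts)
        bm = tissue.brain_mask
        assert np.allclose(np.asarray(m0a.values)[bm], truth.m0a_signal,
                           rtol=1e-9)

    def test_floor_masks_low_voxels(self, pasl_phantom):
        tissue, truth = pasl_phantom
        low = truth.m0t_map.copy()
        i, j, k = np.argwhere(tissue.brain_mask)[0]
        low[i, j, k] = 1e-6
        m0a = asl.m0a_voxelwise(asl.M0Map(low, "M0t", "SatRec"), tissue,
                                CalibOptions(te_ms=19.0, smoothing="none"))
        assert np.isnan(np.asarray(m0a.values)[i, j, k])

    def test_smoothing_extent_bookkeeping(self):
        assert CalibOptions().smoothing_extent_mm == pytest.approx(10.5)
        assert CalibOptions(smoothing="5x5").smoothing_extent_mm == \
            pytest.approx(17.5)
        assert CalibOptions(smoothing="none").smoothing_extent_mm == 0.0

    @settings(max_examples=20, deadline=None)
    @given(w=st.tuples(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)))
    def test_lambda_pve_bounded_by_constants(self, w):
        total = sum(w)
        if total == 0:
            return
        w = tuple(x / total for x in w)
        lam = (w[0] * C.LAMBDA_GM + w[1] * C.LAMBDA_WM
               + w[2] * C.LAMBDA_CSF)
        assert min(C.LAMBDA_TISSUE) - 1e-12 <= lam
        assert lam <= max(C.LAMBDA_TISSUE) + 1e-12
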