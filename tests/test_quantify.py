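"""Thresholding methods, correction operators, %LVM and salvage index."""

import numpy as np
import pytest

import cmrquant.geometry as geo
import cmrquant.quantify as q
from cmrquant.io import ImageStack
from cmrquant.phantom import PhantomSpec, core_seed, generate_phantom, remote_seed
from conftest import otsu_brute_oracle, random_phantom_spec


def _flat_myo(n_slices=2, size=20):
    mask = np.ones((n_slices, size, size), bool)
    return geo.MyoMask(mask=mask, contoured=np.ones(n_slices, bool),
                       excluded_apical=np.zeros(n_slices, bool))


def _stack(voxels, spacing=1.0, thickness=10.0, gap=0.0):
    return ImageStack(voxels=voxels, pixel_spacing=(spacing, spacing),
                      slice_thickness=thickness, slice_gap=gap)


def _roi(myo, slice_index, rows, cols):
    return geo.Roi(slice_index=slice_index, rows=np.asarray(rows),
                   cols=np.asarray(cols), target_area_cm2=0.0)


class TestKsdThreshold:
    def test_formula_mu_plus_k_sigma(self):
        vox = np.full((2, 20, 20), 0.0)
        # ROI with mean 100, sample SD 10
        roi_vals = np.array([90.0, 110.0, 90.0, 110.0, 90.0, 110.0])
        sd = roi_vals.std(ddof=1)
        vox[0, 0, :6] = roi_vals
        stack = _stack(vox)
        myo = _flat_myo()
        res = q.threshold_ksd(stack, myo, _roi(myo, 0, [0] * 6, range(6)), k=5)
        assert res.remote_mean == pytest.approx(100.0)
        assert res.remote_sd == pytest.approx(sd)
        assert res.thresholds[0] == pytest.approx(100.0 + 5 * sd)

    def test_k8_with_unit_sd(self):
        rng = np.random.default_rng(0)
        vox = rng.normal(0, 1, size=(2, 20, 20))
        stack = _stack(vox)
        myo = _flat_myo()
        rows, cols = np.meshgrid(range(10), range(10), indexing="ij")
        roi = _roi(myo, 0, rows.ravel(), cols.ravel())
        vals = vox[0, rows.ravel(), cols.ravel()]
        res = q.threshold_ksd(stack, myo, roi, k=8)
        assert res.thresholds[0] == pytest.approx(vals.mean() + 8 * vals.std(ddof=1))

    def test_degenerate_constant_roi_allowed(self):
        vox = np.full((2, 20, 20), 100.0)
        vox[1, 5, 5] = 300.0
        stack = _stack(vox)
        myo = _flat_myo()
        res = q.threshold_ksd(stack, myo, _roi(myo, 0, [0, 0], [0, 1]), k=5)
        assert res.remote_sd == 0.0
        assert res.enhancement_mask.sum() == 1  # only the 300 voxel exceeds 100

    def test_strict_inequality(self):
        """Enhancement requires SI strictly above the threshold."""
        vox = np.full((2, 4, 4), 100.0)
        stack = _stack(vox)
        myo = _flat_myo(size=4)
        res = q.threshold_ksd(stack, myo, _roi(myo, 0, [0, 0], [0, 1]), k=5)
        assert not res.enhancement_mask.any()


class TestFwhmThreshold:
    def test_half_of_core_max(self):
        vox = np.full((2, 20, 20), 50.0)
        vox[0, 3, 3] = 200.0
        stack = _stack(vox)
        myo = _flat_myo()
        res = q.threshold_fwhm(stack, myo, _roi(myo, 0, [3, 3], [3, 4]))
        assert res.core_max == 200.0
        assert res.thresholds[0] == 100.0

    def test_auto_mode_uses_global_myocardial_max(self):
        vox = np.full((3, 20, 20), 50.0)
        vox[1, 7, 7] = 300.0
        vox[2, 2, 2] = 500.0  # apical slice, excluded below
        stack = _stack(vox)
        myo = geo.exclude_apical_slice(_flat_myo(n_slices=3))
        res = q.threshold_fwhm(stack, myo)
        assert res.core_max == 300.0  # excluded slice does not contribute

    def test_uniform_myocardium_degenerate(self):
        """Uniform SI: threshold is half of it and everything is enhanced."""
        vox = np.full((2, 10, 10), 50.0)
        stack = _stack(vox)
        myo = _flat_myo(size=10)
        res = q.threshold_fwhm(stack, myo)
        assert res.thresholds[0] == 25.0
        assert res.enhancement_mask.sum() == myo.quantifiable_volume().sum()


class TestOtsuPerSlice:
    def test_bimodal_toy_slice(self):
        vox = np.full((2, 3, 2), 0.0)
        vox[0] = np.array([[1, 1], [1, 9], [9, 9]])
        vox[1] = vox[0]
        stack = _stack(vox)
        myo = _flat_myo(size=0)  # replaced below
        myo = geo.MyoMask(mask=np.ones((2, 3, 2), bool), contoured=np.ones(2, bool),
                          excluded_apical=np.zeros(2, bool))
        res = q.threshold_otsu_per_slice(stack, myo)
        assert 1 < res.thresholds[0] < 9
        assert res.enhancement_mask[0].sum() == 3

    def test_constant_slice_warns_no_enhancement(self):
        vox = np.full((2, 4, 4), 5.0)
        vox[1, 0, 0] = 9.0
        stack = _stack(vox)
        myo = _flat_myo(size=4)
        with pytest.warns(UserWarning, match="constant myocardial signal"):
            res = q.threshold_otsu_per_slice(stack, myo)
        assert not res.enhancement_mask[0].any()
        assert np.isnan(res.thresholds[0])

    def test_two_gaussian_slice_threshold_between_modes(self):
        rng = np.random.default_rng(11)
        vals = np.concatenate([rng.normal(100, 15, 200), rng.normal(400, 15, 100)])
        vox = np.zeros((2, 1, 300))
        vox[0, 0] = vals
        vox[1, 0] = vals
        stack = _stack(vox)
        myo = geo.MyoMask(mask=np.ones((2, 1, 300), bool), contoured=np.ones(2, bool),
                          excluded_apical=np.zeros(2, bool))
        res = q.threshold_otsu_per_slice(stack, myo)
        assert 100 < res.thresholds[0] < 400
        assert res.thresholds[0] == otsu_brute_oracle(vals)

    def test_matches_brute_force_on_small_slices(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            vals = np.round(rng.uniform(0, 300, n), 1)
            if vals.min() == vals.max():
                continue
            vox = np.zeros((2, 1, n))
            vox[0, 0] = vals
            vox[1, 0] = vals
            stack = _stack(vox)
            myo = geo.MyoMask(mask=np.ones((2, 1, n), bool),
                              contoured=np.ones(2, bool),
                              excluded_apical=np.zeros(2, bool))
            res = q.threshold_otsu_per_slice(stack, myo)
            assert res.thresholds[0] == otsu_brute_oracle(vals)

    def test_threshold_on_every_slice_including_infarct_free(self):
        """The per-slice threshold is computed whether or not infarct exists —
        the documented overestimation mechanism."""
        rng = np.random.default_rng(9)
        spec = random_phantom_spec(rng, noise_sd=10.0, infarct_slice_span=(2, 4))
        lge, _, _, truth = generate_phantom(spec)
        myo = truth.to_myo_mask()
        res = q.threshold_otsu_per_slice(lge, myo)
        infarct_free = [s for s in range(spec.n_slices)
                        if myo.quantifiable[s] and not truth.infarct_mask[s].any()]
        assert infarct_free
        for s in infarct_free:
            assert np.isfinite(res.thresholds[s])
            assert res.enhancement_mask[s].any()  # noise split into "enhanced"


class TestCorrectionA:
    def _setup(self, size=16):
        vox = np.full((2, size, size), 0.0)
        stack = _stack(vox)
        mask = np.zeros((2, size, size), bool)
        return stack, mask

    def test_enclosed_hole_filled(self):
        stack, mask = self._setup()
        mask[:, 2:14, 2:14] = True  # solid myocardial block
        myo = geo.MyoMask(mask=mask, contoured=np.ones(2, bool),
                          excluded_apical=np.zeros(2, bool))
        enh = mask.copy()
        enh[0, 6:8, 6:11] = False  # 2x5 = 10-voxel enclosed hole
        res = q.QuantResult(method="x", enhancement_mask=enh,
                            thresholds=np.full(2, np.nan))
        before = int(enh.sum())
        out = q.correction_a_fill_cores(res, myo)
        assert int(out.enhancement_mask.sum()) == before + 10

    def test_hole_open_to_remote_not_filled(self):
        stack, mask = self._setup()
        mask[:, 2:14, 2:14] = True
        myo = geo.MyoMask(mask=mask, contoured=np.ones(2, bool),
                          excluded_apical=np.zeros(2, bool))
        enh = mask.copy()
        enh[0, 6:8, 6:14] = False  # notch reaching the myocardial border
        res = q.QuantResult(method="x", enhancement_mask=enh,
                            thresholds=np.full(2, np.nan))
        out = q.correction_a_fill_cores(res, myo)
        np.testing.assert_array_equal(out.enhancement_mask, enh)

    def test_core_touching_blood_pool_is_filled(self):
        """A subendocardial core abutting the cavity is still included."""
        spec = PhantomSpec(noise_sd=0, blur_sigma_mm=0)
        lge, _, _, truth = generate_phantom(spec)
        myo = truth.to_myo_mask()
        enh = truth.infarct_mask & myo.quantifiable_volume()
        # carve a hole that touches the endocardial border inside the wedge
        sl = 2
        hole = np.zeros_like(enh[sl])
        rows, cols = np.nonzero(truth.infarct_mask[sl])
        centre = (spec.matrix_size - 1) / 2
        d = np.hypot(rows - centre, cols - centre)
        ang = np.degrees(np.arctan2(rows - centre, cols - centre))
        # subendocardial band in the angular middle of the wedge only
        inner = (d < spec.endo_radius / spec.pixel_spacing + 1.5) & (np.abs(ang) < 20)
        hole[rows[inner], cols[inner]] = True
        enh[sl] &= ~hole
        res = q.QuantResult(method="x", enhancement_mask=enh,
                            thresholds=np.full(spec.n_slices, np.nan))
        out = q.correction_a_fill_cores(res, myo)
        assert out.enhancement_mask[sl][hole].all()

    def test_phantom_mvo_recovered(self):
        spec = PhantomSpec(noise_sd=0, blur_sigma_mm=0, mvo_fraction=0.2)
        lge, _, _, truth = generate_phantom(spec)
        myo = truth.to_myo_mask()
        sl, r, c = remote_seed(spec)
        roi = geo.build_roi(myo, lge, sl, (r, c))
        res = q.threshold_ksd(lge, myo, roi, k=5)
        res = q.correction_a_fill_cores(res, myo)
        pct = q.percent_lvm(res, myo, lge)
        assert pct == pytest.approx(truth.true_is_percent_lvm, abs=0.5)

    def test_idempotent(self):
        stack, mask = self._setup()
        mask[:, 2:14, 2:14] = True
        myo = geo.MyoMask(mask=mask, contoured=np.ones(2, bool),
                          excluded_apical=np.zeros(2, bool))
        enh = mask.copy()
        enh[0, 6:8, 6:11] = False
        res = q.QuantResult(method="x", enhancement_mask=enh,
                            thresholds=np.full(2, np.nan))
        once = q.correction_a_fill_cores(res, myo)
        twice = q.correction_a_fill_cores(once, myo)
        np.testing.assert_array_equal(once.enhancement_mask, twice.enhancement_mask)
        assert twice.corrections_applied == ("a",)


class TestCorrectionB:
    def _myo(self, n_slices=4, size=16):
        mask = np.ones((n_slices, size, size), bool)
        return geo.MyoMask(mask=mask, contoured=np.ones(n_slices, bool),
                           excluded_apical=np.zeros(n_slices, bool))

    def test_single_slice_speck_removed(self):
        myo = self._myo()
        enh = np.zeros_like(myo.mask)
        enh[0:3, 2:6, 2:6] = True  # main 3-slice component
        enh[1, 12, 12:14] = True  # isolated 2-voxel speck
        res = q.QuantResult(method="x", enhancement_mask=enh,
                            thresholds=np.full(4, np.nan))
        out = q.correction_b_remove_noise(res, myo)
        assert not out.enhancement_mask[1, 12, 12]
        assert out.enhancement_mask[0:3, 2:6, 2:6].all()

    def test_two_slice_component_retained(self):
        myo = self._myo()
        enh = np.zeros_like(myo.mask)
        enh[1:3, 12, 12] = True
        res = q.QuantResult(method="x", enhancement_mask=enh,
                            thresholds=np.full(4, np.nan))
        out = q.correction_b_remove_noise(res, myo)
        assert out.enhancement_mask.sum() == 2

    def test_protect_mask_overrides_removal(self):
        myo = self._myo()
        enh = np.zeros_like(myo.mask)
        enh[1, 12, 12] = True
        protect = np.zeros_like(enh)
        protect[1, 12, 12] = True
        res = q.QuantResult(method="x", enhancement_mask=enh,
                            thresholds=np.full(4, np.nan))
        out = q.correction_b_remove_noise(res, myo, protect_mask=protect)
        assert out.enhancement_mask[1, 12, 12]

    def test_phantom_speckles_removed(self):
        spec = PhantomSpec(noise_sd=0, blur_sigma_mm=0, speckle_count=5, seed=3)
        lge, _, _, truth = generate_phantom(spec)
        assert truth.speckle_mask.any()
        myo = truth.to_myo_mask()
        sl, r, c = remote_seed(spec)
        roi = geo.build_roi(myo, lge, sl, (r, c))
        res = q.threshold_ksd(lge, myo, roi, k=5)
        assert (res.enhancement_mask & truth.speckle_mask).any()
        out = q.correction_b_remove_noise(res, myo)
        assert not (out.enhancement_mask & truth.speckle_mask).any()
        pct = q.percent_lvm(out, myo, lge)
        assert pct == pytest.approx(truth.true_is_percent_lvm, abs=0.5)

    def test_corrections_commute_on_phantoms(self):
        spec = PhantomSpec(noise_sd=0, blur_sigma_mm=0, speckle_count=4,
                           mvo_fraction=0.15, seed=8)
        lge, _, _, truth = generate_phantom(spec)
        myo = truth.to_myo_mask()
        sl, r, c = remote_seed(spec)
        roi = geo.build_roi(myo, lge, sl, (r, c))
        base = q.threshold_ksd(lge, myo, roi, k=5)
        ab = q.correction_b_remove_noise(q.correction_a_fill_cores(base, myo), myo)
        ba = q.correction_a_fill_cores(q.correction_b_remove_noise(base, myo), myo)
        np.testing.assert_array_equal(ab.enhancement_mask, ba.enhancement_mask)


class TestPercentAndSalvage:
    def test_percent_simple_ratio(self):
        myo = _flat_myo(n_slices=2, size=20)  # 800 voxels, uniform geometry
        stack = _stack(np.zeros((2, 20, 20)))
        enh = np.zeros_like(myo.mask)
        enh[0].flat[:80] = True
        res = q.QuantResult(method="x", enhancement_mask=enh,
                            thresholds=np.full(2, np.nan))
        assert q.percent_lvm(res, myo, stack) == pytest.approx(10.0)

    def test_empty_enhancement_zero(self):
        myo = _flat_myo()
        stack = _stack(np.zeros((2, 20, 20)))
        res = q.QuantResult(method="x", enhancement_mask=np.zeros_like(myo.mask),
                            thresholds=np.full(2, np.nan))
        assert q.percent_lvm(res, myo, stack) == 0.0

    def test_manual_reference_mean(self):
        assert q.manual_reference([10, 12, 14, 10, 12, 14]) == pytest.approx(12.0)
        assert q.manual_reference([7.5]) == 7.5
        with pytest.raises(q.QuantError):
            q.manual_reference([10, 12], subjects=["A", "B"])

    def test_manual_reference_converges_with_replicates(self):
        """Mean of 6 jittered manual analyses approaches truth as SD/sqrt(6)."""
        rng = np.random.default_rng(21)
        truth = 20.0
        sd = 2.0
        means = [
            q.manual_reference(truth + rng.normal(0, sd, 6)) for _ in range(300)
        ]
        assert np.std(means) == pytest.approx(sd / np.sqrt(6), rel=0.15)
        assert np.mean(means) == pytest.approx(truth, abs=0.2)

    def test_salvage_index(self):
        assert q.salvage_index(40, 10).msi == pytest.approx(75.0)
        assert q.salvage_index(25, 25).msi == 0.0
        assert q.salvage_index(30, 0).msi == 100.0
        with pytest.raises(q.QuantError):
            q.salvage_index(0, 0)
        with pytest.warns(UserWarning, match="exceeds AAR"):
            assert q.salvage_index(10, 20).msi == pytest.approx(-100.0)


class TestRecoveryAndMonotonicity:
    def test_noise_free_every_threshold_recovers_truth(self):
        """With separable SI levels, any threshold between remote and infarct
        segments exactly the true infarct after corrections."""
        spec = PhantomSpec(noise_sd=0, blur_sigma_mm=0, mvo_fraction=0.15,
                           speckle_count=3, seed=2)
        lge, _, _, truth = generate_phantom(spec)
        myo = truth.to_myo_mask()
        sl, r, c = remote_seed(spec)
        roi = geo.build_roi(myo, lge, sl, (r, c))
        for k in (2, 5, 8):  # thresholds 100 < T < 400 (sigma = 0)
            res = q.quantify_stack(lge, myo, "ksd", remote_roi=roi, k=k)
            np.testing.assert_array_equal(
                res.enhancement_mask, truth.infarct_mask & myo.quantifiable_volume()
            )

    def test_ksd_monotone_in_k(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            spec = random_phantom_spec(rng)
            lge, _, _, truth = generate_phantom(spec)
            myo = truth.to_myo_mask()
            sl, r, c = remote_seed(spec)
            roi = geo.build_roi(myo, lge, sl, (r, c), avoid_rim_px=1)
            pcts = [
                q.quantify_stack(lge, myo, "ksd", remote_roi=roi, k=k).percent_lvm
                for k in (5, 6, 7, 8)
            ]
            assert pcts == sorted(pcts, reverse=True)

    def test_aar_2sd_and_otsu_on_t2w(self):
        """AAR on T2w recovers the oedema wedge in the separable case."""
        spec = PhantomSpec(noise_sd=0, blur_sigma_mm=0, mvo_fraction=0.1, seed=4)
        _, t2w, _, truth = generate_phantom(spec)
        myo = truth.to_myo_mask()
        sl, r, c = remote_seed(spec)
        roi = geo.build_roi(myo, t2w, sl, (r, c))
        for method, kw in (("ksd", {"remote_roi": roi, "k": 2}), ("otsu", {})):
            res = q.quantify_stack(t2w, myo, method, **kw)
            assert res.percent_lvm == pytest.approx(truth.true_aar_percent_lvm, abs=0.5)
        msi = q.salvage_index(truth.true_aar_percent_lvm, truth.true_is_percent_lvm)
        assert 0 <= msi.msi <= 100
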