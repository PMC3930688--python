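import numpy as np
import pytest

from clusteridif import idif, phantom, svca
from clusteridif.core_io import (
    TAC,
    BloodSampleSet,
    DynamicImage,
    MaskVolume,
    ValidationError,
)
from clusteridif.idif import (
    ParentFractionFit,
    PVCCoefficients,
    correct_pvc,
    extract_carotid_tac,
    extract_surround_tac,
    fit_parent_fraction,
    fit_pvc,
    fit_triexponential,
    metabolite_correct,
)
from clusteridif.svca import WeightMaps

from conftest import make_schedule


def _weights(shape, gray=0.0, white=0.0, blood=1.0):
    return WeightMaps(
        gray=np.full(shape, gray), white=np.full(shape, white), blood=np.full(shape, blood)
    )


def _img(vox, durations=None):
    vox = np.asarray(vox, float)
    durations = durations or [1.0] * vox.shape[3]
    return DynamicImage(vox, (2.0, 2.0, 2.0), make_schedule(durations))


class TestExtractCarotid:
    def test_identical_voxels_any_weights(self):
        vox = np.tile(np.array([5.0, 3.0, 1.0]), (4, 1, 1, 1))
        img = _img(vox)
        w = WeightMaps(
            gray=np.zeros((4, 1, 1)),
            white=np.zeros((4, 1, 1)),
            blood=np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1),
        )
        tac = extract_carotid_tac(img, MaskVolume(np.ones((4, 1, 1), bool)), w)
        np.testing.assert_allclose(tac.values, [5.0, 3.0, 1.0])

    def test_weighted_mean_arithmetic(self):
        # weights 1 and 3, values 2 and 6 -> (1*2 + 3*6)/4 = 5
        vox = np.array([[[[2.0]]], [[[6.0]]]])
        img = _img(vox)
        w = WeightMaps(
            gray=np.zeros((2, 1, 1)),
            white=np.zeros((2, 1, 1)),
            blood=np.array([1.0, 3.0]).reshape(2, 1, 1),
        )
        tac = extract_carotid_tac(img, MaskVolume(np.ones((2, 1, 1), bool)), w)
        assert tac.values[0] == pytest.approx(5.0)

    def test_blood_fraction_selection(self):
        vox = np.array([[[[2.0]]], [[[100.0]]]])
        img = _img(vox)
        w = WeightMaps(
            gray=np.array([0.0, 5.0]).reshape(2, 1, 1),
            white=np.zeros((2, 1, 1)),
            blood=np.array([1.0, 1.0]).reshape(2, 1, 1),
        )
        # voxel 1 has blood fraction 1/6 < 0.5 -> dropped
        tac = extract_carotid_tac(img, MaskVolume(np.ones((2, 1, 1), bool)), w)
        assert tac.values[0] == pytest.approx(2.0)

    def test_empty_selection_mentions_threshold(self):
        img = _img(np.ones((2, 1, 1, 1)))
        w = _weights((2, 1, 1), gray=1.0, blood=0.1)
        with pytest.raises(ValidationError, match="threshold|weight"):
            extract_carotid_tac(img, MaskVolume(np.ones((2, 1, 1), bool)), w)

    def test_unblurred_phantom_recovers_truth_exactly(
        self, small_phantom_sharp, small_templates
    ):
        img, truth = small_phantom_sharp
        std = svca.standardize_frames(img)
        w = svca.solve_weights(std, small_templates, truth.carotid_mask)
        tac = extract_carotid_tac(img, truth.carotid_mask, w)
        np.testing.assert_allclose(
            tac.values, truth.whole_blood_frames.values, atol=1e-9
        )


class TestExtractSurround:
    def test_uniform_surround(self):
        img = _img(np.full((3, 1, 1, 2), 4.0), [1.0, 1.0])
        w = _weights((3, 1, 1), gray=1.0, blood=0.0)
        tac = extract_surround_tac(img, MaskVolume(np.ones((3, 1, 1), bool)), w)
        np.testing.assert_allclose(tac.values, 4.0)

    def test_voxel_above_cutoff_excluded(self):
        img = _img(np.array([[[[1.0]]], [[[100.0]]]]))
        w = WeightMaps(
            gray=np.array([1.0, 1.0]).reshape(2, 1, 1),
            white=np.zeros((2, 1, 1)),
            blood=np.array([0.0, 0.002]).reshape(2, 1, 1),  # fraction ~0.002 > 0.001
        )
        tac = extract_surround_tac(img, MaskVolume(np.ones((2, 1, 1), bool)), w)
        assert tac.values[0] == pytest.approx(1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        vox = rng.random((5, 1, 1, 3))
        w = _weights((5, 1, 1), gray=1.0, blood=0.0)
        img = _img(vox)
        perm = _img(vox[::-1].copy())
        m = MaskVolume(np.ones((5, 1, 1), bool))
        np.testing.assert_allclose(
            extract_surround_tac(img, m, w).values,
            extract_surround_tac(perm, m, w).values,
        )

    def test_empty_selection_rejected(self):
        img = _img(np.ones((2, 1, 1, 1)))
        w = _weights((2, 1, 1), gray=1.0, blood=1.0)
        with pytest.raises(ValidationError):
            extract_surround_tac(img, MaskVolume(np.ones((2, 1, 1), bool)), w)


def _pvc_fixture(rc=0.55, sp=0.25, times=(6.0, 20.0, 60.0, 90.0)):
    t = np.arange(0.25, 91.0, 0.5)
    wb = 40.0 * np.exp(-0.05 * t) + 5.0 * np.exp(-0.005 * t)
    sur = 8.0 * (1.0 - np.exp(-0.2 * t)) * np.exp(-0.002 * t)
    carotid = TAC(t, rc * wb + sp * sur)
    surround = TAC(t, sur)
    ts = np.asarray(times)
    blood = BloodSampleSet(
        ts, np.interp(ts, t, wb), 0.9 * np.exp(-0.01 * ts), 0.08
    )
    return carotid, surround, blood


class TestFitPVC:
    def test_exact_recovery(self):
        carotid, surround, blood = _pvc_fixture()
        c = fit_pvc(carotid, surround, blood)
        assert c.rc == pytest.approx(0.55, rel=1e-10)
        assert c.sp == pytest.approx(0.25, rel=1e-10)
        assert c.n_samples == 4

    def test_identity_case(self):
        carotid, surround, blood = _pvc_fixture(rc=1.0, sp=0.0)
        c = fit_pvc(carotid, surround, blood)
        assert c.rc == pytest.approx(1.0, rel=1e-9)
        assert c.sp == pytest.approx(0.0, abs=1e-9)

    def test_three_sample_variant(self):
        carotid, surround, blood = _pvc_fixture(times=(6.0, 20.0, 60.0))
        c = fit_pvc(carotid, surround, blood)
        assert c.rc == pytest.approx(0.55, rel=1e-9)
        assert c.sp == pytest.approx(0.25, rel=1e-9)

    def test_collinear_design_rejected(self):
        t = np.arange(0.25, 91.0, 0.5)
        wb = 10.0 * np.exp(-0.01 * t)
        ts = np.array([6.0, 20.0, 60.0])
        blood = BloodSampleSet(ts, np.interp(ts, t, wb), np.full(3, 0.5), 0.05)
        surround = TAC(t, 2.0 * wb)  # proportional to whole blood
        carotid = TAC(t, wb)
        with pytest.raises(ValidationError, match="rank"):
            fit_pvc(carotid, surround, blood)

    def test_two_samples_minimum(self):
        with pytest.raises(ValidationError):
            BloodSampleSet([6.0], [20.0], [0.9], 0.05)

    def test_negative_sp_flagged_not_fatal(self):
        carotid, surround, blood = _pvc_fixture(rc=0.5, sp=-0.1)
        c = fit_pvc(carotid, surround, blood)
        assert c.sp_negative

    def test_sample_beyond_scan_rejected(self):
        carotid, surround, _ = _pvc_fixture()
        blood = BloodSampleSet([6.0, 200.0], [10.0, 1.0], [0.9, 0.5], 0.05)
        with pytest.raises(ValidationError, match="scan duration"):
            fit_pvc(carotid, surround, blood)


class TestCorrectPVC:
    def test_identity_coefficients(self):
        carotid, surround, _ = _pvc_fixture()
        out = correct_pvc(carotid, surround, PVCCoefficients(rc=1.0, sp=0.0))
        np.testing.assert_allclose(out.values, carotid.values)

    def test_forward_then_inverse_is_identity(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0.5, 90.0, 40)
        wb = TAC(t, rng.random(40) + 1.0)
        sur = TAC(t, rng.random(40))
        c = PVCCoefficients(rc=0.37, sp=0.44)
        forward = TAC(t, c.rc * wb.values + c.sp * sur.values)
        back = correct_pvc(forward, sur, c)
        np.testing.assert_allclose(back.values, wb.values, atol=1e-12)

    def test_nonpositive_rc_rejected(self):
        with pytest.raises(ValidationError):
            PVCCoefficients(rc=0.0, sp=0.1)


class TestParentFraction:
    def test_exact_monoexponential(self):
        t = np.array([6.0, 20.0, 60.0, 90.0])
        blood = BloodSampleSet(t, np.ones(4), 0.8 * np.exp(-0.02 * t), 0.05)
        fit = fit_parent_fraction(blood)
        assert fit.a == pytest.approx(0.8, abs=1e-6)
        assert fit.lam == pytest.approx(0.02, abs=1e-6)

    def test_constant_fraction_one(self):
        t = np.array([6.0, 20.0, 60.0])
        blood = BloodSampleSet(t, np.ones(3), np.ones(3), 0.05)
        fit = fit_parent_fraction(blood)
        assert fit.a == pytest.approx(1.0, abs=1e-9)
        assert fit.lam == pytest.approx(0.0, abs=1e-9)

    def test_evaluation_clamped_to_unit(self):
        fit = ParentFractionFit(a=1.05, lam=0.01)
        assert fit(0.0) == 1.0
        assert fit(500.0) < 1.0

    def test_all_zero_rejected(self):
        blood = BloodSampleSet([6.0, 20.0], [1.0, 1.0], [0.0, 0.0], 0.05)
        with pytest.raises(ValidationError):
            fit_parent_fraction(blood)


class TestMetaboliteCorrect:
    def test_unit_fraction_is_identity(self):
        tac = TAC([1.0, 2.0], [10.0, 5.0])
        out = metabolite_correct(tac, ParentFractionFit(a=1.0, lam=0.0))
        np.testing.assert_allclose(out.values, tac.values)

    def test_half_fraction(self):
        tac = TAC([1.0, 2.0], [10.0, 5.0])
        out = metabolite_correct(tac, ParentFractionFit(a=0.5, lam=0.0))
        np.testing.assert_allclose(out.values, [5.0, 2.5])

    def test_phantom_monoexponential_truth(self, small_phantom_sharp):
        _, truth = small_phantom_sharp
        blood = phantom.sample_blood(truth)
        fit = fit_parent_fraction(blood)
        wb = truth.whole_blood_frames
        out = metabolite_correct(wb, fit)
        np.testing.assert_allclose(
            out.values, truth.plasma_parent_frames.values, rtol=0.02, atol=1e-6
        )


class TestTriexponential:
    def _sampled(self, amps, rates, peak_time=1.0):
        t = np.concatenate([[0.25, 0.5, peak_time], np.arange(2.0, 91.0, 2.0)])
        tail = sum(a * np.exp(-r * t) for a, r in zip(amps, rates))
        rise = tail[2] * t / peak_time
        vals = np.where(t < peak_time, rise, tail)
        return TAC(t, vals)

    def test_recovers_known_triexponential(self):
        amps, rates = (40.0, 12.0, 3.0), (1.0, 0.1, 0.01)
        plasma = self._sampled(amps, rates)
        fn = fit_triexponential(plasma)
        tsel = plasma.times[plasma.times >= fn.peak_time]
        model = fn.tail(tsel)
        truth = sum(a * np.exp(-r * tsel) for a, r in zip(amps, rates))
        rmse = np.sqrt(np.mean((model - truth) ** 2))
        assert rmse <= 1e-3 * plasma.values.max()

    def test_single_exponential_degenerates_gracefully(self):
        plasma = self._sampled((30.0, 0.0, 0.0), (0.05, 1.0, 1.0))
        fn = fit_triexponential(plasma)
        tsel = plasma.times[plasma.times >= fn.peak_time]
        rmse = np.sqrt(np.mean((fn.tail(tsel) - 30.0 * np.exp(-0.05 * tsel)) ** 2))
        assert rmse <= 1e-3 * plasma.values.max()

    def test_fitted_tail_nonnegative(self):
        rng = np.random.default_rng(4)
        amps, rates = (40.0, 12.0, 3.0), (1.0, 0.1, 0.01)
        plasma = self._sampled(amps, rates)
        noisy = TAC(plasma.times, plasma.values + rng.normal(0, 0.5, plasma.values.size))
        fn = fit_triexponential(noisy)
        grid = np.linspace(fn.peak_time, 90.0, 2000)
        assert fn.tail(grid).min() >= 0.0

    def test_peak_at_last_sample_rejected(self):
        with pytest.raises(ValidationError, match="peak"):
            fit_triexponential(TAC([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))

    def test_piecewise_evaluation(self):
        plasma = self._sampled((40.0, 12.0, 3.0), (1.0, 0.1, 0.01))
        fn = fit_triexponential(plasma)
        # pre-peak: linear interpolation of measured samples from (0, 0)
        assert fn.evaluate(np.array([0.0]))[0] == 0.0
        mid = 0.5 * plasma.values[0]
        assert fn.evaluate(np.array([0.125]))[0] == pytest.approx(mid)


class TestLinearity:
    def test_scaling_image_scales_curves(self, small_phantom, small_templates):
        img, truth = small_phantom
        c = 2.5
        std = svca.standardize_frames(img)
        w = svca.solve_weights(std, small_templates, truth.carotid_mask)
        scaled_img = DynamicImage(img.voxels * c, img.voxel_size, img.schedule)
        tac1 = extract_carotid_tac(img, truth.carotid_mask, w)
        tac2 = extract_carotid_tac(scaled_img, truth.carotid_mask, w)
        np.testing.assert_allclose(tac2.values, c * tac1.values, rtol=1e-12)

    def test_rc_sp_invariant_under_scaling(self):
        carotid, surround, blood = _pvc_fixture()
        c = 3.0
        blood2 = BloodSampleSet(
            blood.times, blood.whole_blood * c, blood.parent_fraction, blood.f_p
        )
        c1 = fit_pvc(carotid, surround, blood)
        c2 = fit_pvc(
            TAC(carotid.times, carotid.values * c),
            TAC(surround.times, surround.values * c),
            blood2,
        )
        assert c2.rc == pytest.approx(c1.rc, rel=1e-9)
        assert c2.sp == pytest.approx(c1.sp, rel=1e-9)


class TestPhantomEndToEnd:
    def test_corrected_idif_auc_within_5pct(self, small_phantom, small_templates):
        img, truth = small_phantom
        std = svca.standardize_frames(img)
        from clusteridif import masks as masks_mod

        vt = masks_mod.average_blood_weights(
            [svca.solve_weights(std, small_templates).blood]
        )
        cmask = masks_mod.carotid_template_mask(vt)
        smask = masks_mod.surround_template_mask(cmask, img.voxel_size)
        analysis = MaskVolume(
            std.stats_mask.indicator | cmask.indicator | smask.indicator
        )
        w = svca.solve_weights(std, small_templates, analysis)
        carotid = extract_carotid_tac(img, cmask, w)
        surround = extract_surround_tac(img, smask, w)
        blood = phantom.sample_blood(truth)
        coeffs = fit_pvc(carotid, surround, blood)
        wb = correct_pvc(carotid, surround, coeffs)
        plasma = metabolite_correct(wb, fit_parent_fraction(blood))
        fn = fit_triexponential(plasma)
        auc = fn.auc(0.0, 90.0)
        auc_true = np.trapezoid(
            truth.plasma_parent_fine.values, truth.plasma_parent_fine.times
        )
        assert auc == pytest.approx(auc_true, rel=0.05)

    def test_rc_recovery_across_replicates(self, small_templates):
        # median relative RC error over noisy replicates <= 10%, against the
        # forward-blur oracle for the selected voxels
        from clusteridif.masks import surround_template_mask

        errors = []
        for i in range(12):
            spec = phantom.PhantomSpec.small(noise=0.5, seed=100 + i)
            img, truth = phantom.build_phantom(spec)
            std = svca.standardize_frames(img)
            surround_mask = surround_template_mask(truth.carotid_mask, spec.voxel_size)
            analysis = MaskVolume(
                truth.carotid_mask.indicator | surround_mask.indicator
            )
            w = svca.solve_weights(std, small_templates, analysis)
            frac = w.blood_fraction()
            sel = truth.carotid_mask.indicator & (frac > 0.5)
            if not sel.any():
                continue
            blur_ind = phantom.apply_psf(
                truth.carotid_mask.indicator.astype(float),
                spec.psf_fwhm_mm,
                spec.voxel_size,
            )
            wsel = w.blood[sel]
            rc_true = float((wsel * blur_ind[sel]).sum() / wsel.sum())
            carotid = extract_carotid_tac(img, truth.carotid_mask, w)
            surround = extract_surround_tac(img, surround_mask, w)
            coeffs = fit_pvc(carotid, surround, phantom.sample_blood(truth))
            errors.append(abs(coeffs.rc - rc_true) / rc_true)
        assert len(errors) >= 10
        assert np.median(errors) <= 0.10
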