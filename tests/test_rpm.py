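"""Basis-function SRTM fitting with vascular correction."""

import numpy as np
import pytest

from pkpet.cohort import BLOOD, GRAY_NONSPECIFIC, GRAY_SPECIFIC, WHITE_MATTER
from pkpet.kinetics import (
    InputError,
    SRTMParams,
    TimeActivityCurve,
    TissueKineticParams,
    ValidationError,
    add_noise,
    frame_average,
    srtm_forward,
    two_tissue_tac,
)
from pkpet.rpm import (
    STATUS_DEGENERATE,
    default_frame_weights,
    fit_srtm_vb,
    make_basis,
    parametric_map,
)

from oracles import dense_conv_oracle


@pytest.fixture(scope="module")
def ref_frame(class_tacs):
    return class_tacs[GRAY_NONSPECIFIC]


@pytest.fixture(scope="module")
def blood_frame(class_tacs):
    return class_tacs[BLOOD]


@pytest.fixture(scope="module")
def basis(ref_frame, schedule):
    return make_basis(ref_frame, schedule)


def bp_grid_tolerance(grid, k2, bp_true):
    """BP_ND uncertainty of one theta3 grid step around the true theta3."""
    theta = k2 / (1.0 + bp_true)
    j = int(np.clip(np.searchsorted(grid, theta), 1, grid.size - 1))
    return max(abs(k2 / grid[j - 1] - 1.0 - bp_true), abs(k2 / grid[j] - 1.0 - bp_true))


class TestMakeBasis:
    def test_large_theta3_impulse_limit(self, ref_frame, schedule):
        """For theta3 >> washout, Cr * e^(-theta3 t) -> Cr/theta3 at late times."""
        b = make_basis(ref_frame, schedule, theta3_min=6.0, theta3_max=12.0, n_basis=2)
        late = slice(-4, None)
        np.testing.assert_allclose(
            b.basis_curves[0, late], ref_frame.values[late] / 6.0, rtol=0.05
        )

    def test_small_theta3_matches_convolution_oracle(self, ref_frame, schedule, t_fine):
        b = make_basis(ref_frame, schedule, theta3_min=0.006, theta3_max=0.6, n_basis=4)
        anchor_t = np.concatenate([[0.0], ref_frame.times])
        anchor_v = np.concatenate([[0.0], ref_frame.values])
        cr_fine = np.interp(t_fine, anchor_t, anchor_v)
        conv = dense_conv_oracle(cr_fine, t_fine, 0.006)
        oracle = frame_average(TimeActivityCurve(t_fine, conv), schedule).values
        np.testing.assert_allclose(b.basis_curves[0], oracle, rtol=1e-5,
                                   atol=1e-5 * oracle.max())

    def test_basis_nonnegative_for_nonnegative_reference(self, basis):
        assert np.all(basis.basis_curves >= -1e-12)

    def test_invalid_bounds_rejected(self, ref_frame, schedule):
        with pytest.raises(ValidationError):
            make_basis(ref_frame, schedule, theta3_min=-0.1, theta3_max=0.6)
        with pytest.raises(ValidationError):
            make_basis(ref_frame, schedule, theta3_min=0.6, theta3_max=0.006)


class TestFitSrtmVb:
    def test_self_fit_identity(self, ref_frame, basis, blood_frame):
        res = fit_srtm_vb(ref_frame, basis, blood=blood_frame)
        assert res.params.r1 == pytest.approx(1.0, abs=1e-6)
        assert res.params.bp_nd == pytest.approx(0.0, abs=1e-6)
        assert res.params.vb == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_recovery_of_bp_and_vb(self, ref_tissue_fine, cb_fine, schedule):
        """Generator-as-oracle: recover (bp_nd, vb) from a noiseless SRTM TAC."""
        ref_frame = frame_average(ref_tissue_fine, schedule)
        b = make_basis(ref_frame, schedule)
        truth = SRTMParams.from_binding(1.0, 0.15, 0.5, 0.05)
        target = frame_average(srtm_forward(ref_tissue_fine, truth, cb=cb_fine), schedule)
        blood = frame_average(cb_fine, schedule)
        res = fit_srtm_vb(target, b, blood=blood)
        tol = bp_grid_tolerance(b.theta3_grid, truth.k2, truth.bp_nd)
        assert abs(res.params.bp_nd - 0.5) <= tol
        assert res.params.vb == pytest.approx(0.05, abs=0.005)

    def test_one_tissue_target_with_reference_kinetics_has_zero_binding(
        self, ref_frame, basis, blood_frame, cp_fine, cb_fine, schedule
    ):
        """A k3 = 0 voxel sharing the reference class kinetics fits to bp ~ 0."""
        p = TissueKineticParams(K1=0.10, k2t=0.20, k3=0.0, k4=0.0, vb=0.03)
        target = frame_average(two_tissue_tac(cp_fine, p, cb=cb_fine), schedule)
        res = fit_srtm_vb(target, basis, blood=blood_frame)
        assert abs(res.params.bp_nd) <= 0.02

    def test_all_zero_target_is_degenerate(self, basis, blood_frame, schedule):
        target = TimeActivityCurve(schedule.mid_times, np.zeros(schedule.n_frames))
        res = fit_srtm_vb(target, basis, blood=blood_frame)
        assert res.status == STATUS_DEGENERATE and res.params is None

    def test_plain_srtm_equals_independent_two_column_fit(
        self, ref_frame, basis, schedule, ref_tissue_fine
    ):
        """With the vascular term disabled the fit is exactly plain basis SRTM."""
        truth = SRTMParams.from_binding(0.9, 0.18, 0.3, 0.0)
        target = frame_average(srtm_forward(ref_tissue_fine, truth), schedule)
        res = fit_srtm_vb(target, basis, vascular=False)
        # independent oracle: per-theta3 weighted lstsq, explicit loop
        w = np.sqrt(default_frame_weights(schedule))
        best = None
        for j, theta3 in enumerate(basis.theta3_grid):
            a = np.column_stack([basis.reference_tac.values, basis.basis_curves[j]])
            coef, *_ = np.linalg.lstsq(a * w[:, None], target.values * w, rcond=None)
            rss = float(((target.values * w - (a * w[:, None]) @ coef) ** 2).sum())
            if best is None or rss < best[0] - 0.0:
                best = (rss, j, coef)
        assert res.theta3_index == best[1]
        assert res.params.r1 == pytest.approx(best[2][0], abs=1e-10)
        assert res.params.k2 == pytest.approx(
            best[2][1] + best[2][0] * basis.theta3_grid[best[1]], abs=1e-10
        )

    def test_scale_invariance(self, ref_frame, basis, blood_frame, class_tacs, schedule):
        target = class_tacs[GRAY_SPECIFIC]
        res1 = fit_srtm_vb(target, basis, blood=blood_frame)
        c = 137.0
        ref_s = ref_frame.with_values(c * ref_frame.values)
        basis_s = make_basis(ref_s, schedule)
        res2 = fit_srtm_vb(target.with_values(c * target.values), basis_s,
                           blood=blood_frame.with_values(c * blood_frame.values))
        assert res2.params.bp_nd == pytest.approx(res1.params.bp_nd, abs=1e-8)
        assert res2.params.r1 == pytest.approx(res1.params.r1, abs=1e-8)
        assert res2.params.k2 == pytest.approx(res1.params.k2, abs=1e-8)
        assert res2.params.vb == pytest.approx(res1.params.vb, abs=1e-8)

    def test_monotone_refinement_on_nested_grids(self, ref_frame, schedule, blood_frame,
                                                 class_tacs):
        """A log-grid refinement containing the coarse grid never increases RSS."""
        target = class_tacs[GRAY_SPECIFIC]
        coarse = make_basis(ref_frame, schedule, n_basis=17)
        fine = make_basis(ref_frame, schedule, n_basis=33)  # superset of coarse
        assert np.allclose(fine.theta3_grid[::2], coarse.theta3_grid)
        r_coarse = fit_srtm_vb(target, coarse, blood=blood_frame).rss
        r_fine = fit_srtm_vb(target, fine, blood=blood_frame).rss
        assert r_fine <= r_coarse + 1e-12

    def test_parameter_recovery_bias_over_bp_noise_grid(
        self, ref_tissue_fine, cb_fine, schedule
    ):
        """Mean bias of fitted bp over 100 replicates per (bp, noise) cell."""
        ref_frame = frame_average(ref_tissue_fine, schedule)
        b = make_basis(ref_frame, schedule)
        blood = frame_average(cb_fine, schedule)
        rng_seed = 100
        for bp_true in (0.0, 0.15, 0.5):
            truth = SRTMParams.from_binding(1.0, 0.2, bp_true, 0.03)
            clean = frame_average(srtm_forward(ref_tissue_fine, truth, cb=cb_fine), schedule)
            tol0 = 0.02 + bp_grid_tolerance(b.theta3_grid, truth.k2, bp_true)
            for alpha in (0.0, 0.1, 0.3):
                n_rep = 1 if alpha == 0 else 100
                fitted = []
                for r in range(n_rep):
                    noisy = add_noise(clean, schedule, alpha, seed=rng_seed + r)
                    res = fit_srtm_vb(noisy, b, blood=blood)
                    fitted.append(res.params.bp_nd)
                bias = abs(np.mean(fitted) - bp_true)
                assert bias <= (tol0 if alpha == 0 else 0.05 + tol0 - 0.02), (
                    f"bp={bp_true}, alpha={alpha}, bias={bias}"
                )


class TestParametricMap:
    def test_noiseless_phantom_bp_error(self, noiseless_phantom, class_tacs):
        ph = noiseless_phantom
        maps = parametric_map(ph.image, class_tacs[GRAY_NONSPECIFIC],
                              class_tacs[BLOOD], ph.mask, ph.schedule)
        sel = ph.class_map == GRAY_SPECIFIC
        med = np.median(np.abs(maps.bp_nd[sel] - ph.bp_true[sel]))
        assert med <= 0.02

    def test_blood_voxels_fit_high_vb(self, noiseless_phantom, class_tacs):
        ph = noiseless_phantom
        maps = parametric_map(ph.image, class_tacs[GRAY_NONSPECIFIC],
                              class_tacs[BLOOD], ph.mask, ph.schedule)
        assert np.all(maps.vb[ph.class_map == BLOOD] >= 0.9)

    def test_single_voxel_mask_bookkeeping(self, noiseless_phantom, class_tacs):
        ph = noiseless_phantom
        mask = np.zeros_like(ph.mask)
        inside = np.argwhere(ph.class_map == WHITE_MATTER)[0]
        mask[tuple(inside)] = True
        maps = parametric_map(ph.image, class_tacs[GRAY_NONSPECIFIC],
                              class_tacs[BLOOD], mask, ph.schedule)
        assert np.isfinite(maps.bp_nd).sum() == 1

    def test_frame_mismatch_rejected(self, noiseless_phantom, class_tacs, schedule):
        ph = noiseless_phantom
        bad_ref = TimeActivityCurve(schedule.mid_times[:-1] / 2.0,
                                    class_tacs[0].values[:-1])
        with pytest.raises(InputError):
            parametric_map(ph.image, bad_ref, class_tacs[BLOOD], ph.mask, ph.schedule)
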