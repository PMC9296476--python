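"""SRTM forward model, frame binning and basis-function fitting."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hdacscope.core import DynamicImage, FrameSchedule, KineticParams
from hdacscope.kinetics import (
    BasisGrid,
    bin_frames,
    fit_srtm,
    fit_srtm_volume,
    make_r1_map,
    regional_tacs,
    srtm_forward,
)
from hdacscope.synthetic_data import simulate_dynamic_pet


class TestFrameSchedule:
    def test_paper_binning_has_26_frames_totalling_5400s(self, schedule):
        assert schedule.n_frames == 26
        assert schedule.total_duration == 5400.0
        # 6x10, 6x20, 2x30, 1x60, 5x300, 6x600
        expected = [10.0] * 6 + [20.0] * 6 + [30.0] * 2 + [60.0] + [300.0] * 5 + [600.0] * 6
        assert np.array_equal(schedule.durations, expected)

    @pytest.mark.parametrize(
        "starts,durations",
        [
            ([0.0, 5.0], [10.0, 10.0]),     # overlapping
            ([0.0, 10.0], [10.0, -1.0]),    # negative duration
            ([10.0, 0.0], [5.0, 5.0]),      # decreasing starts
        ],
    )
    def test_invalid_schedules_rejected(self, starts, durations):
        with pytest.raises(ValueError):
            FrameSchedule(starts, durations)


class TestSrtmForward:
    def test_unit_delivery_no_binding_reproduces_reference(self, schedule, ref_tac):
        """R1=1, BP=0 zeroes the convolution coefficient: output == reference."""
        out = srtm_forward(KineticParams(1.0, 0.1, 0.0), ref_tac, schedule)
        assert np.array_equal(out, ref_tac)

    def test_zero_parameters_give_zero_curve(self, schedule, ref_tac):
        out = srtm_forward(KineticParams(0.0, 0.0, 0.0), ref_tac, schedule)
        assert np.allclose(out, 0.0)

    def test_matches_ode_integration(self, schedule):
        """Frame means agree with a numeric ODE solution of the model within 0.5%."""
        A1, l1, l2 = 50.0, 4e-4, 0.02
        cr = lambda t: A1 * (np.exp(-l1 * t) - np.exp(-l2 * t))
        cr_prime = lambda t: A1 * (-l1 * np.exp(-l1 * t) + l2 * np.exp(-l2 * t))
        params = KineticParams(0.8, 0.1, 0.5)
        R1 = params.R1
        k2 = params.k2_per_min / 60.0
        k2a = params.k2a_per_min / 60.0

        def rhs(t, y):
            return [R1 * cr_prime(t) + k2 * cr(t) - k2a * y[0]]

        t_fine = np.arange(0.0, 5400.0 + 1.0)
        sol = solve_ivp(rhs, (0.0, 5400.0), [0.0], t_eval=t_fine, rtol=1e-10, atol=1e-12)
        frame_means = np.array(
            [
                np.trapezoid(
                    sol.y[0][int(s) : int(s + d) + 1], dx=1.0
                )
                / d
                for s, d in zip(schedule.starts, schedule.durations)
            ]
        )
        ref_frames = np.array(
            [
                np.trapezoid(cr(np.arange(s, s + d + 1.0)), dx=1.0) / d
                for s, d in zip(schedule.starts, schedule.durations)
            ]
        )
        out = srtm_forward(params, ref_frames, schedule, ref_fine=cr(t_fine))
        assert np.max(np.abs(out - frame_means) / np.max(frame_means)) < 0.005

    def test_linear_in_reference_curve(self, schedule, ref_tac):
        params = KineticParams(0.9, 0.12, 0.4)
        a, b = 2.5, -0.7
        other = np.linspace(1.0, 3.0, schedule.n_frames)
        combined = srtm_forward(params, a * ref_tac + b * other, schedule)
        split = a * srtm_forward(params, ref_tac, schedule) + b * srtm_forward(
            params, other, schedule
        )
        assert np.allclose(combined, split, rtol=1e-10, atol=1e-10)


class TestBinFrames:
    def _dyn(self, values, durations, affine=np.eye(4)):
        sched = FrameSchedule.from_durations(durations)
        data = np.asarray(values, dtype=float).reshape(1, 1, 1, -1)
        return DynamicImage(data, affine, sched)

    def test_identity_rebin(self, schedule, ref_tac):
        dyn = DynamicImage(ref_tac.reshape(1, 1, 1, -1), np.eye(4), schedule)
        out = bin_frames(dyn, schedule)
        assert np.allclose(out.data, dyn.data)

    def test_weighted_mean_of_two_frames(self):
        dyn = self._dyn([1.0, 3.0], [10.0, 10.0])
        target = FrameSchedule([0.0], [20.0])
        out = bin_frames(dyn, target)
        assert out.data[0, 0, 0, 0] == pytest.approx(2.0)

    def test_activity_time_integral_conserved(self):
        rng = np.random.default_rng(42)
        durations = [10.0] * 6 + [30.0] * 4
        values = rng.uniform(0.5, 5.0, size=10)
        dyn = self._dyn(values, durations)
        target = FrameSchedule.from_durations([60.0, 120.0])
        out = bin_frames(dyn, target)
        src_integral = np.sum(values * np.asarray(durations))
        dst_integral = np.sum(out.data[0, 0, 0] * target.durations)
        assert dst_integral == pytest.approx(src_integral, rel=1e-12)

    @pytest.mark.parametrize("start,dur", [(5.0, 10.0), (0.0, 15.0)])
    def test_non_decomposable_target_rejected(self, start, dur):
        dyn = self._dyn([1.0, 2.0], [10.0, 10.0])
        with pytest.raises(ValueError, match="frame"):
            bin_frames(dyn, FrameSchedule([start], [dur]))


class TestFitSrtm:
    @pytest.mark.parametrize(
        "r1,k2,bp", [(0.8, 0.10, 0.5), (1.2, 0.12, 0.3), (0.7, 0.15, 1.0)]
    )
    def test_noiseless_roundtrip_within_one_percent(self, schedule, ref_tac, r1, k2, bp):
        tac = srtm_forward(KineticParams(r1, k2, bp), ref_tac, schedule)
        fit = fit_srtm(tac, ref_tac, schedule)
        assert fit.params.R1 == pytest.approx(r1, rel=0.01)
        assert fit.params.k2_per_min == pytest.approx(k2, rel=0.01)
        assert fit.params.BP == pytest.approx(bp, rel=0.01)

    def test_reference_identical_target_degenerate(self, schedule, ref_tac):
        fit = fit_srtm(ref_tac, ref_tac, schedule)
        assert fit.params.R1 == pytest.approx(1.0, abs=1e-8)
        assert fit.params.BP == 0.0
        assert fit.params.degenerate

    def test_single_candidate_at_true_k2a_recovers_linear_params(self, schedule, ref_tac):
        params = KineticParams(0.8, 0.1, 0.5)
        tac = srtm_forward(params, ref_tac, schedule)
        grid = BasisGrid(params.k2a_per_min, params.k2a_per_min * 1.0001, 1)
        fit = fit_srtm(tac, ref_tac, schedule, grid=grid)
        assert fit.params.R1 == pytest.approx(0.8, rel=1e-6)
        assert fit.params.k2_per_min == pytest.approx(0.1, rel=1e-6)
        # residual at machine precision relative to the curve's scale
        assert fit.wrss <= 1e-12 * np.sum(schedule.durations * tac**2)

    def test_residual_nonincreasing_under_grid_refinement(self, schedule, ref_tac):
        tac = srtm_forward(KineticParams(0.8, 0.1, 0.5), ref_tac, schedule)
        wrss = [
            fit_srtm(
                tac, ref_tac, schedule, grid=BasisGrid(n=n), refine_rounds=0
            ).wrss
            for n in (4, 8, 16, 32, 64)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(wrss, wrss[1:]))

    def test_noisy_fits_unbiased(self, schedule, ref_tac):
        """Mean over 200 noisy replicates recovers truth within 3% at 5% noise."""
        rng = np.random.default_rng(7)
        truth = KineticParams(0.8, 0.1, 0.5)
        clean = srtm_forward(truth, ref_tac, schedule)
        frame_sd = 0.05 * clean.max() / np.sqrt(schedule.durations / schedule.durations.max())
        Y = clean + rng.standard_normal((200, schedule.n_frames)) * frame_sd
        R1, k2, BP, _, _ = fit_srtm_volume(Y, ref_tac, schedule)
        assert np.mean(R1) == pytest.approx(truth.R1, rel=0.03)
        assert np.mean(k2) == pytest.approx(truth.k2_per_min, rel=0.03)
        assert np.mean(BP) == pytest.approx(truth.BP, rel=0.03)

    def test_zero_reference_rejected(self, schedule):
        with pytest.raises(ValueError, match="reference"):
            fit_srtm(np.ones(schedule.n_frames), np.zeros(schedule.n_frames), schedule)

    def test_nonfinite_tac_rejected(self, schedule, ref_tac):
        bad = ref_tac.copy()
        bad[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_srtm(bad, ref_tac, schedule)


class TestMakeR1Map:
    def test_uniform_kinetics_give_unit_r1(self, three_region_map, three_region_spec, schedule, ref_tac):
        dyn = simulate_dynamic_pet(
            three_region_map,
            {},
            ref_tac,
            schedule,
            noise_sd=0.0,
            reference_labels=[1, 2, 3],
        )
        brain = three_region_map.data > 0
        img = make_r1_map(dyn, three_region_map.mask(2), brain, grid=BasisGrid(n=16))
        assert np.allclose(img.data[brain], 1.0, atol=1e-6)

    def test_two_region_roundtrip_and_mask_contract(
        self, three_region_map, three_region_spec, schedule, ref_tac, kinetic_truth
    ):
        dyn = simulate_dynamic_pet(
            three_region_map,
            kinetic_truth,
            ref_tac,
            schedule,
            noise_sd=0.0,
            reference_labels=[2],
        )
        brain = three_region_map.data > 0
        img = make_r1_map(dyn, three_region_map.mask(2), brain)
        for label, truth in kinetic_truth.items():
            vals = img.data[three_region_map.data == label]
            assert np.nanmean(vals) == pytest.approx(truth.R1, rel=0.01)
        # voxels outside the mask are never fitted
        assert np.isnan(img.data[~brain]).all()

    def test_empty_reference_rejected(self, three_region_map, schedule, ref_tac):
        dyn = simulate_dynamic_pet(
            three_region_map, {}, ref_tac, schedule, reference_labels=[1, 2, 3]
        )
        with pytest.raises(ValueError, match="reference"):
            make_r1_map(dyn, np.zeros(three_region_map.data.shape, bool),
                        three_region_map.data > 0)


class TestRegionalTacs:
    def test_single_label_equals_global_mean(self, three_region_map, schedule, ref_tac):
        rng = np.random.default_rng(3)
        lone = np.ones(three_region_map.data.shape, dtype=np.int32)
        from hdacscope.core import DynamicImage, LabelMap

        labelmap = LabelMap(lone, three_region_map.affine)
        data = rng.uniform(0, 2, size=lone.shape + (schedule.n_frames,))
        dyn = DynamicImage(data, three_region_map.affine, schedule)
        tacs = regional_tacs(dyn, labelmap, {"all": 1})
        expected = data.reshape(-1, schedule.n_frames).mean(axis=0)
        got = tacs.sort_values("frame")["value"].to_numpy()
        assert np.allclose(got, expected)

    def test_constant_region_yields_constant_curve(self, three_region_map, schedule):
        from hdacscope.core import DynamicImage

        data = np.zeros(three_region_map.data.shape + (schedule.n_frames,))
        data[three_region_map.data == 1] = 3.0
        dyn = DynamicImage(data, three_region_map.affine, schedule)
        tacs = regional_tacs(dyn, three_region_map, {"target": 1})
        assert np.allclose(tacs["value"], 3.0)
        assert (tacs["n_voxels"] == 216).all()

    def test_region_means_match_bruteforce(self, three_region_map, schedule):
        from hdacscope.core import DynamicImage

        rng = np.random.default_rng(11)
        data = rng.standard_normal(three_region_map.data.shape + (schedule.n_frames,))
        dyn = DynamicImage(data, three_region_map.affine, schedule)
        tacs = regional_tacs(dyn, three_region_map, {"a": 1, "b": 3})
        for name, label in [("a", 1), ("b", 3)]:
            sub = tacs[tacs.region == name].sort_values("frame")["value"].to_numpy()
            brute = np.array(
                [
                    data[..., f][three_region_map.data == label].mean()
                    for f in range(schedule.n_frames)
                ]
            )
            assert np.allclose(sub, brute)

    def test_absent_label_named_in_error(self, three_region_map, schedule):
        from hdacscope.core import DynamicImage

        data = np.zeros(three_region_map.data.shape + (schedule.n_frames,))
        dyn = DynamicImage(data, three_region_map.affine, schedule)
        with pytest.raises(ValueError, match="99"):
            regional_tacs(dyn, three_region_map, {"ghost": 99})
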