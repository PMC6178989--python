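"""Kinetic models against analytic constructions and ODE-generated truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petquant as pq
from petquant.kinetics import (TAC, KineticsError, running_integral,
                               tac_from_values)
from petquant.phantom import default_frame_schedule, simulate_tacs


@pytest.fixture(scope="module")
def schedule():
    return default_frame_schedule()


@pytest.fixture(scope="module")
def mids(schedule):
    starts, durs = schedule
    return starts + durs / 2


@pytest.fixture(scope="module")
def cref(schedule):
    starts, durs = schedule
    activity, _ = simulate_tacs("reference", {}, starts, durs)
    return activity


def _tac(mids, values, durs=None):
    return TAC(mids, values, durs)


class TestExtractTac:
    def test_constant_region(self, small_labels):
        frames = np.full(small_labels.labels.shape + (4,), 5.0)
        pet = pq.DynamicPET(frames, small_labels.affine, np.arange(4.0),
                            np.ones(4))
        tac = pq.extract_tac(pet, small_labels, 2)
        np.testing.assert_allclose(tac.activity, 5.0)
        np.testing.assert_allclose(tac.frame_mid_times, np.arange(4.0) + 0.5)

    def test_matches_brute_force_mean(self, small_labels):
        rng = np.random.default_rng(0)
        frames = rng.random(small_labels.labels.shape + (4,))
        pet = pq.DynamicPET(frames, small_labels.affine, np.arange(4.0),
                            np.ones(4))
        tac = pq.extract_tac(pet, small_labels, 1)
        mask = small_labels.labels == 1
        expect = np.array([frames[..., k][mask].mean() for k in range(4)])
        np.testing.assert_allclose(tac.activity, expect, rtol=1e-12)

    def test_absent_region_rejected(self, small_labels):
        pet = pq.DynamicPET(np.zeros(small_labels.labels.shape + (3,)),
                            small_labels.affine, np.arange(3.0), np.ones(3))
        with pytest.raises(KineticsError, match="absent"):
            pq.extract_tac(pet, small_labels, 9)


class TestTacIntegral:
    def test_constant_activity(self):
        t = np.linspace(0.5, 10.0, 20)
        tac = _tac(t, np.ones(20))
        # 0-anchored: the first segment rises from 0 to 1 over 0.5 min
        assert pq.tac_integral(tac, 10.0) == pytest.approx(10.0 - 0.25, abs=1e-9)

    def test_linear_activity_closed_form(self):
        t = np.linspace(0.05, 10.0, 400)
        tac = _tac(t, t.copy())
        assert pq.tac_integral(tac, 10.0) == pytest.approx(50.0, rel=1e-4)

    def test_single_leading_trapezoid(self):
        t = np.array([2.0, 4.0, 6.0])
        tac = _tac(t, np.array([3.0, 5.0, 7.0]))
        assert pq.tac_integral(tac, 2.0) == pytest.approx(2.0 * 3.0 / 2.0)

    def test_T_outside_range_rejected(self):
        tac = _tac(np.array([1.0, 2.0, 3.0]), np.ones(3))
        with pytest.raises(KineticsError):
            pq.tac_integral(tac, 0.5)
        with pytest.raises(KineticsError):
            pq.tac_integral(tac, 4.0)


class TestLogan:
    def test_proportional_curves_force_slope(self, mids, cref):
        fit = pq.logan(_tac(mids, 2.0 * cref), _tac(mids, cref), t_star=20.0)
        assert fit.parameters["DVR"] == pytest.approx(2.0, abs=1e-9)
        assert fit.parameters["BPnd"] == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_recovers_bpnd_from_srtm_simulation(self, schedule, mids, cref):
        starts, durs = schedule
        ct, _ = simulate_tacs("reversible",
                              {"R1": 1.0, "k2": 0.3, "BPnd": 1.5}, starts, durs)
        fit = pq.logan(_tac(mids, ct), _tac(mids, cref), t_star=20.0)
        assert fit.parameters["BPnd"] == pytest.approx(1.5, rel=0.05)

    def test_t_star_beyond_scan_rejected(self, mids, cref):
        with pytest.raises(KineticsError, match="t_star"):
            pq.logan(_tac(mids, cref), _tac(mids, cref), t_star=120.0)

    def test_dvr_monotone_in_simulated_bpnd(self, schedule, mids, cref):
        starts, durs = schedule
        dvrs = []
        for bpnd in (0.5, 1.0, 2.0):
            ct, _ = simulate_tacs("reversible",
                                  {"R1": 1.0, "k2": 0.1, "BPnd": bpnd},
                                  starts, durs)
            dvrs.append(pq.logan(_tac(mids, ct), _tac(mids, cref),
                                 t_star=20.0).parameters["DVR"])
        assert dvrs[0] < dvrs[1] < dvrs[2]

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(0.1, 50.0))
    def test_scale_invariance(self, mids, cref, scale):
        base = pq.logan(_tac(mids, 2.0 * cref), _tac(mids, cref), 20.0)
        scaled = pq.logan(_tac(mids, 2.0 * scale * cref),
                          _tac(mids, scale * cref), 20.0)
        assert scaled.parameters["DVR"] == pytest.approx(
            base.parameters["DVR"], rel=1e-9)


class TestPatlak:
    def test_constructed_ki_and_intercept(self, mids, cref):
        ct = 0.01 * running_integral(mids, cref) + 1.0 * cref
        fit = pq.patlak(_tac(mids, ct), _tac(mids, cref), t_star=20.0)
        assert fit.parameters["Ki"] == pytest.approx(0.01, abs=1e-12)
        assert fit.parameters["V"] == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared > 0.999

    def test_irreversible_archetype_round_trip(self, schedule, mids, cref):
        starts, durs = schedule
        ct, truth = simulate_tacs("irreversible", {"Ki": 0.02, "V": 0.8},
                                  starts, durs)
        fit = pq.patlak(_tac(mids, ct), _tac(mids, cref), t_star=20.0)
        assert fit.parameters["Ki"] == pytest.approx(truth["Ki"], rel=0.05)

    def test_t_star_insensitive_past_equilibrium(self, schedule, mids, cref):
        starts, durs = schedule
        ct, _ = simulate_tacs("irreversible", {"Ki": 0.01, "V": 1.0},
                              starts, durs)
        k20 = pq.patlak(_tac(mids, ct), _tac(mids, cref), 20.0).parameters["Ki"]
        k30 = pq.patlak(_tac(mids, ct), _tac(mids, cref), 30.0).parameters["Ki"]
        assert abs(k30 - k20) / k20 < 0.02

    def test_zero_input_in_window_rejected(self, mids):
        cin = np.where(mids < 30, 1.0, 0.0)
        with pytest.raises(KineticsError, match="nonpositive input"):
            pq.patlak(_tac(mids, np.ones_like(mids)), _tac(mids, cin), 20.0)


class TestSRTM:
    @pytest.mark.parametrize("params", [
        {"R1": 1.0, "k2": 0.1, "BPnd": 1.5},
        {"R1": 0.8, "k2": 0.15, "BPnd": 0.5},
    ])
    def test_noiseless_recovery_within_3_percent(self, schedule, mids, cref,
                                                 params):
        starts, durs = schedule
        ct, _ = simulate_tacs("reversible", params, starts, durs)
        fit = pq.srtm(_tac(mids, ct, durs), _tac(mids, cref, durs))
        for key in ("R1", "k2", "BPnd"):
            assert fit.parameters[key] == pytest.approx(params[key], rel=0.03)

    def test_zero_binding_recovered_near_zero(self, schedule, mids, cref):
        starts, durs = schedule
        ct, _ = simulate_tacs("reversible", {"R1": 1.0, "k2": 0.1, "BPnd": 0.0},
                              starts, durs)
        fit = pq.srtm(_tac(mids, ct, durs), _tac(mids, cref, durs))
        assert abs(fit.parameters["BPnd"]) < 0.05

    def test_degenerate_grid_rejected(self, mids, cref):
        with pytest.raises(KineticsError, match="grid"):
            pq.srtm(_tac(mids, cref), _tac(mids, cref), k2a_grid=[0.1])

    def test_boundary_optimum_warns(self, schedule, mids, cref):
        starts, durs = schedule
        ct, _ = simulate_tacs("reversible", {"R1": 1.0, "k2": 0.1, "BPnd": 1.5},
                              starts, durs)
        with pytest.warns(UserWarning, match="bracket"):
            pq.srtm(_tac(mids, ct), _tac(mids, cref),
                    k2a_grid=np.linspace(0.2, 1.0, 10))


class TestSUVR:
    def test_flat_curves(self, mids):
        durs = np.ones_like(mids)
        fit = pq.suvr(_tac(mids, np.full_like(mids, 2.0), durs),
                      _tac(mids, np.ones_like(mids), durs), (30, 60))
        assert fit.parameters["SUVR"] == pytest.approx(2.0)

    def test_scale_invariance(self, mids, cref):
        durs = np.ones_like(mids)
        a = pq.suvr(_tac(mids, 2 * cref + 1, durs), _tac(mids, cref + 1, durs),
                    (30, 60)).parameters["SUVR"]
        b = pq.suvr(_tac(mids, 7 * (2 * cref + 1), durs),
                    _tac(mids, 7 * (cref + 1), durs), (30, 60)).parameters["SUVR"]
        assert a == pytest.approx(b, rel=1e-12)

    def test_two_frame_window_hand_computed(self):
        mids = np.array([1.0, 3.0, 5.0, 7.0])
        durs = np.array([2.0, 2.0, 2.0, 4.0])
        tgt = np.array([1.0, 2.0, 6.0, 12.0])
        ref = np.array([1.0, 1.0, 2.0, 4.0])
        # window [4, 8] covers the last two frames
        num = (6.0 * 2 + 12.0 * 4) / 6.0
        den = (2.0 * 2 + 4.0 * 4) / 6.0
        fit = pq.suvr(TAC(mids, tgt, durs), TAC(mids, ref, durs), (4, 8))
        assert fit.parameters["SUVR"] == pytest.approx(num / den, rel=1e-12)
        assert fit.n_points_used == 2

    def test_empty_window_rejected(self, mids, cref):
        with pytest.raises(KineticsError, match="window"):
            pq.suvr(_tac(mids, cref), _tac(mids, cref), (100, 120))


class TestVoxelwiseMap:
    def test_voxel_estimates_match_roi_estimates_on_flat_phantom(
            self, small_labels, schedule):
        starts, durs = schedule
        mids = starts + durs / 2
        cref, _ = simulate_tacs("reference", {}, starts, durs)
        lut = np.array([0.0, 1.0, 2.0])  # region 2 has double the reference
        frames = lut[small_labels.labels][..., None] * cref[None, None, None, :]
        pet = pq.DynamicPET(frames, small_labels.affine, starts, durs)
        input_tac = tac_from_values(pet, cref)
        vmap, failures = pq.voxelwise_map(pet, input_tac, "logan", t_star=20.0)
        region2 = small_labels.labels == 2
        roi_fit = pq.logan(pq.extract_tac(pet, small_labels, 2), input_tac, 20.0)
        np.testing.assert_allclose(vmap.data[region2],
                                   roi_fit.parameters["DVR"], atol=1e-6)
        assert not failures[region2].any()
        # background voxels are all-zero: masked out, value 0
        assert failures[small_labels.labels == 0].all()
        assert np.all(vmap.data[small_labels.labels == 0] == 0)
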