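"""Phantom generator: geometry, archetype kinetics, forward model, noise."""

import numpy as np
import pytest

import petquant as pq
from petquant.kinetics import TAC, running_integral
from petquant.phantom import (PhantomError, RegionSpec, default_frame_schedule,
                              simulate_tacs, static_observation)


class TestLabelPhantom:
    def test_putamen_volume_matches_analytic_ellipsoid(self, spec, labels):
        rid = [k for k, v in labels.name_map.items() if v == "putamen"][0]
        voxels = int((labels.labels == rid).sum())
        a, b, c = 12.4, 8.8, 8.8
        analytic = 4.0 / 3.0 * np.pi * a * b * c
        assert voxels * spec.voxel_size_mm ** 3 == pytest.approx(analytic,
                                                                 rel=0.10)
        assert analytic > 4000.0  # ~4 cm^3, a realistic putamen size

    def test_each_voxel_has_exactly_one_label(self, labels):
        # rasterization is single-assignment by construction; all present
        # region ids are disjoint and the named regions exist
        present = set(np.unique(labels.labels))
        assert {0, 1, 2, 3, 4, 5} == present

    def test_determinism(self, spec, labels):
        again = pq.make_label_phantom(pq.PhantomSpec())
        np.testing.assert_array_equal(again.labels, labels.labels)

    def test_overlapping_primitives_rejected(self):
        spec = pq.PhantomSpec(regions=[
            RegionSpec("a", 1, "ellipsoid", (0, 0, 0), (10, 10, 10)),
            RegionSpec("b", 2, "ellipsoid", (5, 0, 0), (10, 10, 10)),
        ])
        with pytest.raises(PhantomError, match="overlap"):
            pq.make_label_phantom(spec)

    def test_foreground_clears_the_psf_margin(self, spec, labels):
        """All labeled voxels sit >= 3 sigma (of the 6.5 mm PSF) from the
        grid edges so blurring loses no activity off the volume."""
        sigma = 6.5 / (2 * np.sqrt(2 * np.log(2)))
        margin_vox = int(np.ceil(3 * sigma / spec.voxel_size_mm))
        fg = labels.labels > 0
        assert not fg[:margin_vox].any() and not fg[-margin_vox:].any()
        assert not fg[:, :margin_vox].any() and not fg[:, -margin_vox:].any()
        assert not fg[:, :, :margin_vox].any() and not fg[:, :, -margin_vox:].any()


class TestArchetypes:
    def test_reference_curve_starts_at_zero_and_peaks(self):
        starts, durs = default_frame_schedule()
        activity, _ = simulate_tacs("reference", {}, starts, durs)
        assert activity[0] < activity.max() * 0.2
        mids = starts + durs / 2
        assert 5.0 < mids[np.argmax(activity)] < 30.0

    def test_reversible_equilibrium_ratio_approaches_dvr(self):
        """With a slowly varying input and enough scan time (several 1/k2a),
        the target/reference ratio settles at the DVR.  With k2a = 0.04 /min
        equilibration takes hours, hence the long schedule here; on the
        63-min default schedule the ratio still carries transient bias."""
        starts = np.arange(0.0, 300.0, 10.0)
        durs = np.full(30, 10.0)
        mids = starts + durs / 2
        ref_params = {"tau": 500.0, "b": 0.2, "A_peak": 20.0}
        cref, _ = simulate_tacs("reference", {}, starts, durs,
                                ref_params=ref_params)
        ct, truth = simulate_tacs("reversible",
                                  {"R1": 1.0, "k2": 0.1, "BPnd": 1.5},
                                  starts, durs, ref_params=ref_params)
        late = mids >= 250.0
        ratio = ct[late].mean() / cref[late].mean()
        assert truth["DVR"] == 2.5
        assert ratio == pytest.approx(2.5, rel=0.10)

    def test_irreversible_pair_is_patlak_linear_by_construction(self):
        starts, durs = default_frame_schedule()
        mids = starts + durs / 2
        cref, _ = simulate_tacs("reference", {}, starts, durs)
        ct, truth = simulate_tacs("irreversible", {"Ki": 0.015, "V": 0.9},
                                  starts, durs)
        fit = pq.patlak(TAC(mids, ct), TAC(mids, cref), t_star=10.0)
        assert fit.parameters["Ki"] == pytest.approx(0.015, abs=1e-10)
        assert fit.r_squared > 0.999

    def test_negative_rates_rejected(self):
        starts, durs = default_frame_schedule()
        with pytest.raises(PhantomError):
            simulate_tacs("reversible", {"R1": 1.0, "k2": -0.1, "BPnd": 1.0},
                          starts, durs)

    def test_unknown_archetype_rejected(self):
        starts, durs = default_frame_schedule()
        with pytest.raises(PhantomError, match="archetype"):
            simulate_tacs("bolus", {}, starts, durs)


class TestRenderDynamicPet:
    def test_no_blur_no_noise_reproduces_regional_tacs(self, spec, labels,
                                                       truth):
        pet = pq.render_dynamic_pet(labels, truth, psf=pq.PSF(0.0),
                                    noise_scale=0.0)
        for rid in labels.region_ids():
            name = labels.region_name(rid)
            voxel_tacs = pet.frames[labels.labels == rid]
            expected = np.asarray(truth.region_tacs[name])[None, :]
            np.testing.assert_allclose(voxel_tacs,
                                       np.broadcast_to(expected,
                                                       voxel_tacs.shape),
                                       rtol=1e-12)

    def test_blur_causes_spill_out_from_small_bright_regions(
            self, labels, truth, noiseless_pet):
        """At 6.5 mm FWHM the putamen-like region loses activity to its
        surroundings: observed/true integral ratio < 1."""
        mids = noiseless_pet.frame_mid_times
        rid = [k for k, v in labels.name_map.items() if v == "putamen"][0]
        observed = noiseless_pet.frames[labels.labels == rid].mean(axis=0)
        obs_int = running_integral(mids, observed)[-1]
        true_int = running_integral(
            mids, np.asarray(truth.region_tacs["putamen"]))[-1]
        assert obs_int / true_int < 1.0

    def test_same_seed_is_bit_identical(self, labels, truth):
        a = pq.render_dynamic_pet(labels, truth, seed=11)
        b = pq.render_dynamic_pet(labels, truth, seed=11)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_noise_is_unbiased(self, labels, truth, noiseless_pet):
        """Across seeds the mean observed regional TAC converges on the
        noiseless TAC (within 3 Monte-Carlo standard errors)."""
        rid = [k for k, v in labels.name_map.items() if v == "putamen"][0]
        mask = labels.labels == rid
        base = noiseless_pet.frames[mask][:, -1].mean()
        draws = []
        for s in range(50):
            vol = static_observation(noiseless_pet, 4.7, seed=s)
            draws.append(vol.data[mask].mean())
        draws = np.array(draws)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        base_static = pq.time_weighted_average(noiseless_pet).data[mask].mean()
        assert abs(draws.mean() - base_static) < 3 * se

    def test_missing_tac_for_label_rejected(self, spec, labels):
        truth = pq.simulate_region_tacs(spec, labels)
        del truth.region_tacs["putamen"]
        with pytest.raises(PhantomError, match="missing TAC"):
            pq.render_dynamic_pet(labels, truth)


class TestApplyMisregistration:
    def test_identity_is_noop_within_interpolation(self, noiseless_pet):
        out = pq.apply_misregistration(noiseless_pet,
                                       pq.RigidTransform.identity())
        np.testing.assert_allclose(out.frames, noiseless_pet.frames, atol=1e-9)

    def test_translation_moves_center_of_mass(self, noiseless_pet):
        t = pq.RigidTransform([0, 0, 0], [7.0, 0, 0])
        moved = pq.apply_misregistration(noiseless_pet, t)
        from scipy import ndimage
        a = pq.time_weighted_average(noiseless_pet).data
        b = pq.time_weighted_average(moved).data
        com_a = np.asarray(ndimage.center_of_mass(a))
        com_b = np.asarray(ndimage.center_of_mass(b))
        shift_mm = (com_b - com_a) * 2.0  # 2 mm voxels
        assert shift_mm[0] == pytest.approx(7.0, abs=0.5)
        assert abs(shift_mm[1]) < 0.5 and abs(shift_mm[2]) < 0.5

    def test_transform_then_inverse_is_near_involution(self, noiseless_pet):
        t = pq.RigidTransform([0, 3.0, 0], [4.0, -2.0, 1.0])
        once = pq.apply_misregistration(noiseless_pet, t)
        back = pq.apply_misregistration(once, t.inverse())
        single_err = np.sqrt(np.mean(
            (pq.apply_misregistration(noiseless_pet, pq.RigidTransform.identity())
             .frames - noiseless_pet.frames) ** 2))
        round_err = np.sqrt(np.mean((back.frames - noiseless_pet.frames) ** 2))
        # two interpolations cost at most ~2x the single-resampling error,
        # measured against the smoothing scale of the data
        assert round_err < max(2 * single_err, 0.05 * noiseless_pet.frames.max())


class TestBidsEmission:
    def test_tree_is_discoverable_and_complete(self, tmp_path):
        pq.make_bids_phantom(tmp_path / "bids", n_subjects=2, seed=3)
        records = pq.discover_bids(tmp_path / "bids")
        assert [r.subject_id for r in records] == ["01", "02"]
        for rec in records:
            assert rec.t1_path is not None
            assert rec.label_paths
            pet = pq.read_dynamic_pet(rec.pet_path,
                                      rec.pet_path.with_name(
                                          rec.pet_path.name.replace(
                                              ".nii.gz", ".json")))
            assert pet.n_frames == 22
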