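"""Synthetic dynamic-PET phantom generator with ground-truth bookkeeping.

The generator emulates a simulated-PET validation setup: an anatomical label
phantom built from geometric primitives (cortical shell, putamen-like and
caudate-like ellipsoids, a cerebellum-like reference region, and a white
matter-like filler), per-region time-activity curves drawn from three tracer
archetypes, Gaussian PSF blurring, and frame-dependent Gaussian noise.
Scanner physics (scatter, randoms, attenuation, reconstruction) is
deliberately replaced by the blur + noise forward model: the point of the
phantom is to exercise the pipeline's inversion properties, not scanner
realism.

Tracer archetypes:

* ``reference`` — gamma-variate A t^b exp(-t/tau); the cerebellum-like
  reference curve and, rescaled, the nonspecific background curve.
* ``reversible`` — simplified-reference-tissue kinetics (R1, k2, BPnd),
  integrated on a fine time grid (RK4, step <= 0.01 min) and frame-averaged;
  a raclopride-like striatal signal.
* ``irreversible`` — Patlak-linear construction C(t) = Ki int(C_ref) + V
  C_ref; an FDOPA-like signal with exactly known Ki.
* ``ratio`` — a scaled copy of the reference curve; an FDG-like signal with
  exactly known SUVR.

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import running_integral
from .pvc import PSF, gaussian_blur
from .volumes_io import (DynamicPET, LabelVolume, Volume3D, resample,
                         write_dynamic_pet, write_label_names, write_labels,
                         write_volume)


class PhantomError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Frame schedule
# ---------------------------------------------------------------------------


def default_frame_schedule():
    """6 x 0.5 min, 4 x 3 min, 12 x 4 min (~63 min), a common dynamic
    protocol shape.  Returns (frame_starts, frame_durations) in minutes."""
    durations = np.array([0.5] * 6 + [3.0] * 4 + [4.0] * 12)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return starts, durations


# ---------------------------------------------------------------------------
# Label phantom
# ---------------------------------------------------------------------------


@dataclass
class RegionSpec:
    """A geometric primitive: ellipsoid, ellipsoidal shell, or cuboid.

    ``size_mm`` holds semi-axes (ellipsoid/cuboid half-sizes); shells add
    ``inner_scale`` (inner semi-axes = inner_scale * size_mm).
    """

    name: str
    label: int
    kind: str  # ellipsoid | shell | cuboid
    center_mm: tuple
    size_mm: tuple
    inner_scale: float = 0.8


@dataclass
class PhantomSpec:
    shape: tuple = (48, 56, 48)
    voxel_size_mm: float = 2.0
    regions: list = field(default_factory=list)
    filler_label: int = 5
    filler_name: str = "rest"
    frame_starts: np.ndarray = None
    frame_durations: np.ndarray = None
    psf_fwhm_mm: float = 6.5
    # calibrated so the late-frame putamen regional-mean SNR is ~20
    noise_scale: float = 4.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_starts is None or self.frame_durations is None:
            self.frame_starts, self.frame_durations = default_frame_schedule()
        self.frame_starts = np.asarray(self.frame_starts, dtype=float)
        self.frame_durations = np.asarray(self.frame_durations, dtype=float)
        if not self.regions:
            self.regions = default_regions()

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size_mm
        aff[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * self.voxel_size_mm
        return aff

    @property
    def frame_mid_times(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations / 2.0


def default_regions() -> list:
    """Brain-like layout on a ~96 x 112 x 96 mm field of view.

    The putamen-like ellipsoid has semi-axes (12.4, 8.8, 8.8) mm,
    i.e. an analytic volume 4*pi*abc/3 of ~4.0 cm^3."""
    return [
        RegionSpec("cortex", 1, "shell", (0.0, 0.0, 6.0), (34.0, 40.0, 32.0),
                   inner_scale=0.8),
        RegionSpec("putamen", 2, "ellipsoid", (12.0, 6.0, 6.0),
                   (12.4, 8.8, 8.8)),
        RegionSpec("caudate", 3, "ellipsoid", (-14.0, 10.0, 8.0),
                   (10.0, 7.0, 7.0)),
        RegionSpec("cerebellum", 4, "ellipsoid", (0.0, -18.0, -4.0),
                   (11.0, 8.0, 8.0)),
    ]


def _world_grid(spec: PhantomSpec):
    aff = spec.affine
    idx = np.indices(spec.shape, dtype=float)
    world = np.einsum("ij,j...->i...", aff[:3, :3], idx) + aff[:3, 3][:, None, None, None]
    return world


def _inside_ellipsoid(world, center, semi):
    q = sum(((world[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return q <= 1.0


def make_label_phantom(spec: PhantomSpec) -> LabelVolume:
    """Rasterize the region primitives; voxels inside the outermost shell but
    unclaimed get the filler label.  Overlapping primitives are an error."""
    world = _world_grid(spec)
    labels = np.zeros(spec.shape, dtype=np.int32)
    name_map = {}
    filler_support = np.zeros(spec.shape, dtype=bool)
    for region in spec.regions:
        center = np.asarray(region.center_mm, float)
        semi = np.asarray(region.size_mm, float)
        if region.kind == "ellipsoid":
            mask = _inside_ellipsoid(world, center, semi)
        elif region.kind == "shell":
            outer = _inside_ellipsoid(world, center, semi)
            inner = _inside_ellipsoid(world, center, semi * region.inner_scale)
            mask = outer & ~inner
            filler_support |= inner
        elif region.kind == "cuboid":
            mask = np.all([np.abs(world[i] - center[i]) <= semi[i]
                           for i in range(3)], axis=0)
        else:
            raise PhantomError(f"unknown primitive kind {region.kind!r}")
        if (labels[mask] != 0).any():
            raise PhantomError(f"region {region.name!r} overlaps an earlier region")
        labels[mask] = region.label
        name_map[region.label] = region.name
    fill = filler_support & (labels == 0)
    if fill.any():
        labels[fill] = spec.filler_label
        name_map[spec.filler_label] = spec.filler_name
    return LabelVolume(labels, spec.affine, name_map)


# ---------------------------------------------------------------------------
# TAC archetypes
# ---------------------------------------------------------------------------

DEFAULT_REFERENCE_PARAMS = {"A_peak": 20.0, "b": 1.0, "tau": 15.0}


def _gamma_variate(t, A_peak, b, tau):
    t = np.asarray(t, dtype=float)
    t_peak = b * tau
    peak = t_peak ** b * np.exp(-b)
    scale = A_peak / peak
    out = scale * np.power(np.clip(t, 0, None), b) * np.exp(-np.clip(t, 0, None) / tau)
    return np.where(t <= 0, 0.0, out)


def _srtm_ode(times_fine, cref_fine, r1, k2, bpnd):
    """RK4 integration of dCt/dt = R1 dCref/dt + k2 Cref - k2a Ct."""
    k2a = k2 / (1.0 + bpnd)
    dt = times_fine[1] - times_fine[0]
    dcref = np.gradient(cref_fine, dt)
    ct = np.zeros_like(cref_fine)

    def rhs(i_float, y):
        i0 = int(np.clip(np.floor(i_float), 0, len(cref_fine) - 2))
        w = i_float - i0
        cr = (1 - w) * cref_fine[i0] + w * cref_fine[i0 + 1]
        dcr = (1 - w) * dcref[i0] + w * dcref[i0 + 1]
        return r1 * dcr + k2 * cr - k2a * y

    for i in range(len(times_fine) - 1):
        y = ct[i]
        k1 = rhs(i, y)
        k2_ = rhs(i + 0.5, y + 0.5 * dt * k1)
        k3 = rhs(i + 0.5, y + 0.5 * dt * k2_)
        k4 = rhs(i + 1.0, y + dt * k3)
        ct[i + 1] = y + dt / 6.0 * (k1 + 2 * k2_ + 2 * k3 + k4)
    return ct


def _frame_average(times_fine, values_fine, starts, durations):
    out = np.empty(len(starts))
    for i, (s, d) in enumerate(zip(starts, durations)):
        sel = (times_fine >= s) & (times_fine <= s + d)
        out[i] = values_fine[sel].mean()
    return out


def simulate_tacs(archetype: str, params: dict, frame_starts, frame_durations,
                  ref_params: dict | None = None, ode_step: float = 0.01):
    """Generate one regional TAC of the given archetype on the frame grid.

    Returns ``(activity, truth)`` where ``activity`` is the noiseless
    regional activity per frame and ``truth`` records the generating
    parameters (including the derived DVR/Ki/SUVR where applicable).
    """
    frame_starts = np.asarray(frame_starts, float)
    frame_durations = np.asarray(frame_durations, float)
    mids = frame_starts + frame_durations / 2.0
    ref_params = dict(DEFAULT_REFERENCE_PARAMS, **(ref_params or {}))
    if ref_params["tau"] <= 0 or ref_params["b"] < 0:
        raise PhantomError("reference archetype requires positive tau and b >= 0")
    cref = _gamma_variate(mids, **ref_params)
    truth = {"archetype": archetype, "params": dict(params),
             "ref_params": ref_params}

    if archetype == "reference":
        activity = _gamma_variate(mids, **dict(ref_params, **params))
    elif archetype == "ratio":
        scale = params.get("scale", 2.0)
        if scale < 0:
            raise PhantomError("ratio archetype requires scale >= 0")
        activity = scale * cref
        truth["SUVR"] = scale
    elif archetype == "irreversible":
        ki, v = params.get("Ki", 0.01), params.get("V", 1.0)
        if ki < 0 or v < 0:
            raise PhantomError("irreversible archetype requires Ki, V >= 0")
        activity = ki * running_integral(mids, cref) + v * cref
        truth["Ki"] = ki
        truth["V"] = v
    elif archetype == "reversible":
        r1 = params.get("R1", 1.0)
        k2 = params.get("k2", 0.1)
        bpnd = params.get("BPnd", 2.0)
        if r1 < 0 or k2 <= 0 or bpnd < 0:
            raise PhantomError("reversible archetype requires R1 >= 0, k2 > 0, "
                               "BPnd >= 0")
        end = frame_starts[-1] + frame_durations[-1]
        times_fine = np.arange(0.0, end + ode_step, ode_step)
        cref_fine = _gamma_variate(times_fine, **ref_params)
        ct_fine = _srtm_ode(times_fine, cref_fine, r1, k2, bpnd)
        activity = _frame_average(times_fine, ct_fine, frame_starts,
                                  frame_durations)
        truth.update({"R1": r1, "k2": k2, "BPnd": bpnd, "DVR": 1.0 + bpnd})
    else:
        raise PhantomError(f"unknown archetype {archetype!r}")
    return activity, truth


DEFAULT_REGION_KINETICS = {
    # region name -> (archetype, params); the validation assignments are
    # FDG-like ratio kinetics in cortex, FDOPA-like irreversible in putamen,
    # raclopride-like reversible in caudate, reference kinetics in cerebellum
    "cortex": ("ratio", {"scale": 2.0}),
    "putamen": ("irreversible", {"Ki": 0.01, "V": 1.0}),
    "caudate": ("reversible", {"R1": 1.0, "k2": 0.1, "BPnd": 2.0}),
    "cerebellum": ("reference", {}),
    "rest": ("ratio", {"scale": 0.5}),
}


@dataclass
class GroundTruth:
    """Everything needed to compute recovery ratios against the truth."""

    region_tacs: dict          # region name -> noiseless activity per frame
    region_params: dict        # region name -> generating parameters
    frame_starts: np.ndarray
    frame_durations: np.ndarray
    psf_fwhm_mm: float = 0.0
    noise_scale: float = 0.0
    seed: int = 0
    transform: object = None

    @property
    def frame_mid_times(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations / 2.0

    def to_json(self, path) -> None:
        payload = {
            "region_tacs": {k: list(v) for k, v in self.region_tacs.items()},
            "region_params": _jsonable(self.region_params),
            "frame_starts_min": list(self.frame_starts),
            "frame_durations_min": list(self.frame_durations),
            "psf_fwhm_mm": self.psf_fwhm_mm,
            "noise_scale": self.noise_scale,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def simulate_region_tacs(spec: PhantomSpec, labels: LabelVolume,
                         region_kinetics: dict | None = None) -> GroundTruth:
    """Noiseless TACs for every nonzero label in the phantom."""
    region_kinetics = region_kinetics or DEFAULT_REGION_KINETICS
    tacs, params = {}, {}
    for rid in labels.region_ids():
        name = labels.region_name(rid)
        if name not in region_kinetics:
            raise PhantomError(f"no kinetics declared for region {name!r}")
        archetype, p = region_kinetics[name]
        activity, truth = simulate_tacs(archetype, p, spec.frame_starts,
                                        spec.frame_durations)
        tacs[name] = activity
        params[name] = truth
    return GroundTruth(tacs, params, spec.frame_starts, spec.frame_durations,
                       psf_fwhm_mm=spec.psf_fwhm_mm,
                       noise_scale=spec.noise_scale, seed=spec.seed)


# ---------------------------------------------------------------------------
# Forward rendering
# ---------------------------------------------------------------------------


def render_dynamic_pet(labels: LabelVolume, truth: GroundTruth,
                       psf: PSF | None = None, noise_scale: float | None = None,
                       seed: int | None = None) -> DynamicPET:
    """Paint regional TACs into the label volume, blur each frame with the
    PSF, and add zero-mean Gaussian noise with per-voxel standard deviation
    ``noise_scale * sqrt(value / frame_duration)``; seeded and reproducible.
    """
    if psf is None:
        psf = PSF(truth.psf_fwhm_mm)
    if noise_scale is None:
        noise_scale = truth.noise_scale
    if seed is None:
        seed = truth.seed
    name_to_tac = truth.region_tacs
    for rid in labels.region_ids():
        if labels.region_name(rid) not in name_to_tac:
            raise PhantomError(f"missing TAC for label {rid} "
                               f"({labels.region_name(rid)})")
    n_frames = len(truth.frame_starts)
    shape = labels.labels.shape
    frames = np.zeros(shape + (n_frames,))
    lut = np.zeros(int(labels.labels.max()) + 1)
    rng = np.random.default_rng(seed)
    for k in range(n_frames):
        for rid in labels.region_ids():
            lut[rid] = name_to_tac[labels.region_name(rid)][k]
        painted = lut[labels.labels]
        blurred = (gaussian_blur(Volume3D(painted, labels.affine), psf).data
                   if np.any(np.asarray(psf.fwhm) > 0) else painted)
        if noise_scale > 0:
            sd = noise_scale * np.sqrt(np.clip(blurred, 0, None)
                                       / truth.frame_durations[k])
            blurred = blurred + rng.standard_normal(shape) * sd
        frames[..., k] = blurred
    return DynamicPET(frames, labels.affine, truth.frame_starts,
                      truth.frame_durations)


def render_t1_proxy(labels: LabelVolume, smooth_fwhm_mm: float = 2.0,
                    intensities: dict | None = None) -> Volume3D:
    """A T1-weighted-like anatomical volume synthesized from the labels
    (distinct tissue intensities, mild smoothing); the registration and QC
    fixed image for phantom experiments."""
    default = {"cortex": 70.0, "putamen": 85.0, "caudate": 85.0,
               "cerebellum": 75.0, "rest": 100.0}
    lut = np.zeros(int(labels.labels.max()) + 1)
    for rid in labels.region_ids():
        name = labels.region_name(rid)
        lut[rid] = (intensities or default).get(name, 60.0)
    vol = Volume3D(lut[labels.labels], labels.affine)
    return gaussian_blur(vol, PSF(smooth_fwhm_mm))


def static_observation(noiseless_pet: DynamicPET, noise_scale: float,
                       seed: int, transform=None) -> Volume3D:
    """A noisy time-weighted-average volume drawn in one shot.

    Equivalent in mean and variance to rendering every frame with
    frame-dependent noise and then duration-averaging, but needs a single 3D
    noise draw, which keeps large QC cohorts cheap.  ``transform`` optionally
    misregisters the observation.
    """
    w = noiseless_pet.frame_durations / noiseless_pet.frame_durations.sum()
    mean = np.tensordot(noiseless_pet.frames, w, axes=([3], [0]))
    var_frames = (noise_scale ** 2) * np.clip(noiseless_pet.frames, 0, None) \
        / noiseless_pet.frame_durations
    sd = np.sqrt(np.tensordot(var_frames, w ** 2, axes=([3], [0])))
    rng = np.random.default_rng(seed)
    data = mean + rng.standard_normal(mean.shape) * sd
    vol = Volume3D(data, noiseless_pet.affine)
    if transform is not None:
        vol = resample(vol, transform, vol.affine, data.shape, "trilinear")
    return vol


def apply_misregistration(pet: DynamicPET, transform) -> DynamicPET:
    """Resample every frame through the rigid transform (content moves by
    the forward transform on the fixed grid)."""
    out = np.empty_like(pet.frames)
    for k in range(pet.n_frames):
        vol = Volume3D(pet.frames[..., k], pet.affine)
        out[..., k] = resample(vol, transform, pet.affine,
                               pet.frames.shape[:3], "trilinear").data
    return DynamicPET(out, pet.affine, pet.frame_starts, pet.frame_durations)


# ---------------------------------------------------------------------------
# Full phantom experiment + BIDS emission
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec | None = None,
                     region_kinetics: dict | None = None):
    """One-call phantom: returns (pet, labels, truth)."""
    spec = spec or PhantomSpec()
    labels = make_label_phantom(spec)
    truth = simulate_region_tacs(spec, labels, region_kinetics)
    pet = render_dynamic_pet(labels, truth)
    return pet, labels, truth


def make_bids_phantom(root, n_subjects: int = 1, seed: int = 0,
                      spec: PhantomSpec | None = None,
                      region_kinetics: dict | None = None,
                      task: str = "rest") -> list[Path]:
    """Emit a ready-to-run BIDS tree of phantom subjects.

    Each subject shares the anatomy and true TACs but has an independent
    noise seed derived from ``seed``.  Writes PET + timing sidecar, a
    T1-proxy, the label volume, and a ground_truth.json per subject.
    """
    root = Path(root)
    spec = spec or PhantomSpec(seed=seed)
    labels = make_label_phantom(spec)
    truth = simulate_region_tacs(spec, labels, region_kinetics)
    t1 = render_t1_proxy(labels)
    written = []
    for i in range(n_subjects):
        sub = f"{i + 1:02d}"
        subject_seed = (seed * 1000 + i) % (2 ** 31 - 1)
        pet = render_dynamic_pet(labels, truth, seed=subject_seed)
        pet_dir = root / f"sub-{sub}" / "pet"
        anat_dir = root / f"sub-{sub}" / "anat"
        pet_dir.mkdir(parents=True, exist_ok=True)
        anat_dir.mkdir(parents=True, exist_ok=True)
        stem = f"sub-{sub}_task-{task}"
        write_dynamic_pet(pet, pet_dir / f"{stem}_pet.nii.gz",
                          pet_dir / f"{stem}_pet.json")
        write_volume(t1, anat_dir / f"sub-{sub}_T1w.nii.gz")
        write_labels(labels, anat_dir / f"sub-{sub}_dseg.nii.gz")
        write_label_names(labels.name_map, anat_dir / f"sub-{sub}_dseg.tsv")
        gt = GroundTruth(truth.region_tacs, truth.region_params,
                         truth.frame_starts, truth.frame_durations,
                         truth.psf_fwhm_mm, truth.noise_scale, subject_seed)
        gt.to_json(pet_dir / f"{stem}_ground_truth.json")
        written.append(pet_dir / f"{stem}_pet.nii.gz")
    return written
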