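"""Rigid PET-to-T1 coregistration by normalized mutual information.

Registration proceeds hierarchically in two stages: a coarse fit of binary
head masks treated as 0/1 images, then a refinement on the intensity images,
each through a Gaussian smoothing pyramid from coarse to fine scales.  The
similarity is normalized mutual information, NMI = (H(A)+H(B))/H(A,B),
maximal at alignment; MI, joint entropy (feature-space entropy) and Pearson
cross-correlation are exposed as well because the QC stage reuses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation
from skimage.filters import threshold_otsu

from .volumes_io import LabelVolume, Volume3D, resample


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Rigid transform
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform:
    """Six-parameter rigid map between world coordinate frames.

    Rotations are in degrees about x, y, z (intrinsic, applied z then y then
    x) about ``center`` (mm, typically the moving volume's intensity center
    of mass); translations in mm.  ``direction`` documents which way the map
    goes (by convention PET world -> T1 world).
    """

    rotations: np.ndarray
    translations: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: str = "pet_to_t1"

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if self.rotations.shape != (3,) or self.translations.shape != (3,):
            raise ValueError("rigid transform requires exactly 6 parameters")

    @property
    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotations
        return Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True).as_matrix()

    @property
    def matrix(self) -> np.ndarray:
        """4x4 world-to-world matrix: w' = R (w - c) + c + t."""
        R = self.rotation_matrix
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = self.center + self.translations - R @ self.center
        return m

    def inverse(self) -> "RigidTransform":
        R_inv = self.rotation_matrix.T
        rz, ry, rx = Rotation.from_matrix(R_inv).as_euler("ZYX", degrees=True)
        parts = self.direction.split("_to_")
        direction = "_to_".join(parts[::-1]) if len(parts) == 2 else self.direction
        return RigidTransform(
            rotations=[rx, ry, rz],
            translations=-(R_inv @ self.translations),
            center=self.center,
            direction=direction,
        )

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0), direction="pet_to_t1") -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3), np.asarray(center, float), direction)

    def to_file(self, path) -> None:
        lines = [f"{v:.10g}" for v in np.concatenate([self.rotations, self.translations])]
        lines.append("rotations_deg_xyz_intrinsic_zyx_about_center;translations_mm")
        lines.append(self.direction)
        lines.append(" ".join(f"{v:.10g}" for v in self.center))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RigidTransform":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if len(lines) != 9:
            raise ValueError(f"expected 9-line transform file, got {len(lines)} lines")
        params = [float(v) for v in lines[:6]]
        center = [float(v) for v in lines[8].split()]
        return cls(params[:3], params[3:], center, direction=lines[7])


# ---------------------------------------------------------------------------
# Joint histogram and similarity metrics
# ---------------------------------------------------------------------------


@dataclass
class Histogram2D:
    counts: np.ndarray
    edges_a: np.ndarray
    edges_b: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _robust_edges(values: np.ndarray, bins: int, percentiles=(1.0, 99.0)) -> np.ndarray:
    lo, hi = np.percentile(values, percentiles)
    if hi <= lo:  # constant image: one wide bin catches everything
        lo, hi = lo - 0.5, lo + 0.5
    return np.linspace(lo, hi, bins + 1)


def joint_histogram(a, b, mask=None, bins: int = 64,
                    percentiles=(1.0, 99.0)) -> Histogram2D:
    """Joint intensity histogram of two volumes on the same grid.

    Intensities are linearly binned between per-volume robust (percentile)
    bounds, values outside clipped into the end bins, so the counts sum to
    the in-mask voxel count.
    """
    da = a.data if isinstance(a, Volume3D) else np.asarray(a, float)
    db = b.data if isinstance(b, Volume3D) else np.asarray(b, float)
    if da.shape != db.shape:
        raise ValueError("joint_histogram requires volumes on the same grid")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if mask is None:
        va, vb = da.ravel(), db.ravel()
    else:
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("empty mask")
        va, vb = da[mask], db[mask]
    edges_a = _robust_edges(va, bins, percentiles)
    edges_b = _robust_edges(vb, bins, percentiles)
    va = np.clip(va, edges_a[0], edges_a[-1])
    vb = np.clip(vb, edges_b[0], edges_b[-1])
    counts, _, _ = np.histogram2d(va, vb, bins=[edges_a, edges_b])
    return Histogram2D(counts, edges_a, edges_b)


def _joint_prob(h: Histogram2D) -> np.ndarray:
    n = h.counts.sum()
    if n <= 0:
        raise ValueError("empty histogram")
    return h.counts / n


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information(h: Histogram2D) -> float:
    """MI in nats: sum p(a,b) ln[p(a,b) / (p(a) p(b))], zero cells skipped."""
    p = _joint_prob(h)
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    mi = _entropy(pa) + _entropy(pb) - _entropy(p)
    return max(mi, 0.0)


def feature_space_entropy(h: Histogram2D) -> float:
    """Joint entropy H(A,B) in nats over occupied histogram cells."""
    return _entropy(_joint_prob(h))


def normalized_mutual_information(h: Histogram2D) -> float:
    """NMI = (H(A)+H(B)) / H(A,B); 1 for independence, 2 for identity."""
    p = _joint_prob(h)
    h_joint = _entropy(p)
    if h_joint <= 0:
        raise ValueError("NMI undefined: both images constant (zero joint entropy)")
    return (_entropy(p.sum(axis=1)) + _entropy(p.sum(axis=0))) / h_joint


def cross_correlation(a, b, mask=None) -> float:
    """Pearson correlation of in-mask intensities."""
    da = a.data if isinstance(a, Volume3D) else np.asarray(a, float)
    db = b.data if isinstance(b, Volume3D) else np.asarray(b, float)
    if mask is None:
        va, vb = da.ravel(), db.ravel()
    else:
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("empty mask")
        va, vb = da[mask], db[mask]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("undefined correlation: constant input")
    return float(np.corrcoef(va, vb)[0, 1])


# ---------------------------------------------------------------------------
# Masking helpers
# ---------------------------------------------------------------------------


def default_mask(vol: Volume3D) -> np.ndarray:
    """Otsu threshold, largest connected component, morphological closing."""
    data = vol.data
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise RegistrationError("automatic mask is empty")
    labeled, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))
        fg = labeled == (1 + int(np.argmax(sizes)))
    return ndimage.binary_closing(fg, structure=np.ones((3, 3, 3)), border_value=0)


def _center_of_mass_world(data: np.ndarray, affine: np.ndarray) -> np.ndarray:
    w = np.clip(np.asarray(data, float), 0, None)
    com_idx = np.asarray(ndimage.center_of_mass(w))
    return affine[:3, :3] @ com_idx + affine[:3, 3]


# ---------------------------------------------------------------------------
# Hierarchical registration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationConfig:
    """Pyramid and optimizer settings for the two-stage rigid fit."""

    pyramid_fwhm: tuple = (8.0, 4.0, 2.0)       # intensity stage, coarse -> fine
    mask_pyramid_fwhm: tuple = (8.0, 4.0)       # mask stage
    bins: int = 64
    percentiles: tuple = (1.0, 99.0)
    xtol: float = 1e-3
    maxfev: int = 200
    min_overlap_voxels: int = 50
    run_mask_stage: bool = True

    def __post_init__(self) -> None:
        if self.bins < 8:
            raise ValueError("bins must be >= 8")
        if list(self.pyramid_fwhm) != sorted(self.pyramid_fwhm, reverse=True):
            raise ValueError("pyramid must be ordered coarse to fine")


def _smooth_volume(vol: Volume3D, fwhm: float) -> Volume3D:
    if fwhm <= 0:
        return vol
    sigma_mm = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / vol.voxel_sizes
    return Volume3D(ndimage.gaussian_filter(vol.data, sigma=sigma_vox), vol.affine)


def _decimate(vol: Volume3D, step: int) -> Volume3D:
    if step <= 1:
        return vol
    data = vol.data[::step, ::step, ::step]
    aff = vol.affine.copy()
    aff[:3, :3] *= step
    return Volume3D(data, aff)


def _decimate_mask(mask: np.ndarray, step: int) -> np.ndarray:
    return mask if step <= 1 else mask[::step, ::step, ::step]


def _nmi_objective(params, moving, fixed, fixed_mask, center, config):
    t = RigidTransform(params[3:], params[:3], center)
    mov = resample(moving, t, fixed.affine, fixed.data.shape, "trilinear")
    support = np.abs(mov.data) > 0
    overlap = fixed_mask & support
    if overlap.sum() < config.min_overlap_voxels:
        return 10.0  # rejected step: keep objective finite for the optimizer
    try:
        h = joint_histogram(mov, fixed, overlap, config.bins, config.percentiles)
        return -normalized_mutual_information(h)
    except ValueError:
        return 10.0


def _optimize_level(params0, moving, fixed, fixed_mask, center, config):
    res = optimize.minimize(
        _nmi_objective, np.asarray(params0, float),
        args=(moving, fixed, fixed_mask, center, config),
        method="Powell",
        options={"xtol": config.xtol, "ftol": 1e-6, "maxfev": config.maxfev},
    )
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        raise RegistrationError("optimizer produced a non-finite objective")
    # prefer the smaller parameter vector on an exact tie with the start
    f0 = _nmi_objective(np.asarray(params0, float), moving, fixed, fixed_mask,
                        center, config)
    if res.fun == f0 and np.linalg.norm(params0) < np.linalg.norm(res.x):
        return np.asarray(params0, float), f0
    return res.x, float(res.fun)


def rigid_register(pet_static: Volume3D, t1: Volume3D,
                   pet_mask: np.ndarray | None = None,
                   t1_mask: np.ndarray | None = None,
                   config: RegistrationConfig | None = None):
    """Register PET (moving) to T1 (fixed), returning the rigid transform
    mapping PET world coordinates into T1 world coordinates.

    Stage 0 translates to align intensity centers of mass; stage 1 fits the
    binary masks as 0/1 images through the coarse pyramid levels; stage 2
    refines on the intensity images (histogram over the mask union) through
    all levels.  Returns ``(transform, info)`` where ``info`` holds the
    achieved NMI per stage.
    """
    config = config or RegistrationConfig()
    if pet_mask is None:
        pet_mask = default_mask(pet_static)
    if t1_mask is None:
        t1_mask = default_mask(t1)
    pet_mask = np.asarray(pet_mask, bool)
    t1_mask = np.asarray(t1_mask, bool)

    center = _center_of_mass_world(pet_static.data * pet_mask, pet_static.affine)
    t1_com = _center_of_mass_world(t1.data * t1_mask, t1.affine)
    params = np.concatenate([t1_com - center, np.zeros(3)])  # [t, r]

    # overlap sanity check after center-of-mass alignment
    t0 = RigidTransform(params[3:], params[:3], center)
    pm = resample(Volume3D(pet_mask.astype(float), pet_static.affine), t0,
                  t1.affine, t1.data.shape, "trilinear")
    if ((pm.data > 0.5) & t1_mask).sum() < config.min_overlap_voxels:
        raise RegistrationError("insufficient overlap between masks after centering")

    info = {"stage_nmi": {}}
    moving_img = Volume3D(pet_static.data, pet_static.affine)
    fixed_img = Volume3D(t1.data, t1.affine)
    mask_moving = Volume3D(pet_mask.astype(float), pet_static.affine)
    mask_fixed = Volume3D(t1_mask.astype(float), t1.affine)

    if config.run_mask_stage:
        fun = 0.0
        for fwhm in config.mask_pyramid_fwhm:
            step = max(1, int(round(fwhm / (2.0 * float(np.min(t1.voxel_sizes))))))
            mov = _smooth_volume(mask_moving, fwhm)
            fix = _decimate(_smooth_volume(mask_fixed, fwhm), step)
            fmask = fix.data > 0.05  # generous support of the smoothed head mask
            params, fun = _optimize_level(params, mov, fix, fmask, center, config)
        info["stage_nmi"]["mask"] = -fun

    fun = 0.0
    for fwhm in config.pyramid_fwhm:
        step = max(1, int(round(fwhm / (2.0 * float(np.min(t1.voxel_sizes))))))
        mov = _smooth_volume(moving_img, fwhm)
        fix = _decimate(_smooth_volume(fixed_img, fwhm), step)
        # histogram over the union of the two head masks in fixed space
        t_cur = RigidTransform(params[3:], params[:3], center)
        pm = resample(mask_moving, t_cur, fix.affine, fix.data.shape, "trilinear")
        union = _decimate_mask(t1_mask, step) | (pm.data > 0.5)
        params, fun = _optimize_level(params, mov, fix, union, center, config)
    info["stage_nmi"]["intensity"] = -fun

    transform = RigidTransform(params[3:], params[:3], center)
    info["final_nmi"] = -fun
    return transform, info
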