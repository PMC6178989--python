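"""Volumetric I/O, BIDS discovery, arterial input parsing, and resampling.

Conventions used throughout the package:

* time unit is **minutes** (BIDS sidecar seconds are converted at read time),
* activity unit is kBq/mL,
* voxel indices are 0-based; world coordinates come from the NIfTI affine
  (RAS, mm),
* input PET is assumed decay-corrected (as reconstructed research PET);
  no decay handling is performed anywhere.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised when an input file violates the expected on-disk format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Volume3D:
    """A 3D scalar grid with a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires 3D data, got {self.data.ndim}D")
        if any(s < 2 for s in self.data.shape):
            raise ValueError("Volume3D requires >= 2 voxels per axis")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class DynamicPET:
    """A 4D dynamic PET acquisition: frames plus per-frame timing (minutes)."""

    frames: np.ndarray
    affine: np.ndarray
    frame_starts: np.ndarray
    frame_durations: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.frame_starts = np.asarray(self.frame_starts, dtype=float)
        self.frame_durations = np.asarray(self.frame_durations, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("DynamicPET requires 4D data")
        n = self.frames.shape[3]
        if len(self.frame_starts) != n or len(self.frame_durations) != n:
            raise FormatError("frame timing mismatch: timing entries != frame count")
        if np.any(self.frame_durations <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(self.frame_starts) < 0):
            raise ValueError("frame starts must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[3]

    @property
    def frame_mid_times(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations / 2.0

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class LabelVolume:
    """Integer-labeled 3D volume; 0 is reserved for background."""

    labels: np.ndarray
    affine: np.ndarray
    name_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(rounded, self.labels):
                raise ValueError("labels must be integer-valued")
            self.labels = rounded.astype(np.int32)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume requires 3D labels")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        present = set(np.unique(self.labels).tolist())
        absent = [k for k in self.name_map if k not in present]
        if absent:
            warnings.warn(f"labels absent from volume: {sorted(absent)}")

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def region_ids(self, include_background: bool = False) -> list[int]:
        ids = [int(i) for i in np.unique(self.labels)]
        if not include_background:
            ids = [i for i in ids if i != 0]
        return ids

    def region_name(self, region_id: int) -> str:
        return self.name_map.get(region_id, str(region_id))


@dataclass
class InputCurve:
    """A sampled input function (reference-region or arterial)."""

    times: np.ndarray
    activity: np.ndarray
    kind: str = "reference_region"
    units: str = "kBq/mL"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.kind not in {"reference_region", "arterial_blood", "arterial_plasma"}:
            raise ValueError(f"unknown input-curve kind {self.kind!r}")
        if len(self.times) < 3:
            raise ValueError("length >= 3 required for an input curve")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("input-curve times must be strictly increasing")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("input-curve activity must be finite")


@dataclass
class SubjectRecord:
    """One PET acquisition discovered in a BIDS tree."""

    subject_id: str
    pet_path: Path
    session_id: str | None = None
    task_id: str | None = None
    run_id: str | None = None
    t1_path: Path | None = None
    label_paths: list[Path] = field(default_factory=list)
    dft_path: Path | None = None

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")


# ---------------------------------------------------------------------------
# NIfTI / sidecar I/O
# ---------------------------------------------------------------------------


def read_dynamic_pet(pet_path, sidecar_path) -> DynamicPET:
    """Read a 4D PET NIfTI plus its BIDS JSON sidecar.

    The sidecar must provide ``FrameTimesStart`` and ``FrameDuration`` arrays
    in seconds; they are converted to minutes.
    """
    img = nib.load(str(pet_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected 4D PET, got {data.ndim}D: {pet_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    for key in ("FrameTimesStart", "FrameDuration"):
        if key not in sidecar:
            raise FormatError(f"sidecar missing field {key}: {sidecar_path}")
    starts = np.asarray(sidecar["FrameTimesStart"], dtype=float)
    durations = np.asarray(sidecar["FrameDuration"], dtype=float)
    n = data.shape[3]
    if len(starts) != n or len(durations) != n:
        raise FormatError(
            f"frame timing mismatch: {n} frames but FrameTimesStart has "
            f"{len(starts)} and FrameDuration has {len(durations)} entries"
        )
    return DynamicPET(data, np.asarray(img.affine), starts / 60.0, durations / 60.0)


def read_volume(path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected 3D volume, got {data.ndim}D: {path}")
    return Volume3D(data, np.asarray(img.affine))


def write_volume(vol: Volume3D, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    nib.save(img, str(path))


def read_labels(path, name_map: dict[int, str] | None = None) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected 3D label volume, got {data.ndim}D: {path}")
    return LabelVolume(np.rint(data).astype(np.int32), np.asarray(img.affine),
                       name_map or {})


def write_labels(labels: LabelVolume, path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.int16), labels.affine)
    nib.save(img, str(path))


def write_label_names(name_map: dict[int, str], path) -> None:
    """BIDS-style dseg lookup table: index<TAB>name."""
    lines = ["index\tname"]
    for rid in sorted(name_map):
        lines.append(f"{rid}\t{name_map[rid]}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_label_names(path) -> dict[int, str]:
    name_map = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("index"):
            raise FormatError(f"unexpected dseg lookup header in {path}")
        for line in fh:
            if line.strip():
                rid, _, name = line.rstrip("\n").partition("\t")
                name_map[int(rid)] = name
    return name_map


def write_dynamic_pet(pet: DynamicPET, pet_path, sidecar_path=None) -> None:
    img = nib.Nifti1Image(np.asarray(pet.frames, dtype=np.float64), pet.affine)
    nib.save(img, str(pet_path))
    if sidecar_path is not None:
        sidecar = {
            "FrameTimesStart": (pet.frame_starts * 60.0).tolist(),
            "FrameDuration": (pet.frame_durations * 60.0).tolist(),
            "Units": "kBq/mL",
        }
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Turku .dft arterial input curves
# ---------------------------------------------------------------------------

_DFT_KINDS = {
    "blood": "arterial_blood",
    "plasma": "arterial_plasma",
    "reference": "reference_region",
}


def parse_dft(path) -> InputCurve:
    """Parse a Turku-style ``.dft`` text input function.

    Supported dialect: ``#``-prefixed header lines, which may declare a unit
    (e.g. ``# unit: kBq/cc``) and curve kind (``# kind: plasma``); data rows
    are whitespace-separated ``start end activity`` (times in minutes, sample
    time taken as the interval midpoint) or ``time activity``.
    """
    units = "kBq/mL"
    kind = "arterial_plasma"
    times: list[float] = []
    activities: list[float] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").strip()
                if ":" in header:
                    key, _, value = header.partition(":")
                    key, value = key.strip().lower(), value.strip()
                    if key in {"unit", "units"}:
                        units = value
                    elif key == "kind":
                        for token, kname in _DFT_KINDS.items():
                            if token in value.lower():
                                kind = kname
                continue
            cells = line.split()
            if len(cells) not in (2, 3):
                raise FormatError(f"{path}: line {lineno}: expected 2 or 3 columns")
            if ncols is None:
                ncols = len(cells)
            elif len(cells) != ncols:
                raise FormatError(f"{path}: line {lineno}: inconsistent column count")
            try:
                values = [float(c) for c in cells]
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-numeric cell") from None
            if ncols == 3:
                start, end, act = values
                times.append((start + end) / 2.0)
            else:
                t, act = values
                times.append(t)
            activities.append(act)
    if len(times) < 3:
        raise FormatError(f"{path}: length >= 3 required, got {len(times)} rows")
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2
        raise FormatError(f"{path}: non-monotone times at data row {bad}")
    return InputCurve(t, np.asarray(activities), kind=kind, units=units)


# ---------------------------------------------------------------------------
# BIDS discovery
# ---------------------------------------------------------------------------

_ENTITY_RE = re.compile(r"([a-zA-Z0-9]+)-([a-zA-Z0-9]+)")


def parse_bids_entities(filename: str) -> dict[str, str]:
    """Extract ``key-value`` entities from a BIDS filename stem."""
    stem = Path(filename).name
    for suffix in (".nii.gz", ".nii", ".json"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    entities: dict[str, str] = {}
    for token in stem.split("_"):
        m = _ENTITY_RE.fullmatch(token)
        if m:
            entities[m.group(1)] = m.group(2)
    return entities


def _find_sidecar(pet_path: Path) -> Path | None:
    name = pet_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            candidate = pet_path.with_name(name[: -len(suffix)] + ".json")
            if candidate.exists():
                return candidate
    return None


def discover_bids(root) -> list[SubjectRecord]:
    """Discover PET acquisitions under a BIDS root.

    One record per ``*_pet.nii[.gz]`` file; entities parsed from the filename;
    the anatomical T1 and label volumes are looked up in the matching ``anat``
    folder.  Records missing a T1 are returned with ``t1_path=None`` plus a
    warning.  Output is sorted lexicographically by PET path.
    """
    root = Path(root)
    subject_dirs = sorted(root.glob("sub-*"))
    subject_dirs = [d for d in subject_dirs if d.is_dir()]
    if not subject_dirs:
        raise FormatError(f"no sub-* directories under {root}")
    records: list[SubjectRecord] = []
    for sub_dir in subject_dirs:
        session_dirs = sorted(d for d in sub_dir.glob("ses-*") if d.is_dir())
        scopes = session_dirs if session_dirs else [sub_dir]
        for scope in scopes:
            pet_files = sorted(scope.glob("pet/*_pet.nii*"))
            pet_files = [p for p in pet_files
                         if p.name.endswith((".nii", ".nii.gz"))]
            anat_dir = scope / "anat"
            t1s = sorted(anat_dir.glob("*_T1w.nii*")) if anat_dir.is_dir() else []
            labels = sorted(anat_dir.glob("*_dseg.nii*")) if anat_dir.is_dir() else []
            for pet_path in pet_files:
                ent = parse_bids_entities(pet_path.name)
                sub = ent.get("sub") or sub_dir.name[len("sub-"):]
                t1_path = t1s[0] if t1s else None
                if t1_path is None:
                    warnings.warn(f"no T1w found for {pet_path}")
                dfts = sorted(pet_path.parent.glob("*.dft"))
                records.append(
                    SubjectRecord(
                        subject_id=sub,
                        session_id=ent.get("ses"),
                        task_id=ent.get("task"),
                        run_id=ent.get("run"),
                        pet_path=pet_path,
                        t1_path=t1_path,
                        label_paths=list(labels),
                        dft_path=dfts[0] if dfts else None,
                    )
                )
    records.sort(key=lambda r: str(r.pet_path))
    return records


# ---------------------------------------------------------------------------
# Resampling and temporal averaging
# ---------------------------------------------------------------------------


def resample(source, transform=None, target_affine=None, target_shape=None,
             interpolation: str = "trilinear"):
    """Pull-resample a volume onto a target grid through a rigid transform.

    ``transform`` maps source world coordinates to target world coordinates
    (identity if ``None``).  Each target voxel's world coordinate is mapped
    through the inverse transform into the source volume and interpolated.
    Out-of-field voxels are set to 0.  Label volumes must use ``nearest``.
    """
    is_labels = isinstance(source, LabelVolume)
    if is_labels and interpolation != "nearest":
        raise ValueError("label volumes must be resampled with nearest interpolation")
    if interpolation not in {"trilinear", "nearest"}:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 0 if interpolation == "nearest" else 1
    data = source.labels if is_labels else source.data
    src_affine = source.affine
    if target_affine is None:
        target_affine = src_affine
    if target_shape is None:
        target_shape = data.shape

    if transform is None:
        world_map = np.eye(4)
    else:
        world_map = transform.matrix if hasattr(transform, "matrix") else np.asarray(transform)
    # target index -> target world -> (inverse map) source world -> source index
    full = np.linalg.inv(src_affine) @ np.linalg.inv(world_map) @ np.asarray(target_affine)
    idx = np.indices(target_shape, dtype=float).reshape(3, -1)
    src_idx = full[:3, :3] @ idx + full[:3, 3:4]
    out = ndimage.map_coordinates(
        np.asarray(data, dtype=float), src_idx, order=order, mode="constant", cval=0.0
    ).reshape(target_shape)
    if is_labels:
        return LabelVolume(np.rint(out).astype(np.int32), np.asarray(target_affine),
                           dict(source.name_map))
    return Volume3D(out, np.asarray(target_affine))


def time_weighted_average(pet: DynamicPET) -> Volume3D:
    """Duration-weighted mean over frames; the static volume used for
    coregistration and masking."""
    w = pet.frame_durations / pet.frame_durations.sum()
    data = np.tensordot(pet.frames, w, axes=([3], [0]))
    return Volume3D(data, pet.affine)
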