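"""Tracer kinetic quantification from time-activity curves.

Implemented models:

* **Logan plot** — graphical analysis for reversible tracers; with a
  reference-tissue input the slope is the distribution volume ratio
  (DVR, with BPnd = DVR - 1), with an arterial input it is the total
  distribution volume V_T.  The reduced form without the k2' term is used,
  appropriate at late times t >= t*.
* **Patlak-Gjedde plot** — graphical analysis for irreversible tracers;
  slope is the net influx rate Ki (min^-1), intercept the initial
  distribution volume V.
* **SRTM** — simplified reference tissue model solved with basis functions:
  C_t(t) = R1 C_ref(t) + (k2 - R1 k2a) [C_ref (*) exp(-k2a t)](t), scanning
  k2a over a grid (with local refinement) and solving the two linear
  coefficients by least squares.
* **SUVR** — ratio of duration-weighted mean activities over a late window.

All running integrals are 0-anchored trapezoids on frame mid-times (activity
taken as 0 at t = 0); arterial input curves are linearly resampled to the
frame mid-times before modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize_scalar

from .volumes_io import DynamicPET, InputCurve, LabelVolume, Volume3D


class KineticsError(ValueError):
    pass


@dataclass
class TAC:
    """A time-activity curve on the dynamic frame grid."""

    frame_mid_times: np.ndarray
    activity: np.ndarray
    frame_durations: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.frame_mid_times = np.asarray(self.frame_mid_times, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if len(self.frame_mid_times) < 3:
            raise ValueError("TAC length >= 3 required")
        if len(self.activity) != len(self.frame_mid_times):
            raise ValueError("TAC activity/time length mismatch")
        if np.any(np.diff(self.frame_mid_times) <= 0):
            raise ValueError("TAC times must be strictly increasing")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("TAC activity must be finite")
        if self.frame_durations is not None:
            self.frame_durations = np.asarray(self.frame_durations, dtype=float)


@dataclass
class KineticFit:
    model: str
    parameters: dict[str, float]
    t_star: float | None = None
    n_points_used: int = 0
    r_squared: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# TAC utilities
# ---------------------------------------------------------------------------


def extract_tac(pet: DynamicPET, labels: LabelVolume, region_id: int) -> TAC:
    """Per-frame unweighted mean activity over the voxels of one region."""
    mask = labels.labels == region_id
    if not mask.any():
        raise KineticsError(f"region {region_id} absent from label volume")
    activity = pet.frames[mask].mean(axis=0)
    return TAC(pet.frame_mid_times, activity, pet.frame_durations,
               source=labels.region_name(region_id))


def tac_from_values(pet_like: DynamicPET, values: np.ndarray, source: str = "") -> TAC:
    return TAC(pet_like.frame_mid_times, values, pet_like.frame_durations, source)


def _anchored(times: np.ndarray, values: np.ndarray):
    """Prepend the (t=0, activity=0) anchor unless the curve starts at 0."""
    if times[0] > 0:
        return np.concatenate([[0.0], times]), np.concatenate([[0.0], values])
    return times, values


def running_integral(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """0-anchored cumulative trapezoid of the curve, evaluated at ``times``."""
    t, v = _anchored(np.asarray(times, float), np.asarray(values, float))
    cum = cumulative_trapezoid(v, t, initial=0.0)
    return cum[1:] if len(t) != len(times) else cum


def tac_integral(tac: TAC, T: float) -> float:
    """Integral of the TAC from 0 to T (kBq*min/mL), 0-anchored trapezoid."""
    t, v = _anchored(tac.frame_mid_times, tac.activity)
    first_mid = tac.frame_mid_times[0]
    if T < first_mid:
        raise KineticsError(f"T={T} precedes the first frame mid-time {first_mid}")
    if T > tac.frame_mid_times[-1]:
        raise KineticsError(f"T={T} beyond the last frame mid-time")
    vT = np.interp(T, t, v)
    keep = t < T
    tt = np.concatenate([t[keep], [T]])
    vv = np.concatenate([v[keep], [vT]])
    return float(np.trapezoid(vv, tt))


def resample_input(curve, mid_times: np.ndarray) -> np.ndarray:
    """Linear resampling of an input curve onto frame mid-times (0-anchored
    before its first sample, held constant after its last)."""
    if isinstance(curve, TAC):
        t, v = curve.frame_mid_times, curve.activity
    else:
        t, v = curve.times, curve.activity
    t0, v0 = _anchored(t, v)
    return np.interp(mid_times, t0, v0)


def _is_reference_input(curve) -> bool:
    if isinstance(curve, InputCurve):
        return curve.kind == "reference_region"
    return True  # a tissue TAC used as input is a reference region curve


def _ols_line(x: np.ndarray, y: np.ndarray):
    A = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), res, _, _ = np.linalg.lstsq(A, y, rcond=None)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(res[0]) if len(res) else float(((A @ [slope, intercept] - y) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


# ---------------------------------------------------------------------------
# Graphical analyses
# ---------------------------------------------------------------------------


def logan(tac_target: TAC, input_curve, t_star: float = 20.0) -> KineticFit:
    """Logan graphical analysis: OLS of int(C_t)/C_t against int(C_in)/C_t
    over frames with mid-time >= t*."""
    t = tac_target.frame_mid_times
    if t_star > t[-1]:
        raise KineticsError("t_star beyond the last frame")
    cin = resample_input(input_curve, t)
    int_ct = running_integral(t, tac_target.activity)
    int_cin = running_integral(t, cin)
    window = t >= t_star
    if window.sum() < 3:
        raise KineticsError("fewer than 3 frames at/after t_star")
    ct = tac_target.activity[window]
    if np.any(ct <= 0):
        raise KineticsError("nonpositive target activity in the Logan window")
    x = int_cin[window] / ct
    y = int_ct[window] / ct
    slope, intercept, r2 = _ols_line(x, y)
    reference = _is_reference_input(input_curve)
    params = {"DVR" if reference else "VT": slope, "intercept": intercept}
    if reference:
        params["BPnd"] = slope - 1.0
    return KineticFit("logan", params, t_star, int(window.sum()), r2)


def patlak(tac_target: TAC, input_curve, t_star: float = 20.0) -> KineticFit:
    """Patlak-Gjedde plot: OLS of C_t/C_in against int(C_in)/C_in for
    mid-times >= t*; slope Ki (min^-1), intercept V."""
    t = tac_target.frame_mid_times
    if t_star > t[-1]:
        raise KineticsError("t_star beyond the last frame")
    cin = resample_input(input_curve, t)
    int_cin = running_integral(t, cin)
    window = t >= t_star
    if window.sum() < 3:
        raise KineticsError("fewer than 3 frames at/after t_star")
    if np.any(cin[window] <= 0):
        raise KineticsError("nonpositive input activity in the Patlak window")
    x = int_cin[window] / cin[window]
    y = tac_target.activity[window] / cin[window]
    slope, intercept, r2 = _ols_line(x, y)
    return KineticFit("patlak", {"Ki": slope, "V": intercept}, t_star,
                      int(window.sum()), r2)


# ---------------------------------------------------------------------------
# SRTM basis functions
# ---------------------------------------------------------------------------


def exp_conv_piecewise_linear(times: np.ndarray, values: np.ndarray,
                              k: float) -> np.ndarray:
    """Convolution B(t) = int_0^t C(s) exp(-k (t-s)) ds on a nonuniform grid,
    with C piecewise linear and anchored at C(0) = 0; exact per segment."""
    t, v = _anchored(np.asarray(times, float), np.asarray(values, float))
    B = np.zeros(len(t))
    for i in range(1, len(t)):
        dt = t[i] - t[i - 1]
        c0, c1 = v[i - 1], v[i]
        if k * dt < 1e-12:
            seg = 0.5 * (c0 + c1) * dt
        else:
            m = (c1 - c0) / dt
            e = np.exp(-k * dt)
            seg = c0 * (1 - e) / k + m * (dt / k - (1 - e) / k ** 2)
        B[i] = B[i - 1] * np.exp(-k * dt) + seg
    return B[1:] if len(t) != len(times) else B


def default_k2a_grid(n: int = 30, lo: float = 0.01, hi: float = 1.0) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n)


def _srtm_sse(k2a, t, ct, cref):
    basis = exp_conv_piecewise_linear(t, cref, k2a)
    A = np.vstack([cref, basis]).T
    theta, res, _, _ = np.linalg.lstsq(A, ct, rcond=None)
    sse = float(res[0]) if len(res) else float(((A @ theta - ct) ** 2).sum())
    return sse, theta


def srtm(tac_target: TAC, tac_ref: TAC, k2a_grid=None,
         refine: bool = True) -> KineticFit:
    """Simplified reference tissue model by basis-function search over k2a.

    For each candidate k2a the model is linear in (R1, k2 - R1 k2a); the k2a
    minimizing the residual is selected from the grid and then polished by a
    bounded 1-D search between its grid neighbours.  Reports R1, k2 (min^-1)
    and BPnd = k2/k2a - 1.
    """
    if k2a_grid is None:
        k2a_grid = default_k2a_grid()
    k2a_grid = np.asarray(k2a_grid, dtype=float)
    if len(k2a_grid) < 2:
        raise KineticsError("degenerate k2a grid: need >= 2 candidate values")
    if np.any(k2a_grid <= 0) or np.any(np.diff(k2a_grid) <= 0):
        raise KineticsError("k2a grid must be positive and sorted")
    t = tac_target.frame_mid_times
    if not np.allclose(t, tac_ref.frame_mid_times):
        raise KineticsError("target and reference TACs must share the frame grid")
    ct, cref = tac_target.activity, tac_ref.activity

    sses = np.empty(len(k2a_grid))
    for i, k2a in enumerate(k2a_grid):
        sses[i], _ = _srtm_sse(k2a, t, ct, cref)
    best = int(np.argmin(sses))
    if best in (0, len(k2a_grid) - 1):
        warnings.warn("grid does not bracket optimum: best k2a at grid boundary")
        k2a_best = k2a_grid[best]
    elif refine:
        res = minimize_scalar(lambda k: _srtm_sse(k, t, ct, cref)[0],
                              bounds=(k2a_grid[best - 1], k2a_grid[best + 1]),
                              method="bounded",
                              options={"xatol": 1e-6})
        k2a_best = float(res.x)
    else:
        k2a_best = k2a_grid[best]

    sse, theta = _srtm_sse(k2a_best, t, ct, cref)
    r1 = float(theta[0])
    k2 = float(theta[1] + r1 * k2a_best)
    bpnd = k2 / k2a_best - 1.0
    ss_tot = float(((ct - ct.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - sse / ss_tot
    return KineticFit("srtm", {"R1": r1, "k2": k2, "k2a": k2a_best, "BPnd": bpnd},
                      None, len(t), r2, extras={"sse": sse})


# ---------------------------------------------------------------------------
# SUVR
# ---------------------------------------------------------------------------


def _windowed_mean(tac: TAC, window) -> float:
    lo, hi = window
    sel = (tac.frame_mid_times >= lo) & (tac.frame_mid_times <= hi)
    if not sel.any():
        raise KineticsError(f"no frames inside window [{lo}, {hi}] min")
    w = (tac.frame_durations[sel] if tac.frame_durations is not None
         else np.ones(sel.sum()))
    return float(np.average(tac.activity[sel], weights=w))


def suvr(tac_target: TAC, tac_ref: TAC, window) -> KineticFit:
    """Standardized uptake value ratio: duration-weighted mean target
    activity over the window divided by the same for the reference."""
    num = _windowed_mean(tac_target, window)
    den = _windowed_mean(tac_ref, window)
    if den <= 0:
        raise KineticsError("reference mean must be positive for SUVR")
    sel = ((tac_target.frame_mid_times >= window[0])
           & (tac_target.frame_mid_times <= window[1]))
    return KineticFit("suvr", {"SUVR": num / den}, None, int(sel.sum()), None)


# ---------------------------------------------------------------------------
# Voxelwise parametric maps
# ---------------------------------------------------------------------------

_PRIMARY_PARAM = {"logan": "DVR", "patlak": "Ki", "srtm": "BPnd", "suvr": "SUVR"}


def voxelwise_map(pet: DynamicPET, input_curve, model: str,
                  mask: np.ndarray | None = None, **model_kwargs):
    """Apply a kinetic model independently to every voxel TAC.

    Returns ``(map, failures)``: a :class:`Volume3D` of the model's primary
    parameter (DVR, Ki, BPnd or SUVR) and a boolean volume marking voxels
    whose fit failed a precondition (their map value is 0, never
    interpolated).
    """
    if model not in _PRIMARY_PARAM:
        raise KineticsError(f"unknown model {model!r}")
    shape = pet.frames.shape[:3]
    if mask is None:
        mask = pet.frames.max(axis=3) > 0
    out = np.zeros(shape)
    failures = np.zeros(shape, dtype=bool)
    mids = pet.frame_mid_times
    durs = pet.frame_durations
    for idx in np.argwhere(mask):
        tac = TAC(mids, pet.frames[idx[0], idx[1], idx[2], :], durs)
        try:
            if model == "logan":
                fit = logan(tac, input_curve, **model_kwargs)
            elif model == "patlak":
                fit = patlak(tac, input_curve, **model_kwargs)
            elif model == "srtm":
                fit = srtm(tac, input_curve, **model_kwargs)
            else:
                fit = suvr(tac, input_curve, **model_kwargs)
            out[tuple(idx)] = fit.parameters[_PRIMARY_PARAM[model]]
        except (KineticsError, ValueError):
            failures[tuple(idx)] = True
    failures |= ~mask
    return Volume3D(out, pet.affine), failures
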