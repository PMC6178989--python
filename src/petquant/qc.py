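"""Automated quality control.

For each subject and processing stage a trio of similarity metrics is
computed (CC = Pearson cross-correlation, MI = mutual information, FSE =
feature-space/joint entropy).  Across subjects, each (stage, metric) sample
is modeled with a Gaussian-kernel density estimate; a subject's score is the
lowest-density-region tail probability — the total probability mass of
points whose density does not exceed the density at the subject's value.
The mode scores 1, far outliers score near 0, and values with probability
below the threshold (default 0.05) are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coregistration import (cross_correlation, feature_space_entropy,
                             joint_histogram, mutual_information)

QC_METRICS = ("CC", "MI", "FSE")
DEFAULT_FLAG_THRESHOLD = 0.05


class QCError(ValueError):
    pass


@dataclass
class QCRecord:
    subject_id: str
    stage: str
    metric: str
    value: float
    session_id: str | None = None
    task_id: str | None = None
    density: float | None = None
    outlier_probability: float | None = None
    flagged: bool = False


@dataclass
class KDEModel:
    """Gaussian-kernel density estimate on an explicit evaluation grid."""

    values: np.ndarray
    bandwidth: float
    grid: np.ndarray = field(default=None)
    density: np.ndarray = field(default=None)
    degenerate: bool = False

    def evaluate(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.values[None, :]) / self.bandwidth
        d = np.exp(-0.5 * z ** 2).sum(axis=1)
        d /= len(self.values) * self.bandwidth * np.sqrt(2 * np.pi)
        return d


def silverman_bandwidth(values: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * len(values) ** (-0.2)


def fit_kde(values, grid_points: int = 512, min_values: int = 5) -> KDEModel:
    """Fit a Gaussian KDE with Silverman bandwidth.

    Requires at least ``min_values`` finite values (the group-QC contract is
    5 subjects); a zero-spread sample yields a degenerate sentinel model
    under which nothing is flagged.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < min_values:
        raise QCError("insufficient subjects for automated QC (need >= 5)")
    h = silverman_bandwidth(values)
    if h <= 0:
        return KDEModel(values, bandwidth=0.0, degenerate=True)
    # covers at least [min - 3h, max + 3h]; the wider span keeps the tail
    # integral honest for values just beyond the sample range
    half_span = max(6 * h, 3 * np.ptp(values) if np.ptp(values) > 0 else 6 * h)
    grid = np.linspace(values.min() - half_span, values.max() + half_span,
                       grid_points)
    model = KDEModel(values, bandwidth=h)
    model.grid = grid
    model.density = model.evaluate(grid)
    return model


def outlier_probability(model: KDEModel, x: float,
                        threshold: float = DEFAULT_FLAG_THRESHOLD):
    """Lowest-density-region tail probability of ``x`` under the KDE.

    p(x) = integral of the density over {u : density(u) <= density(x)},
    evaluated on the model grid; ``flag`` is True when p < threshold.
    Degenerate (zero-spread) models flag nothing and score 1.
    """
    if model.degenerate:
        return 1.0, False
    dx = float(model.evaluate(x)[0])
    below = model.density <= dx
    cell = model.grid[1] - model.grid[0]
    total = float(model.density.sum() * cell)
    p = float(model.density[below].sum() * cell) / total if total > 0 else 0.0
    p = min(p, 1.0)
    return p, bool(p < threshold)


# ---------------------------------------------------------------------------
# Stage metrics
# ---------------------------------------------------------------------------


def similarity_metrics(a, b, mask=None, bins: int = 64) -> dict[str, float]:
    """The QC similarity trio between two volumes on the same grid."""
    h = joint_histogram(a, b, mask, bins=bins)
    return {
        "CC": cross_correlation(a, b, mask),
        "MI": mutual_information(h),
        "FSE": feature_space_entropy(h),
    }


def coreg_qc_metrics(pet_static, t1_in_pet_space, mask=None,
                     subject_id: str = "", bins: int = 64,
                     **entities) -> list[QCRecord]:
    """CC, MI and FSE between the static PET and the resampled T1."""
    metrics = similarity_metrics(pet_static, t1_in_pet_space, mask, bins=bins)
    return [QCRecord(subject_id=subject_id, stage="coregistration",
                     metric=name, value=val, **entities)
            for name, val in metrics.items()]


def stage_qc_metrics(stage: str, before, after, mask=None,
                     subject_id: str = "", bins: int = 64,
                     **entities) -> list[QCRecord]:
    """Same similarity trio between a stage's input and output volumes
    (extension of the coregistration QC to the PVC/quantification stages)."""
    metrics = similarity_metrics(before, after, mask, bins=bins)
    return [QCRecord(subject_id=subject_id, stage=stage, metric=name,
                     value=val, **entities)
            for name, val in metrics.items()]


def group_qc(records: list[QCRecord],
             threshold: float = DEFAULT_FLAG_THRESHOLD,
             min_subjects: int = 5) -> list[QCRecord]:
    """Score every record against the group distribution of its
    (stage, metric) cell; under-populated cells are skipped with a warning.

    Each subject is scored against the KDE of the *other* subjects' values
    (leave-one-out — a subject's own kernel must not certify its own value),
    and the raw tail probability gets the add-one finite-sample correction
    p = (1 + (n-1) p_raw) / n, which makes the score a valid p-value: a
    gross outlier scores 1/n while under the null the flag rate stays well
    below the nominal threshold.

    Returns new records sorted by (stage, metric, subject, session, task).
    """
    cells: dict[tuple, list[QCRecord]] = {}
    for rec in records:
        cells.setdefault((rec.stage, rec.metric), []).append(rec)
    out: list[QCRecord] = []
    for (stage, metric), cell in sorted(cells.items()):
        values = np.array([r.value for r in cell], dtype=float)
        n = len(values)
        if n < min_subjects:
            warnings.warn(
                f"QC cell ({stage}, {metric}) has {n} subjects; "
                f"need {min_subjects}, skipped")
            continue
        for i, rec in enumerate(cell):
            model = fit_kde(np.delete(values, i), min_values=min_subjects - 1)
            p_raw, _ = outlier_probability(model, rec.value, threshold)
            p = (1.0 + (n - 1) * p_raw) / n
            flag = bool(p < threshold) and not model.degenerate
            density = (0.0 if model.degenerate
                       else float(model.evaluate(rec.value)[0]))
            out.append(QCRecord(
                subject_id=rec.subject_id, stage=stage, metric=metric,
                value=rec.value, session_id=rec.session_id,
                task_id=rec.task_id, density=density,
                outlier_probability=p, flagged=flag))
    out.sort(key=lambda r: (r.stage, r.metric, r.subject_id,
                            r.session_id or "", r.task_id or ""))
    return out
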