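"""Functional and diffusion connectivity matrix construction.

Functional connectivity (FC) is the pairwise Pearson correlation between
ROI time series, Fisher r-to-z transformed. Task runs are first
residualized against HRF-convolved block regressors so the resulting
matrices represent intrinsic (background) connectivity during task
performance, directly comparable to resting-state FC. Streamline-count
matrices are normalized by the mean volume of the two endpoint ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ConnectivityMatrix, NodeScheme, ValidationError
from .synth import canonical_hrf

__all__ = [
    "RoiTimeseries",
    "TaskDesign",
    "ConstantSeriesError",
    "fc_from_timeseries",
    "hrf_block_regressor",
    "task_regressors",
    "regress_task",
    "normalize_dti_counts",
    "read_timeseries",
    "write_timeseries",
]

R_CLIP = 1.0 - 1e-7


class ConstantSeriesError(ValidationError):
    """An ROI series is constant; its correlations are undefined."""


@dataclass
class RoiTimeseries:
    """ROI x T series for one subject and condition."""

    values: np.ndarray
    scheme: NodeScheme
    tr: float = 2.5
    condition: str = "rest"
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, t = self.values.shape
        if n != len(self.scheme):
            raise ValidationError(f"{n} series but scheme has {len(self.scheme)} nodes")
        if t < 20:
            raise ValidationError(f"series too short (T={t} < 20)")
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite sample in time series")


@dataclass
class TaskDesign:
    """Block design: a label sequence over 30-s blocks at a fixed TR.

    The default alternates right-hand movement, rest, left-hand movement,
    rest, tiling 600 volumes at TR = 2.5 s; a sequence that overruns the
    scan is truncated at T with a warning.
    """

    total_volumes: int = 600
    tr: float = 2.5
    block_seconds: float = 30.0
    sequence: tuple[str, ...] = ("right", "rest", "left", "rest")

    def __post_init__(self) -> None:
        if self.total_volumes <= 0:
            raise ValidationError("design must span at least one volume")
        if self.block_seconds <= 0 or self.tr <= 0:
            raise ValidationError("block length and TR must be positive")

    def volume_labels(self) -> list[str]:
        per_block = int(round(self.block_seconds / self.tr))
        labels: list[str] = []
        while len(labels) < self.total_volumes:
            for lab in self.sequence:
                labels.extend([lab] * per_block)
        if len(labels) > self.total_volumes:
            full_cycle = per_block * len(self.sequence)
            if self.total_volumes % full_cycle:
                warnings.warn(
                    f"design truncated at {self.total_volumes} volumes "
                    f"(cycle is {full_cycle} volumes)"
                )
        return labels[: self.total_volumes]

    @property
    def conditions(self) -> list[str]:
        return [c for c in dict.fromkeys(self.sequence) if c != "rest"]


def fc_from_timeseries(ts: RoiTimeseries) -> ConnectivityMatrix:
    """Pairwise Pearson r over time for every node pair, clipped to
    |r| <= 1 - 1e-7, Fisher z-transformed, diagonal 0."""
    x = ts.values
    rng_ = np.ptp(x, axis=1)
    if np.any(rng_ == 0):
        node = ts.scheme.names[int(np.argmin(rng_))]
        raise ConstantSeriesError(f"constant time series at node {node!r}")
    r = np.corrcoef(x)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    modality = "FC_task" if ts.condition == "task" else "FC_rest"
    return ConnectivityMatrix.create(
        z, ts.scheme, modality=modality, level="subject",
        subject_id=ts.subject_id, weight_kind="fisher_z",
    )


def hrf_block_regressor(design: TaskDesign, condition: str | None = None) -> np.ndarray:
    """Boxcar for one condition (or all non-rest blocks when ``condition`` is
    None) convolved with the canonical double-gamma HRF, unit-peak scaled."""
    labels = design.volume_labels()
    if condition is None:
        box = np.array([1.0 if lab != "rest" else 0.0 for lab in labels])
    else:
        box = np.array([1.0 if lab == condition else 0.0 for lab in labels])
    hrf = canonical_hrf(design.tr)
    reg = np.convolve(box, hrf)[: design.total_volumes]
    m = np.abs(reg).max()
    return reg / m if m > 0 else reg


def task_regressors(design: TaskDesign) -> np.ndarray:
    """T x k matrix of HRF-convolved regressors, one per non-rest condition."""
    return np.column_stack([hrf_block_regressor(design, c) for c in design.conditions])


def regress_task(ts: RoiTimeseries, regressors: np.ndarray) -> RoiTimeseries:
    """Per-node OLS residualization of the series on [intercept, regressors];
    residuals are orthogonal to every regressor (background connectivity)."""
    r = np.atleast_2d(np.asarray(regressors, float))
    if r.shape[0] != ts.values.shape[1]:
        r = r.T
    t = ts.values.shape[1]
    if r.shape[0] != t:
        raise ValidationError("regressor length does not match series length")
    if r.shape[1] >= t:
        raise ValidationError("more regressors than time points")
    x = np.column_stack([np.ones(t), r])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("rank-deficient task design")
    y = ts.values.T  # T x N
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = (y - x @ beta).T
    return RoiTimeseries(resid, ts.scheme, tr=ts.tr,
                         condition=ts.condition, subject_id=ts.subject_id)


def normalize_dti_counts(
    counts: ConnectivityMatrix | np.ndarray,
    roi_sizes: np.ndarray,
    scheme: NodeScheme | None = None,
    subject_id: str | None = None,
) -> ConnectivityMatrix:
    """Normalize streamline counts by ROI size: w_ij = c_ij / ((v_i + v_j)/2).

    Zero counts stay zero and, within any fixed pair of ROI sizes, edge
    ordering is preserved.
    """
    if isinstance(counts, ConnectivityMatrix):
        scheme = counts.scheme
        c = counts.values
        subject_id = subject_id or counts.subject_id
    else:
        if scheme is None:
            raise ValidationError("scheme required for a bare count array")
        c = np.asarray(counts, float)
    v = np.asarray(roi_sizes, float)
    if v.shape != (len(scheme),):
        raise ValidationError(f"roi_sizes must have length {len(scheme)}")
    if np.any(v <= 0):
        raise ValidationError("ROI sizes must be positive")
    if np.any(c < 0):
        raise ValidationError("streamline counts must be nonnegative")
    denom = (v[:, None] + v[None, :]) / 2.0
    w = c / denom
    return ConnectivityMatrix.create(
        w, scheme, modality="DTI", level="subject",
        subject_id=subject_id, weight_kind="normalized_count",
    )


def write_timeseries(ts: RoiTimeseries, path) -> None:
    """TSV: one row per node (node name first column), volumes as columns."""
    with open(path, "w") as f:
        t = ts.values.shape[1]
        f.write("node\t" + "\t".join(f"t{i}" for i in range(t)) + "\n")
        for name, row in zip(ts.scheme.names, ts.values):
            f.write(name + "\t" + "\t".join(format(v, ".8g") for v in row) + "\n")


def read_timeseries(path, scheme: NodeScheme, tr: float = 2.5,
                    condition: str = "rest", subject_id: str | None = None) -> RoiTimeseries:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    order = scheme.indices_of(df.index.tolist())
    values = np.empty((len(scheme), df.shape[1]))
    values[order] = df.to_numpy(float)
    return RoiTimeseries(values, scheme, tr=tr, condition=condition, subject_id=subject_id)
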