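"""Structural covariance networks (SCN).

An SCN is a group-level network: after regressing age, sex and total
intracranial volume out of each region's morphometry, edge (i, j) is the
cross-subject Pearson correlation between regions i and j, Fisher
r-to-z transformed. Because each group yields a single network, group
inference on SCN metrics uses label permutation: group assignments are
shuffled, both SCNs and their metrics recomputed, and the two-tailed
permutation p-value reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, NodeScheme, ValidationError
from .graphnet import (
    ThresholdConfig,
    clustering_coefficient,
    global_efficiency,
    proportional_threshold,
)
from .synth import Morphometry

__all__ = [
    "ConstantRegionError",
    "ScnNetwork",
    "residualize_covariates",
    "build_scn",
    "scn_metrics",
    "scn_group_compare",
    "SCN_METRICS",
]

R_CLIP = 1.0 - 1e-7


class ConstantRegionError(ValidationError):
    """A region has zero variance across subjects; correlation undefined."""


@dataclass
class ScnNetwork:
    """Group-level Fisher-z covariance network."""

    values: np.ndarray
    group: str
    n_subjects: int

    def to_connectivity(self, scheme: NodeScheme) -> ConnectivityMatrix:
        return ConnectivityMatrix.create(
            self.values, scheme, modality="SCN", level="group", weight_kind="fisher_z"
        )


def residualize_covariates(morph: Morphometry) -> Morphometry:
    """OLS-residualize every region on [intercept, age, sex, TIV].

    Residuals have zero mean and zero sample correlation with each
    covariate, so any linear covariate effect planted in the raw values is
    removed exactly.
    """
    x = np.column_stack([
        np.ones(len(morph.covariates)),
        morph.covariates["age"].to_numpy(float),
        morph.covariates["sex"].to_numpy(float),
        morph.covariates["tiv"].to_numpy(float),
    ])
    if x.shape[0] < x.shape[1] + 2:
        raise ValidationError(
            f"need at least {x.shape[1] + 2} subjects to adjust {x.shape[1] - 1} covariates"
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("rank-deficient covariate matrix")
    y = morph.values.to_numpy(float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return Morphometry(
        pd.DataFrame(resid, index=morph.values.index, columns=morph.values.columns),
        morph.covariates,
    )


def build_scn(adjusted: Morphometry, subject_ids: Sequence[str], group: str = "") -> ScnNetwork:
    """Cross-subject Pearson correlations between all region pairs for one
    group, clipped to |r| <= 1 - 1e-7 and Fisher z-transformed; diagonal 0."""
    sub = adjusted.values.loc[list(subject_ids)]
    n = len(sub)
    if n < 4:
        raise ValidationError(f"need >= 4 subjects for an SCN, got {n}")
    y = sub.to_numpy(float)
    rng_ = np.ptp(y, axis=0)
    if np.any(rng_ == 0):
        name = sub.columns[int(np.argmin(rng_))]
        raise ConstantRegionError(f"region {name!r} is constant across subjects")
    r = np.corrcoef(y, rowvar=False)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ScnNetwork(z, group=group, n_subjects=n)


def _mean_retained_z(scn: ScnNetwork, rho: float) -> float:
    wadj = proportional_threshold(scn.values, ThresholdConfig(rho, True, "weighted"))
    iu = np.triu_indices(wadj.shape[0], 1)
    retained = wadj[iu][wadj[iu] != 0]
    return float(retained.mean())


#: cheap global SCN metrics (computed on the top-rho positive-edge network)
SCN_METRICS: dict[str, Callable[[ScnNetwork, float], float]] = {
    "mean_correlation_strength": _mean_retained_z,
    "global_efficiency": lambda s, rho: global_efficiency(
        proportional_threshold(s.values, ThresholdConfig(rho, True, "binary"))
    ),
    "mean_degree": lambda s, rho: float(
        proportional_threshold(s.values, ThresholdConfig(rho, True, "binary")).sum(axis=1).mean()
    ),
    "clustering": lambda s, rho: clustering_coefficient(
        proportional_threshold(s.values, ThresholdConfig(rho, True, "binary"))
    )[0],
}


def scn_metrics(scn: ScnNetwork, rho: float = 0.05) -> dict[str, float]:
    """The global metric set for one SCN at density rho (positive edges only)."""
    return {name: fn(scn, rho) for name, fn in SCN_METRICS.items()}


def scn_group_compare(
    adjusted: Morphometry,
    ids_a: Sequence[str],
    ids_b: Sequence[str],
    metric_names: Sequence[str],
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    rho: float = 0.05,
) -> dict[str, dict[str, float]]:
    """Permutation test on SCN metric differences between two groups.

    Group labels are shuffled ``n_perm`` times; both SCNs and the requested
    metrics are recomputed per shuffle; two-tailed
    p = (1 + #{|perm diff| >= |observed diff|}) / (n_perm + 1).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    unknown = [m for m in metric_names if m not in SCN_METRICS]
    if unknown:
        raise ValidationError(f"unknown SCN metric(s): {unknown}")

    def diffs(a_ids, b_ids) -> dict[str, float]:
        sa = build_scn(adjusted, a_ids)
        sb = build_scn(adjusted, b_ids)
        return {m: SCN_METRICS[m](sa, rho) - SCN_METRICS[m](sb, rho) for m in metric_names}

    observed = diffs(list(ids_a), list(ids_b))
    pooled = np.array(list(ids_a) + list(ids_b))
    na = len(ids_a)
    exceed = {m: 0 for m in metric_names}
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        d = diffs(pooled[perm[:na]].tolist(), pooled[perm[na:]].tolist())
        for m in metric_names:
            if abs(d[m]) >= abs(observed[m]) - 1e-12:
                exceed[m] += 1
    return {
        m: {
            "observed_diff": observed[m],
            "p": (1 + exceed[m]) / (n_perm + 1),
        }
        for m in metric_names
    }
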