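"""Edge-wise structure-function coupling between connectivity modalities.

Coupling between two matrices on the same node scheme is the Pearson
correlation of their upper-triangle edge vectors (raw weights, not
thresholded topology). Two couplings are compared with the Fisher r-to-z
statistic z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import ConnectivityMatrix, ValidationError
from .graphnet import ThresholdConfig, proportional_threshold

__all__ = ["CouplingResult", "CouplingComparison", "edge_vector", "coupling", "fisher_compare"]


@dataclass(frozen=True)
class CouplingResult:
    """Edge-wise cross-modal correlation."""

    r: float
    p: float
    n_edges: int
    modality_a: str
    modality_b: str
    mask: str = "all"


@dataclass(frozen=True)
class CouplingComparison:
    """Fisher z comparison of two independent couplings; z is antisymmetric
    under swapping the inputs, p is two-tailed normal."""

    z: float
    p: float
    r1: float
    n1: int
    r2: float
    n2: int


def edge_vector(matrix: ConnectivityMatrix, mask: np.ndarray | None = None) -> np.ndarray:
    """Strict upper-triangle weights in fixed (i < j) row-major order; with a
    boolean edge mask, only the masked entries (same ordering)."""
    n = matrix.values.shape[0]
    iu = np.triu_indices(n, 1)
    v = matrix.values[iu]
    if mask is None:
        return v
    m = np.asarray(mask, bool)
    if m.shape == (n, n):
        m = m[iu]
    if m.shape != v.shape:
        raise ValidationError("edge mask has wrong shape")
    return v[m]


def thresholded_union_mask(
    a: ConnectivityMatrix, b: ConnectivityMatrix, rho: float = 0.05
) -> np.ndarray:
    """Boolean edge mask (upper-triangle order): union of each matrix's
    top-rho edges."""
    n = a.values.shape[0]
    iu = np.triu_indices(n, 1)
    cfg = ThresholdConfig(rho, True, "binary")
    return (proportional_threshold(a, cfg)[iu] > 0) | (proportional_threshold(b, cfg)[iu] > 0)


def coupling(
    a: ConnectivityMatrix,
    b: ConnectivityMatrix,
    mask: str = "all",
    rho: float = 0.05,
) -> CouplingResult:
    """Pearson correlation between the edge vectors of two matrices.

    mask='all' uses all N(N-1)/2 unique node pairs; mask='thresholded'
    restricts to the union of each matrix's top-rho edges. The p-value is
    the two-tailed t transform with n_edges - 2 degrees of freedom.
    """
    if a.scheme.names != b.scheme.names:
        raise ValidationError("matrices use different node schemes")
    if mask == "all":
        edge_mask = None
    elif mask == "thresholded":
        edge_mask = thresholded_union_mask(a, b, rho)
        if int(edge_mask.sum()) < 10:
            raise ValidationError("thresholded mask retains fewer than 10 edges")
    else:
        raise ValidationError(f"unknown mask {mask!r}")
    va = edge_vector(a, edge_mask)
    vb = edge_vector(b, edge_mask)
    if va.std() == 0 or vb.std() == 0:
        raise ValidationError("zero-variance edge vector")
    res = sps.pearsonr(va, vb)
    return CouplingResult(
        r=float(res.statistic), p=float(res.pvalue), n_edges=len(va),
        modality_a=a.modality, modality_b=b.modality, mask=mask,
    )


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> CouplingComparison:
    """Compare two independent correlations via Fisher r-to-z."""
    if n1 <= 3 or n2 <= 3:
        raise ValidationError("need n > 3 in both samples")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValidationError("|r| must be < 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return CouplingComparison(z=float(z), p=float(p), r1=r1, n1=n1, r2=r2, n2=n2)
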