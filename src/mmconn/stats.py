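"""Group-comparison and clinical correlation statistics.

The testing policy mirrors standard clinical-neuroimaging practice: a
Shapiro-Wilk normality gate selects between a Welch t-test (with Cohen's d)
and a Mann-Whitney U test (with rank-biserial correlation); categorical
variables use Pearson's chi-square; multiple comparisons are controlled by
Benjamini-Hochberg FDR; metric-vs-clinical associations use Spearman rank
correlation (exact permutation p for n <= 10, t approximation above).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import CohortTable, ValidationError

__all__ = [
    "GroupComparison",
    "ClinicalCorrelation",
    "compare_groups",
    "mann_whitney",
    "rank_biserial",
    "cohens_d",
    "chi_square_counts",
    "fdr_bh",
    "spearman",
    "clinical_correlation_table",
]


@dataclass(frozen=True)
class GroupComparison:
    test: str  # "t" | "mann_whitney" | "chi_square"
    statistic: float
    p: float
    effect_size: float
    effect_name: str  # "cohens_d" | "rank_biserial" | "none"
    mean_a: float | None = None
    sd_a: float | None = None
    mean_b: float | None = None
    sd_b: float | None = None
    n_a: int = 0
    n_b: int = 0


@dataclass(frozen=True)
class ClinicalCorrelation:
    metric: str
    clinical: str
    rho: float
    p: float
    n: int

    @property
    def stars(self) -> str:
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""


def cohens_d(a, b) -> float:
    """(mean_a - mean_b) / pooled SD, n-1 pooling."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 observations per group")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValidationError("zero pooled SD")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def rank_biserial(u: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation r = 1 - 2U/(n1*n2) for a Mann-Whitney U."""
    if not 0 <= u <= n1 * n2:
        raise ValidationError(f"U={u} outside [0, {n1 * n2}]")
    return 1.0 - 2.0 * u / (n1 * n2)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #{(i,j): a_i > b_j} + 0.5 #{ties}."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(a, b, exact_max_n: int = 10) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    For n1 + n2 <= ``exact_max_n`` the p-value is the exact permutation
    probability over all C(n1+n2, n1) group labelings (valid under ties);
    larger samples use the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    u_obs = _u_statistic(a, b)
    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([a, b])
        idx = np.arange(n1 + n2)
        # two-tailed: distance of U from its null mean
        mu = n1 * n2 / 2.0
        count = 0
        total = 0
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
            total += 1
        return u_obs, count / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def compare_groups(values_a, values_b, policy: str = "auto") -> GroupComparison:
    """Compare two samples with the gated parametric/non-parametric policy.

    policy='auto' runs Shapiro-Wilk on each group at alpha = 0.05 and picks
    the Welch t-test (effect size Cohen's d) only if both groups pass;
    otherwise the Mann-Whitney U test (effect size rank-biserial r).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("need >= 3 observations per group")
    if policy not in ("auto", "t", "mann_whitney"):
        raise ValidationError(f"unknown policy {policy!r}")
    if policy == "auto":
        normal = all(
            x.std() > 0 and sps.shapiro(x).pvalue > 0.05 for x in (a, b)
        )
        policy = "t" if normal else "mann_whitney"
    summary = dict(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        n_a=len(a), n_b=len(b),
    )
    if policy == "t":
        res = sps.ttest_ind(a, b, equal_var=False)
        try:
            d = cohens_d(a, b)
        except ValidationError:
            d = 0.0
        return GroupComparison("t", float(res.statistic), float(res.pvalue),
                               d, "cohens_d", **summary)
    u, p = mann_whitney(a, b)
    return GroupComparison("mann_whitney", u, p,
                           rank_biserial(u, len(a), len(b)), "rank_biserial", **summary)


def chi_square_counts(counts_a, counts_b) -> GroupComparison:
    """Pearson chi-square (no Yates correction) on a 2 x k contingency table
    of category counts per group."""
    table = np.array([counts_a, counts_b], float)
    if table.min() < 0 or table.sum() == 0:
        raise ValidationError("invalid contingency counts")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return GroupComparison("chi_square", float(chi2), float(p), float("nan"), "none",
                           n_a=int(table[0].sum()), n_b=int(table[1].sum()))


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (reject flags, adjusted p)."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-tailed permutation p for Spearman rho at small n: enumerate
    all n! orderings of one rank vector (chunked matmul)."""
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        raise ValidationError("constant input vector")
    obs = abs(rho_obs)
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []

    def flush(chunk) -> int:
        perm = np.array(chunk)
        stat = np.abs((ryc[perm] @ rxc) / denom)
        return int((stat >= obs - 1e-12).sum())

    for p in itertools.permutations(range(n)):
        chunk.append(p)
        total += 1
        if len(chunk) == 100_000:
            count += flush(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
    return count / total


def spearman(x, y, metric: str = "x", clinical: str = "y") -> ClinicalCorrelation:
    """Tie-aware Spearman rank correlation.

    rho is the Pearson correlation of mid-ranks; the p-value is an exact
    permutation probability for n <= 10 and the t approximation otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValidationError("need equal-length inputs with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n <= 10:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return ClinicalCorrelation(metric, clinical, rho, p, n)


def clinical_correlation_table(
    metrics_by_subject: pd.DataFrame,
    cohort: CohortTable,
    pairs: list[tuple[str, str]],
) -> list[ClinicalCorrelation]:
    """Spearman correlations between network metrics and clinical measures
    in the patient group.

    ``metrics_by_subject`` is indexed by subject_id with one column per
    metric; ``pairs`` lists (metric, clinical measure) combinations, where
    the clinical measure is a cohort column (grip_left, grip_right,
    alsfrs_r, ...).
    """
    pat = cohort.patients.set_index("subject_id")
    common = [s for s in pat.index if s in metrics_by_subject.index]
    if not common:
        raise ValidationError("no overlapping patient subjects")
    out = []
    for metric, clinical in pairs:
        if metric not in metrics_by_subject.columns:
            raise ValidationError(f"unknown metric {metric!r}")
        if clinical not in pat.columns:
            raise ValidationError(f"unknown clinical measure {clinical!r}")
        m = metrics_by_subject.loc[common, metric].to_numpy(float)
        c = pat.loc[common, clinical].to_numpy(float)
        out.append(spearman(m, c, metric=metric, clinical=clinical))
    return out
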