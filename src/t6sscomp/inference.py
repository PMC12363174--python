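"""Hypothesis-level statistics for the competition-relatedness analysis.

* :func:`relatedness_regression` — OLS of the per-strain sensitivity
  statistic S on a relatedness predictor (cophenetic distance to the focal
  strain, or resource overlap), with both a parametric slope p-value and a
  predictor-permutation p-value.
* :func:`permanova` — one-factor permutational multivariate ANOVA on a
  distance matrix (weighted UniFrac in the pipeline), with the pseudo-F
  partition of squared distances and a label-permutation test.
* :func:`rank_sum_test` — Wilcoxon-Mann-Whitney for CFU contrasts.
* :func:`bh_fdr` — Benjamini-Hochberg adjustment for families of
  differential-abundance tests.
* :func:`qpcr_quantify` — absolute quantification from a Cq standard
  curve, including the amplification-efficiency diagnostic.

All permutation p-values use the add-one rule p = (1 + #{T_perm >= T_obs})
/ (n_perm + 1), so p = 0 is impossible and p >= 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import CalibrationError, InsufficientDataError

__all__ = [
    "RegressionResult",
    "PermanovaResult",
    "QpcrCalibration",
    "relatedness_regression",
    "permanova",
    "permanova_null_pvalues",
    "rank_sum_test",
    "bh_fdr",
    "qpcr_quantify",
]


@dataclass
class RegressionResult:
    """OLS fit of sensitivity on a relatedness predictor."""

    slope: float
    intercept: float
    r_squared: float
    p_parametric: float
    p_permutation: float
    n: int
    n_perm: int

    def summary(self) -> str:
        return (
            f"OLS sensitivity ~ predictor (n={self.n})\n"
            f"  slope      {self.slope: .4f}\n"
            f"  intercept  {self.intercept: .4f}\n"
            f"  R^2        {self.r_squared:.4f}\n"
            f"  p (param)  {self.p_parametric:.4g}\n"
            f"  p (perm)   {self.p_permutation:.4g}  ({self.n_perm} permutations)"
        )


def relatedness_regression(scores, predictor, n_perm: int = 9999,
                           seed: int = 0) -> RegressionResult:
    """Regress per-strain sensitivity S on a relatedness predictor.

    ``scores`` and ``predictor`` are aligned per-strain values (Series or
    arrays); pairs with a missing value on either side are excluded. The
    permutation p-value shuffles the predictor and counts |slope| >=
    |observed slope| with the add-one rule.
    """
    s = pd.Series(scores).astype(float)
    x = pd.Series(predictor).astype(float)
    if isinstance(scores, pd.Series) and isinstance(predictor, pd.Series):
        x = x.reindex(s.index)
    mask = s.notna() & x.notna()
    s, x = s[mask].to_numpy(), x[mask].to_numpy()
    n = len(s)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        return RegressionResult(float("nan"), float(s.mean()), 0.0,
                                float("nan"), float("nan"), n, n_perm)

    fit = sm.OLS(s, sm.add_constant(x)).fit()
    slope = float(fit.params[1])
    intercept = float(fit.params[0])

    # permutation null for the slope: shuffle the predictor
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    sc = s - s.mean()
    denom = (xc ** 2).sum()
    perm_slopes = np.empty(n_perm)
    for b in range(n_perm):
        xp = xc[rng.permutation(n)]
        perm_slopes[b] = (xp * sc).sum() / denom
    p_perm = (1 + (np.abs(perm_slopes) >= abs(slope)).sum()) / (n_perm + 1)

    return RegressionResult(
        slope=slope, intercept=intercept, r_squared=float(fit.rsquared),
        p_parametric=float(fit.pvalues[1]), p_permutation=float(p_perm),
        n=n, n_perm=n_perm,
    )


@dataclass
class PermanovaResult:
    """One-factor PERMANOVA on a distance matrix."""

    pseudo_f: float
    r_squared: float
    p: float
    n_perm: int
    n_samples: int
    n_groups: int

    def summary(self) -> str:
        return (
            f"PERMANOVA ({self.n_samples} samples, {self.n_groups} groups)\n"
            f"  pseudo-F  {self.pseudo_f:.4f}\n"
            f"  R^2       {self.r_squared:.4f}\n"
            f"  p         {self.p:.4g}  ({self.n_perm} permutations)"
        )


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, codes: np.ndarray):
    """Pseudo-F and R^2 from the squared-distance partition.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within = sum_g sum_{i<j in g}
    d_ij^2 / n_g (the Gower-centered partition); SS_between is the
    difference.
    """
    n = len(labels)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in codes:
        mask = labels == g
        n_g = mask.sum()
        ss_within += d2[np.ix_(mask, mask)].sum() / (2 * n_g)
    ss_between = ss_total - ss_within
    k = len(codes)
    if ss_within == 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(dist, groups, n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA of a distance matrix by one factor.

    ``dist``: square symmetric distance matrix (ndarray, DataFrame, or
    skbio DistanceMatrix); ``groups``: per-sample labels in matrix order
    (or a mapping/Series keyed by sample id when ``dist`` carries ids).
    Every group must have >= 2 samples.
    """
    ids = None
    if hasattr(dist, "ids"):  # skbio DistanceMatrix
        ids = list(dist.ids)
        d = np.asarray(dist.data, dtype=float)
    elif isinstance(dist, pd.DataFrame):
        ids = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    if isinstance(groups, (dict, pd.Series)) and ids is not None:
        labels = np.asarray([groups[i] for i in ids])
    else:
        labels = np.asarray(list(groups))
    if len(labels) != d.shape[0]:
        raise ValueError("groups length does not match distance matrix")
    codes, counts = np.unique(labels, return_counts=True)
    if len(codes) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        single = codes[counts < 2]
        raise ValueError(f"singleton group(s): {list(single)}")

    d2 = d ** 2
    f_obs, r2 = _pseudo_f(d2, labels, codes)

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f(d2, labels[rng.permutation(len(labels))], codes)
        if f_perm >= f_obs:
            count_ge += 1
    p = (1 + count_ge) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm,
                           len(labels), len(codes))


def permanova_null_pvalues(n_samples_per_group: int, n_groups: int,
                           n_datasets: int, n_perm: int = 999,
                           seed: int = 0) -> np.ndarray:
    """Permutation p-values under an exchangeable null (type-I calibration).

    Each dataset draws iid bivariate-normal coordinates, computes Euclidean
    distances, assigns arbitrary balanced labels and runs
    :func:`permanova`; under the null the returned p-values are uniform on
    the achievable grid. Vectorized over permutations for speed.
    """
    rng = np.random.default_rng(seed)
    n = n_samples_per_group * n_groups
    labels = np.repeat(np.arange(n_groups), n_samples_per_group)
    codes = np.arange(n_groups)
    pvals = np.empty(n_datasets)
    for rep in range(n_datasets):
        coords = rng.normal(size=(n, 2))
        diff = coords[:, None, :] - coords[None, :, :]
        d2 = (diff ** 2).sum(axis=-1)
        f_obs, _ = _pseudo_f(d2, labels, codes)
        # batch the permuted pseudo-F values
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        perm_labels = labels[perms]  # (n_perm, n)
        n_samples = n
        ss_total = d2.sum() / (2 * n_samples)
        ss_within = np.zeros(n_perm)
        for g in codes:
            m = (perm_labels == g).astype(float)  # (n_perm, n)
            n_g = n_samples_per_group
            ss_within += np.einsum("pi,ij,pj->p", m, d2, m) / (2 * n_g)
        ss_between = ss_total - ss_within
        k = n_groups
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = (ss_between / (k - 1)) / (ss_within / (n_samples - k))
        pvals[rep] = (1 + (f_perm >= f_obs).sum()) / (n_perm + 1)
    return pvals


def rank_sum_test(x, y, alternative: str = "two_sided"):
    """Wilcoxon-Mann-Whitney rank-sum test with midrank ties.

    Exact enumeration when ``len(x) + len(y) <= 12`` and the pooled sample
    has no ties; otherwise the normal approximation with continuity and
    tie correction. Returns ``(statistic, p)`` where the statistic is the
    Mann-Whitney U of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}
    if alternative not in alt:
        raise ValueError(f"unknown alternative: {alternative!r}")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alt[alternative], method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class QpcrCalibration:
    """Fitted qPCR standard curve Cq = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    efficiency_percent: float
    r_squared: float

    def copies(self, cq, volume_factor: float = 1.0) -> np.ndarray:
        """Invert the curve: copy numbers for unknown Cq values."""
        cq = np.asarray(cq, dtype=float)
        return volume_factor * 10 ** ((cq - self.intercept) / self.slope)

    def summary(self) -> str:
        return (
            f"qPCR standard curve: Cq = {self.slope:.4f} log10(copies) "
            f"+ {self.intercept:.4f}\n"
            f"  efficiency  {self.efficiency_percent:.1f}%\n"
            f"  R^2         {self.r_squared:.4f}"
        )


def qpcr_quantify(standards, unknowns=None, volume_factor: float = 1.0):
    """Fit a Cq standard curve and convert unknown Cq values to copies.

    ``standards``: (log10 copies, Cq) pairs, >= 3 points spanning >= 2
    log10 units. Amplification efficiency follows the standard dilution-
    series convention E% = (10^(-1/slope) - 1) * 100, so the theoretical
    slope of -3.3219 (perfect doubling) gives 100%. Returns the
    calibration, or ``(calibration, copies_per_unit)`` when ``unknowns``
    Cq values are given.
    """
    standards = np.asarray(standards, dtype=float)
    if standards.ndim != 2 or standards.shape[1] != 2 or standards.shape[0] < 3:
        raise ValueError("standards must be >= 3 (log10 copies, Cq) pairs")
    log_copies, cq = standards[:, 0], standards[:, 1]
    if np.ptp(log_copies) < 2:
        raise ValueError("standards must span >= 2 log10 units")
    slope, intercept = np.polyfit(log_copies, cq, 1)
    if slope >= 0:
        raise CalibrationError(
            f"standard-curve slope must be negative (got {slope:.4f})"
        )
    fitted = slope * log_copies + intercept
    ss_res = ((cq - fitted) ** 2).sum()
    ss_tot = ((cq - cq.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    efficiency = (10 ** (-1.0 / slope) - 1.0) * 100.0
    calib = QpcrCalibration(float(slope), float(intercept),
                            float(efficiency), float(r2))
    if unknowns is None:
        return calib
    return calib, calib.copies(unknowns, volume_factor)
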