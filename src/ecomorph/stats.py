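"""Ordination and permutation inference shared by all pipeline stages.

Permutation p-values throughout use the add-one correction
p = (exceedances + 1) / (n_permutations + 1), so a permutation p-value is
never zero.  Group labels (not residuals) are permuted, and every routine
takes an explicit seed or :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .datatypes import DistanceMatrix, EllipseSpec, GroupTestResult, Ordination

__all__ = [
    "pca",
    "equal_frequency_ellipse",
    "ellipse_overlap",
    "sea_seac",
    "cva",
    "npmanova",
    "anova_oneway",
    "holm_adjust",
    "pearson",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def pca(x: np.ndarray) -> Ordination:
    """Principal component analysis of a column-centered data matrix.

    Eigendecomposition of the sample covariance (ddof=1); the sign of each
    axis is fixed so its largest-magnitude loading is positive.
    """
    x = np.asarray(x, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("pca needs an n x p matrix with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("pca input contains missing values")
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (x.shape[0] - 1)
    axes = vt.T
    for j in range(axes.shape[1]):
        lead = np.argmax(np.abs(axes[:, j]))
        if axes[lead, j] < 0:
            axes[:, j] *= -1.0
    scores = centered @ axes
    return Ordination(scores=scores, axes=axes, eigenvalues=eigenvalues)


def equal_frequency_ellipse(points: np.ndarray, probability: float) -> EllipseSpec:
    """Ellipse containing the given probability mass of a bivariate normal fit.

    Center = sample mean; boundary = Mahalanobis contour at the chi-square
    (2 df) quantile of ``probability``; area = pi * q * sqrt(det covariance).
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise ValueError("need an n x 2 point set with n >= 3")
    if not 0.0 < probability < 1.0:
        raise ValueError("probability must be in (0, 1)")
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False, ddof=1)
    det = np.linalg.det(cov)
    if det <= 0:
        raise ValueError("singular covariance: points are collinear")
    q = scipy.stats.chi2.ppf(probability, df=2)
    return EllipseSpec(
        center=center,
        covariance=cov,
        probability=probability,
        area=float(np.pi * q * np.sqrt(det)),
    )


def ellipse_overlap(a: EllipseSpec, b: EllipseSpec, n_points: int = 512) -> float:
    """Area of intersection of two ellipses (polygonal approximation)."""
    from shapely.geometry import Polygon

    pa = Polygon(a.boundary(n_points))
    pb = Polygon(b.boundary(n_points))
    return float(pa.intersection(pb).area)


def sea_seac(points: np.ndarray) -> tuple[float, float]:
    """Standard ellipse area (SEA) and its small-sample correction (SEAc).

    SEA = pi * sqrt(lambda1 * lambda2) from the sample covariance eigenvalues;
    SEAc = SEA * (n - 1) / (n - 2).
    """
    points = np.asarray(points, float)
    n = points.shape[0]
    if n < 3:
        raise ValueError("SEA needs at least 3 points")
    cov = np.cov(points, rowvar=False, ddof=1)
    eigvals = np.linalg.eigvalsh(cov)
    sea = float(np.pi * np.sqrt(np.prod(np.clip(eigvals, 0.0, None))))
    return sea, sea * (n - 1) / (n - 2)


def _group_indices(groups: Sequence) -> tuple[np.ndarray, list]:
    labels = pd.unique(pd.Series(list(groups)))
    codes = pd.Series(list(groups)).map({g: i for i, g in enumerate(labels)}).to_numpy()
    return codes, list(labels)


def _reduce_rank(x: np.ndarray, rel_tol: float = 1e-12) -> np.ndarray:
    """Project onto the PCA subspace of non-negligible eigenvalues.

    Shape data are rank-deficient after superimposition (2k - 4 dimensions),
    so the two-matrix eigenproblem is solved in the reduced space.
    """
    ord_ = pca(x)
    keep = ord_.eigenvalues > rel_tol * ord_.eigenvalues[0]
    return ord_.scores[:, keep]


def _pooled_within(x: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    n, p = x.shape
    w = np.zeros((p, p))
    for g in range(n_groups):
        sub = x[codes == g]
        c = sub - sub.mean(axis=0)
        w += c.T @ c
    return w / (n - n_groups)


def _mahalanobis(delta: np.ndarray, w: np.ndarray) -> float:
    return float(np.sqrt(delta @ np.linalg.solve(w, delta)))


def cva(
    x: np.ndarray,
    groups: Sequence,
    n_perm: int = 10000,
    rng=None,
) -> tuple[Ordination, GroupTestResult]:
    """Canonical variate analysis with permutation tests.

    The input is first reduced to its informative PCA subspace, canonical axes
    come from the between- vs pooled-within-group eigenproblem, and group
    separation is summarized by pairwise Mahalanobis and Euclidean
    ("Procrustes-space") distances between group means, with p-values from
    group-label permutation (Bonferroni-adjusted in the pairwise table).
    """
    rng = _as_rng(rng)
    x = np.asarray(x, float)
    codes, labels = _group_indices(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("CVA needs at least 2 groups")
    counts = np.bincount(codes, minlength=g)
    if np.any(counts < 2):
        small = [labels[i] for i in np.where(counts < 2)[0]]
        raise ValueError(f"groups with fewer than 2 members: {small}")

    z = _reduce_rank(x)
    n, p = z.shape
    w = _pooled_within(z, codes, g)
    grand = z.mean(axis=0)
    means = np.stack([z[codes == i].mean(axis=0) for i in range(g)])
    b = sum(
        counts[i] * np.outer(means[i] - grand, means[i] - grand) for i in range(g)
    ) / (g - 1)
    evals, evecs = scipy.linalg.eigh(b, w)
    order = np.argsort(evals)[::-1][: min(g - 1, p)]
    axes = evecs[:, order]
    evals = np.clip(evals[order], 0.0, None)
    # normalize axes so within-group variance along each axis is 1
    for j in range(axes.shape[1]):
        scale = np.sqrt(axes[:, j] @ w @ axes[:, j])
        if scale > 0:
            axes[:, j] /= scale
        lead = np.argmax(np.abs(axes[:, j]))
        if axes[lead, j] < 0:
            axes[:, j] *= -1
    scores = (z - grand) @ axes
    ordination = Ordination(scores=scores, axes=axes, eigenvalues=evals)

    def trace_stat(c: np.ndarray) -> float:
        ww = _pooled_within(z, c, g)
        mm = np.stack([z[c == i].mean(axis=0) for i in range(g)])
        bb = sum(
            np.sum(c == i) * np.outer(mm[i] - grand, mm[i] - grand) for i in range(g)
        ) / (g - 1)
        return float(np.trace(np.linalg.solve(ww, bb)))

    observed = trace_stat(codes)
    exceed = 0
    for _ in range(n_perm):
        if trace_stat(rng.permutation(codes)) >= observed:
            exceed += 1
    p_global = (exceed + 1) / (n_perm + 1)

    pairs = list(combinations(range(g), 2))
    rows = []
    for i, j in pairs:
        mask = (codes == i) | (codes == j)
        sub = z[mask]
        sub_codes = (codes[mask] == j).astype(int)
        w_pair = _pooled_within(sub, sub_codes, 2)
        delta = sub[sub_codes == 1].mean(axis=0) - sub[sub_codes == 0].mean(axis=0)
        d_mah = _mahalanobis(delta, w_pair)
        d_euc = float(np.linalg.norm(delta))
        exceed_mah = exceed_euc = 0
        for _ in range(n_perm):
            pc = rng.permutation(sub_codes)
            dd = sub[pc == 1].mean(axis=0) - sub[pc == 0].mean(axis=0)
            if _mahalanobis(dd, _pooled_within(sub, pc, 2)) >= d_mah:
                exceed_mah += 1
            if np.linalg.norm(dd) >= d_euc:
                exceed_euc += 1
        p_mah = (exceed_mah + 1) / (n_perm + 1)
        p_euc = (exceed_euc + 1) / (n_perm + 1)
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mahalanobis": d_mah,
                "euclidean": d_euc,
                "p_mahalanobis": p_mah,
                "p_euclidean": p_euc,
                "p_mahalanobis_adj": min(1.0, p_mah * len(pairs)),
                "p_euclidean_adj": min(1.0, p_euc * len(pairs)),
            }
        )
    result = GroupTestResult(
        statistic=observed,
        p_value=p_global,
        n_permutations=n_perm,
        statistic_name="trace(W^-1 B)",
        pairwise=pd.DataFrame(rows),
    )
    return ordination, result


def _npmanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances via the Anderson partitioning."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.where(codes == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if ss_within == 0.0:
        return np.inf
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def npmanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 10000,
    rng=None,
    pairwise: bool = True,
) -> GroupTestResult:
    """Nonparametric (permutational) MANOVA on a distance matrix.

    Pseudo-F follows the sums-of-squared-pairwise-distance partitioning; the
    p-value permutes group labels; the pairwise table multiplies raw p-values
    by the number of comparisons (Bonferroni).
    """
    rng = _as_rng(rng)
    if isinstance(groups, dict):
        groups = [groups[l] for l in d.labels]
    groups = list(groups)
    if len(groups) != d.n:
        raise ValueError(f"{len(groups)} labels for a {d.n} x {d.n} matrix")
    codes, labels = _group_indices(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes, minlength=g)
    if np.any(counts < 2):
        small = [labels[i] for i in np.where(counts < 2)[0]]
        raise ValueError(f"groups with fewer than 2 members: {small}")

    d2 = d.values**2
    observed = _npmanova_f(d2, codes, g)
    exceed = 0
    for _ in range(n_perm):
        if _npmanova_f(d2, rng.permutation(codes), g) >= observed:
            exceed += 1
    p_global = (exceed + 1) / (n_perm + 1)

    table = None
    if pairwise and g > 2:
        pairs = list(combinations(range(g), 2))
        rows = []
        for i, j in pairs:
            idx = np.where((codes == i) | (codes == j))[0]
            sub2 = d2[np.ix_(idx, idx)]
            sub_codes = (codes[idx] == j).astype(int)
            f_pair = _npmanova_f(sub2, sub_codes, 2)
            exceed_pair = 0
            for _ in range(n_perm):
                if _npmanova_f(sub2, rng.permutation(sub_codes), 2) >= f_pair:
                    exceed_pair += 1
            p_raw = (exceed_pair + 1) / (n_perm + 1)
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "F": f_pair,
                    "p_raw": p_raw,
                    "p_adjusted": min(1.0, p_raw * len(pairs)),
                }
            )
        table = pd.DataFrame(rows)
    return GroupTestResult(
        statistic=float(observed),
        p_value=p_global,
        n_permutations=n_perm,
        statistic_name="pseudo-F",
        pairwise=table,
    )


def anova_oneway(values: Sequence[float], groups: Sequence) -> GroupTestResult:
    """Classical one-way ANOVA F-test across labeled groups."""
    values = np.asarray(list(values), float)
    codes, labels = _group_indices(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[codes == i] for i in range(g)]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 values")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance: F undefined")
    f, p = scipy.stats.f_oneway(*samples)
    return GroupTestResult(statistic=float(f), p_value=float(p), statistic_name="F")


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down (sequential Bonferroni) adjusted p-values.

    Monotone in the raw ordering and never smaller than the raw value;
    capped at 1.
    """
    p = np.asarray(list(p_values), float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its t-distribution p-value."""
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)
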