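"""Cross-dataset covariation: shape vs. ecology vs. genome.

Two-block PLS finds paired axes of maximal cross-covariance between a shape
block and an environmental block; Mantel and partial Mantel tests relate
distance matrices (morphology, F_ST, geography) under row/column permutation;
SNP utilities thin loci for linkage, run a dosage PCA, and compute
Hudson-type pairwise F_ST as the genomic distance input.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import DistanceMatrix, GenotypeData, Ordination, PLSResult
from .stats import pca as _pca

logger = logging.getLogger(__name__)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def two_block_pls(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10000,
    rng=None,
) -> PLSResult:
    """Two-block partial least squares between paired data blocks.

    SVD of the cross-covariance of the column-centered blocks gives paired
    singular axes; per-axis significance permutes the specimen rows of Y with
    the singular value as statistic.
    """
    rng = _as_rng(rng)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"blocks pair {x.shape[0]} vs {y.shape[0]} specimens")
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 paired specimens")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)

    def cross_svd(ycm: np.ndarray):
        c = xc.T @ ycm / (n - 1)
        return np.linalg.svd(c, full_matrices=False)

    u, s, vt = cross_svd(yc)
    m = len(s)
    x_scores = xc @ u
    y_scores = yc @ vt.T
    corr = np.array(
        [
            np.corrcoef(x_scores[:, j], y_scores[:, j])[0, 1]
            if np.std(x_scores[:, j]) > 0 and np.std(y_scores[:, j]) > 0
            else 0.0
            for j in range(m)
        ]
    )
    exceed = np.zeros(m)
    for _ in range(n_perm):
        s_perm = cross_svd(yc[rng.permutation(n)])[1]
        exceed += s_perm >= s
    p = (exceed + 1) / (n_perm + 1)
    return PLSResult(
        singular_values=s,
        x_scores=x_scores,
        y_scores=y_scores,
        x_weights=u,
        y_weights=vt.T,
        score_correlations=corr,
        permutation_p=p,
        n_permutations=n_perm,
    )


def _check_labels(*mats: DistanceMatrix) -> None:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValueError("distance matrices must share identical label order")


def _mantel_r(a: np.ndarray, b: np.ndarray) -> float:
    iu = np.triu_indices(a.shape[0], 1)
    va, vb = a[iu], b[iu]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 10000,
    rng=None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Simple Mantel test between two labeled distance matrices.

    r is the Pearson correlation of the off-diagonal (upper-triangle) vectors;
    the p-value permutes rows and columns of ``a`` simultaneously.  One-tailed
    positive association by default; ``alternative`` in {greater, two-sided}.
    """
    rng = _as_rng(rng)
    _check_labels(a, b)
    if a.n < 4:
        raise ValueError("Mantel test needs at least 4 labels")
    r_obs = _mantel_r(a.values, b.values)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.n)
        r = _mantel_r(a.values[np.ix_(perm, perm)], b.values)
        if alternative == "two-sided":
            exceed += abs(r) >= abs(r_obs)
        else:
            exceed += r >= r_obs
    return r_obs, (exceed + 1) / (n_perm + 1)


def _residual_matrix(y: DistanceMatrix, x: DistanceMatrix) -> np.ndarray:
    """Residualize y's off-diagonal entries on x's, returned as a matrix."""
    n = y.n
    iu = np.triu_indices(n, 1)
    vx, vy = x.values[iu], y.values[iu]
    if np.std(vx) == 0:
        raise ValueError("constant conditioning matrix")
    beta, alpha = np.polyfit(vx, vy, 1)
    resid = vy - (alpha + beta * vx)
    mat = np.zeros((n, n))
    mat[iu] = resid
    return mat + mat.T


def partial_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    n_perm: int = 10000,
    rng=None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Partial Mantel test of a vs. b controlling for c (residual method).

    Both a and b are residualized on c over their off-diagonal entries; the
    test then permutes rows/columns of a's residualized matrix.
    """
    rng = _as_rng(rng)
    _check_labels(a, b, c)
    ra = _residual_matrix(a, c)
    rb = _residual_matrix(b, c)
    if np.allclose(np.std(ra[np.triu_indices(a.n, 1)]), 0):
        raise ValueError("a is collinear with c: partial Mantel undefined")
    if np.allclose(np.std(rb[np.triu_indices(a.n, 1)]), 0):
        raise ValueError("b is collinear with c: partial Mantel undefined")
    r_obs = _mantel_r(ra, rb)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.n)
        r = _mantel_r(ra[np.ix_(perm, perm)], rb)
        if alternative == "two-sided":
            exceed += abs(r) >= abs(r_obs)
        else:
            exceed += r >= r_obs
    return r_obs, (exceed + 1) / (n_perm + 1)


def scale_to_unit(m: DistanceMatrix) -> DistanceMatrix:
    """Divide all entries by the maximum off-diagonal distance (max becomes 1)."""
    iu = np.triu_indices(m.n, 1)
    top = m.values[iu].max() if m.n > 1 else 0.0
    if top <= 0:
        raise ValueError("zero matrix cannot be scaled to unit")
    return DistanceMatrix(list(m.labels), m.values / top)


def filter_snps(
    g: GenotypeData,
    min_spacing: int = 500_000,
    require_complete: bool = True,
) -> GenotypeData:
    """Linkage thinning: complete-data loci at least ``min_spacing`` bp apart.

    Loci with any missing genotype are dropped first (when
    ``require_complete``); then a greedy left-to-right walk per chromosome
    keeps a locus iff it lies at least ``min_spacing`` from the last kept one.
    """
    n_in = g.n_loci
    complete = (
        np.all(np.isfinite(g.genotypes), axis=0)
        if require_complete
        else np.ones(n_in, bool)
    )
    keep: list[int] = []
    for chrom, sub in g.loci.groupby("chrom", sort=False):
        last = None
        for idx in sub.index:
            if not complete[g.loci.index.get_loc(idx)]:
                continue
            pos = int(g.loci.loc[idx, "pos"])
            if last is None or pos - last >= min_spacing:
                keep.append(g.loci.index.get_loc(idx))
                last = pos
    logger.info(
        "SNP thinning: %d in, %d dropped incomplete, %d kept",
        n_in,
        int(np.sum(~complete)),
        len(keep),
    )
    return GenotypeData(
        samples=list(g.samples),
        loci=g.loci.iloc[keep].reset_index(drop=True),
        genotypes=g.genotypes[:, keep].copy(),
    )


def genotype_pca(g: GenotypeData, scale: bool = False) -> Ordination:
    """PCA of the centered alternate-allele dosage matrix.

    Columns are centered (and optionally scaled to unit variance); monomorphic
    -only input is rejected.
    """
    if not np.all(np.isfinite(g.genotypes)):
        raise ValueError("genotype matrix has missing data: filter first")
    x = g.genotypes.astype(float)
    variances = x.var(axis=0)
    if np.all(variances == 0):
        raise ValueError("all loci are monomorphic: PCA undefined")
    if scale:
        keep = variances > 0
        x = x[:, keep] / np.sqrt(variances[keep])
    return _pca(x)


def hudson_fst_components(
    p1: np.ndarray, p2: np.ndarray, n1: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus numerator and denominator of the Hudson F_ST estimator.

    ``p`` are sample alternate-allele frequencies, ``n`` allele counts
    (2 x samples).  N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1);
    D = p1(1-p2) + p2(1-p1).
    """
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def pairwise_fst(
    g: GenotypeData, populations, floor_at_zero: bool = True
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """Pairwise Hudson F_ST between populations (ratio of averages over loci).

    Returns the distance matrix (negative estimates floored at 0 when
    ``floor_at_zero``) plus a table with the raw (unfloored) estimates.
    """
    populations = list(populations)
    if len(populations) != len(g.samples):
        raise ValueError("one population label per sample required")
    labels = list(pd.unique(pd.Series(populations)))
    if len(labels) < 2:
        raise ValueError("need at least 2 populations")
    masks = {lab: np.array([p == lab for p in populations]) for lab in labels}
    if any(m.sum() < 2 for m in masks.values()):
        raise ValueError("every population needs at least 2 samples")

    rows = []
    values = np.zeros((len(labels), len(labels)))
    for a, b in combinations(range(len(labels)), 2):
        ga = g.genotypes[masks[labels[a]]]
        gb = g.genotypes[masks[labels[b]]]
        ok = np.any(np.isfinite(ga), axis=0) & np.any(np.isfinite(gb), axis=0)
        if not np.any(ok):
            raise ValueError(
                f"no loci with data in both {labels[a]} and {labels[b]}"
            )
        n1 = 2.0 * np.sum(np.isfinite(ga[:, ok]), axis=0)
        n2 = 2.0 * np.sum(np.isfinite(gb[:, ok]), axis=0)
        p1 = np.nansum(ga[:, ok], axis=0) / n1
        p2 = np.nansum(gb[:, ok], axis=0) / n2
        informative = (n1 > 2) & (n2 > 2)
        num, den = hudson_fst_components(
            p1[informative], p2[informative], n1[informative], n2[informative]
        )
        poly = den > 0
        raw = float(num[poly].sum() / den[poly].sum()) if np.any(poly) else 0.0
        fst = max(0.0, raw) if floor_at_zero else raw
        values[a, b] = values[b, a] = fst
        rows.append(
            {
                "pop_a": labels[a],
                "pop_b": labels[b],
                "fst": fst,
                "fst_raw": raw,
                "n_loci": int(np.sum(poly)),
            }
        )
    return DistanceMatrix(labels, values), pd.DataFrame(rows)


def great_circle_distances(
    latitudes, longitudes, labels=None, radius_km: float = 6371.0
) -> DistanceMatrix:
    """Great-circle distance matrix (spherical law of cosines), in km."""
    lat = np.radians(np.asarray(list(latitudes), float))
    lon = np.radians(np.asarray(list(longitudes), float))
    n = len(lat)
    labels = [str(i) for i in range(n)] if labels is None else list(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cosang = np.sin(lat[i]) * np.sin(lat[j]) + np.cos(lat[i]) * np.cos(
                lat[j]
            ) * np.cos(lon[i] - lon[j])
            d[i, j] = d[j, i] = radius_km * np.arccos(np.clip(cosang, -1.0, 1.0))
    return DistanceMatrix(labels, d)
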