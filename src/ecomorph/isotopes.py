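"""Stable-isotope niche analysis.

Works on per-individual tables of delta13C / delta15N (per mille) with C:N
ratio by weight as a lipid proxy.  Lipid normalization is the arithmetic
two-equation chain: the C:N ratio predicts tissue lipid percentage, which in
turn predicts the 13C depletion to add back.  Niche geometry uses the
standard ellipse area with its small-sample correction (SEAc), and
individual-level diet distances treat (delta13C, delta15N) as Cartesian
coordinates.  No baseline correction is applied, so cross-site comparisons
are refused unless explicitly overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import DistanceMatrix, EllipseSpec
from .stats import anova_oneway, ellipse_overlap, equal_frequency_ellipse, sea_seac

logger = logging.getLogger(__name__)

ISOTOPE_COLUMNS = ["specimen_id", "species", "site", "d13C", "d15N", "cn_ratio"]


@dataclass
class LipidModelParams:
    """Parameters of the C:N-based arithmetic lipid normalization.

    ``lipid_percent_coefficients`` (a, b, c) map C:N to lipid percentage
    L = a / (1 + (b * CN - c)^-1); ``D`` (per mille) is the protein-lipid
    discrimination and ``I`` a small intercept; ``reference_constants``
    (k1, k2) shape the correction kernel
    delta13C' = delta13C + D * (I + k1 / (1 + k2 / L)).
    Defaults follow the published model estimates; the correction is the
    identity when D = 0.
    """

    D: float = 7.018
    I: float = 0.048
    lipid_percent_coefficients: tuple[float, float, float] = (93.0, 0.246, 0.775)
    reference_constants: tuple[float, float] = (3.90, 287.0)

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be nonnegative")


def delta_value(r_sample: float, r_standard: float) -> float:
    """Delta notation in per mille: (R_sample / R_standard - 1) * 1000."""
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError("isotope ratios must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def lipid_percent(cn_ratio, params: LipidModelParams | None = None):
    """Tissue lipid percentage predicted from the C:N ratio (by weight)."""
    params = params or LipidModelParams()
    a, b, c = params.lipid_percent_coefficients
    cn = np.asarray(cn_ratio, float)
    denom = b * cn - c
    if np.any(denom == 0):
        raise ValueError("C:N ratio hits the singularity b*CN = c")
    lipid = a / (1.0 + 1.0 / denom)
    clipped = np.clip(lipid, 0.0, 100.0)
    if np.any(clipped != lipid):
        logger.warning("lipid percentage outside [0, 100] clamped")
    return clipped if np.ndim(cn_ratio) else float(clipped)


def lipid_correction_offset(cn_ratio, params: LipidModelParams | None = None):
    """Per mille shift added to raw delta13C for a given C:N ratio."""
    params = params or LipidModelParams()
    k1, k2 = params.reference_constants
    lipid = lipid_percent(cn_ratio, params)
    return params.D * (params.I + k1 / (1.0 + k2 / np.asarray(lipid, float)))


def lipid_correct(
    table: pd.DataFrame, params: LipidModelParams | None = None
) -> pd.DataFrame:
    """Add a ``d13C_corrected`` column; the raw ``d13C`` column is retained."""
    params = params or LipidModelParams()
    if np.any(table["cn_ratio"] <= 0):
        raise ValueError("C:N ratios must be positive")
    out = table.copy()
    offset = lipid_correction_offset(out["cn_ratio"].to_numpy(), params)
    out["d13C_corrected"] = out["d13C"].to_numpy() + offset
    return out


def preservation_paired_test(dried, preserved) -> dict:
    """Paired comparison of air-dried vs. chemically preserved tissue values.

    Returns the mean difference (preserved - dried), the Wilcoxon signed-rank
    statistic and p (exact for n <= 25), and the paired t statistic and p.
    """
    dried = np.asarray(list(dried), float)
    preserved = np.asarray(list(preserved), float)
    if dried.shape != preserved.shape:
        raise ValueError("paired vectors must have equal length")
    diff = preserved - dried
    out = {"mean_difference": float(diff.mean()), "n": len(diff)}
    if np.all(diff == 0):
        # degenerate: no evidence of any shift
        out["t_stat"], out["t_p"] = 0.0, 1.0
        out["wilcoxon_stat"], out["wilcoxon_p"] = 0.0, 1.0
        return out
    t_stat, t_p = scipy.stats.ttest_rel(preserved, dried)
    out["t_stat"], out["t_p"] = float(t_stat), float(t_p)
    mode = "exact" if len(diff) <= 25 else "approx"
    w_stat, w_p = scipy.stats.wilcoxon(diff, method=mode)
    out["wilcoxon_stat"], out["wilcoxon_p"] = float(w_stat), float(w_p)
    return out


def within_site_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Per-site one-way ANOVA between species, separately per isotope.

    Sites with a single species are skipped (logged); sites containing any
    species with fewer than 3 individuals are flagged but still tested when
    every species has at least 2.
    """
    col_corr = "d13C_corrected" if "d13C_corrected" in table.columns else "d13C"
    rows = []
    for site, sub in table.groupby("site", sort=False):
        species = sub["species"].unique()
        if len(species) < 2:
            logger.info("site %s has a single species; skipped", site)
            continue
        counts = sub.groupby("species").size()
        flag = bool((counts < 3).any())
        for element, col in (("d13C", col_corr), ("d15N", "d15N")):
            try:
                res = anova_oneway(sub[col].to_numpy(), sub["species"].to_numpy())
            except ValueError as exc:
                logger.info("site %s %s: %s", site, element, exc)
                continue
            rows.append(
                {
                    "site": site,
                    "element": element,
                    "F": res.statistic,
                    "p": res.p_value,
                    "n": len(sub),
                    "small_sample_flag": flag,
                }
            )
    return pd.DataFrame(rows)


def isotopic_distance_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between individuals in (delta13C, delta15N) space."""
    if "d13C_corrected" not in table.columns:
        raise ValueError("run lipid_correct first: d13C_corrected column missing")
    bad = table.loc[
        table[["d13C_corrected", "d15N"]].isna().any(axis=1), "specimen_id"
    ].tolist()
    if bad:
        raise ValueError(f"missing isotope values for specimens: {bad}")
    pts = table[["d13C_corrected", "d15N"]].to_numpy(float)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=[str(s) for s in table["specimen_id"]], values=d)


def niche_ellipses(
    table: pd.DataFrame,
    by: str = "species",
    probability: float = 0.9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SEA/SEAc and equal-frequency ellipses per group, plus pairwise overlap.

    Groups with fewer than 3 individuals are skipped with a log entry.
    Returns (per-group table, pairwise overlap-area table).
    """
    col_corr = "d13C_corrected" if "d13C_corrected" in table.columns else "d13C"
    specs: dict[str, EllipseSpec] = {}
    rows = []
    for group, sub in table.groupby(by, sort=False):
        if len(sub) < 3:
            logger.info("group %s has n=%d < 3; skipped", group, len(sub))
            continue
        pts = sub[[col_corr, "d15N"]].to_numpy(float)
        sea, seac = sea_seac(pts)
        spec = equal_frequency_ellipse(pts, probability)
        specs[group] = spec
        rows.append(
            {"group": group, "n": len(sub), "sea": sea, "seac": seac, "area": spec.area}
        )
    overlap_rows = []
    names = list(specs)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlap_rows.append(
                {"group_a": a, "group_b": b, "overlap_area": ellipse_overlap(specs[a], specs[b])}
            )
    return pd.DataFrame(rows), pd.DataFrame(overlap_rows)


def cross_site_guard(allow_cross_site: bool = False) -> None:
    """Refuse cross-site isotope comparisons unless explicitly overridden.

    Raw isotope values are not baseline-corrected, so sites are not on a
    common scale; comparisons across sites require an explicit opt-in.
    """
    if not allow_cross_site:
        raise ValueError(
            "cross-site isotope comparisons are disabled: values are not "
            "baseline-corrected; pass allow_cross_site=True to override"
        )
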