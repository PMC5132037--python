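"""Diet composition and discrete trophic-trait statistics.

Stomach contents are six-category percentage compositions (by volume); overlap
between species uses Schoener's index D = 1 - 0.5 * sum |p_i - q_i| (on
proportions), with D > 0.6 conventionally flagged as substantial overlap.
Gut length is analyzed as relative gut length log10(gut) / log10(standard
length) after log correction of the allometric gut-body relationship.
"""

from __future__ import annotations

from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .datatypes import GroupTestResult
from .stats import anova_oneway, holm_adjust, pearson

DIET_CATEGORIES = [
    "algae_cyanobacteria",
    "cellulose_plant",
    "small_arthropods",
    "fry_eggs",
    "fish_remains_scales",
    "grit_sand",
]

SCHOENER_SUBSTANTIAL = 0.6


def normalize_composition(values: Sequence[float]) -> np.ndarray:
    """Validate a percentage composition and renormalize it to sum to 100.

    Totals within [95, 105] (allowing for rounded field estimates) are
    accepted and rescaled; anything else is an error.
    """
    arr = np.asarray(list(values), float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError(f"category percentages must lie in [0, 100]: {arr}")
    total = arr.sum()
    if not 95.0 <= total <= 105.0:
        raise ValueError(f"composition sums to {total:.2f}, outside [95, 105]")
    return arr * (100.0 / total)


def schoener_overlap(p: Sequence[float], q: Sequence[float]) -> float:
    """Schoener's dietary overlap index on two percentage compositions."""
    if len(p) != len(q):
        raise ValueError("compositions must share the same category set")
    pa = normalize_composition(p)
    qa = normalize_composition(q)
    return float(1.0 - 0.5 * np.sum(np.abs(pa - qa)) / 100.0)


def filter_stomachs(table: pd.DataFrame, min_content: float = 1.0) -> pd.DataFrame:
    """Drop specimens whose total stomach content is below ``min_content`` %."""
    totals = table[DIET_CATEGORIES].sum(axis=1)
    return table.loc[totals >= min_content].copy()


def composition_summary(table: pd.DataFrame, by: str = "species") -> pd.DataFrame:
    """Mean composition per group; each group's means sum to 100."""
    rows = []
    for group, sub in table.groupby(by, sort=False):
        comps = np.stack([normalize_composition(r) for r in sub[DIET_CATEGORIES].to_numpy()])
        mean = comps.mean(axis=0)
        rows.append({by: group, "n": len(sub), **dict(zip(DIET_CATEGORIES, mean))})
    return pd.DataFrame(rows)


def schoener_matrix(table: pd.DataFrame, by: str = "species") -> pd.DataFrame:
    """Pairwise Schoener overlap of group mean compositions, with flags."""
    summary = composition_summary(table, by=by).set_index(by)
    groups = list(summary.index)
    rows = []
    for a, b in combinations(groups, 2):
        d = schoener_overlap(
            summary.loc[a, DIET_CATEGORIES].to_numpy(),
            summary.loc[b, DIET_CATEGORIES].to_numpy(),
        )
        rows.append(
            {"group_a": a, "group_b": b, "schoener_d": d, "substantial": d > SCHOENER_SUBSTANTIAL}
        )
    return pd.DataFrame(rows)


def relative_gut_length(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``relative_gut_length`` = log10(gut length) / log10(standard length)."""
    if table[["gut_length", "standard_length"]].isna().any().any():
        raise ValueError("missing gut or standard lengths")
    if np.any(table["gut_length"] <= 0) or np.any(table["standard_length"] <= 0):
        raise ValueError("lengths must be positive")
    out = table.copy()
    out["relative_gut_length"] = np.log10(out["gut_length"]) / np.log10(
        out["standard_length"]
    )
    return out


def relative_gut_length_tests(
    table: pd.DataFrame,
    by: str = "species",
    adult_filter: Optional[Callable[[pd.DataFrame], pd.DataFrame]] = None,
) -> GroupTestResult:
    """Overall and pairwise one-way ANOVA on relative gut length.

    ``adult_filter`` lets the caller exclude juveniles before testing (the
    ontogenetic-effect guard is the user's responsibility).  Pairwise
    comparisons use Holm (sequential Bonferroni) adjustment.
    """
    if adult_filter is not None:
        table = adult_filter(table)
    table = relative_gut_length(table)
    counts = table.groupby(by).size()
    if (counts < 3).any() or len(counts) < 2:
        raise ValueError("need >= 2 groups with >= 3 adults each")
    overall = anova_oneway(table["relative_gut_length"].to_numpy(), table[by].to_numpy())
    groups = list(counts.index)
    rows = []
    for a, b in combinations(groups, 2):
        sub = table[table[by].isin([a, b])]
        res = anova_oneway(sub["relative_gut_length"].to_numpy(), sub[by].to_numpy())
        rows.append({"group_a": a, "group_b": b, "F": res.statistic, "p_raw": res.p_value})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adjusted"] = holm_adjust(pairwise["p_raw"].tolist())
    overall.pairwise = pairwise
    return overall


def _aicc(rss: float, n: int, k: int) -> float:
    if rss <= 0:
        rss = np.finfo(float).tiny
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return float(aic)


def gut_model_comparison(table: pd.DataFrame, by: str = "species") -> pd.DataFrame:
    """Compare linear / exponential / logarithmic / quadratic gut-length models.

    All four forms are least-squares mean functions for y = log10(gut length)
    against x = log10(standard length), with Gaussian error on the common
    (log) response scale, ranked per group by small-sample AIC (AICc).
    "Polynomial" is the quadratic, the lowest-order nonlinearity.
    """
    table = relative_gut_length(table)  # validates lengths
    rows = []
    for group, sub in table.groupby(by, sort=False):
        if len(sub) < 6:
            raise ValueError(f"group {group} has n={len(sub)} < 6")
        x = np.log10(sub["standard_length"].to_numpy(float))
        y = np.log10(sub["gut_length"].to_numpy(float))
        n = len(x)
        fits: dict[str, tuple[float, int]] = {}

        def poly_rss(deg: int) -> float:
            coef = np.polyfit(x, y, deg)
            return float(np.sum((np.polyval(coef, x) - y) ** 2))

        fits["linear"] = (poly_rss(1), 3)  # slope, intercept, sigma
        fits["quadratic"] = (poly_rss(2), 4)
        if np.any(x <= 0):
            raise ValueError("logarithmic model needs log10(SL) > 0 (SL > 1 unit)")
        xl = np.log(x)
        coef = np.polyfit(xl, y, 1)
        fits["logarithmic"] = (float(np.sum((np.polyval(coef, xl) - y) ** 2)), 3)

        def expo(xv, a, b):
            return a * np.exp(b * xv)

        try:
            b0 = np.polyfit(x, np.log(np.abs(y) + 1e-9), 1)[0]
            popt, _ = scipy.optimize.curve_fit(
                expo, x, y, p0=[np.mean(y), b0], maxfev=10000
            )
            rss_exp = float(np.sum((expo(x, *popt) - y) ** 2))
        except RuntimeError:
            rss_exp = np.inf
        fits["exponential"] = (rss_exp, 3)

        for model, (rss, k) in fits.items():
            rows.append(
                {by: group, "model": model, "n": n, "rss": rss, "aicc": _aicc(rss, n, k)}
            )
    out = pd.DataFrame(rows)
    out["rank"] = out.groupby(by)["aicc"].rank(method="first").astype(int)
    return out.sort_values([by, "rank"]).reset_index(drop=True)


def raker_tests(
    counts: Sequence[int],
    standard_lengths: Sequence[float],
    groups: Sequence,
) -> tuple[tuple[float, float], GroupTestResult]:
    """Gill-raker count analysis: size correlation plus across-group ANOVA.

    Returns ((Pearson r of count vs. standard length, p), one-way ANOVA of
    counts across groups).  Constant counts raise (correlation undefined).
    """
    counts = np.asarray(list(counts), float)
    if len(counts) < 3:
        raise ValueError("need at least 3 counts")
    if np.any(counts <= 0) or np.any(counts != np.round(counts)):
        raise ValueError("raker counts must be positive integers")
    r_p = pearson(counts, standard_lengths)
    res = anova_oneway(counts, groups)
    return r_p, res
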