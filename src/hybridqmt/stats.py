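"""Group-difference and correlation statistics for ROI measurements.

The analysis pipeline: per-ROI summaries (mean, sample variance, n) are
aggregated into lobar values with inverse-variance weighting; amyloid-
negative and -positive groups are compared per (measure, lobe) cell with the
Mann–Whitney U test and Hedge's g effect sizes (bias-corrected standardized
mean difference, |g| bands 0.5 / 0.8 / 1.2 labeling medium / large / very
large); family-wise error is controlled by Bonferroni (five lobar
comparisons -> 0.01; six subcortical structures + global white matter ->
0.007 at three-decimal reporting).  Associations with amyloid burden (PET
SUVR) use Pearson's correlation.  Hemisphere values enter the tests as
separate observations (two per subject) — deliberate, documented
pseudo-replication matching the lobar-scatter convention of the source
analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import LOBAR_FAMILY_SIZE, SUBCORTICAL_FAMILY_SIZE, LobeMap

GROUPS = ("Abeta_neg", "Abeta_pos")

#: |g| cutoffs for small / medium / large / very large effects
G_CUTOFFS = (0.5, 0.8, 1.2)

#: long-format measurement table columns
MEASUREMENT_COLUMNS = ("subject", "group", "hemisphere", "roi", "measure",
                       "mean", "sample_variance", "n_samples")

#: cap applied to inverse-variance weights when a variance is zero
MAX_WEIGHT = 1e12


@dataclass(frozen=True)
class GroupComparison:
    U: float
    p_value: float
    hedges_g: float
    category: str
    n_per_group: tuple


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    p_value: float
    n: int


def effect_category(g: float) -> str:
    a = abs(g)
    if a < G_CUTOFFS[0]:
        return "small"
    if a < G_CUTOFFS[1]:
        return "medium"
    if a < G_CUTOFFS[2]:
        return "large"
    return "very_large"


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def lobar_aggregate(measurements: pd.DataFrame, lobemap: LobeMap | None = None,
                    weighting: str = "mean_variance") -> pd.DataFrame:
    """Inverse-variance weighted lobar means.

    Input: long-format table with MEASUREMENT_COLUMNS.  Output: one row per
    (subject, group, hemisphere, lobe, measure) with the weighted mean of
    the constituent non-excluded ROIs.

    ``weighting="mean_variance"`` uses w_i = n_i / s_i^2 (the inverse
    variance of each ROI's *mean*, the maximum-likelihood combination for
    normally distributed samples); ``"sample_variance"`` uses w_i = 1/s_i^2.
    Zero variances get the capped weight MAX_WEIGHT with a warning.
    """
    lobemap = lobemap or LobeMap()
    if weighting not in ("mean_variance", "sample_variance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    df = measurements
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table is missing columns {sorted(missing)}")
    if (df["sample_variance"] < 0).any():
        raise ValueError("negative sample variance")
    s2 = df["sample_variance"].to_numpy(float)
    if np.any(s2 == 0):
        warnings.warn("zero sample variance: weight capped")
    denom = np.where(s2 > 0, s2, np.inf)
    w = (df["n_samples"].to_numpy(float) / denom) if weighting == "mean_variance" \
        else (1.0 / denom)
    w = np.where(s2 > 0, w, MAX_WEIGHT)
    work = df[["subject", "group", "hemisphere", "roi", "measure", "mean"]].copy()
    work["_w"] = w
    work["_wx"] = w * work["mean"].to_numpy(float)
    keys = ["subject", "group", "hemisphere", "measure"]
    frames = []
    for lobe in lobemap.lobe_names:
        members = lobemap.members(lobe)
        sub = work[work["roi"].isin(members)]
        if sub.empty:
            continue
        agg = sub.groupby(keys, sort=True, observed=True)[["_w", "_wx"]].sum()
        frame = agg.reset_index()
        frame["lobe"] = lobe
        frame["value"] = frame["_wx"] / frame["_w"]
        frames.append(frame[keys[:3] + ["lobe", "measure", "value"]])
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["subject", "group", "hemisphere", "lobe", "measure", "value"])
    return out.sort_values(["measure", "lobe", "subject", "hemisphere"],
                           ignore_index=True)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: #(a_i > b_j) + 0.5 #(a_i == b_j)."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_u(group_a, group_b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of group_a, p).

    ``exact`` enumerates the permutation null over all C(n1+n2, n1)
    relabelings (ties handled via the 0.5 convention); allowed for
    n1 + n2 <= 14.  ``normal`` uses the tie-corrected Gaussian
    approximation with continuity correction.  ``auto`` picks exact for
    n1 + n2 <= 12.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    u_obs = _u_statistic(a, b)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return u_obs, 1.0
    if mode == "auto":
        mode = "exact" if n1 + n2 <= 12 else "normal"
    if mode == "exact":
        if n1 + n2 > 14:
            raise ValueError("exact enumeration limited to n1 + n2 <= 14")
        pooled = np.concatenate([a, b])
        idx = np.arange(n1 + n2)
        mid = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mid)
        count = 0
        total = 0
        for comb in combinations(idx, n1):
            mask = np.zeros(n1 + n2, bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            count += abs(u - mid) >= dev_obs - 1e-12
            total += 1
        return u_obs, count / total
    if mode == "normal":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return u_obs, float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


def hedges_g(group_pos, group_neg) -> tuple[float, str]:
    """Bias-corrected standardized mean difference, positive when the
    positive group is larger.

    g = J * (mean_pos - mean_neg) / s_pooled with
    s_pooled^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2) and the small-sample
    correction J = 1 - 3 / (4N - 9).
    """
    x = np.asarray(group_pos, float)
    y = np.asarray(group_neg, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ZeroDivisionError("zero pooled variance")
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = float(J * (np.mean(x) - np.mean(y)) / math.sqrt(sp2))
    return g, effect_category(g)


def bonferroni_threshold(alpha: float, m: int, decimals: int | None = None) -> float:
    """Family-wise corrected level alpha / m (optionally rounded for reporting)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    out = alpha / m
    return round(out, decimals) if decimals is not None else out


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided p from the t distribution."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched vectors of length >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(pearson_r=float(r), p_value=float(p), n=len(x))


# ---------------------------------------------------------------------------
# table-level analyses
# ---------------------------------------------------------------------------

def _observations(sub: pd.DataFrame, hemisphere_mode: str) -> pd.Series:
    if hemisphere_mode == "pooled":
        return sub["value"]
    if hemisphere_mode == "averaged":
        return sub.groupby("subject", observed=True)["value"].mean()
    raise ValueError(f"unknown hemisphere_mode {hemisphere_mode!r}")


def run_group_analysis(lobar: pd.DataFrame, family_size: int | None = None,
                       alpha: float = 0.05, mw_mode: str = "auto",
                       hemisphere_mode: str = "pooled") -> pd.DataFrame:
    """Group comparison per (measure, lobe).

    Input: lobar value table from :func:`lobar_aggregate` (columns subject,
    group, hemisphere, lobe, measure, value).  Hemisphere values enter as
    separate observations by default ("pooled"); "averaged" collapses to one
    value per subject.  Output: one row per (measure, lobe) with U, p,
    Hedge's g, category, significance markers '*' (p < alpha) and '**'
    (p < alpha/family) and the effect symbol († / ‡ / § for medium / large /
    very large).
    """
    m = family_size or lobar["lobe"].nunique()
    bonf = bonferroni_threshold(alpha, m)
    rows = []
    for (meas, lobe), sub in lobar.groupby(["measure", "lobe"], sort=True,
                                           observed=True):
        pos = _observations(sub[sub["group"] == "Abeta_pos"], hemisphere_mode)
        neg = _observations(sub[sub["group"] == "Abeta_neg"], hemisphere_mode)
        subj_counts = sub.groupby("subject", observed=True).size()
        expected = 2 if hemisphere_mode == "pooled" else 1
        if hemisphere_mode == "pooled" and (subj_counts < expected).any():
            warnings.warn(f"({meas}, {lobe}): subject with missing hemisphere; "
                          "row skipped")
            continue
        if len(pos) < 2 or len(neg) < 2:
            warnings.warn(f"({meas}, {lobe}): group too small; row skipped")
            continue
        try:
            u, p = mann_whitney_u(pos, neg, mode=mw_mode)
            g, cat = hedges_g(pos, neg)
        except (ValueError, ZeroDivisionError) as exc:
            warnings.warn(f"({meas}, {lobe}) skipped: {exc}")
            continue
        rows.append({
            "measure": meas, "lobe": lobe, "U": u, "p_value": p,
            "hedges_g": g, "category": cat,
            "n_pos": len(pos), "n_neg": len(neg),
            "significant": "*" if p < alpha else "",
            "significant_bonferroni": "**" if p < bonf else "",
            "effect_symbol": {"small": "", "medium": "†", "large": "‡",
                              "very_large": "§"}[cat],
        })
    return pd.DataFrame(rows)


def run_correlation_analysis(lobar: pd.DataFrame, suvr_measure: str = "SUVR",
                             alpha: float = 0.05,
                             hemisphere_mode: str = "pooled") -> pd.DataFrame:
    """Pearson correlation of each (measure, lobe) against amyloid burden.

    ``suvr_measure`` names the measure used as the burden axis; each other
    measure is correlated against it within the same (subject, hemisphere,
    lobe) cells.
    """
    suvr = lobar[lobar["measure"] == suvr_measure]
    if suvr.empty:
        raise ValueError(f"no rows with measure {suvr_measure!r}")
    keys = ["subject", "hemisphere", "lobe"]
    rows = []
    others = [m for m in lobar["measure"].unique() if m != suvr_measure]
    for meas in sorted(others):
        sub = lobar[lobar["measure"] == meas]
        merged = sub.merge(suvr[keys + ["value"]], on=keys, suffixes=("", "_suvr"))
        for lobe, cell in merged.groupby("lobe", sort=True, observed=True):
            if hemisphere_mode == "averaged":
                cell = cell.groupby("subject", observed=True, as_index=False)[
                    ["value", "value_suvr"]].mean()
            try:
                res = pearson(cell["value_suvr"], cell["value"])
            except ValueError as exc:
                warnings.warn(f"({meas}, {lobe}) skipped: {exc}")
                continue
            rows.append({"measure": meas, "lobe": lobe, "pearson_r": res.pearson_r,
                         "p_value": res.p_value, "n": res.n,
                         "significant": "*" if res.p_value < alpha else ""})
    return pd.DataFrame(rows)
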