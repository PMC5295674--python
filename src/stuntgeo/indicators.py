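"""Child- and household-level indicator scoring.

Implements the classification procedures the downstream analysis consumes:

* height-for-age z-scores (HAZ) from an LMS (lambda-mu-sigma) growth
  reference, and the stunting / severe-stunting classification at the
  conventional -2 / -3 SD thresholds;
* the Household Food Insecurity Access Scale (HFIAS) four-level category
  from the nine occurrence/frequency items;
* the household dietary diversity score (0-12 food groups) and its
  lowest / medium / high classes;
* an asset-based relative wealth index (first principal component of
  standardized indicators) cut into quintiles;
* the technical error of measurement (TEM) and coefficient of
  reliability R used to standardize anthropometric measurement teams.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HAZ_IMPLAUSIBLE = 6.0  # |z| beyond this is flagged as biologically implausible

STUNTED = "stunted"
SEVERELY_STUNTED = "severely_stunted"
NOT_STUNTED = "not_stunted"

HFIAS_LABELS = {
    1: "food_secure",
    2: "mildly_food_insecure",
    3: "moderately_food_insecure",
    4: "severely_food_insecure",
}

DD_LOWEST, DD_MEDIUM, DD_HIGH = "lowest", "medium", "high"


# ---------------------------------------------------------------------------
# LMS reference and HAZ
# ---------------------------------------------------------------------------

def load_lms_reference(path) -> pd.DataFrame:
    """Read an LMS reference table (columns: sex, age_months, L, M, S).

    The WHO growth-standard table is a user-supplied fixture; any table in
    this schema works (tests use a small synthetic one).
    """
    ref = pd.read_csv(path)
    required = {"sex", "age_months", "L", "M", "S"}
    missing = required - set(ref.columns)
    if missing:
        raise ValueError(f"LMS reference missing columns: {sorted(missing)}")
    if (ref["M"] <= 0).any() or (ref["S"] <= 0).any():
        raise ValueError("LMS reference requires M > 0 and S > 0")
    return ref


def compute_haz(height_cm, age_months, sex, reference: pd.DataFrame):
    """Height-for-age z-score via the LMS formula.

    z = ((height/M)^L - 1) / (L*S), or ln(height/M)/S when L == 0.

    Scalar or vector inputs; the (sex, age_months) pair must be present in
    ``reference`` (ages are matched on the integer month).
    """
    h = np.asarray(height_cm, dtype=float)
    age = np.asarray(age_months)
    sx = np.asarray(sex)
    scalar = h.ndim == 0
    h, age, sx = np.atleast_1d(h), np.atleast_1d(age), np.atleast_1d(sx)
    if (h <= 0).any():
        raise ValueError("height_cm must be positive")

    key = reference.set_index(["sex", "age_months"])
    try:
        rows = key.loc[list(zip(sx, np.floor(age).astype(int)))]
    except KeyError as exc:
        raise LookupError(f"age/sex not covered by LMS reference: {exc}") from exc
    L = rows["L"].to_numpy(float)
    M = rows["M"].to_numpy(float)
    S = rows["S"].to_numpy(float)

    ratio = h / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(L == 0.0, np.log(ratio) / S, (ratio ** L - 1.0) / (L * S))
    return float(z[0]) if scalar else z


def classify_stunting(haz):
    """Classify HAZ into not_stunted / stunted / severely_stunted.

    Strict inequalities: severe iff z < -3, stunted iff -3 <= z < -2.
    For prevalence purposes severely stunted children also count as stunted
    (the -2 threshold is a superset); this function returns the exclusive
    three-way partition.
    """
    z = np.asarray(haz, dtype=float)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    if not np.isfinite(z).all():
        raise ValueError("HAZ must be finite")
    out = np.where(z < -3.0, SEVERELY_STUNTED, np.where(z < -2.0, STUNTED, NOT_STUNTED))
    return str(out[0]) if scalar else out


def is_implausible_haz(haz) -> np.ndarray:
    """Flag |z| > 6 as implausible (excluded upstream, never silently)."""
    return np.abs(np.asarray(haz, dtype=float)) > HAZ_IMPLAUSIBLE


# ---------------------------------------------------------------------------
# HFIAS
# ---------------------------------------------------------------------------

# Category implied by each item at each frequency level (0 = not experienced,
# 1 = rarely, 2 = sometimes, 3 = often).  The household category is the
# maximum over items, which reproduces the standard FANTA v3 decision table
# and makes monotonicity structural: a more severe response can only raise
# the maximum.
_HFIAS_ITEM_CATEGORY = np.array(
    [
        # freq:   0  1  2  3
        [1, 1, 2, 2],  # Q1 worry about food
        [1, 2, 2, 2],  # Q2 unable to eat preferred foods
        [1, 2, 3, 3],  # Q3 limited variety
        [1, 2, 3, 3],  # Q4 ate unwanted foods
        [1, 3, 3, 4],  # Q5 smaller meal
        [1, 3, 3, 4],  # Q6 fewer meals
        [1, 4, 4, 4],  # Q7 no food of any kind in household
        [1, 4, 4, 4],  # Q8 went to sleep hungry
        [1, 4, 4, 4],  # Q9 whole day and night without eating
    ]
)

# Some surveys define the severe class by the last three scenarios only;
# under this stricter reading Q5/Q6 at "often" cap at category 3.
_HFIAS_ITEM_CATEGORY_STRICT = _HFIAS_ITEM_CATEGORY.copy()
_HFIAS_ITEM_CATEGORY_STRICT[4, 3] = 3
_HFIAS_ITEM_CATEGORY_STRICT[5, 3] = 3


def hfias_category(occurrence, frequency, severe_rule: str = "standard") -> int:
    """HFIAS four-level category from the nine occurrence/frequency items.

    Parameters
    ----------
    occurrence : nine 0/1 flags, whether each scenario was experienced.
    frequency : nine ints in {1: rarely, 2: sometimes, 3: often};
        consulted only where the item occurred (must be present there).
    severe_rule : "standard" uses the full FANTA decision table;
        "strict" restricts category 4 to the last three scenarios
        (running out of food, going to bed hungry, a whole day without
        eating).

    Returns the category: 1 food secure ... 4 severely food insecure.
    """
    occ = np.asarray(occurrence)
    freq = np.asarray(frequency)
    if occ.shape[-1] != 9 or freq.shape[-1] != 9:
        raise ValueError("HFIAS requires exactly 9 items")
    occ = occ.astype(float)
    if np.isnan(occ).any():
        idx = int(np.flatnonzero(np.isnan(occ))[0])
        raise ValueError(f"HFIAS occurrence missing for item {idx + 1}")
    occ = occ.astype(int)
    freq = np.where(occ == 1, freq, 0)
    if occ.any():
        f_ans = np.asarray(frequency, dtype=float)[occ == 1]
        if np.isnan(f_ans).any() or not np.isin(f_ans[~np.isnan(f_ans)], [1, 2, 3]).all():
            bad = int(np.flatnonzero(occ)[np.isnan(f_ans) | ~np.isin(f_ans, [1, 2, 3])][0])
            raise ValueError(f"HFIAS frequency missing/invalid for affirmed item {bad + 1}")
    if severe_rule not in ("standard", "strict"):
        raise ValueError("severe_rule must be 'standard' or 'strict'")
    table = _HFIAS_ITEM_CATEGORY if severe_rule == "standard" else _HFIAS_ITEM_CATEGORY_STRICT
    return int(table[np.arange(9), freq.astype(int)].max())


def hfias_category_frame(items: pd.DataFrame, severe_rule: str = "standard") -> pd.Series:
    """Vectorized :func:`hfias_category` over a frame with columns
    hfias_q1..hfias_q9 (occurrence) and hfias_f1..hfias_f9 (frequency)."""
    occ = items[[f"hfias_q{i}" for i in range(1, 10)]].to_numpy(int)
    freq = items[[f"hfias_f{i}" for i in range(1, 10)]].to_numpy(float)
    freq = np.where(occ == 1, freq, 0).astype(int)
    table = _HFIAS_ITEM_CATEGORY if severe_rule == "standard" else _HFIAS_ITEM_CATEGORY_STRICT
    cats = table[np.arange(9)[None, :], freq].max(axis=1)
    return pd.Series(cats, index=items.index, name="hfias_category")


# ---------------------------------------------------------------------------
# Dietary diversity
# ---------------------------------------------------------------------------

def dietary_diversity(food_groups):
    """Score (count of the 12 food groups consumed) and class.

    lowest: <= 3 groups, medium: 4-5, high: >= 6.
    """
    flags = np.asarray(food_groups)
    if flags.shape[-1] != 12:
        raise ValueError("dietary diversity requires exactly 12 food-group flags")
    if not np.isin(flags, [0, 1]).all():
        raise ValueError("food-group flags must be binary")
    score = int(flags.sum(axis=-1)) if flags.ndim == 1 else flags.sum(axis=-1)
    if flags.ndim == 1:
        return score, _dd_class_scalar(score)
    return score, np.array([_dd_class_scalar(s) for s in score])


def _dd_class_scalar(score: int) -> str:
    if score <= 3:
        return DD_LOWEST
    if score <= 5:
        return DD_MEDIUM
    return DD_HIGH


# ---------------------------------------------------------------------------
# Wealth index
# ---------------------------------------------------------------------------

@dataclass
class WealthIndex:
    """First-principal-component asset score and quintile per household."""

    scores: pd.Series
    quintiles: pd.Series          # 1 = poorest ... 5 = richest
    loadings: pd.Series
    explained_share: float        # PC1 eigenvalue / trace
    n_imputed: int


def wealth_index(
    assets: pd.DataFrame,
    positive_indicator: str | None = None,
    weights=None,
) -> WealthIndex:
    """Relative wealth: PCA on standardized asset indicators, quintile cut.

    Indicators with zero variance are dropped; missing entries are
    mean-imputed (count logged).  The PC1 sign is oriented so the declared
    wealth-positive indicator (default: first column) loads positively.
    Quintile boundaries are (optionally weighted) 20% cut points of the
    score, so each quintile holds ~20% of households.
    """
    X = assets.astype(float).copy()
    n_imputed = int(X.isna().sum().sum())
    if n_imputed:
        logger.info("wealth_index: mean-imputing %d missing asset entries", n_imputed)
        X = X.fillna(X.mean())
    sd = X.std(ddof=0)
    keep = sd[sd > 0].index
    if len(keep) < 2:
        raise ValueError("wealth index needs >= 2 indicators with nonzero variance")
    if len(X) < 5:
        raise ValueError("wealth index needs >= 5 households")
    Z = (X[keep] - X[keep].mean()) / sd[keep]

    # PCA on the correlation matrix via SVD of the standardized matrix
    u, s, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    loadings = pd.Series(vt[0], index=keep)
    explained = float(s[0] ** 2 / (s ** 2).sum())
    scores = Z.to_numpy() @ loadings.to_numpy()

    anchor = positive_indicator if positive_indicator is not None else keep[0]
    if anchor not in keep:
        raise ValueError(f"positive_indicator {anchor!r} dropped or absent")
    if loadings[anchor] < 0:
        loadings = -loadings
        scores = -scores

    scores = pd.Series(scores, index=assets.index, name="wealth_score")
    quintiles = _weighted_quintiles(scores, weights)
    return WealthIndex(scores, quintiles, loadings, explained, n_imputed)


def _weighted_quintiles(scores: pd.Series, weights=None) -> pd.Series:
    w = np.ones(len(scores)) if weights is None else np.asarray(weights, float)
    order = np.argsort(scores.to_numpy(), kind="stable")
    cum = np.cumsum(w[order])
    frac = (cum - 0.5 * w[order]) / cum[-1]
    q = np.minimum(np.searchsorted([0.2, 0.4, 0.6, 0.8], frac, side="right") + 1, 5)
    out = np.empty(len(scores), dtype=int)
    out[order] = q
    return pd.Series(out, index=scores.index, name="wealth_quintile")


# ---------------------------------------------------------------------------
# Measurement standardization
# ---------------------------------------------------------------------------

def technical_error_of_measurement(first, second):
    """Intra-pair TEM and coefficient of reliability R for duplicate measures.

    TEM = sqrt(sum d_i^2 / (2n)) over n subjects measured twice;
    R = 1 - TEM^2 / s^2 with s^2 the variance of all 2n measurements.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired measurement vectors of equal length required")
    n = len(a)
    if n < 2:
        raise ValueError("TEM requires at least 2 subjects")
    tem = math.sqrt(float(((a - b) ** 2).sum()) / (2 * n))
    total_var = float(np.var(np.concatenate([a, b]), ddof=1))
    r = 1.0 - tem ** 2 / total_var if total_var > 0 else (1.0 if tem == 0 else float("nan"))
    return tem, r


# ---------------------------------------------------------------------------
# Convenience: score a whole child-record table
# ---------------------------------------------------------------------------

def score_records(
    records: pd.DataFrame,
    lms_reference: pd.DataFrame | None = None,
    severe_rule: str = "standard",
) -> pd.DataFrame:
    """Append haz, stunting_class, hfias_category, dd_score/class and
    wealth_quintile columns to a child-record table.

    HAZ is recomputed from height where a height column and reference are
    supplied, otherwise the existing ``haz`` column is used.  Wealth PCA is
    run at household level (one vote per household) and merged back.
    """
    out = records.copy()
    if lms_reference is not None and "height_cm" in out.columns:
        ok = out["height_cm"].notna()
        out.loc[ok, "haz"] = compute_haz(
            out.loc[ok, "height_cm"], out.loc[ok, "age_months"], out.loc[ok, "sex"], lms_reference
        )
    if "haz" not in out.columns:
        raise ValueError("records need either haz or height_cm + LMS reference")
    out["stunting_class"] = classify_stunting(out["haz"].to_numpy())
    out["stunted"] = (out["haz"] < -2).astype(int)
    out["severely_stunted"] = (out["haz"] < -3).astype(int)

    hf_cols = [f"hfias_q{i}" for i in range(1, 10)] + [f"hfias_f{i}" for i in range(1, 10)]
    if set(hf_cols) <= set(out.columns):
        out["hfias_category"] = hfias_category_frame(out[hf_cols], severe_rule=severe_rule)

    fg_cols = [f"food_group_{i}" for i in range(1, 13)]
    if set(fg_cols) <= set(out.columns):
        score, cls = dietary_diversity(out[fg_cols].to_numpy())
        out["dd_score"], out["dd_class"] = score, cls

    asset_cols = [c for c in out.columns if c.startswith("asset_")]
    if asset_cols and "household_id" in out.columns:
        hh = out.groupby("household_id")[asset_cols].first()
        wi = wealth_index(hh, positive_indicator=asset_cols[0])
        out["wealth_quintile"] = out["household_id"].map(wi.quintiles).astype(int)
    return out
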