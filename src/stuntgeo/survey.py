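"""Design-based prevalence estimation for the stratified cluster survey.

Villages are the primary sampling units (PSUs), agro-ecology zones the
strata, and census records carry smaller sampling weights than the random
sample.  Point estimates are weighted ratios; variances come from Taylor
linearization of the ratio estimator with between-PSU variation within
strata; confidence intervals are built on the logit scale with Student-t
degrees of freedom = #PSUs - #strata.  The extended Mantel-Haenszel
chi-square provides one-degree-of-freedom linear-trend tests for ordered
exposures, and a stratified report reproduces the descriptive table's
layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

logger = logging.getLogger(__name__)


@dataclass
class SurveyDesign:
    """Per-record stratum / PSU labels and sampling weights."""

    stratum: np.ndarray
    psu: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        self.stratum = np.asarray(self.stratum)
        self.psu = np.asarray(self.psu)
        self.weight = np.asarray(self.weight, float)
        if (self.weight <= 0).any():
            raise ValueError("all analyzed records need weight > 0")
        if not len(self.stratum) == len(self.psu) == len(self.weight):
            raise ValueError("design vectors must share one length")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, stratum="stratum", psu="psu", weight="weight"):
        return cls(df[stratum].to_numpy(), df[psu].to_numpy(), df[weight].to_numpy())

    def subset(self, mask) -> "SurveyDesign":
        return SurveyDesign(self.stratum[mask], self.psu[mask], self.weight[mask])


@dataclass
class PrevalenceEstimate:
    proportion: float
    se: float
    ci_low: float
    ci_high: float
    weighted_n: float
    n: int
    df: int


def weighted_prevalence(
    indicator,
    design: SurveyDesign,
    single_psu: str = "error",
    ci_level: float = 0.95,
) -> PrevalenceEstimate:
    """Survey-weighted proportion with Taylor-linearized variance.

    point = sum(w*y)/sum(w).  The linearized score for a record is
    u_i = w_i (y_i - p) / sum(w); variance sums stratum-level between-PSU
    squared deviations of PSU score totals with the n_h/(n_h - 1) factor.
    CI: logit transform with t(df = #PSU - #strata) critical value.

    ``single_psu``: 'error' (default) or 'center' — a lone-PSU stratum
    contributes its deviation from the overall mean score instead of
    erroring out (logged).
    """
    y = np.asarray(indicator, float)
    if not np.isin(y[~np.isnan(y)], [0.0, 1.0]).all():
        raise ValueError("indicator must be binary")
    ok = ~np.isnan(y)
    y, w = y[ok], design.weight[ok]
    strata, psu = design.stratum[ok], design.psu[ok]

    wsum = w.sum()
    p = float((w * y).sum() / wsum)
    u = w * (y - p) / wsum  # linearized scores

    var = 0.0
    n_psu_total = 0
    strata_labels = np.unique(strata)
    grand_mean_tot = None
    for h in strata_labels:
        m = strata == h
        psu_tot = pd.Series(u[m]).groupby(pd.Series(psu[m])).sum().to_numpy()
        n_h = len(psu_tot)
        n_psu_total += n_h
        if n_h < 2:
            if single_psu == "error":
                raise ValueError(f"stratum {h!r} has a single PSU; variance undefined")
            if grand_mean_tot is None:
                all_tot = pd.Series(u).groupby([pd.Series(strata), pd.Series(psu)]).sum()
                grand_mean_tot = float(all_tot.mean())
            logger.info("single-PSU stratum %r centered at the grand mean", h)
            var += (psu_tot[0] - grand_mean_tot) ** 2
            continue
        var += n_h / (n_h - 1) * ((psu_tot - psu_tot.mean()) ** 2).sum()

    se = float(np.sqrt(var))
    df = max(n_psu_total - len(strata_labels), 1)
    tcrit = stats.t.ppf(0.5 + ci_level / 2, df)
    if 0 < p < 1 and se > 0:
        l, se_l = logit(p), se / (p * (1 - p))
        lo, hi = expit(l - tcrit * se_l), expit(l + tcrit * se_l)
    else:
        lo = hi = p
    return PrevalenceEstimate(p, se, float(lo), float(hi), float(wsum), int(ok.sum()), df)


def bootstrap_prevalence_se(
    indicator, design: SurveyDesign, n_replicates: int = 2000, seed: int = 0
) -> float:
    """PSU-resampling bootstrap SE (Rao-Wu style: n_h - 1 PSUs with
    replacement per stratum, weights rescaled).  Independent check on the
    Taylor-linearized SE."""
    y = np.asarray(indicator, float)
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"y": y, "w": design.weight, "s": design.stratum, "p": design.psu})
    grouped = {
        s: [g for _, g in sub.groupby("p")] for s, sub in df.groupby("s")
    }
    est = np.empty(n_replicates)
    for r in range(n_replicates):
        num = den = 0.0
        for s, psus in grouped.items():
            n_h = len(psus)
            take = rng.integers(0, n_h, size=max(n_h - 1, 1))
            scale = n_h / max(n_h - 1, 1)
            for t in take:
                g = psus[t]
                num += scale * float((g["w"] * g["y"]).sum())
                den += scale * float(g["w"].sum())
        est[r] = num / den
    return float(est.std(ddof=1))


# ---------------------------------------------------------------------------
# Trend test
# ---------------------------------------------------------------------------

def trend_test(outcome, ordered_exposure, scores=None, levels=None):
    """Extended Mantel-Haenszel chi-square for linear trend (1 df).

    Equivalent to (N - 1) * r^2 with r the Pearson correlation between the
    outcome indicator and the exposure scores; default scores are the
    integer ranks 1..K of the ordered levels.  Empty levels are dropped
    with a warning.  Returns (chi2, p).
    """
    y = np.asarray(outcome, float)
    e = pd.Series(ordered_exposure)
    if levels is None:
        levels = sorted(e.dropna().unique().tolist())
    present = [lv for lv in levels if (e == lv).any()]
    if len(present) < len(levels):
        logger.warning("trend_test: dropping empty levels %s",
                       [lv for lv in levels if lv not in present])
    if len(present) < 2:
        raise ValueError("trend test needs >= 2 ordered levels with data")
    if scores is None:
        score_map = {lv: k + 1 for k, lv in enumerate(present)}
    else:
        score_map = dict(zip(levels, scores))
    ok = e.isin(present).to_numpy() & ~np.isnan(y)
    s = e[ok].map(score_map).to_numpy(float)
    yy = y[ok]
    n = len(yy)
    r = np.corrcoef(s, yy)[0, 1]
    chi2 = (n - 1) * r ** 2
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def midpoint_scores(levels, bounds: dict):
    """Midpoint scoring alternative to integer ranks (e.g. age categories)."""
    return [0.5 * (bounds[lv][0] + bounds[lv][1]) for lv in levels]


# ---------------------------------------------------------------------------
# Descriptive report
# ---------------------------------------------------------------------------

#: characteristic -> (column, ordered levels or None, trend tested?)
DEFAULT_CHARACTERISTICS = [
    ("Age in months", "age_category", ["<6", "6-11", "12-23", "24-35", "36-47", "48-59"], True),
    ("Sex of the child", "sex", ["female", "male"], False),
    ("Place of delivery", "place_of_delivery", ["home", "facility"], False),
    ("Mother's education", "maternal_education", ["none", "read_write", "primary_plus"], True),
    ("Household food insecurity", "hfias_category", [1, 2, 3, 4], True),
    ("Dietary diversity", "dd_class", ["lowest", "medium", "high"], True),
    ("Household wealth", "wealth_quintile", [1, 2, 3, 4, 5], True),
]


def table1_report(
    records: pd.DataFrame,
    design: SurveyDesign | None = None,
    characteristics=DEFAULT_CHARACTERISTICS,
    single_psu: str = "error",
) -> pd.DataFrame:
    """Stratified prevalence table: % stunted / % severely stunted, mean
    HAZ, weighted and unweighted child counts per category level, with the
    trend-test p-value where the characteristic is ordered, plus a totals
    row with design-based 95% CIs."""
    if design is None:
        design = SurveyDesign.from_frame(records)
    w = design.weight
    rows = []
    for label, col, levels, do_trend in characteristics:
        if col not in records.columns:
            continue
        trend_p = {}
        if do_trend:
            for out_col in ("stunted", "severely_stunted"):
                _, pv = trend_test(records[out_col].to_numpy(),
                                   records[col], levels=levels)
                trend_p[out_col] = pv
        for lv in levels:
            m = (records[col] == lv).to_numpy()
            if not m.any():
                continue
            ww = w[m]
            rows.append({
                "characteristic": label,
                "level": str(lv),
                "pct_stunted": 100 * float((ww * records.loc[m, "stunted"]).sum() / ww.sum()),
                "pct_severe": 100 * float(
                    (ww * records.loc[m, "severely_stunted"]).sum() / ww.sum()),
                "mean_haz": float((ww * records.loc[m, "haz"]).sum() / ww.sum()),
                "weighted_n": float(ww.sum()),
                "n": int(m.sum()),
                "trend_p_stunted": trend_p.get("stunted", np.nan),
                "trend_p_severe": trend_p.get("severely_stunted", np.nan),
            })
    tot = weighted_prevalence(records["stunted"], design, single_psu=single_psu)
    tot_sev = weighted_prevalence(records["severely_stunted"], design, single_psu=single_psu)
    rows.append({
        "characteristic": "Total", "level": "",
        "pct_stunted": 100 * tot.proportion, "pct_severe": 100 * tot_sev.proportion,
        "mean_haz": float((w * records["haz"]).sum() / w.sum()),
        "weighted_n": float(w.sum()), "n": len(records),
        "trend_p_stunted": np.nan, "trend_p_severe": np.nan,
        "ci_stunted": f"[{100 * tot.ci_low:.1f},{100 * tot.ci_high:.1f}]",
        "ci_severe": f"[{100 * tot_sev.ci_low:.1f},{100 * tot_sev.ci_high:.1f}]",
    })
    return pd.DataFrame(rows)


def report_to_markdown(report: pd.DataFrame) -> str:
    """Render the stratified report as a Markdown table."""
    cols = ["characteristic", "level", "pct_stunted", "pct_severe",
            "mean_haz", "weighted_n", "n"]
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join(["---"] * len(cols)) + "|"]
    for _, row in report.iterrows():
        vals = [str(row["characteristic"]), str(row["level"]),
                f"{row['pct_stunted']:.1f}", f"{row['pct_severe']:.1f}",
                f"{row['mean_haz']:.2f}", f"{row['weighted_n']:.0f}", str(int(row["n"]))]
        lines.append("| " + " | ".join(vals) + " |")
    return "\n".join(lines)
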