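"""Exploratory spatial statistics for village-level prevalence.

Great-circle distances, the empirical semivariogram with an
exponential-model fit (practical-range convention), inverse-distance
spatial weights, and Anselin's Local Moran's I with conditional-permutation
inference and HH/LL/HL/LH cluster labelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

CLUSTER_HH, CLUSTER_LL, CLUSTER_HL, CLUSTER_LH = "HH", "LL", "HL", "LH"
CLUSTER_NS = "not significant"


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between (lon, lat) points in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, float)) for x in (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def distance_matrix_km(lon, lat) -> np.ndarray:
    """Pairwise haversine distance matrix (km) for coordinate vectors."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


# ---------------------------------------------------------------------------
# Semivariogram
# ---------------------------------------------------------------------------

@dataclass
class SemivariogramEstimate:
    """Binned empirical semivariogram: gamma(h) = mean squared half-difference."""

    bin_centers: np.ndarray  # km
    gamma: np.ndarray
    pair_counts: np.ndarray

    def nonempty(self) -> "SemivariogramEstimate":
        m = self.pair_counts > 0
        return SemivariogramEstimate(self.bin_centers[m], self.gamma[m], self.pair_counts[m])


@dataclass
class ExponentialVariogramFit:
    """gamma(h) = nugget + psill * (1 - exp(-3h/range_km)).

    Practical-range convention: the fitted curve reaches 95% of the sill at
    h = range_km.
    """

    nugget: float
    partial_sill: float
    range_km: float
    residual: float

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h):
        h = np.asarray(h, float)
        if self.range_km <= 0:
            return np.full_like(h, self.nugget + self.partial_sill)
        return self.nugget + self.partial_sill * (1.0 - np.exp(-3.0 * h / self.range_km))


def empirical_semivariogram(
    values, lon, lat, n_bins: int = 12, max_lag: float | None = None
) -> SemivariogramEstimate:
    """Isotropic empirical semivariogram of a point-referenced field.

    gamma(h) = 1/(2 N(h)) * sum over pairs in the lag bin of (z_i - z_j)^2.
    Default lags: ``n_bins`` equal-width bins to half the maximum pairwise
    distance.  Empty bins are kept (count 0) and flagged by the caller via
    :meth:`SemivariogramEstimate.nonempty`.
    """
    z = np.asarray(values, float)
    n = len(z)
    if n < 5:
        raise ValueError("semivariogram requires at least 5 sites")
    D = distance_matrix_km(lon, lat)
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    sq = (z[iu[0]] - z[iu[1]]) ** 2
    if max_lag is None:
        max_lag = d.max() / 2.0
    if max_lag > d.max():
        raise ValueError("max_lag exceeds the maximum pairwise distance")
    use = d <= max_lag
    if use.sum() < 2:
        raise ValueError("fewer than 2 pairs within max_lag")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    idx = np.clip(np.digitize(d[use], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sq[use], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if (counts == 0).any():
        logger.info("semivariogram: %d empty lag bins", int((counts == 0).sum()))
    return SemivariogramEstimate(centers, gamma, counts)


class VariogramFitError(RuntimeError):
    """Fit failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best: ExponentialVariogramFit):
        super().__init__(message)
        self.best = best


def fit_exponential_variogram(est: SemivariogramEstimate) -> ExponentialVariogramFit:
    """Weighted least squares fit of the exponential model to binned gamma.

    Weights are the per-bin pair counts; nugget, partial sill and range are
    constrained nonnegative.  A flat (pure-nugget) variogram is handled by
    letting the range run to its lower bound.
    """
    e = est.nonempty()
    if len(e.gamma) < 3:
        raise ValueError("need >= 3 non-empty lag bins to fit")
    h, g, w = e.bin_centers, e.gamma, e.pair_counts.astype(float)
    gmax = max(g.max(), 1e-12)
    hmax = h.max()

    def model(theta):
        nug, ps, rng = theta
        return nug + ps * (1.0 - np.exp(-3.0 * h / max(rng, 1e-9)))

    def resid(theta):
        return np.sqrt(w) * (model(theta) - g)

    best = None
    for rng0 in (hmax / 3.0, hmax, hmax / 10.0):
        x0 = np.array([0.1 * gmax, 0.9 * gmax, rng0])
        res = optimize.least_squares(
            resid, x0, bounds=([0, 0, 1e-9], [np.inf, np.inf, 100 * hmax]), method="trf"
        )
        if best is None or res.cost < best.cost:
            best = res
    fit = ExponentialVariogramFit(*best.x, residual=float(best.cost))
    if not best.success:
        raise VariogramFitError(f"variogram fit did not converge: {best.message}", fit)
    return fit


def plot_variogram(est: SemivariogramEstimate, fit: ExponentialVariogramFit | None = None,
                   path=None):
    """Binned semivariance with the fitted exponential curve overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    e = est.nonempty()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(e.bin_centers, e.gamma, s=10 + 2 * np.sqrt(e.pair_counts), c="k",
               label="empirical")
    if fit is not None:
        h = np.linspace(0, est.bin_centers.max(), 200)
        ax.plot(h, fit(h), "r-",
                label=f"exponential (range {fit.range_km:.1f} km)")
    ax.set_xlabel("lag distance (km)")
    ax.set_ylabel("semivariance")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Spatial weights
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeightMatrix:
    """Inverse-distance weights with zero diagonal, optionally row-standardized."""

    site_ids: list
    weights: np.ndarray
    row_standardized: bool = False


def inverse_distance_weights(
    lon,
    lat,
    site_ids=None,
    power: float = 1.0,
    row_standardize: bool = True,
    threshold_km: float | None = None,
) -> SpatialWeightMatrix:
    """w_ij = d_ij^(-power) for distinct sites i != j.

    Optional distance cutoff zeroes weights beyond ``threshold_km``.  Row
    standardization rescales each nonzero row to sum to one, so the spatial
    lag is a weighted average of neighbours.
    """
    D = distance_matrix_km(lon, lat)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    if (D[off] == 0).any():
        raise ValueError("zero distance between distinct sites; jitter coordinates first")
    W = np.zeros_like(D)
    W[off] = D[off] ** (-power)
    if threshold_km is not None:
        W[D > threshold_km] = 0.0
    if row_standardize:
        rs = W.sum(axis=1, keepdims=True)
        W = np.divide(W, rs, out=np.zeros_like(W), where=rs > 0)
    ids = list(site_ids) if site_ids is not None else list(range(n))
    return SpatialWeightMatrix(ids, W, row_standardized=row_standardize)


# ---------------------------------------------------------------------------
# Local Moran's I
# ---------------------------------------------------------------------------

def global_morans_i(values, W: SpatialWeightMatrix) -> float:
    """Global Moran's I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2."""
    x = np.asarray(values, float)
    z = x - x.mean()
    Wm = W.weights
    s0 = Wm.sum()
    return float(len(x) / s0 * (z @ Wm @ z) / (z @ z))


def local_morans_i(
    values,
    W: SpatialWeightMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Anselin's Local Moran's I with conditional-permutation inference.

    I_i = (z_i / m2) * sum_j w_ij z_j, with z the mean deviations and
    m2 = sum z^2 / (n - 1).  For each site the remaining values are permuted
    (the focal value held fixed); the one-tail pseudo p is
    (r + 1)/(M + 1) with r the count of permuted statistics at least as
    extreme as the observed one, and the reported p doubles the smaller
    tail (capped at 1) so that the nominal level is calibrated: selecting
    the tail adaptively without folding would reject ~2*alpha under the
    null.
    Cluster classes: HH/LL where own and lagged deviations share sign (I > 0),
    HL/LH spatial outliers otherwise; labelled significant only at p <= alpha.
    """
    x = np.asarray(values, float)
    n = len(x)
    if n < 5 or n != W.weights.shape[0]:
        raise ValueError("need >= 5 sites matching the weight matrix order")
    if np.ptp(x) == 0:
        raise ValueError("values have zero variance")
    z = x - x.mean()
    m2 = (z @ z) / (n - 1)
    Wm = W.weights
    lag = Wm @ z
    I_obs = z / m2 * lag

    rng = np.random.default_rng(seed)
    p_sim = np.empty(n)
    z_sim = np.empty(n)
    e_sim = np.empty(n)
    M = int(n_permutations)
    others = np.arange(n)
    for i in range(n):
        rest = z[others != i]
        wi = Wm[i, others != i]
        # permute the remaining values among the remaining positions
        perm = rng.permuted(np.broadcast_to(rest, (M, n - 1)), axis=1)
        lag_perm = perm @ wi
        I_perm = z[i] / m2 * lag_perm
        e_sim[i] = I_perm.mean()
        sd = I_perm.std(ddof=1)
        z_sim[i] = (I_obs[i] - e_sim[i]) / sd if sd > 0 else np.nan
        if I_obs[i] >= e_sim[i]:
            r = int((I_perm >= I_obs[i]).sum())
        else:
            r = int((I_perm <= I_obs[i]).sum())
        p_sim[i] = min(1.0, 2.0 * (r + 1) / (M + 1))

    quadrant = np.where(
        z >= 0,
        np.where(lag >= 0, CLUSTER_HH, CLUSTER_HL),
        np.where(lag >= 0, CLUSTER_LH, CLUSTER_LL),
    )
    cluster = np.where(p_sim <= alpha, quadrant, CLUSTER_NS)
    return pd.DataFrame(
        {
            "site_id": W.site_ids,
            "local_i": I_obs,
            "expected_i": e_sim,
            "p_sim": p_sim,
            "z_sim": z_sim,
            "quadrant": quadrant,
            "cluster": cluster,
        }
    )


def fdr_adjust_lisa(lisa: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment of the LISA pseudo p-values.

    No correction is applied by default in :func:`local_morans_i`
    (matching common practice); this helper adds ``p_fdr`` and relabels
    ``cluster`` using the adjusted values."""
    from statsmodels.stats.multitest import multipletests

    out = lisa.copy()
    reject, p_adj, _, _ = multipletests(out["p_sim"], alpha=alpha, method="fdr_bh")
    out["p_fdr"] = p_adj
    out["cluster"] = np.where(reject, out["quadrant"], CLUSTER_NS)
    return out


# ---------------------------------------------------------------------------
# Normality screen
# ---------------------------------------------------------------------------

@dataclass
class NormalityCheck:
    statistic: float
    p_value: float
    hist_counts: np.ndarray = field(repr=False)
    hist_edges: np.ndarray = field(repr=False)


def normality_check(values, bins: int = 10) -> NormalityCheck:
    """Shapiro-Wilk test plus a binned histogram for reporting.

    Spatial association statistics can mislead on heavily non-normal
    prevalence fields, so the field is screened before LISA.
    """
    x = np.asarray(values, float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    w, p = stats.shapiro(x)
    counts, edges = np.histogram(x, bins=bins)
    return NormalityCheck(float(w), float(p), counts, edges)
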