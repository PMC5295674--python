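"""Bayesian logistic regression with and without a geostatistical random
effect, plus the supporting variable-selection machinery.

Model (spatial variant)::

    y_ij ~ Bernoulli(p_ij)
    logit p_ij = x_ij' beta + S_j
    S ~ GP(0, sigma2 * exp(-phi * d)),  d = great-circle distance in km

with weakly-informative priors: beta ~ N(0, 1e6), sigma2 ~ IG(0.1, 0.1),
phi ~ Uniform over the range implied by the inter-village distances.  The
non-spatial variant drops S entirely (fixed-effects logistic).  Sampling is
Metropolis-within-Gibbs: an adaptive joint random walk for beta
(preconditioned by the MLE covariance), per-village random-walk updates for
S, a conjugate inverse-gamma draw for sigma2, and a log-scale random walk
for phi.  Models are compared by DIC = Dbar + pD, pD = Dbar - D(theta_bar).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
import statsmodels.api as sm

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

_AGE_DUMMY = {"6-11": "age_6_11", "12-23": "age_12_23", "24-35": "age_24_35",
              "36-47": "age_36_47", "48-59": "age_48_59"}
_WEALTH_DUMMY = {4: "wealth_rich", 3: "wealth_middle", 2: "wealth_poor", 1: "wealth_poorest"}
_HFIAS_DUMMY = {2: "hfias_mild", 3: "hfias_moderate", 4: "hfias_severe"}


def design_matrix(
    records: pd.DataFrame,
    include_morbidity: bool = False,
    include_altitude: bool = True,
):
    """Dummy-coded design matrix with the analysis' reference levels.

    References: age <6 months, female, home delivery, primary+ maternal
    education, Guraghe ethnicity, food-secure household, richest quintile.
    Altitude enters per metre, centred.  Returns (X, names) without an
    intercept column.
    """
    cols: dict[str, np.ndarray] = {}
    for level, name in _AGE_DUMMY.items():
        cols[name] = (records["age_category"] == level).to_numpy(float)
    cols["male"] = (records["sex"] == "male").to_numpy(float)
    cols["facility_delivery"] = (records["place_of_delivery"] == "facility").to_numpy(float)
    cols["edu_read_write"] = (records["maternal_education"] == "read_write").to_numpy(float)
    cols["edu_none"] = (records["maternal_education"] == "none").to_numpy(float)
    cols["eth_siltie"] = (records["ethnicity"] == "siltie").to_numpy(float)
    cols["eth_mareko"] = (records["ethnicity"] == "mareko").to_numpy(float)
    cols["eth_other"] = (records["ethnicity"] == "other").to_numpy(float)
    for level, name in _HFIAS_DUMMY.items():
        cols[name] = (records["hfias_category"].astype(int) == level).to_numpy(float)
    for level, name in _WEALTH_DUMMY.items():
        cols[name] = (records["wealth_quintile"].astype(int) == level).to_numpy(float)
    if include_morbidity and "morbidity" in records.columns:
        cols["morbid"] = (records["morbidity"] == "morbid").to_numpy(float)
    if include_altitude and "altitude_m" in records.columns:
        alt = records["altitude_m"].to_numpy(float)
        cols["altitude_m"] = alt - alt.mean()
    names = list(cols.keys())
    X = np.column_stack([cols[nm] for nm in names])
    return X, names


def compute_vif(X, names=None) -> pd.Series:
    """Variance inflation factor per column: VIF_j = 1/(1 - R2_j), with R2_j
    from regressing column j on the remaining columns (plus intercept).
    Exactly collinear columns are reported as ``inf``."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= p:
        raise ValueError("VIF needs more rows than columns")
    names = names if names is not None else [f"x{j}" for j in range(p)]
    out = {}
    ones = np.ones((n, 1))
    for j in range(p):
        yj = X[:, j]
        Zj = np.column_stack([ones, np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(Zj, yj, rcond=None)
        resid = yj - Zj @ coef
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    vif = pd.Series(out, name="vif")
    if np.isinf(vif).any():
        logger.warning("exact collinearity detected: %s", list(vif.index[np.isinf(vif)]))
    return vif


# ---------------------------------------------------------------------------
# Two-level random-intercept logistic (Laplace) for univariable screening
# ---------------------------------------------------------------------------

def _bernoulli_loglik(y, eta):
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


@dataclass
class TwoLevelLogitFit:
    beta: np.ndarray
    se: np.ndarray
    names: list
    sigma2_kebele: float
    sigma2_village: float
    loglik: float
    p_values: np.ndarray
    converged: bool
    penalized: bool = False


def fit_two_level_logit(
    y, X, kebele, village, names=None, max_outer: int = 200, ridge: float = 0.0
) -> TwoLevelLogitFit:
    """Laplace-approximate two-level random-intercept logistic regression.

    Random intercepts for kebeles and for villages (crossed coding, nested
    in practice).  For fixed variance components the joint penalized
    log-likelihood is maximized over (beta, u) by Newton iterations; the
    Laplace correction -0.5 log|H_uu| completes the marginal likelihood,
    which a Nelder-Mead search maximizes over the two log-variances.
    Wald SEs come from the fixed-effect block of the inverse joint Hessian.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    keb_lab, keb_idx = np.unique(kebele, return_inverse=True)
    vil_lab, vil_idx = np.unique(village, return_inverse=True)
    K, V = len(keb_lab), len(vil_lab)
    Zk = np.zeros((n, K))
    Zk[np.arange(n), keb_idx] = 1.0
    Zv = np.zeros((n, V))
    Zv[np.arange(n), vil_idx] = 1.0
    Z = np.column_stack([X, Zk, Zv])
    q = K + V

    def inner_mode(s2k, s2v, theta0=None):
        dinv = np.concatenate([np.full(p, ridge), np.full(K, 1.0 / s2k), np.full(V, 1.0 / s2v)])
        theta = np.zeros(p + q) if theta0 is None else theta0.copy()
        for _ in range(100):
            eta = Z @ theta
            mu = expit(eta)
            g = Z.T @ (y - mu) - dinv * theta
            w = mu * (1.0 - mu) + 1e-12
            H = (Z * w[:, None]).T @ Z + np.diag(dinv)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            # dampen long steps (guards against separation blow-up)
            nrm = np.linalg.norm(step)
            if nrm > 10.0:
                step *= 10.0 / nrm
            theta = theta + step
            if np.linalg.norm(g) < 1e-8 * (1 + np.linalg.norm(theta)):
                break
        eta = Z @ theta
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        H = (Z * w[:, None]).T @ Z + np.diag(dinv)
        pen = 0.5 * float((dinv[p:] * theta[p:] ** 2).sum())
        ll_joint = _bernoulli_loglik(y, eta) - pen
        H_uu = H[p:, p:]
        sign, logdet_huu = np.linalg.slogdet(H_uu)
        logdet_d = K * np.log(s2k) + V * np.log(s2v)
        laplace = ll_joint - 0.5 * (logdet_d + logdet_huu)
        return theta, H, laplace

    cache = {"theta": None}

    def neg_laplace(log_s2):
        s2k, s2v = np.exp(np.clip(log_s2, -12, 6))
        theta, _, la = inner_mode(s2k, s2v, cache["theta"])
        cache["theta"] = theta
        return -la

    res = optimize.minimize(neg_laplace, x0=np.log([0.1, 0.1]), method="Nelder-Mead",
                            options={"maxiter": max_outer, "xatol": 1e-3, "fatol": 1e-4})
    s2k, s2v = np.exp(np.clip(res.x, -12, 6))
    theta, H, la = inner_mode(s2k, s2v, cache["theta"])
    penalized = ridge > 0
    if ridge == 0 and (not np.isfinite(theta[:p]).all() or np.abs(theta[:p]).max() > 15):
        # quasi-separation: refit with a small ridge on the fixed effects
        logger.warning("quasi-separation detected; refitting with ridge penalty")
        refit = fit_two_level_logit(y, X, kebele, village, names, max_outer, ridge=1e-2)
        refit.penalized = True
        return refit
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov)[:p])
    z = theta[:p] / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return TwoLevelLogitFit(
        beta=theta[:p], se=se, names=names or [f"x{j}" for j in range(p)],
        sigma2_kebele=float(s2k), sigma2_village=float(s2v), loglik=float(la),
        p_values=pvals, converged=bool(res.success), penalized=penalized,
    )


@dataclass
class ScreenResult:
    variable: str
    levels: list
    estimates: np.ndarray
    p_values: np.ndarray
    retained: bool
    fit: TwoLevelLogitFit = field(repr=False)


def univariable_screen(
    records: pd.DataFrame,
    variable: str,
    outcome: str = "stunted",
    kebele_col: str = "kebele_id",
    village_col: str = "village_id",
    threshold: float = 0.2,
) -> ScreenResult:
    """Screen one covariate with a two-level random-intercept logistic model.

    The covariate is dummy-coded against its first observed level; the
    variable is retained when any level's Wald p-value falls below
    ``threshold`` (the conventional 0.2 screening cut)."""
    v = records[variable]
    if v.nunique() < 2:
        raise ValueError(f"{variable!r} has fewer than 2 observed levels")
    if pd.api.types.is_numeric_dtype(v) and v.nunique() > 6:
        X = np.column_stack([np.ones(len(v)), (v - v.mean()).to_numpy(float)])
        names = ["intercept", variable]
    else:
        dummies = pd.get_dummies(v, prefix=variable, drop_first=True).astype(float)
        X = np.column_stack([np.ones(len(v)), dummies.to_numpy()])
        names = ["intercept"] + list(dummies.columns)
    fit = fit_two_level_logit(
        records[outcome].to_numpy(float), X, records[kebele_col], records[village_col],
        names=names,
    )
    est, pv = fit.beta[1:], fit.p_values[1:]
    return ScreenResult(variable, names[1:], est, pv, bool((pv < threshold).any()), fit)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class Priors:
    beta_variance: float = 1e6
    sigma2_shape: float = 0.1
    sigma2_rate: float = 0.1
    phi_bounds: tuple | None = None  # default: (3/d_max, 3/d_min)


@dataclass
class GeoLogisticModel:
    """Outcome, design and spatial structure for one Bayesian logistic fit."""

    y: np.ndarray
    X: np.ndarray                 # without intercept column
    names: list
    spatial: bool = False
    village_index: np.ndarray | None = None   # per record, into distance matrix
    distances_km: np.ndarray | None = None    # village-level
    priors: Priors = field(default_factory=Priors)

    def __post_init__(self):
        self.y = np.asarray(self.y, float)
        self.X = np.asarray(self.X, float)
        if self.spatial:
            if self.village_index is None or self.distances_km is None:
                raise ValueError("spatial model requires village_index and distances_km")
            self.village_index = np.asarray(self.village_index, int)

    @property
    def Xfull(self) -> np.ndarray:
        return np.column_stack([np.ones(len(self.y)), self.X])

    @property
    def param_names(self) -> list:
        return ["intercept"] + list(self.names)


@dataclass
class MCMCConfig:
    burn_in: int = 10_000
    kept: int = 20_000
    thin: int = 10
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.burn_in, self.kept, self.thin, self.n_chains) < 1:
            raise ValueError("MCMC settings must be positive")
        if self.kept // self.thin < 100:
            raise ValueError("kept/thin must be >= 100 for stable summaries")


#: Reduced schedule for tests and quick runs.
FAST_MCMC = dict(burn_in=600, kept=1200, thin=2, n_chains=1)
#: The production schedule: long burn-in, heavy thinning, two chains.
FULL_MCMC = dict(burn_in=10_000, kept=20_000, thin=10, n_chains=2)


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws, one leading axis per chain."""

    beta: np.ndarray              # (chains, draws, p+1)
    names: list
    deviance: np.ndarray          # (chains, draws)
    S: np.ndarray | None = None   # (chains, draws, n_villages)
    sigma2: np.ndarray | None = None
    phi: np.ndarray | None = None
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])


def _mle_start(model: GeoLogisticModel):
    Xf = model.Xfull
    if len(model.y) == 0:  # prior-only run (no data): start at the prior mode
        return np.zeros(Xf.shape[1]), np.eye(Xf.shape[1])
    try:
        fit = sm.GLM(model.y, Xf, family=sm.families.Binomial()).fit()
        beta0 = np.asarray(fit.params, float)
        cov = np.asarray(fit.cov_params(), float)
        if not (np.isfinite(beta0).all() and np.isfinite(cov).all()):
            raise ValueError
    except Exception:
        logger.warning("logistic MLE failed; ridge fallback for MCMC start")
        fit = sm.GLM(model.y, Xf, family=sm.families.Binomial()).fit_regularized(alpha=1e-3)
        beta0 = np.asarray(fit.params, float)
        w = expit(Xf @ beta0)
        H = (Xf * (w * (1 - w))[:, None]).T @ Xf + 1e-3 * np.eye(Xf.shape[1])
        cov = np.linalg.inv(H)
    # symmetrize and factor
    cov = 0.5 * (cov + cov.T) + 1e-10 * np.eye(cov.shape[0])
    return beta0, np.linalg.cholesky(cov)


def run_mcmc(model: GeoLogisticModel, config: MCMCConfig) -> PosteriorDraws:
    """Sample the posterior; reproducible for a fixed config seed."""
    chains = []
    for c in range(config.n_chains):
        chains.append(_run_chain(model, config, seed=config.seed + 1000 * c, chain_id=c))
    out = PosteriorDraws(
        beta=np.stack([ch["beta"] for ch in chains]),
        names=model.param_names,
        deviance=np.stack([ch["deviance"] for ch in chains]),
        accept_rates=chains[0]["accept"],
    )
    if model.spatial:
        out.S = np.stack([ch["S"] for ch in chains])
        out.sigma2 = np.stack([ch["sigma2"] for ch in chains])
        out.phi = np.stack([ch["phi"] for ch in chains])
    return out


def _corr_factor(D, phi):
    R = np.exp(-phi * D)
    R[np.diag_indices_from(R)] += 1e-9
    L = np.linalg.cholesky(R)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    Rinv = np.linalg.inv(R)
    return Rinv, logdet


def _run_chain(model: GeoLogisticModel, config: MCMCConfig, seed: int, chain_id: int):
    rng = np.random.default_rng(seed)
    y, Xf = model.y, model.Xfull
    n, p1 = Xf.shape
    prior = model.priors
    beta, prop_chol = _mle_start(model)
    beta = beta + 0.1 * prop_chol @ rng.standard_normal(p1)  # overdispersed start

    spatial = model.spatial
    if spatial:
        D = model.distances_km
        nv = D.shape[0]
        vidx = model.village_index
        rows_of = [np.flatnonzero(vidx == j) for j in range(nv)]
        offd = D[np.triu_indices(nv, k=1)]
        dmin = max(offd[offd > 0].min(), 1e-6)
        lo, hi = prior.phi_bounds or (3.0 / offd.max(), 3.0 / dmin)
        phi = float(np.sqrt(lo * hi))
        sigma2 = 1.0
        S = np.zeros(nv)
        Rinv, logdetR = _corr_factor(D, phi)
        s_scales = np.full(nv, 0.5)
        phi_scale = 0.5
    else:
        S = None

    eta = Xf @ beta + (S[vidx] if spatial else 0.0)
    ll = _bernoulli_loglik(y, eta)

    def lprior_beta(b):
        return -0.5 * float(b @ b) / prior.beta_variance

    lp_beta = lprior_beta(beta)
    beta_scale = 2.38 / np.sqrt(p1)
    acc = {"beta": 0, "S": 0, "phi": 0}
    tries = {"beta": 0, "S": 0, "phi": 0}

    n_iter = config.burn_in + config.kept
    n_keep = config.kept // config.thin
    kb = np.empty((n_keep, p1))
    kdev = np.empty(n_keep)
    if spatial:
        kS = np.empty((n_keep, nv))
        ks2 = np.empty(n_keep)
        kphi = np.empty(n_keep)
    kept_i = 0

    for it in range(n_iter):
        adapting = it < config.burn_in
        # ---- beta: joint preconditioned random walk ----
        prop = beta + beta_scale * (prop_chol @ rng.standard_normal(p1))
        eta_prop = Xf @ prop + (S[vidx] if spatial else 0.0)
        ll_prop = _bernoulli_loglik(y, eta_prop)
        lp_prop = lprior_beta(prop)
        tries["beta"] += 1
        a = ll_prop + lp_prop - ll - lp_beta
        if np.log(rng.random()) < a:
            beta, eta, ll, lp_beta = prop, eta_prop, ll_prop, lp_prop
            acc["beta"] += 1
        if adapting and tries["beta"] % 50 == 0:
            rate = acc["beta"] / tries["beta"]
            beta_scale *= np.exp(0.5 * (rate - 0.234))

        if spatial:
            # ---- S: per-village random walk ----
            Q = Rinv / sigma2
            for j in rng.permutation(nv):
                sj = S[j]
                sp = sj + s_scales[j] * rng.standard_normal()
                rows = rows_of[j]
                if len(rows):
                    eta_j = eta[rows]
                    d_eta = sp - sj
                    ll_old = float(y[rows] @ eta_j - np.logaddexp(0.0, eta_j).sum())
                    eta_new = eta_j + d_eta
                    ll_new = float(y[rows] @ eta_new - np.logaddexp(0.0, eta_new).sum())
                else:
                    ll_old = ll_new = 0.0
                cross = float(Q[j] @ S) - Q[j, j] * sj
                dprior = -0.5 * Q[j, j] * (sp ** 2 - sj ** 2) - (sp - sj) * cross
                tries["S"] += 1
                if np.log(rng.random()) < (ll_new - ll_old + dprior):
                    S[j] = sp
                    if len(rows):
                        eta[rows] += d_eta
                        ll += ll_new - ll_old
                    acc["S"] += 1
                    if adapting:
                        s_scales[j] *= np.exp(0.05 * (1 - 0.44))
                elif adapting:
                    s_scales[j] *= np.exp(0.05 * (0 - 0.44))

            # ---- sigma2: conjugate inverse-gamma ----
            quad = float(S @ Rinv @ S)
            shape = prior.sigma2_shape + 0.5 * nv
            rate_ = prior.sigma2_rate + 0.5 * quad
            sigma2 = rate_ / rng.gamma(shape)

            # ---- phi: random walk on log phi, Uniform(lo, hi) prior ----
            lphi = np.log(phi) + phi_scale * rng.standard_normal()
            phi_prop = float(np.exp(lphi))
            tries["phi"] += 1
            if lo <= phi_prop <= hi:
                Rinv_p, logdetR_p = _corr_factor(D, phi_prop)
                quad_p = float(S @ Rinv_p @ S)
                lpost_old = -0.5 * logdetR - 0.5 * quad / sigma2 + np.log(phi)
                lpost_new = -0.5 * logdetR_p - 0.5 * quad_p / sigma2 + np.log(phi_prop)
                if np.log(rng.random()) < lpost_new - lpost_old:
                    phi, Rinv, logdetR = phi_prop, Rinv_p, logdetR_p
                    acc["phi"] += 1
                    if adapting:
                        phi_scale *= np.exp(0.1 * (1 - 0.44))
                elif adapting:
                    phi_scale *= np.exp(0.1 * (0 - 0.44))
            elif adapting:
                phi_scale *= np.exp(0.1 * (0 - 0.44))

        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite likelihood at iteration {it}; state: beta={beta}, "
                f"sigma2={sigma2 if spatial else None}"
            )

        k = it - config.burn_in
        if k >= 0 and (k + 1) % config.thin == 0 and kept_i < n_keep:
            kb[kept_i] = beta
            kdev[kept_i] = -2.0 * ll
            if spatial:
                kS[kept_i] = S
                ks2[kept_i] = sigma2
                kphi[kept_i] = phi
            kept_i += 1

    out = {
        "beta": kb, "deviance": kdev,
        "accept": {k: (acc[k] / tries[k] if tries[k] else np.nan) for k in acc},
    }
    if spatial:
        out.update({"S": kS, "sigma2": ks2, "phi": kphi})
    return out


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

@dataclass
class DICResult:
    dic: float
    p_d: float
    d_bar: float
    d_hat: float


def model_deviance(model: GeoLogisticModel, beta, S=None) -> float:
    eta = model.Xfull @ np.asarray(beta, float)
    if model.spatial and S is not None:
        eta = eta + np.asarray(S, float)[model.village_index]
    return -2.0 * _bernoulli_loglik(model.y, eta)


def dic_from_deviance(deviance_draws, deviance_at_mean: float) -> DICResult:
    """Assemble DIC from deviance draws and the plug-in deviance.

    DIC = Dbar + pD, pD = Dbar - D(theta_bar).  Model-agnostic: any
    likelihood whose deviance can be evaluated drawwise and at the
    posterior mean can use this directly."""
    dev = np.asarray(deviance_draws, float).ravel()
    d_bar = float(dev.mean())
    p_d = d_bar - float(deviance_at_mean)
    if p_d < 0:
        logger.warning("negative pD (%.3f): posterior mean outside bulk of draws", p_d)
    return DICResult(dic=d_bar + p_d, p_d=p_d, d_bar=d_bar, d_hat=float(deviance_at_mean))


def compute_dic(draws: PosteriorDraws, model: GeoLogisticModel) -> DICResult:
    """DIC = Dbar + pD with pD = Dbar - D(theta_bar); theta_bar is the
    posterior mean of (beta, S).  A negative pD is reported with a warning,
    never suppressed."""
    dev = draws.pooled("deviance")
    if dev.size < 500:
        raise ValueError("DIC needs >= 500 draws")
    beta_bar = draws.pooled("beta").mean(axis=0)
    S_bar = draws.pooled("S").mean(axis=0) if draws.S is not None else None
    return dic_from_deviance(dev, model_deviance(model, beta_bar, S_bar))


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def summarize_posterior(draws: PosteriorDraws, distance_unit: str = "km") -> pd.DataFrame:
    """Per-parameter mean/SD/median/95% BCI plus odds-ratio columns.

    OR intervals are the exponential of the coefficient draw quantiles
    (quantile-then-exp; exact under the monotone transform).  For spatial
    models the practical range 3/phi is summarized in km alongside the
    spatial variance."""
    rows = []

    def add(name, arr, odds=False):
        q = np.percentile(arr, [2.5, 50, 97.5])
        row = {"parameter": name, "mean": arr.mean(), "sd": arr.std(ddof=1),
               "median": q[1], "bci_2.5": q[0], "bci_97.5": q[2]}
        if odds:
            row.update({"or": float(np.exp(arr).mean()), "or_median": np.exp(q[1]),
                        "or_2.5": np.exp(q[0]), "or_97.5": np.exp(q[2])})
        rows.append(row)

    b = draws.pooled("beta")
    for j, nm in enumerate(draws.names):
        add(nm, b[:, j], odds=nm != "intercept")
    if draws.sigma2 is not None:
        add("spatial_variance", draws.pooled("sigma2"))
        rng_draws = 3.0 / draws.pooled("phi")
        add(f"spatial_range_{distance_unit}", rng_draws)
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def _autocorr(x: np.ndarray) -> np.ndarray:
    n = len(x)
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    return acov / acov[0] if acov[0] > 0 else np.zeros(n)


def effective_sample_size(x) -> float:
    """ESS via Geyer's initial-positive-sequence estimator on the pooled
    autocorrelation: n / (1 + 2 * sum of paired positive autocorrelations)."""
    x = np.asarray(x, float).ravel()
    n = len(x)
    rho = _autocorr(x)
    # sum consecutive pairs rho[2t-1] + rho[2t]; stop at the first negative pair
    tau = 1.0
    t = 1
    while t + 1 < n:
        s = rho[t] + rho[t + 1]
        if s < 0:
            break
        tau += 2.0 * s
        t += 2
    return float(n / max(tau, 1e-12))


def _spectral_se(x: np.ndarray) -> float:
    n = len(x)
    ess = effective_sample_size(x)
    return float(np.std(x, ddof=1) / np.sqrt(ess)) if n > 1 else np.nan


def geweke_z(x, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score: standardized difference between the mean
    of the first 10% and the last 50% of a chain, with autocorrelation-
    adjusted standard errors."""
    x = np.asarray(x, float).ravel()
    n = len(x)
    if n < 50:
        raise ValueError("too few draws for the Geweke diagnostic")
    a = x[: int(first * n)]
    b = x[int((1 - last) * n):]
    return float((a.mean() - b.mean()) / np.hypot(_spectral_se(a), _spectral_se(b)))


def convergence_diagnostics(draws: PosteriorDraws) -> pd.DataFrame:
    """Geweke z and ESS per parameter (computed chainwise, ESS summed)."""
    rows = []
    series = {nm: draws.beta[:, :, j] for j, nm in enumerate(draws.names)}
    if draws.sigma2 is not None:
        series["spatial_variance"] = draws.sigma2
        series["phi"] = draws.phi
    for nm, arr in series.items():
        z = np.mean([geweke_z(chain) for chain in arr])
        ess = float(sum(effective_sample_size(chain) for chain in arr))
        rows.append({"parameter": nm, "geweke_z": z, "ess": ess,
                     "n_draws": arr.size})
    return pd.DataFrame(rows).set_index("parameter")


def export_traces(draws: PosteriorDraws, path) -> None:
    """Persist pooled draws as CSV, one column per parameter."""
    cols = {nm: draws.pooled("beta")[:, j] for j, nm in enumerate(draws.names)}
    if draws.sigma2 is not None:
        cols["spatial_variance"] = draws.pooled("sigma2")
        cols["phi"] = draws.pooled("phi")
    cols["deviance"] = draws.pooled("deviance")
    pd.DataFrame(cols).to_csv(path, index=False)
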