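"""Seeded synthetic study regions and child-level survey data.

The generator emulates the study conditions of a district-scale stunting
survey in rural southern Ethiopia: ~40 kebeles subdivided into ~45 surveyed
villages inside a ~30 km extent, ~4,000 children under five, covariate
margins matching the survey's descriptive table (three quarters of mothers
without formal education, ~15% facility deliveries, balanced sex ratio),
a logistic outcome model with village-level Gaussian-process spatial
effects under exponential correlation (variance 0.96, practical range
33 km), and raw HFIAS / food-group / asset items constructed so that
re-scoring them with :mod:`stuntgeo.indicators` reproduces the category or
quintile assigned at simulation time.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import indicators
from .spatial import distance_matrix_km

# Anchor of the study extent (degrees); a rural district ~130 km south of
# Addis Ababa.
ANCHOR_LON, ANCHOR_LAT = 38.4576, 8.0421

KM_PER_DEG_LAT = 110.574


AGE_CATEGORIES = ["<6", "6-11", "12-23", "24-35", "36-47", "48-59"]
_AGE_BOUNDS = {"<6": (0, 5), "6-11": (6, 11), "12-23": (12, 23),
               "24-35": (24, 35), "36-47": (36, 47), "48-59": (48, 59)}

#: Default covariate margins: the emulated survey's descriptive distribution.
DEFAULT_MARGINS: dict[str, dict] = {
    "age_category": {"<6": 0.0735, "6-11": 0.1026, "12-23": 0.1779,
                     "24-35": 0.1839, "36-47": 0.2244, "48-59": 0.2377},
    "sex": {"female": 0.5046, "male": 0.4954},
    "place_of_delivery": {"home": 0.8493, "facility": 0.1507},
    "maternal_education": {"none": 0.7525, "read_write": 0.0378, "primary_plus": 0.2097},
    "ethnicity": {"guraghe": 0.55, "siltie": 0.30, "mareko": 0.10, "other": 0.05},
    "morbidity": {"none": 0.615, "morbid": 0.385},
    "hfias_category": {1: 0.1922, 2: 0.3552, 3: 0.4379, 4: 0.0147},
    "dd_class": {"lowest": 0.157, "medium": 0.787, "high": 0.056},
}

#: Default outcome-model coefficients on the logit scale (named by
#: covariate level; references: age <6, female, home delivery, primary+
#: education, Guraghe, food secure, richest quintile, centered altitude).
DEFAULT_BETA: dict[str, float] = {
    "age_6_11": math.log(1.68), "age_12_23": math.log(4.10),
    "age_24_35": math.log(4.74), "age_36_47": math.log(3.96),
    "age_48_59": math.log(3.19),
    "male": math.log(1.28),
    "facility_delivery": math.log(0.81),
    "edu_read_write": math.log(1.02), "edu_none": math.log(1.21),
    "eth_siltie": math.log(1.14), "eth_mareko": math.log(1.28),
    "eth_other": math.log(0.97),
    "hfias_mild": math.log(1.08), "hfias_moderate": math.log(1.26),
    "hfias_severe": math.log(1.36),
    "wealth_rich": math.log(0.95), "wealth_middle": math.log(1.12),
    "wealth_poor": math.log(1.13), "wealth_poorest": math.log(1.18),
    "altitude_m": 0.0,
}


@dataclass
class StudyRegion:
    """Point locations of surveyed villages grouped into kebeles."""

    villages: pd.DataFrame  # village_id, kebele_id, lon, lat, altitude_m
    extent: dict            # lon_min/lon_max/lat_min/lat_max in degrees

    @property
    def kebele_ids(self) -> list:
        return sorted(self.villages["kebele_id"].unique().tolist())

    def distance_matrix(self) -> np.ndarray:
        return distance_matrix_km(self.villages["lon"], self.villages["lat"])


@dataclass
class SimulationTruth:
    """Ground-truth parameters of the simulated outcome model."""

    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma2_spatial: float = 0.96
    phi_per_km: float = 3.0 / 33.0   # practical range 33 km
    haz_sd: float = 1.6
    prevalence_target: float = 0.437
    seed: int = 0

    def __post_init__(self):
        if self.sigma2_spatial < 0:
            raise ValueError("sigma2_spatial must be >= 0")
        if self.phi_per_km <= 0:
            raise ValueError("phi_per_km must be > 0")
        if self.haz_sd <= 0:
            raise ValueError("haz_sd must be > 0")


def generate_study_region(
    n_kebeles: int = 40, n_villages: int = 45, extent_km: float = 30.0, seed: int = 0
) -> StudyRegion:
    """Scatter kebele centres in a square extent and place villages near them.

    Every kebele receives at least one village; surplus villages go to
    random kebeles.  Altitude follows a smooth west-east gradient plus
    noise, giving the agro-ecology strata something to stratify on.
    """
    if n_kebeles < 1 or n_villages < n_kebeles:
        raise ValueError("require n_villages >= n_kebeles >= 1")
    if extent_km <= 0:
        raise ValueError("extent_km must be positive")
    rng = np.random.default_rng(seed)
    deg_lat = extent_km / KM_PER_DEG_LAT
    deg_lon = extent_km / (KM_PER_DEG_LAT * math.cos(math.radians(ANCHOR_LAT)))
    lon0, lat0 = ANCHOR_LON - deg_lon / 2, ANCHOR_LAT - deg_lat / 2

    keb_lon = lon0 + rng.uniform(0.05, 0.95, n_kebeles) * deg_lon
    keb_lat = lat0 + rng.uniform(0.05, 0.95, n_kebeles) * deg_lat
    owners = np.concatenate(
        [np.arange(n_kebeles), rng.integers(0, n_kebeles, n_villages - n_kebeles)]
    )
    jit = 0.03  # villages sit within a few km of their kebele centre
    lon = keb_lon[owners] + rng.normal(0, jit * deg_lon, n_villages)
    lat = keb_lat[owners] + rng.normal(0, jit * deg_lat, n_villages)
    lon = np.clip(lon, lon0, lon0 + deg_lon)
    lat = np.clip(lat, lat0, lat0 + deg_lat)
    east = (lon - lon0) / deg_lon
    altitude = 1850.0 + 400.0 * east + rng.normal(0, 60.0, n_villages)

    villages = pd.DataFrame(
        {
            "village_id": [f"V{i:03d}" for i in range(1, n_villages + 1)],
            "kebele_id": [f"K{k + 1:03d}" for k in owners],
            "lon": lon,
            "lat": lat,
            "altitude_m": altitude,
        }
    )
    extent = {"lon_min": lon0, "lon_max": lon0 + deg_lon,
              "lat_min": lat0, "lat_max": lat0 + deg_lat}
    return StudyRegion(villages, extent)


def simulate_spatial_effects(
    region: StudyRegion, sigma2: float, phi: float, seed: int = 0
) -> np.ndarray:
    """One realization of a zero-mean GP with covariance sigma2*exp(-phi*d).

    Distances in km.  ``sigma2 == 0`` returns the exact zero vector.
    Duplicated village coordinates are displaced by ~1 m with a warning so
    the covariance stays positive definite; a 1e-9*sigma2 diagonal jitter
    guards the Cholesky factorization.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    n = len(region.villages)
    if sigma2 == 0:
        return np.zeros(n)
    lon = region.villages["lon"].to_numpy().copy()
    lat = region.villages["lat"].to_numpy().copy()
    D = distance_matrix_km(lon, lat)
    dup = np.argwhere(np.triu(D == 0, k=1))
    if len(dup):
        warnings.warn(f"{len(dup)} duplicated village coordinates; displacing by 1 m")
        rng_fix = np.random.default_rng(seed)
        for _, j in dup:
            lat[j] += (1.0 / 111_000.0) * rng_fix.choice([-1.0, 1.0])
        D = distance_matrix_km(lon, lat)
    cov = sigma2 * np.exp(-phi * D) + 1e-9 * sigma2 * np.eye(n)
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    return chol @ rng.standard_normal(n)


# ---------------------------------------------------------------------------
# HFIAS item templates
# ---------------------------------------------------------------------------

def _hfias_items_for_category(cat: int, rng: np.random.Generator):
    """Draw a 9-item (occurrence, frequency) pattern scoring exactly ``cat``.

    Category-4 patterns always affirm one of the last three scenarios, so
    the assignment is invariant to the severe-rule toggle.
    """
    occ = np.zeros(9, dtype=int)
    freq = np.zeros(9, dtype=int)

    def set_item(i, f):
        occ[i], freq[i] = 1, f

    if cat == 1:
        if rng.random() < 0.3:
            set_item(0, 1)                       # sporadic worry only
    elif cat == 2:
        choices = [(0, int(rng.integers(2, 4))), (1, int(rng.integers(1, 4))),
                   (2, 1), (3, 1)]
        for i, f in choices:
            if rng.random() < 0.5:
                set_item(i, f)
        if not occ.any():
            i, f = choices[int(rng.integers(len(choices)))]
            set_item(i, f)
    elif cat == 3:
        choices = [(2, int(rng.integers(2, 4))), (3, int(rng.integers(2, 4))),
                   (4, int(rng.integers(1, 3))), (5, int(rng.integers(1, 3)))]
        for i, f in choices:
            if rng.random() < 0.5:
                set_item(i, f)
        if indicators.hfias_category(occ, np.where(occ, freq, 1)) < 3:
            i, f = choices[int(rng.integers(len(choices)))]
            set_item(i, f)
        # background milder items
        if rng.random() < 0.7:
            set_item(0, int(rng.integers(1, 4)))
        if rng.random() < 0.5:
            set_item(1, int(rng.integers(1, 4)))
    elif cat == 4:
        set_item(int(rng.integers(6, 9)), int(rng.integers(1, 4)))
        for i in range(6):
            if rng.random() < 0.5:
                set_item(i, int(rng.integers(1, 4)))
    else:
        raise ValueError("HFIAS category must be 1..4")
    return occ, freq


_N_FOOD_GROUPS = 12
_DD_SCORE_RANGE = {"lowest": (1, 3), "medium": (4, 5), "high": (6, 9)}

# Asset model: P(own) = expit(a + b * latent wealth); anchored so richer
# households own more of everything (all b > 0).
_ASSETS = [
    ("asset_radio", -0.2, 1.2), ("asset_phone", 0.0, 1.4), ("asset_bed", 0.6, 1.0),
    ("asset_chairs", 0.3, 0.9), ("asset_tin_roof", -0.5, 1.5), ("asset_land", 0.8, 0.7),
    ("asset_latrine_improved", -1.0, 1.1), ("asset_safe_water", -0.4, 0.8),
]


def _validate_margins(margins: dict):
    for name, table in margins.items():
        total = float(sum(table.values()))
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"margins for {name!r} sum to {total}, not 1")
        if any(p < 0 for p in table.values()):
            raise ValueError(f"negative probability in margins for {name!r}")


def _draw_categorical(rng, table: dict, size: int):
    levels = list(table.keys())
    p = np.asarray([table[k] for k in levels], float)
    return np.array(levels, dtype=object)[rng.choice(len(levels), size=size, p=p / p.sum())]


def simulate_survey(
    region: StudyRegion,
    truth: SimulationTruth,
    n_children: int = 4000,
    covariate_margins: dict | None = None,
    census_fraction: float = 0.58,
    census_weight_ratio: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one child-level survey dataset under the study conditions.

    Children are allocated to villages proportional to simulated village
    sizes and grouped into households (household-level covariates are
    shared).  The stunting indicator is Bernoulli(logit^-1(eta)) with
    eta = intercept + X beta + S(village); the intercept is calibrated by
    root-finding so the mean simulated risk equals
    ``truth.prevalence_target``.  HAZ is drawn from a normal whose mean is
    tied to the individual risk (see docs/methods.md) by rejection sampling
    consistent with the drawn indicator.  Villages are flagged census or
    random-sample; census records get weight ``census_weight_ratio``
    relative to 1 for random-sample records.
    """
    if n_children < 1:
        raise ValueError("n_children must be >= 1")
    margins = covariate_margins if covariate_margins is not None else DEFAULT_MARGINS
    _validate_margins(margins)
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    vil = region.villages.reset_index(drop=True)
    n_vil = len(vil)
    size_w = rng.dirichlet(np.full(n_vil, 8.0))
    village_of = rng.choice(n_vil, size=n_children, p=size_w)

    # households: ~1.3 children each, household-level covariates shared
    hh_of = np.empty(n_children, dtype=object)
    hh_records = []
    for v in range(n_vil):
        kids = np.flatnonzero(village_of == v)
        n_hh = max(1, int(math.ceil(len(kids) / 1.3))) if len(kids) else 0
        if not n_hh:
            continue
        assign = rng.integers(0, n_hh, size=len(kids))
        for h in np.unique(assign):
            hh_id = f"{vil.loc[v, 'village_id']}_H{h + 1:03d}"
            hh_of[kids[assign == h]] = hh_id
            hh_records.append(hh_id)

    hh_ids = pd.Index(sorted(set(hh_records)))
    n_hh = len(hh_ids)

    # --- household-level covariates -------------------------------------
    hh = pd.DataFrame(index=hh_ids)
    hh["maternal_education"] = _draw_categorical(rng, margins["maternal_education"], n_hh)
    hh["ethnicity"] = _draw_categorical(rng, margins["ethnicity"], n_hh)
    hh["hfias_target"] = _draw_categorical(rng, margins["hfias_category"], n_hh).astype(int)
    hh["dd_class_target"] = _draw_categorical(rng, margins["dd_class"], n_hh)

    occ_mat = np.zeros((n_hh, 9), dtype=int)
    freq_mat = np.zeros((n_hh, 9), dtype=int)
    for i, cat in enumerate(hh["hfias_target"]):
        occ_mat[i], freq_mat[i] = _hfias_items_for_category(int(cat), rng)
    for q in range(9):
        hh[f"hfias_q{q + 1}"] = occ_mat[:, q]
        hh[f"hfias_f{q + 1}"] = np.where(occ_mat[:, q] == 1, freq_mat[:, q], np.nan)
    hh["hfias_category"] = indicators.hfias_category_frame(hh)

    fg = np.zeros((n_hh, _N_FOOD_GROUPS), dtype=int)
    staples = [0, 9, 11]  # cereals, oil/fat, coffee/tea eaten almost everywhere
    for i, cls in enumerate(hh["dd_class_target"]):
        lo, hi = _DD_SCORE_RANGE[cls]
        k = int(rng.integers(lo, hi + 1))
        base = [g for g in staples[: min(k, 3)]]
        extra = rng.choice([g for g in range(12) if g not in base], size=k - len(base),
                           replace=False)
        fg[i, base] = 1
        fg[i, list(extra)] = 1
    for g in range(_N_FOOD_GROUPS):
        hh[f"food_group_{g + 1}"] = fg[:, g]

    latent_wealth = rng.standard_normal(n_hh)
    for name, a, b in _ASSETS:
        hh[name] = (rng.random(n_hh) < expit(a + b * latent_wealth)).astype(int)
    hh["asset_animals"] = rng.poisson(np.exp(0.9 + 0.4 * latent_wealth))
    asset_cols = [name for name, _, _ in _ASSETS] + ["asset_animals"]
    wi = indicators.wealth_index(hh[asset_cols], positive_indicator="asset_radio")
    hh["wealth_quintile"] = wi.quintiles

    # --- child-level covariates -----------------------------------------
    rec = pd.DataFrame({
        "child_id": [f"C{i:05d}" for i in range(1, n_children + 1)],
        "household_id": hh_of,
        "village_id": vil.loc[village_of, "village_id"].to_numpy(),
        "kebele_id": vil.loc[village_of, "kebele_id"].to_numpy(),
        "lon": vil.loc[village_of, "lon"].to_numpy(),
        "lat": vil.loc[village_of, "lat"].to_numpy(),
        "altitude_m": vil.loc[village_of, "altitude_m"].to_numpy(),
    })
    rec["age_category"] = _draw_categorical(rng, margins["age_category"], n_children)
    lo = rec["age_category"].map(lambda c: _AGE_BOUNDS[c][0]).to_numpy()
    hi = rec["age_category"].map(lambda c: _AGE_BOUNDS[c][1]).to_numpy()
    rec["age_months"] = rng.integers(lo, hi + 1)
    rec["sex"] = _draw_categorical(rng, margins["sex"], n_children)
    rec["place_of_delivery"] = _draw_categorical(rng, margins["place_of_delivery"], n_children)
    rec["morbidity"] = _draw_categorical(rng, margins["morbidity"], n_children)
    for col in ["maternal_education", "ethnicity", "hfias_category", "wealth_quintile",
                "dd_class_target"] + [c for c in hh.columns if c.startswith(("hfias_q",
                "hfias_f", "food_group_", "asset_"))]:
        rec[col] = rec["household_id"].map(hh[col]).to_numpy()
    rec = rec.rename(columns={"dd_class_target": "dd_class"})
    rec["dd_score"] = rec[[f"food_group_{g}" for g in range(1, 13)]].sum(axis=1)

    # --- outcome model ---------------------------------------------------
    from .bayes import design_matrix  # local import avoids cycle at import time

    X, names = design_matrix(rec, include_morbidity=False)
    beta = np.array([truth.beta.get(nm, 0.0) for nm in names])
    s_eff = simulate_spatial_effects(
        region, truth.sigma2_spatial, truth.phi_per_km,
        seed=int(rng.integers(2 ** 31)),
    )
    eta0 = X @ beta + s_eff[village_of]
    intercept = brentq(lambda c: expit(eta0 + c).mean() - truth.prevalence_target, -20, 20)
    p = expit(eta0 + intercept)
    stunted = (rng.random(n_children) < p).astype(int)

    # --- HAZ consistent with the indicator -------------------------------
    from scipy.stats import norm
    mu = -2.0 - truth.haz_sd * norm.ppf(p)   # P(N(mu, sd) < -2) == p

    def inconsistent(h):
        # must match the drawn indicator and stay within the plausibility
        # screen (simulated children are validly measured)
        return ((h < -2.0) != stunted.astype(bool)) | (np.abs(h) > 6.0)

    haz = rng.normal(mu, truth.haz_sd)
    bad = inconsistent(haz)
    attempts = 0
    while bad.any() and attempts < 1000:
        haz[bad] = rng.normal(mu[bad], truth.haz_sd)
        bad = inconsistent(haz)
        attempts += 1
    if bad.any():  # force the sign for any stragglers
        haz[bad] = np.where(stunted[bad] == 1, -2.0 - np.abs(haz[bad] + 2.0) - 1e-6,
                            -2.0 + np.abs(haz[bad] + 2.0))
        haz = np.clip(haz, -5.999, 5.999)
    rec["haz"] = haz
    rec["stunted"] = stunted
    rec["severely_stunted"] = (haz < -3.0).astype(int)
    rec["stunting_class"] = indicators.classify_stunting(haz)

    # --- design variables -------------------------------------------------
    keb_alt = vil.groupby("kebele_id")["altitude_m"].mean()
    terciles = keb_alt.rank(pct=True)
    zone = pd.cut(terciles, [0, 1 / 3, 2 / 3, 1.0001],
                  labels=["lowland", "midland", "highland"]).astype(str)
    rec["stratum"] = rec["kebele_id"].map(zone).to_numpy()
    rec["psu"] = rec["village_id"]

    order = rng.permutation(n_vil)
    counts = np.bincount(village_of, minlength=n_vil)
    cum = np.cumsum(counts[order]) / n_children
    census_villages = set(vil.loc[order[cum <= census_fraction], "village_id"])
    rec["source"] = np.where(rec["village_id"].isin(census_villages), "census", "random")
    w = np.where(rec["source"] == "census", census_weight_ratio, 1.0)
    rec["weight"] = w / w.mean()
    return rec


def generate_dataset(
    seed: int = 0,
    n_kebeles: int = 40,
    n_villages: int = 45,
    extent_km: float = 30.0,
    n_children: int = 4000,
    truth: SimulationTruth | None = None,
    **survey_kwargs,
):
    """Convenience wrapper: region + truth + survey in one seeded call."""
    region = generate_study_region(n_kebeles, n_villages, extent_km, seed=seed)
    if truth is None:
        truth = SimulationTruth(seed=seed)
    records = simulate_survey(region, truth, n_children=n_children,
                              seed=seed + 1, **survey_kwargs)
    return region, truth, records


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_survey_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def region_to_geojson(region: StudyRegion, path=None):
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row.lon, row.lat]},
            "properties": {"village_id": row.village_id, "kebele_id": row.kebele_id,
                           "altitude_m": round(row.altitude_m, 1)},
        }
        for row in region.villages.itertuples()
    ]
    gj = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(gj, fh)
    return gj


def write_truth_json(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=2)
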