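"""End-to-end orchestration: validate -> score -> survey estimates ->
spatial statistics -> Bayesian models, with every artifact written to a run
directory alongside a manifest (input hash, seeds, versions, timings).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes, indicators, spatial, survey, synthetic

logger = logging.getLogger(__name__)

MCMC_PRESETS = {"full": bayes.FULL_MCMC, "fast": bayes.FAST_MCMC}


@dataclass
class PipelineConfig:
    """Inputs, output location and stage settings for one pipeline run."""

    input_csv: str | None = None       # None -> simulate with `seed`
    lms_csv: str | None = None         # optional LMS reference for re-deriving HAZ
    output_dir: str = "stuntgeo_run"
    seed: int = 0
    mcmc_preset: str = "fast"
    outcomes: tuple = ("stunted",)
    n_children: int = 4000             # simulation size when input_csv is None
    lisa_permutations: int = 999
    lisa_alpha: float = 0.05
    idw_power: float = 1.0
    single_psu: str = "error"
    hfias_severe_rule: str = "standard"
    stages: tuple = ("score", "survey", "spatial", "models")


@dataclass
class ValidationReport:
    n_input: int
    n_analyzable: int
    rule_counts: dict
    excluded_index: list = field(repr=False, default_factory=list)

    def summary(self) -> str:
        lines = [f"input records: {self.n_input}",
                 f"analyzable records: {self.n_analyzable}"]
        for rule, cnt in self.rule_counts.items():
            lines.append(f"  excluded ({rule}): {cnt}")
        return "\n".join(lines)


def validate_input(data) -> ValidationReport:
    """Screen a child-record table; nothing is dropped silently.

    Rules (a record is counted once in the headline total, under the first
    rule it violates, but every per-rule count is reported):
    missing age / sex, missing both height and HAZ, age outside 0-59
    months, implausible HAZ (|z| > 6), non-positive weight, and an
    explicit ``surveyed == 0`` flag where the column exists.
    """
    if isinstance(data, (str, Path)):
        try:
            df = pd.read_csv(data)
        except Exception as exc:  # surfaced with pandas' line diagnostics
            raise ValueError(f"malformed CSV {data}: {exc}") from exc
    else:
        df = data
    n = len(df)
    rules: dict[str, np.ndarray] = {}
    rules["missing_age"] = (df["age_months"].isna().to_numpy()
                            if "age_months" in df.columns else np.ones(n, bool))
    rules["missing_sex"] = (df["sex"].isna().to_numpy()
                            if "sex" in df.columns else np.ones(n, bool))
    has_haz = df["haz"].notna().to_numpy() if "haz" in df.columns else np.zeros(n, bool)
    has_height = (df["height_cm"].notna().to_numpy()
                  if "height_cm" in df.columns else np.zeros(n, bool))
    rules["missing_height_haz"] = ~(has_haz | has_height)
    age = df["age_months"] if "age_months" in df.columns else pd.Series(np.nan, index=df.index)
    rules["implausible_age"] = ((age < 0) | (age > 59)).fillna(False).to_numpy()
    if "haz" in df.columns:
        rules["implausible_haz"] = (df["haz"].abs() > indicators.HAZ_IMPLAUSIBLE
                                    ).fillna(False).to_numpy()
    else:
        rules["implausible_haz"] = np.zeros(n, bool)
    if "weight" in df.columns:
        rules["nonpositive_weight"] = (df["weight"] <= 0).fillna(False).to_numpy()
    else:
        rules["nonpositive_weight"] = np.zeros(n, bool)
    if "surveyed" in df.columns:
        rules["unsurveyed"] = (df["surveyed"] == 0).to_numpy()
    else:
        rules["unsurveyed"] = np.zeros(n, bool)

    any_bad = np.zeros(n, bool)
    for mask in rules.values():
        any_bad |= mask
    return ValidationReport(
        n_input=n,
        n_analyzable=int((~any_bad).sum()),
        rule_counts={k: int(v.sum()) for k, v in rules.items()},
        excluded_index=df.index[any_bad].tolist(),
    )


def village_prevalence(records: pd.DataFrame, outcome: str = "stunted") -> pd.DataFrame:
    """Weighted per-village prevalence (%) with village coordinates."""
    def agg(g):
        w = g["weight"]
        return pd.Series({
            "prevalence_pct": 100 * float((w * g[outcome]).sum() / w.sum()),
            "lon": float(g["lon"].iloc[0]),
            "lat": float(g["lat"].iloc[0]),
            "n": len(g),
        })
    return (records.groupby("village_id").apply(agg, include_groups=False)
            .reset_index())


def lisa_to_geojson(lisa: pd.DataFrame, vp: pd.DataFrame, path=None):
    merged = lisa.merge(vp, left_on="site_id", right_on="village_id")
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [r.lon, r.lat]},
            "properties": {"village_id": r.site_id, "local_i": r.local_i,
                           "p_sim": r.p_sim, "cluster": r.cluster,
                           "prevalence_pct": r.prevalence_pct},
        }
        for r in merged.itertuples()
    ]
    gj = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(gj))
    return gj


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages in order, writing artifacts + manifest.

    Returns a dict of in-memory results keyed by stage.  Input files are
    never mutated; partial outputs are retained if a stage fails.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "seed": config.seed,
                "versions": _versions(), "stages": {}, "artifacts": []}
    results: dict = {}
    t_all = time.time()

    def finish_stage(name, t0, *artifacts):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        manifest["artifacts"].extend(str(a) for a in artifacts)
        logger.info("stage %s done in %.2fs", name, time.time() - t0)

    # ---- load / simulate -------------------------------------------------
    t0 = time.time()
    try:
        if config.input_csv is None:
            region, truth, records = synthetic.generate_dataset(
                seed=config.seed, n_children=config.n_children)
            synthetic.write_truth_json(truth, out / "truth.json")
            synthetic.region_to_geojson(region, out / "region.geojson")
            manifest["input"] = {"simulated": True, "n_children": config.n_children}
        else:
            records = pd.read_csv(config.input_csv)
            manifest["input"] = {"path": str(config.input_csv),
                                 "sha256": _sha256(config.input_csv)}
        report = validate_input(records)
        results["validation"] = report
        (out / "validation.json").write_text(json.dumps(
            {"n_input": report.n_input, "n_analyzable": report.n_analyzable,
             "rule_counts": report.rule_counts}, indent=2))
        records = records.drop(index=report.excluded_index).reset_index(drop=True)
    except Exception as exc:
        raise StageError("load", exc) from exc
    finish_stage("load", t0, out / "validation.json")

    # ---- score -----------------------------------------------------------
    if "score" in config.stages:
        t0 = time.time()
        try:
            lms = (indicators.load_lms_reference(config.lms_csv)
                   if config.lms_csv else None)
            records = indicators.score_records(records, lms,
                                               severe_rule=config.hfias_severe_rule)
            records.to_csv(out / "scored.csv", index=False)
        except Exception as exc:
            raise StageError("score", exc) from exc
        finish_stage("score", t0, out / "scored.csv")
    results["records"] = records

    # ---- survey estimation ----------------------------------------------
    if "survey" in config.stages:
        t0 = time.time()
        try:
            design = survey.SurveyDesign.from_frame(records)
            prev = survey.weighted_prevalence(records["stunted"], design,
                                              single_psu=config.single_psu)
            prev_sev = survey.weighted_prevalence(records["severely_stunted"], design,
                                                  single_psu=config.single_psu)
            results["prevalence"] = {"stunted": prev, "severe": prev_sev}
            table1 = survey.table1_report(records, design, single_psu=config.single_psu)
            table1.to_csv(out / "table1.csv", index=False)
            (out / "table1.md").write_text(survey.report_to_markdown(table1))
            results["table1"] = table1
        except Exception as exc:
            raise StageError("survey", exc) from exc
        finish_stage("survey", t0, out / "table1.csv", out / "table1.md")

    # ---- spatial statistics ----------------------------------------------
    if "spatial" in config.stages:
        t0 = time.time()
        try:
            vp = village_prevalence(records)
            results["village_prevalence"] = vp
            norm = spatial.normality_check(vp["prevalence_pct"])
            results["normality"] = norm
            est = spatial.empirical_semivariogram(
                vp["prevalence_pct"], vp["lon"], vp["lat"])
            try:
                fit = spatial.fit_exponential_variogram(est)
            except spatial.VariogramFitError as exc:
                logger.warning("%s; keeping best iterate", exc)
                fit = exc.best
            results["variogram"] = (est, fit)
            pd.DataFrame({"lag_km": est.bin_centers, "gamma": est.gamma,
                          "pairs": est.pair_counts}).to_csv(
                out / "variogram.csv", index=False)
            (out / "variogram_fit.json").write_text(json.dumps(
                {"nugget": fit.nugget, "partial_sill": fit.partial_sill,
                 "sill": fit.sill, "range_km": fit.range_km,
                 "shapiro_w": norm.statistic, "shapiro_p": norm.p_value}, indent=2))

            W = spatial.inverse_distance_weights(
                vp["lon"], vp["lat"], site_ids=vp["village_id"].tolist(),
                power=config.idw_power)
            lisa = spatial.local_morans_i(
                vp["prevalence_pct"], W, n_permutations=config.lisa_permutations,
                seed=config.seed, alpha=config.lisa_alpha)
            results["lisa"] = lisa
            lisa.to_csv(out / "lisa.csv", index=False)
            lisa_to_geojson(lisa, vp, out / "lisa.geojson")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("spatial", exc) from exc
        finish_stage("spatial", t0, out / "variogram.csv", out / "variogram_fit.json",
                     out / "lisa.csv", out / "lisa.geojson")

    # ---- Bayesian models --------------------------------------------------
    if "models" in config.stages:
        t0 = time.time()
        try:
            results["models"] = {}
            X, names = bayes.design_matrix(records)
            vif = bayes.compute_vif(X, names)
            vif.to_csv(out / "vif.csv")
            results["vif"] = vif
            vil_ids = pd.Index(sorted(records["village_id"].unique()))
            vidx = vil_ids.get_indexer(records["village_id"])
            coords = records.groupby("village_id")[["lon", "lat"]].first().loc[vil_ids]
            D = spatial.distance_matrix_km(coords["lon"], coords["lat"])
            mcmc = bayes.MCMCConfig(seed=config.seed, **MCMC_PRESETS[config.mcmc_preset])
            dic_cmp = {}
            for outcome in config.outcomes:
                y = records[outcome].to_numpy(float)
                for spatial_flag in (False, True):
                    model = bayes.GeoLogisticModel(
                        y=y, X=X, names=names, spatial=spatial_flag,
                        village_index=vidx if spatial_flag else None,
                        distances_km=D if spatial_flag else None)
                    draws = bayes.run_mcmc(model, mcmc)
                    summ = bayes.summarize_posterior(draws)
                    dic = bayes.compute_dic(draws, model)
                    tag = f"{outcome}_{'spatial' if spatial_flag else 'nonspatial'}"
                    summ.to_csv(out / f"posterior_{tag}.csv")
                    bayes.export_traces(draws, out / f"traces_{tag}.csv")
                    results["models"][tag] = {"summary": summ, "dic": dic,
                                              "draws": draws}
                    dic_cmp[tag] = dic.dic
                (out / f"summary_{outcome}.json").write_text(
                    _summary_json(results["models"], outcome))
            (out / "dic_comparison.json").write_text(json.dumps(dic_cmp, indent=2))
            results["dic_comparison"] = dic_cmp
        except StageError:
            raise
        except Exception as exc:
            raise StageError("models", exc) from exc
        finish_stage("models", t0, out / "dic_comparison.json")

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results


def _summary_json(models: dict, outcome: str) -> str:
    payload = {}
    for kind in ("nonspatial", "spatial"):
        tag = f"{outcome}_{kind}"
        if tag not in models:
            continue
        summ: pd.DataFrame = models[tag]["summary"]
        payload[kind] = {
            "dic": models[tag]["dic"].dic,
            "p_d": models[tag]["dic"].p_d,
            "parameters": json.loads(summ.round(4).to_json(orient="index")),
        }
    return json.dumps(payload, indent=2)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _versions() -> dict:
    import scipy
    import statsmodels
    from . import __version__
    return {"stuntgeo": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__}
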