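"""End-to-end pipeline orchestration and descriptive outputs.

`run_pipeline` chains simulate (or ingest) -> inclusion/exclusion -> PIRA
detection -> comorbidity featurization -> association analyses ->
(optionally) the prediction benchmark, writes every stage table as CSV,
and records a manifest with SHA-256 digests so a rerun with the same seed
is verifiably identical.

Sensitivity switches mirror the analysis options: restriction to patients
aged >= 50 at therapy start, and restriction of pre-specified comorbidity
flags to >= 3 years of exposure before the index date.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, comorb, predict as predict_mod
from ._time import FOLLOWUP_DAYS
from .pira import PIRAParams, clean_scores, detect_cohort
from .synth import CohortBundle, GeneratorConfig, apply_inclusion_exclusion, baseline_table, generate_cohort

__all__ = ["PipelineConfig", "RunManifest", "edss_trend_by_pira", "assemble_features", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Structured pipeline configuration.

    mode "simulate" generates a synthetic cohort from `generator`; mode
    "ingest" reads the five tables from `in_dir`. The demo profile (the
    default) keeps the prediction stage small: elastic net only, 2 outer
    repeats, 2-level grids.
    """

    mode: str = "simulate"
    seed: int = 0
    out_dir: str = "mspira_run"
    in_dir: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    age_min: float | None = None  # e.g. 50 for the older-subgroup analysis
    min_exposure_years: float | None = None  # e.g. 3 for the exposure-time analysis
    run_predict: bool = False
    demo: bool = True
    predict_models: tuple[str, ...] = ("elastic_net",)
    predict_sets: tuple[str, ...] = ("demographics", "ms_characteristics")
    run_adjusted: bool = False  # MICE-adjusted ORs are the slowest stage

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        gen = GeneratorConfig(**raw.pop("generator", {}))
        for key in ("predict_models", "predict_sets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=gen, **raw)


@dataclass
class RunManifest:
    seed: int
    config: dict
    stage_versions: dict
    digests: dict
    started: str = ""
    finished: str = ""
    complete: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def edss_trend_by_pira(
    edss: pd.DataFrame,
    relapses: pd.DataFrame,
    pira_results: pd.DataFrame,
    bin_width: float = 182.0,
    params: PIRAParams | None = None,
) -> pd.DataFrame:
    """Mean EDSS change from baseline per time bin, stratified by PIRA.

    Relapse-proximal scores are excluded; the per-patient reference is the
    baseline score (closest to therapy start). Bins without observations
    report n=0 and a missing mean.
    """
    from .pira import select_baseline_score

    params = params or PIRAParams()
    status = pira_results.set_index("patient_id")["pira"]
    rel_by = {p: g["t"].to_numpy(float) for p, g in relapses.groupby("patient_id")}
    recs = []
    for p, g in edss.groupby("patient_id"):
        if p not in status.index:
            continue
        t, e = clean_scores(
            g["t"].to_numpy(float), g["edss"].to_numpy(float),
            rel_by.get(p, np.empty(0)), params.relapse_exclusion_window,
        )
        b = select_baseline_score(t, e, params)
        if b is None:
            continue
        post = t > b.t
        for ti, ei in zip(t[post], e[post]):
            recs.append((bool(status[p]), int(ti // bin_width), ei - b.edss))
    df = pd.DataFrame(recs, columns=["pira", "bin", "change"])
    groups = sorted(df["pira"].unique()) if len(df) else []
    rows = []
    max_bin = int(FOLLOWUP_DAYS // bin_width)
    for grp in groups:
        sub = df[df["pira"] == grp]
        for b_i in range(max_bin + 1):
            vals = sub.loc[sub["bin"] == b_i, "change"]
            rows.append(
                {
                    "pira": grp,
                    "bin_start_d": b_i * bin_width,
                    "mean_edss_change": float(vals.mean()) if len(vals) else np.nan,
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def assemble_features(
    bundle: CohortBundle,
    pira_results: pd.DataFrame,
    matrix: comorb.ComorbidityMatrix,
    params: PIRAParams | None = None,
) -> pd.DataFrame:
    """Patient-level analysis table: demographics, MS characteristics
    (including detector-derived baseline EDSS), comorbidity flags, kept ICD
    categories, and the PIRA outcome."""
    pat = bundle.patients.copy()
    pat["therapy_start_year"] = pd.to_datetime(pat["therapy_start"]).dt.year
    base = baseline_table(bundle, params)[["patient_id", "baseline_edss"]]
    out = pat.merge(base, on="patient_id", how="left")
    out = out.merge(
        matrix.prespecified.reset_index().rename(columns={"index": "patient_id"}),
        on="patient_id", how="left",
    )
    icd = matrix.icd_categories[matrix.kept_categories].add_prefix("icd_")
    out = out.merge(icd.reset_index().rename(columns={"index": "patient_id"}), on="patient_id", how="left")
    out = out.merge(pira_results[["patient_id", "pira"]], on="patient_id", how="inner")
    return out.drop(columns=["therapy_start", "married"])


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline; see `PipelineConfig` for the switches."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=config.seed,
        config=dataclasses.asdict(config),
        stage_versions={"mspira": __import__("mspira").__version__},
        digests={},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    params = PIRAParams()

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # pragma: no cover - error plumbing
                (out / "manifest.json").write_text(manifest.to_json())
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    # simulate / ingest
    if config.mode == "simulate":
        gen = dataclasses.replace(config.generator, seed=config.seed)
        bundle = stage("simulate")(lambda: generate_cohort(gen))
    elif config.mode == "ingest":
        if not config.in_dir:
            raise ValueError("ingest mode requires in_dir")
        bundle = stage("ingest")(lambda: CohortBundle.read_csv(config.in_dir))
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    bundle.write_csv(out / "cohort")

    if config.age_min is not None:
        keep = bundle.patients.loc[bundle.patients["age_at_start"] >= config.age_min, "patient_id"]
        bundle = bundle.subset(keep)

    # exclusions + detection
    retained, attrition = stage("exclusions")(lambda: apply_inclusion_exclusion(bundle, params))
    attrition.to_csv(out / "attrition.csv", index=False)
    pids = list(retained.patients["patient_id"])
    pira_results = stage("detect")(
        lambda: detect_cohort(retained.edss, retained.relapses, pids, params)
    )
    pira_results.to_csv(out / "pira_results.csv", index=False)

    # featurization
    defs = comorb.DEFAULT_DEFINITIONS
    matrix = stage("featurize")(
        lambda: comorb.build_matrix(retained.diagnoses, retained.dispensations, pids, defs)
    )
    if config.min_exposure_years is not None:
        matrix.prespecified = comorb.restrict_min_exposure(
            retained.diagnoses, retained.dispensations, pids, defs,
            min_years=config.min_exposure_years,
        )
    features = assemble_features(retained, pira_results, matrix, params)
    features.to_csv(out / "features.csv", index=False)

    # associations
    y = features["pira"].to_numpy(dtype=int)
    forest_rows = []
    for name in matrix.prespecified.columns:
        x = features[name].to_numpy(dtype=float)
        try:
            res = assoc.fit_logistic_or(y, x, None, name)
        except ValueError:  # constant exposure (no carriers) in small cohorts
            res = assoc.AssociationResult(name, np.nan, np.nan, np.nan, np.nan, "crude", False)
        forest_rows.append(
            {
                "exposure": name, "analysis": "crude", "or": res.estimate,
                "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
                "converged": res.converged,
            }
        )
    if config.run_adjusted:
        adj_design_cols = [
            "age_at_start", "sex", "born_in_country", "income", "education", "area",
            "therapy_start_year", "years_since_onset", "n_prior_dmts",
            "n_prior_relapses", "baseline_edss", "sdmt", "msis_physical",
            "msis_psychological",
        ] + list(matrix.prespecified.columns)
        design = features[adj_design_cols].copy()
        design["sex"] = (design["sex"] == "female").astype(float)
        design["born_in_country"] = design["born_in_country"].astype(float)
        for name in matrix.prespecified.columns:
            res = assoc.adjusted_pooled_or(
                y, name, design,
                impute_cols=("sdmt", "msis_physical", "msis_psychological"),
                categorical=("education", "area"),
                seed=config.seed,
            )
            forest_rows.append(
                {
                    "exposure": name, "analysis": "adjusted_pooled", "or": res.estimate,
                    "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
                    "converged": res.converged,
                }
            )
    pd.DataFrame(forest_rows).to_csv(out / "forest_table.csv", index=False)

    manhattan = stage("associate")(
        lambda: assoc.manhattan_table(matrix.icd_categories, y.astype(bool))
    )
    n_kept = int(manhattan["kept"].sum())
    manhattan["bonferroni_threshold"] = (
        assoc.bonferroni_threshold(0.05, n_kept) if n_kept else np.nan
    )
    manhattan.to_csv(out / "manhattan_table.csv", index=False)

    # descriptive trend
    trend = edss_trend_by_pira(retained.edss, retained.relapses, pira_results, params=params)
    trend.to_csv(out / "edss_trend.csv", index=False)

    # prediction benchmark
    if config.run_predict:
        icd_cols = tuple(c for c in features.columns if c.startswith("icd_"))
        sets = {s.name: s for s in predict_mod.make_predictor_sets(features, icd_cols)}
        rows = []
        for fam in config.predict_models:
            spec = predict_mod.MODEL_SPECS[fam]
            if config.demo:
                spec = predict_mod.ModelSpec(
                    spec.family, spec.fixed,
                    {k: (v[0], v[-1]) for k, v in spec.grid.items()},
                )
                outer = (10, 2)
            else:
                outer = (10, 3)
            for set_name in config.predict_sets:
                ev = stage("predict")(
                    lambda s=spec, ps=sets[set_name], o=outer: predict_mod.nested_cv_evaluate(
                        features, y, s, ps, outer=o, seed=config.seed
                    )
                )
                rows.append(
                    {
                        "model": ev.model, "predictor_set": ev.predictor_set,
                        "auc": ev.auc_mean, "auc_se": ev.auc_se,
                        "brier": ev.brier_mean, "brier_se": ev.brier_se,
                    }
                )
                ev.calibration.to_csv(
                    out / f"calibration_{ev.model}_{ev.predictor_set}.csv", index=False
                )
        pd.DataFrame(rows).to_csv(out / "prediction_grid.csv", index=False)

    for p in sorted(out.rglob("*.csv")):
        manifest.digests[str(p.relative_to(out))] = _digest(p)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.complete = True
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
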