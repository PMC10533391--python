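"""End-to-end orchestration: one config, deterministic artifacts.

A run executes the enabled stages in fixed order —

    simulate -> prepare -> diversity -> fit -> cv -> sensitivity -> report

— writing every artifact as delimited text (fixed float formatting) or JSON
under ``<output_dir>/run-<config-hash>/``, so an identical config produces
byte-identical delimited outputs.  Counts reconcile at every stage: rows
into a stage equal rows retained plus rows in the drop log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import diversity as div
from . import inference as inf
from . import spatial as sp
from . import synthetic as syn
from .errors import InvadivError, InvalidArgumentError, MissingArtifactError
from .rng import child_seed
from .trees import TreeIndex

__all__ = ["RunConfig", "RunSummary", "run_pipeline", "report", "load_config"]

log = logging.getLogger("invadiv")

STAGES = ("simulate", "prepare", "diversity", "fit", "cv", "sensitivity", "report")

_FMT = "%.12g"


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    synthetic: dict = field(default_factory=dict)   # SyntheticConfig overrides
    paths: dict = field(default_factory=dict)       # external inputs (non-synthetic)
    buffer_km: float = 250.0
    downsample: dict = field(default_factory=dict)  # {target_n, biome_areas?, preserve_biomes?}
    cv: dict = field(default_factory=lambda: {"n_repeats": 100})
    rf: dict = field(default_factory=lambda: {"enabled": False})
    sensitivity: dict = field(default_factory=lambda: {
        "n_plots": 800, "c": -0.05, "noise_sd": 0.05})
    min_species: int = 3

    def validate(self) -> None:
        problems = []
        if self.buffer_km <= 0:
            problems.append("buffer_km must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            problems.append(f"unknown stages: {sorted(unknown)}")
        if not self.synthetic and self.paths:
            for key in ("inventory", "tree", "traits", "status_a", "status_b",
                        "covariates"):
                p = self.paths.get(key)
                if not p:
                    problems.append(f"paths.{key} is required in non-synthetic mode")
                elif not Path(p).exists():
                    problems.append(f"paths.{key} does not exist: {p}")
        if problems:
            raise InvalidArgumentError(
                "invalid run config: " + "; ".join(problems)
            )

    def hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    full_stages = {s: True for s in STAGES}
    full_stages.update(cfg.stages or {})
    cfg.stages = full_stages
    return cfg


@dataclass
class RunSummary:
    run_dir: str
    config_hash: str
    counts: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    wall_time_s: dict = field(default_factory=dict)

    def write(self, run_dir: Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "counts": self.counts,
            "metrics": self.metrics,
            "wall_time_s": self.wall_time_s,
        }
        (run_dir / "run_summary.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n"
        )


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the enabled stages; any stage failure aborts with its tag."""
    config.validate()
    run_dir = Path(config.output_dir) / f"run-{config.hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(run_dir=str(run_dir), config_hash=config.hash())
    state: dict = {}
    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        t0 = time.perf_counter()
        log.info("stage %s: start", stage)
        try:
            _STAGE_FNS[stage](config, run_dir, state, summary)
        except InvadivError as exc:
            raise InvadivError(f"[stage {stage}] {exc}") from exc
        summary.wall_time_s[stage] = round(time.perf_counter() - t0, 3)
    summary.write(run_dir)
    return summary


def _stage_simulate(config, run_dir, state, summary):
    if not config.synthetic and config.paths:
        return  # external inputs, nothing to simulate
    scfg = syn.SyntheticConfig(seed=config.seed, **config.synthetic)
    dataset = syn.generate_dataset(scfg)
    data_dir = run_dir / "data"
    syn.write_dataset(dataset, data_dir)
    state["data_dir"] = data_dir
    state["truth"] = dataset.ground_truth
    summary.counts["simulate"] = {
        "n_plots": len(dataset.communities),
        "n_stems": len(dataset.inventory),
        "n_species": dataset.tree.n_tips,
    }


def _paths(config, state) -> dict:
    if config.paths:
        return {k: Path(v) for k, v in config.paths.items()}
    data_dir = state.get("data_dir")
    if data_dir is None:
        raise MissingArtifactError("no input paths and the simulate stage did not run")
    return {
        "inventory": data_dir / "inventory.tsv",
        "tree": data_dir / "phylogeny.nwk",
        "traits": data_dir / "traits.tsv",
        "status_a": data_dir / "status_glonaf_like.tsv",
        "status_b": data_dir / "status_kew_like.tsv",
        "covariates": data_dir / "covariates.tsv",
    }


def _stage_prepare(config, run_dir, state, summary):
    paths = _paths(config, state)
    records = comm.load_inventory(paths["inventory"])
    n_raw = len(records)
    records = comm.select_latest_census(records)
    n_latest = len(records)
    records = comm.filter_trees(records)
    n_sized = len(records)

    covariates = pd.read_csv(paths["covariates"], sep="\t")
    status_a = pd.read_csv(paths["status_a"], sep="\t")
    status_b = pd.read_csv(paths["status_b"], sep="\t")
    pairs = records.merge(
        covariates[["plot_id", "region_id"]], on="plot_id"
    )[["plot_id", "species", "region_id"]].drop_duplicates()
    statuses, drop_plots = comm.assign_native_status(pairs, status_a, status_b)
    communities, metrics, drop_log = comm.build_plot_communities(
        records, statuses, covariates, drop_plots=drop_plots,
        min_species=config.min_species,
    )

    if config.downsample.get("target_n"):
        areas = config.downsample.get("biome_areas")
        if not areas:
            areas = {
                b: 1.0 for b in sorted({c.biome for c in communities})
            }
        table = metrics.merge(
            pd.DataFrame(
                {"plot_id": [c.plot_id for c in communities],
                 "biome": [c.biome for c in communities]}
            ),
            on="plot_id",
        )
        kept = comm.downsample_by_biome(
            table, areas, int(config.downsample["target_n"]),
            seed=child_seed(config.seed, "downsample"),
            preserve_biomes=tuple(config.downsample.get("preserve_biomes", ())),
        )
        keep_ids = set(kept["plot_id"])
        removed = sorted(set(metrics["plot_id"]) - keep_ids)
        drop_log = pd.concat(
            [drop_log, pd.DataFrame(
                {"plot_id": removed, "reason": "downsampled"})],
            ignore_index=True,
        )
        communities = [c for c in communities if c.plot_id in keep_ids]
        metrics = metrics[metrics["plot_id"].isin(keep_ids)].reset_index(drop=True)

    state["communities"] = communities
    state["metrics"] = metrics
    state["paths"] = paths
    _tsv(metrics, run_dir / "plot_metrics.tsv")
    _tsv(drop_log, run_dir / "drop_log.tsv")
    summary.counts["prepare"] = {
        "stems_in": n_raw,
        "stems_latest_census": n_latest,
        "stems_after_size_filter": n_sized,
        "plots_retained": len(communities),
        "plots_dropped": int(drop_log["plot_id"].nunique()),
    }


def _stage_diversity(config, run_dir, state, summary):
    paths = state["paths"]
    communities = state["communities"]
    tree = TreeIndex.from_newick(paths["tree"])
    traits_raw = pd.read_csv(paths["traits"], sep="\t").set_index("species")
    traits = div.transform_traits(traits_raw)

    all_species = sorted({s for c in communities for s in c.species})
    tree, placement = div.place_genus_level_taxa(tree, all_species)
    dendrogram = div.build_functional_dendrogram(traits, traits.index)

    plots = [
        (c.plot_id, c.native_species, c.all_species) for c in communities
    ]
    table, excluded = div.diversity_table(plots, tree, dendrogram)
    _tsv(table, run_dir / "diversity.tsv")
    _tsv(placement.as_frame(), run_dir / "placement_report.tsv")

    cov_cols = ["mat", "map", "dist_ports_km", "pop_density",
                "soil_depth", "soil_coarse", "soil_sand", "soil_ph"]
    rows = []
    for c in communities:
        if c.plot_id in excluded:
            continue
        row = {"plot_id": c.plot_id, "lat": c.lat, "lon": c.lon,
               "biome": c.biome,
               "native_richness": len(c.native_species)}
        row.update({k: c.covariates.get(k, np.nan) for k in cov_cols})
        rows.append(row)
    analysis = (
        pd.DataFrame(rows)
        .merge(state["metrics"], on="plot_id")
        .merge(table, on="plot_id")
    )
    state["analysis"] = analysis
    _tsv(analysis, run_dir / "analysis_table.tsv")
    summary.counts["diversity"] = {
        "plots_in": len(communities),
        "plots_computed": len(table),
        "plots_excluded": len(excluded),
        "placed_species_level": placement.species_level,
        "placed_genus_level": placement.genus_level,
        "unplaced": placement.unplaced,
    }


_BASE_PREDICTORS = [
    "native_pd", "native_redundancy", "mat", "map",
    "dist_ports_km", "pop_density", "soil_depth", "soil_coarse",
    "soil_sand", "soil_ph",
]


def _screened(analysis: pd.DataFrame) -> list:
    cols = [c for c in _BASE_PREDICTORS if c in analysis.columns]
    retained, _ = inf.collinearity_screen(
        analysis[cols], always_keep=inf.ALWAYS_KEEP + ("native_pd",
                                                       "native_redundancy"),
    )
    return retained


def _stage_fit(config, run_dir, state, summary):
    analysis = state["analysis"]
    predictors = _screened(analysis)
    index = sp.SpatialIndex(analysis["lat"].to_numpy(), analysis["lon"].to_numpy())
    fits = []

    presence_spec = inf.ModelSpec(
        response="presence_int", family="binomial-logit", predictors=predictors
    )
    analysis = analysis.assign(presence_int=analysis["presence"].astype(int))
    state["analysis"] = analysis
    presence_fit = inf.fit_presence_model(
        analysis, presence_spec, index, buffer_km=config.buffer_km
    )
    fits.append(presence_fit)

    invaded = analysis[analysis["presence"].astype(bool)].reset_index(drop=True)
    state["invaded"] = invaded
    if len(invaded) >= 30:
        inv_index = sp.SpatialIndex(
            invaded["lat"].to_numpy(), invaded["lon"].to_numpy()
        )
        rich_spec = inf.ModelSpec(
            response="nn_species", family="binomial-counts",
            predictors=predictors, trials="total_species",
        )
        abund_spec = inf.ModelSpec(
            response="rel_abundance", family="beta-logit", predictors=predictors
        )
        fit_r0, fit_a0 = inf.fit_severity_models(invaded, rich_spec, abund_spec)
        # response-scale residuals feed the RAC stage
        p_hat_r = _fitted_binomial(invaded, rich_spec, fit_r0)
        rac_r = sp.residual_autocovariate(
            invaded["rel_richness"].to_numpy() - p_hat_r, inv_index,
            radius_km=config.buffer_km,
        )
        mu_a = _fitted_linear(invaded, abund_spec, fit_a0, link="logit")
        rac_a = sp.residual_autocovariate(
            invaded["rel_abundance"].to_numpy() - mu_a, inv_index,
            radius_km=config.buffer_km,
        )
        fit_r, _ = inf.fit_severity_models(invaded, rich_spec, abund_spec, rac=rac_r)
        _, fit_a = inf.fit_severity_models(invaded, rich_spec, abund_spec, rac=rac_a)
        fits += [fit_r, fit_a]

        strat_predictors = [p for p in predictors if p != "native_redundancy"]
        strategy_spec = inf.ModelSpec(
            response="strategy_phylo", family="gaussian",
            predictors=strat_predictors, quadratic=["mat"],
            interactions=[("mat", "map"), ("mat", "dist_ports_km"),
                          ("map", "dist_ports_km")],
        )
        strat0 = inf.fit_strategy_model(invaded, strategy_spec)
        mu_s = _fitted_linear(invaded, strategy_spec, strat0, link="identity",
                              interactions=strat0.extras["final_interactions"])
        rac_s = sp.residual_autocovariate(
            invaded["strategy_phylo"].to_numpy() - mu_s, inv_index,
            radius_km=config.buffer_km,
        )
        strat_fit = inf.fit_strategy_model(invaded, strategy_spec, rac=rac_s)
        fits.append(strat_fit)
        summary.metrics["strategy_elimination"] = strat_fit.extras["elimination"]

    state["fits"] = fits
    state["index"] = index
    state["predictors"] = predictors
    coef = inf.summarize_fits(fits)
    _tsv(coef, run_dir / "coefficients.tsv")
    summary.counts["fit"] = {
        "n_models": len(fits),
        "n_plots": len(analysis),
        "n_invaded": len(invaded),
    }
    summary.metrics["presence_morans_i"] = {
        "stage1": presence_fit.extras["morans_i_stage1"]["i"],
        "stage2": presence_fit.extras["morans_i_stage2"]["i"],
    }

    if config.rf.get("enabled"):
        rf_cfg = config.rf
        imp = inf.rf_shap_importance(
            analysis, "presence_int", predictors,
            seed=child_seed(config.seed, "rf-presence"),
            n_estimators=int(rf_cfg.get("n_estimators", 500)),
            n_simulations=int(rf_cfg.get("n_simulations", 100)),
            shap_rows=rf_cfg.get("shap_rows"),
        )
        _tsv(imp.importance, run_dir / "importance_presence.tsv")
        _tsv(imp.marginal, run_dir / "marginal_presence.tsv")
        summary.metrics["rf_presence_additivity_gap"] = imp.additivity_gap


def _fitted_binomial(data, spec, fit) -> np.ndarray:
    X = inf.design_matrix(data, spec)
    from scipy.special import expit
    return expit(X.to_numpy() @ fit.params.reindex(X.columns).to_numpy())


def _fitted_linear(data, spec, fit, link="identity", interactions=None):
    spec2 = inf.ModelSpec(
        response=spec.response, family=spec.family,
        predictors=spec.predictors,
        interactions=[tuple(t.split(":")) for t in interactions]
        if interactions is not None else spec.interactions,
        quadratic=spec.quadratic, standardize=spec.standardize,
    )
    X = inf.design_matrix(data, spec2)
    eta = X.to_numpy() @ fit.params.reindex(X.columns).to_numpy()
    if link == "logit":
        from scipy.special import expit
        return expit(eta)
    return eta


def _stage_cv(config, run_dir, state, summary):
    analysis = state["analysis"]
    index = state["index"]
    predictors = state["predictors"]
    n_repeats = min(int(config.cv.get("n_repeats", 100)), len(analysis))
    spec = inf.ModelSpec(response="presence_int", family="binomial-logit",
                         predictors=predictors)

    def factory(train, test):
        import statsmodels.api as sm
        Xtr = inf.design_matrix(train, spec)
        res = sm.GLM(
            train["presence_int"].astype(float), Xtr,
            family=sm.families.Binomial(),
        ).fit()
        # standardize the test row with the training moments
        row = {}
        for col in spec.predictors:
            v = train[col].astype(float)
            row[col] = (float(test[col].iloc[0]) - v.mean()) / v.std()
        x = np.array([1.0] + [row[c] for c in spec.predictors])
        from scipy.special import expit
        return expit(x @ res.params.to_numpy())

    result = sp.buffered_loocv(
        factory, analysis, index, response="presence_int",
        buffer_km=config.buffer_km, n_repeats=n_repeats,
        seed=child_seed(config.seed, "cv-presence"), binary=True,
    )
    _tsv(result.predictions, run_dir / "cv_presence.tsv")
    summary.metrics["cv_presence_auc"] = result.metric
    summary.counts["cv"] = {
        "n_repeats": n_repeats,
        "n_skipped": len(result.skipped),
    }


def _stage_sensitivity(config, run_dir, state, summary):
    invaded = state.get("invaded")
    analysis = state["analysis"]
    scfg = config.sensitivity
    two_census = syn.simulate_richness_change(
        n_plots=int(scfg.get("n_plots", 800)),
        c=float(scfg.get("c", -0.05)),
        noise_sd=float(scfg.get("noise_sd", 0.05)),
        seed=child_seed(config.seed, "two-census"),
    )
    severity_data = analysis[analysis["presence"].astype(bool)].reset_index(drop=True)
    if severity_data.empty:
        raise MissingArtifactError("no invaded plots for the sensitivity stage")
    spec = inf.ModelSpec(
        response="nn_species", family="binomial-counts",
        predictors=["native_richness", "mat", "map", "dist_ports_km",
                    "pop_density"],
        trials="total_species",
    )
    result = inf.sensitivity_preinvasion(
        two_census, severity_data, spec,
        richness_col="native_richness",
        change_covariates=("mat", "map"),
    )
    payload = {
        "c": result.c, "c_lo": result.c_lo, "c_hi": result.c_hi,
        "beta_original": result.beta_original,
        "beta_updated": result.beta_updated,
        "relative_change": result.relative_change,
    }
    (run_dir / "sensitivity.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    summary.metrics["sensitivity_relative_change"] = result.relative_change["c"]
    summary.counts["sensitivity"] = {
        "two_census_plots": len(two_census),
        "severity_plots": len(severity_data),
    }


def _stage_report(config, run_dir, state, summary):
    summary.write(run_dir)  # the report sources CV metrics from the summary
    report(run_dir)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "prepare": _stage_prepare,
    "diversity": _stage_diversity,
    "fit": _stage_fit,
    "cv": _stage_cv,
    "sensitivity": _stage_sensitivity,
    "report": _stage_report,
}


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

def report(run_dir) -> str:
    """Render a Markdown report from stage artifacts (never recomputing).

    Raises :class:`MissingArtifactError` when a required artifact is
    absent or unparsable; optional sections (CV, importance, sensitivity)
    are included only when their artifacts exist.
    """
    run_dir = Path(run_dir)
    coef_path = run_dir / "coefficients.tsv"
    if not coef_path.exists():
        raise MissingArtifactError(f"missing artifact: {coef_path}")
    try:
        coef = pd.read_csv(coef_path, sep="\t")
        if coef.empty or not {"model", "term", "estimate", "p"} <= set(coef.columns):
            raise ValueError("truncated or malformed coefficient table")
    except (ValueError, pd.errors.ParserError) as exc:
        raise MissingArtifactError(f"unreadable artifact {coef_path}: {exc}") from exc

    lines = ["# Invasion analysis report", ""]
    for model, grp in coef.groupby("model", sort=True):
        lines.append(f"## Model: {model}")
        lines.append("")
        lines.append(grp.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")

    summary_path = run_dir / "run_summary.json"
    if summary_path.exists():
        metrics = json.loads(summary_path.read_text()).get("metrics", {})
        if "cv_presence_auc" in metrics:
            lines += ["## Cross-validation",
                      f"Buffered LOO-CV presence AUC: {metrics['cv_presence_auc']:.4f}",
                      ""]
    imp_path = run_dir / "importance_presence.tsv"
    if imp_path.exists():
        imp = pd.read_csv(imp_path, sep="\t")
        lines += ["## Random-forest importance (sum |SHAP|)",
                  imp.to_string(index=False, float_format=lambda v: f"{v:.4g}"), ""]
    sens_path = run_dir / "sensitivity.json"
    if sens_path.exists():
        sens = json.loads(sens_path.read_text())
        lines += [
            "## Pre-invasion sensitivity",
            f"richness-change coefficient c = {sens['c']:.4f} "
            f"[{sens['c_lo']:.4f}, {sens['c_hi']:.4f}]",
            f"relative change of the richness coefficient: "
            f"{sens['relative_change']['c']:.4f}",
            "",
        ]
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
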