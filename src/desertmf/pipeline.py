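"""End-to-end orchestration: data in → diversity/SES → functions/MF →
regressions, path models and importance ranking → delimited-text reports.

A run is fully determined by its :class:`RunConfig` (inputs or synthetic
switch, seeds, null-model settings, model edge lists); re-running with the
same config is byte-identical.  The log records versions, seeds, excluded
plots and undefined-metric flags so any single plot's SES can be recomputed
in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association, diversity, functions_mf, importance, io, phylo, phylo_structure
from .synthetic_data import SimulationConfig, simulate_dataset

__all__ = ["RunConfig", "RunResult", "ValidationReport", "load_config",
           "validate_inputs", "assemble_plot_table", "run"]

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS = ("richness", "shannon", "simpson", "PD", "NRI", "NTI",
                      "pH", "SSC", "CN")
# A multifunctionality path model in the style of the field's driver SEMs:
# soil chemistry acts on MF directly and through plant diversity (species
# richness and phylogenetic diversity, themselves linked since PD grows with
# richness).  Over-identified (df = 2), so chi-square/NC/CFI are informative.
DEFAULT_PATH_MODELS = {
    "multifunctionality": (
        ("CN", "richness"), ("pH", "PD"), ("CN", "PD"), ("richness", "PD"),
        ("pH", "MF"), ("CN", "MF"), ("PD", "MF"), ("richness", "MF"),
    ),
}


@dataclass
class RunConfig:
    tree_path: str | None = None
    community_path: str | None = None
    traits_path: str | None = None
    soil_path: str | None = None
    synthetic: SimulationConfig | None = None
    n_rand: int = 999
    seed: int = 0
    abundance_weighted: bool = False
    layer_mode: str = "mean"
    nutrient_mode: str = "zscore"
    predictors: tuple = DEFAULT_PREDICTORS
    path_models: dict = field(default_factory=lambda: dict(DEFAULT_PATH_MODELS))
    n_trees: int = 500
    n_perm: int = 10
    out_dir: str | None = None

    def __post_init__(self):
        if self.n_rand < 2:
            raise ValueError("n_rand must be at least 2")
        if self.synthetic is None:
            paths = (self.tree_path, self.community_path, self.traits_path, self.soil_path)
            missing = [p for p in paths if p is None]
            if missing:
                raise ValueError("either all four input paths or a synthetic config must be given")
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(p)


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML mapping (keys mirror the field names)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "synthetic" in raw and raw["synthetic"] is not None:
        raw["synthetic"] = SimulationConfig(**raw["synthetic"])
    if "path_models" in raw:
        raw["path_models"] = {
            name: tuple(tuple(e) for e in edges) for name, edges in raw["path_models"].items()
        }
    if "predictors" in raw:
        raw["predictors"] = tuple(raw["predictors"])
    return RunConfig(**raw)


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(tree: phylo.Phylogeny, community: pd.DataFrame,
                    traits: pd.Series, soil: pd.DataFrame) -> ValidationReport:
    """Cross-check species/plot sets and soil value ranges."""
    rep = ValidationReport()
    tips = set(tree.tip_labels)
    unknown = sorted(set(community.columns) - tips)
    if unknown:
        rep.errors.append(f"community species absent from the tree: {', '.join(unknown)}")
    untraited = sorted(s for s in community.columns if s not in traits.index)
    if untraited:
        rep.errors.append(f"community species without trait values: {', '.join(untraited)}")
    comm_plots, soil_plots = set(community.index), set(soil.index)
    for p in sorted(comm_plots - soil_plots):
        rep.errors.append(f"plot '{p}' present in community but missing from soil table")
    for p in sorted(soil_plots - comm_plots):
        rep.warnings.append(f"plot '{p}' present in soil but not in community table")
    if (community.values < 0).any():
        rep.errors.append("negative abundances in community matrix")
    ranges = {"pH": (0.0, 14.0), "SWC": (0.0, 100.0)}
    for var, (lo, hi) in ranges.items():
        if var in soil.columns:
            bad = soil.index[(soil[var] < lo) | (soil[var] > hi)]
            for p in bad:
                rep.errors.append(f"{var}={soil.loc[p, var]:g} out of range ({lo}, {hi}) in plot '{p}'")
    neg_cols = [c for c in functions_mf.SOIL_VARIABLES if c in soil.columns and c != "pH"]
    for c in neg_cols:
        if (soil[c] < 0).any():
            rep.errors.append(f"negative values in soil column {c}")
    return rep


@dataclass
class RunResult:
    plot_table: pd.DataFrame
    diversity: pd.DataFrame
    ses: pd.DataFrame
    functions: pd.DataFrame
    regressions: pd.DataFrame
    path_fits: dict
    path_report: pd.DataFrame
    importance: pd.DataFrame
    validation: ValidationReport
    log: list


def assemble_plot_table(div: pd.DataFrame, pd_series: pd.Series, ses: pd.DataFrame,
                        functions: pd.DataFrame, soil: pd.DataFrame) -> pd.DataFrame:
    """Wide per-plot table joining diversity, SES, functions and soil columns."""
    nri_col = ses[ses.metric == "MPD"].set_index("plot")["ses"].rename("NRI")
    nti_col = ses[ses.metric == "MNTD"].set_index("plot")["ses"].rename("NTI")
    table = div.join([pd_series.rename("PD"), nri_col, nti_col, functions], how="inner")
    soil_cols = [c for c in soil.columns if c not in table.columns]
    return table.join(soil[soil_cols], how="inner")


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        data = simulate_dataset(config.synthetic)
        return data.tree, data.landscape.community, data.traits, data.landscape.soil
    tree = io.read_tree(config.tree_path)
    community = io.read_community(config.community_path)
    traits = io.read_traits(config.traits_path)
    soil = io.read_soil(config.soil_path, layer_mode=config.layer_mode)
    return tree, community, traits, soil


def run(config: RunConfig) -> RunResult:
    """Execute every stage; write delimited outputs when out_dir is set."""
    log = [f"desertmf {__version__}", f"master seed {config.seed}",
           f"n_rand {config.n_rand}", f"abundance_weighted {config.abundance_weighted}"]
    tree, community, traits, soil = _load_inputs(config)
    soil = functions_mf.ensure_cn(soil)

    rep = validate_inputs(tree, community, traits, soil)
    for w in rep.warnings:
        log.append(f"WARNING: {w}")
        logger.warning(w)
    if not rep.ok:
        raise ValueError("input validation failed:\n" + "\n".join(rep.errors))

    nonempty = community.index[community.sum(axis=1) > 0]
    excluded = [p for p in community.index if p not in set(nonempty)]
    if excluded:
        log.append(f"excluded empty plots: {', '.join(map(str, excluded))}")
    community = community.loc[nonempty]
    soil = soil.loc[[p for p in community.index if p in soil.index]]

    div = diversity.diversity_table(community)
    cwm_height = diversity.cwm_table(community, traits)
    pd_vals = pd.Series(
        {plot: phylo.faith_pd(tree, community.columns[community.loc[plot] > 0])
         for plot in community.index},
        name="PD")

    dist = phylo.patristic_distances(tree)
    ses = phylo_structure.ses_table(community, dist, n_rand=config.n_rand,
                                    seed=config.seed,
                                    abundance_weighted=config.abundance_weighted)
    for _, row in ses[ses.flag != ""].iterrows():
        log.append(f"undefined {row.metric} SES for plot {row.plot}: {row.flag}")
    log.extend(f"plot {p} seed {s}" for p, s in
               ses[ses.metric == "MPD"][["plot", "seed"]].itertuples(index=False))

    functions = functions_mf.function_matrix(soil, cwm_height,
                                             nutrient_mode=config.nutrient_mode)
    table = assemble_plot_table(div, pd_vals, ses, functions, soil)

    reg_rows = []
    for pred in config.predictors:
        if pred not in table.columns:
            continue
        sub = table[[pred, "MF"]].dropna()
        for form in ("linear", "quadratic"):
            try:
                fit = association.ols_screen(sub["MF"], sub[pred], form=form,
                                             predictor=pred, response="MF")
            except ValueError as exc:  # e.g. near-constant integer predictors
                log.append(f"skipped {form} screen of MF ~ {pred}: {exc}")
                continue
            row = {"predictor": pred, "response": "MF", "form": form,
                   "r2": fit.r2, "p": fit.p_value, "n": fit.n}
            row.update({f"b_{k}": v for k, v in fit.coefficients.items()})
            reg_rows.append(row)
    regressions = pd.DataFrame(reg_rows)

    path_fits, path_rows = {}, []
    for name, edges in config.path_models.items():
        model = association.PathModel(edges=tuple(tuple(e) for e in edges))
        sub = table[list(model.variables)].dropna()
        fit = association.fit_path_model(model, sub)
        path_fits[name] = fit
        log.append(f"path model '{name}': chi2={fit.chi2:.4g} df={fit.df} "
                   f"NC={fit.nc:.4g} CFI={fit.cfi:.4g} n={fit.n}")
        for e in fit.edges:
            path_rows.append({"model": name, "source": e.source, "target": e.target,
                              "coefficient": e.coefficient, "se": e.se, "p": e.p_value,
                              "chi2": fit.chi2, "df": fit.df, "nc": fit.nc,
                              "cfi": fit.cfi, "n": fit.n})
    path_report = pd.DataFrame(path_rows)

    feat = table[list(functions_mf.FUNCTION_COLUMNS)].dropna()
    y = table.loc[feat.index, "MF"]
    log.append("note: response MF is the mean of the four features; importance reflects "
               "variance/covariance contributions, not causal weights")
    forest = importance.fit_forest(feat, y, n_trees=config.n_trees, seed=config.seed)
    ranking = importance.permutation_importance(forest, feat, y,
                                                n_perm=config.n_perm, seed=config.seed)
    log.append("importance order: " + " > ".join(ranking["feature"]))

    result = RunResult(plot_table=table, diversity=div, ses=ses, functions=functions,
                       regressions=regressions, path_fits=path_fits,
                       path_report=path_report, importance=ranking,
                       validation=rep, log=log)
    if config.out_dir:
        _write_outputs(result, config.out_dir)
    return result


def _write_outputs(result: RunResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_table(result.plot_table, out / "plot_table.csv")
    io.write_table(result.diversity, out / "diversity.csv")
    io.write_table(result.ses.set_index("plot"), out / "ses.csv")
    io.write_table(result.functions, out / "functions.csv")
    io.write_table(result.regressions.set_index(["predictor", "form"]),
                   out / "regressions.csv")
    if len(result.path_report):
        io.write_table(result.path_report.set_index(["model", "source", "target"]),
                       out / "path_models.csv")
    io.write_table(result.importance.set_index("feature"), out / "importance.csv")
    (out / "run.log").write_text("\n".join(result.log) + "\n")
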