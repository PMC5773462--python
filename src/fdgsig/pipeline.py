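"""End-to-end orchestration of the uptake-signature analysis.

Stages (in study order): simulate -> quantify -> select -> train ->
evaluate -> cluster -> enrich -> report. Every stage is a plain function
taking the resolved configuration and the output directory; artifacts
are TSV/CSV tables with a provenance comment header, JSON reports, and a
GMT gene-set file. One master seed fans out deterministically to
per-stage seeds, all recorded in the run report.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import ExpressionMatrix, standardize
from .feature_select import univariate_coefficients, select_probes, supervised_pc_cv
from . import latent
from .model_eval import (
    make_model,
    repeated_cv,
    summarize_resamples,
    compare_models,
    external_validate,
    stability_sweep,
)
from .cluster_eval import cluster_pipeline, control_clustering
from .pet_quant import quantify_cohort, cohort_summary, outlier_fences, log2_transform, screen_distribution
from .ssgsea import (
    read_gmt,
    write_gmt,
    summarize_probes_to_genes,
    ssgsea_scores,
    correlate_scores_with_phenotype,
)
from .synthetic import SyntheticConfig, generate_cohort, generate_validation_cohort, generate_genesets

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "STAGES"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {
        # scaled-down defaults keep a full run interactive; the generator
        # accepts the full 22814 x 71 study scale unchanged
        "n_probes": 4000,
        "n_samples": 71,
        "n_signal_probes": 300,
        "n_signal_blocks": 3,
        "block_rho": 0.7,
        "effect_size_range": [0.003, 0.0063],
        "noise_sd": 0.4,
        "validation_n": 13,
        "include_influential": True,
    },
    "feature_selection": {
        "thresholds": [0.15, 0.25, 0.35],
        "max_components": 3,
        "k": 10,
    },
    "models": ["pls", "pcr", "svm", "rf"],
    "pls_components": 3,
    "pcr_components": 18,
    "cv": {"k": 10, "repeats": 5},
    "cluster_k": 5,
    "ssgsea": {"alpha": 0.25, "normalize": True, "n_sets": 20, "set_size_range": [10, 40]},
    "sweep_thresholds": None,  # default: around the chosen threshold
    "heatmap": False,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    for k, v in (overrides or {}).items():
        cfg[k] = v
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _stage_seeds(master: int) -> dict:
    names = ["simulate", "quantify", "select", "train", "evaluate", "cluster", "enrich"]
    ss = np.random.SeedSequence(int(master))
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _write_table(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str, **kw) -> None:
    sep = "\t" if path.suffix == ".tsv" else ","
    with open(path, "w") as fh:
        fh.write(f"# fdgsig v{__version__} stage={stage} config={cfg_hash}\n")
        df.to_csv(fh, sep=sep, **kw)


def _read_table(path: Path, **kw) -> pd.DataFrame:
    sep = "\t" if path.suffix == ".tsv" else ","
    return pd.read_csv(path, sep=sep, comment="#", **kw)


def _write_json(obj, path: Path, stage: str, cfg_hash: str) -> None:
    payload = {"_provenance": {"tool": f"fdgsig v{__version__}", "stage": stage,
                               "config": cfg_hash}, "data": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def stage_simulate(cfg: dict, outdir: Path, seed: int, cfg_hash: str, log) -> None:
    sc = cfg["synthetic"]
    config = SyntheticConfig(
        n_probes=sc["n_probes"],
        n_samples=sc["n_samples"],
        n_signal_probes=sc["n_signal_probes"],
        n_signal_blocks=sc.get("n_signal_blocks", 3),
        block_rho=sc.get("block_rho", 0.7),
        effect_size_range=tuple(sc.get("effect_size_range", (0.001, 0.0021))),
        noise_sd=sc.get("noise_sd", 0.4),
        validation_n=sc.get("validation_n", 13),
        include_influential=sc.get("include_influential", False),
        seed=seed,
    )
    cohort = generate_cohort(config)
    val = generate_validation_cohort(cohort, config)
    log(f"simulate: {cohort.expression.n_probes} probes x "
        f"{cohort.expression.n_samples} training samples, "
        f"{val.expression.n_samples} validation samples")
    cohort.expression.to_tsv(outdir / "expression.tsv")
    val.expression.to_tsv(outdir / "expression_validation.tsv")
    _write_table(cohort.log2_suv.to_frame(), outdir / "phenotype.csv", "simulate", cfg_hash,
                 index_label="sample_id")
    _write_table(val.log2_suv.to_frame(), outdir / "phenotype_validation.csv",
                 "simulate", cfg_hash, index_label="sample_id")
    _write_table(cohort.expression.gene_symbols.to_frame(), outdir / "annotation.tsv",
                 "simulate", cfg_hash, index_label="probe_id")
    _write_table(cohort.pet_covariates, outdir / "pet.csv", "simulate", cfg_hash,
                 index=False)
    truth = {
        "signal_probe_ids": cohort.truth["signal_probe_ids"],
        "coefficients": cohort.truth["coefficients"],
        "noise_sd": cohort.truth["noise_sd"],
        "block_rho": cohort.truth["block_rho"],
        "phenotype_variance": cohort.truth["phenotype_variance"],
    }
    _write_json(truth, outdir / "truth.json", "simulate", cfg_hash)
    gs_cfg = cfg["ssgsea"]
    collection, kinds = generate_genesets(
        cohort.expression.gene_symbols, cohort.truth,
        n_sets=gs_cfg.get("n_sets", 20),
        set_size_range=tuple(gs_cfg.get("set_size_range", (10, 40))),
        seed=seed + 17,
    )
    write_gmt(collection, outdir / "genesets.gmt")
    _write_table(kinds.to_frame(), outdir / "geneset_types.tsv", "simulate", cfg_hash,
                 index_label="geneset")


def _load_training(outdir: Path):
    ann = _read_table(outdir / "annotation.tsv", index_col=0)["gene_symbol"]
    X = ExpressionMatrix.from_tsv(outdir / "expression.tsv", annotation=ann)
    y = _read_table(outdir / "phenotype.csv", index_col=0)["log2_suv"]
    return X, y


def stage_quantify(cfg: dict, outdir: Path, seed: int, cfg_hash: str, log) -> None:
    pet = _read_table(outdir / "pet.csv")
    table = quantify_cohort(pet)
    _write_table(table, outdir / "quantification.csv", "quantify", cfg_hash, index=False)
    summary = cohort_summary(table)
    summary["normality_screen_log2_suv"] = screen_distribution(table["log2_suv"])
    _write_json(summary, outdir / "quantification_summary.json", "quantify", cfg_hash)
    log(f"quantify: {len(table)} patients quantified")


def stage_select(cfg: dict, outdir: Path, seed: int, cfg_hash: str, log) -> None:
    X, y = _load_training(outdir)
    Xstd = standardize(X)
    table = univariate_coefficients(Xstd, y)
    _write_table(table.sort_values("rank"), outdir / "score_table.tsv", "select",
                 cfg_hash, index_label="probe_id")
    fs = cfg["feature_selection"]
    choice = supervised_pc_cv(
        X, y, fs["thresholds"], max_components=fs.get("max_components", 3),
        k=fs.get("k", 10), seed=seed,
    )
    selected = select_probes(table, choice.threshold)
    log(f"select: threshold {choice.threshold:g} with {choice.n_components} "
        f"component(s); {len(selected)} probes selected")
    _write_json(
        {
            "threshold": choice.threshold,
            "n_components": choice.n_components,
            "n_selected": int(len(selected)),
            "grid": choice.grid.to_dict(orient="records"),
        },
        outdir / "threshold_choice.json", "select", cfg_hash,
    )
    (outdir / "selected_probes.txt").write_text("\n".join(selected) + "\n")


def stage_train(cfg: dict, outdir: Path, seed: int, cfg_hash: str, log) -> None:
    choice_path = outdir / "threshold_choice.json"
    if not choice_path.exists():
        raise FileNotFoundError(
            "threshold_choice.json not found — run the 'select' stage first"
        )
    X, y = _load_training(outdir)
    with open(choice_path) as fh:
        choice = json.load(fh)["data"]
    theta = choice["threshold"]
    A = cfg.get("pls_components", 3)
    model = make_model("pls", threshold=theta, n_components=A)
    model.fit(X, y)
    log(f"train: PLS-{A} on {len(model.selected_)} probes at |beta| >= {theta:g}")
    (outdir / "pls_model.json").write_text(
        latent.model_to_json(model.core_.model_, model.params_)
    )
    vip = pd.Series(
        model.core_.model_.vip.to_numpy(), index=model.selected_, name="vip"
    )
    sel = latent.select_by_vip(vip, 1.0, X.gene_symbols)
    vip_table = vip.to_frame()
    vip_table["gene_symbol"] = X.gene_symbols.reindex(vip.index)
    vip_table["beta"] = model.score_table_.loc[vip.index, "beta"]
    _write_table(vip_table.sort_values("vip", ascending=False), outdir / "vip_table.tsv",
                 "train", cfg_hash, index_label="probe_id")
    _write_json(
        {
            "n_vip_ge_1": sel["n_selected"],
            "frac_unannotated_selected": sel.get("frac_unannotated_selected"),
            "frac_unannotated_overall": sel.get("frac_unannotated_overall"),
            "fisher_p": sel.get("fisher_p"),
        },
        outdir / "vip_summary.json", "train", cfg_hash,
    )


def stage_evaluate(cfg: dict, outdir: Path, seed: int, cfg_hash: str, log) -> None:
    X, y = _load_training(outdir)
    Xval = ExpressionMatrix.from_tsv(outdir / "expression_validation.tsv",
                                     annotation=X.gene_symbols)
    yval = _read_table(outdir / "phenotype_validation.csv", index_col=0)["log2_suv"]
    with open(outdir / "threshold_choice.json") as fh:
        theta = json.load(fh)["data"]["threshold"]
    models = []
    for kind in cfg["models"]:
        models.append(
            make_model(kind, threshold=theta, seed=seed,
                       n_components=cfg.get("pls_components", 3),
                       pcr_components=cfg.get("pcr_components", 18))
        )
    res = repeated_cv(models, X, y, k=cfg["cv"]["k"], repeats=cfg["cv"]["repeats"],
                      seed=seed)
    _write_table(res, outdir / "resamples.csv", "evaluate", cfg_hash, index=False)
    summary = summarize_resamples(res)
    _write_table(summary, outdir / "cv_summary.csv", "evaluate", cfg_hash, index=False)
    comp = compare_models(res)
    _write_json(
        {"summary": summary.to_dict(orient="records"),
         "comparisons": comp.to_dict(orient="records")},
        outdir / "model_comparison.json", "evaluate", cfg_hash,
    )
    log("evaluate: " + "; ".join(
        f"{r['model']} RMSE {r['rmse_mean']:.3f}" for _, r in summary.iterrows()
    ))
    # external validation of the frozen PLS model
    fences = outlier_fences(2.0 ** y.to_numpy())
    pls = models[0]
    pls.fit(X, y)
    ext = external_validate(pls, Xval, yval, fences)
    _write_table(ext["per_sample"], outdir / "validation_per_sample.csv", "evaluate",
                 cfg_hash, index_label="sample_id")
    _write_json(
        {k: ext[k] for k in ("rmse_all", "rmse_excluding_influential", "n_all",
                             "n_excluding", "n_outliers_excluded", "n_influential")},
        outdir / "validation_summary.json", "evaluate", cfg_hash,
    )
    log(f"evaluate: validation RMSE {ext['rmse_all']:.3f} (all) / "
        f"{ext['rmse_excluding_influential']:.3f} (excluding influential)")
    sweep_th = cfg.get("sweep_thresholds") or [
        round(theta + d, 6) for d in (-0.1, -0.05, 0.0, 0.05, 0.1)
    ]
    sweep = stability_sweep(X, y, Xval, yval, sweep_th, fences=fences,
                            n_components=cfg.get("pls_components", 3))
    _write_table(sweep, outdir / "stability_sweep.csv", "evaluate", cfg_hash, index=False)


def stage_cluster(cfg: dict, outdir: Path, seed: int, cfg_hash: str, log) -> None:
    X, y = _load_training(outdir)
    selected = (outdir / "selected_probes.txt").read_text().split()
    suv = 2.0 ** y.to_numpy()
    k = cfg.get("cluster_k", 5)
    sig = cluster_pipeline(X.subset_probes(selected), suv, k=k)
    ctrl = control_clustering(X, suv, k=k)
    labels = pd.DataFrame({"signature_cluster": sig.labels,
                           "all_probe_cluster": ctrl.labels})
    _write_table(labels, outdir / "cluster_labels.csv", "cluster", cfg_hash,
                 index_label="sample_id")
    _write_json(
        {
            "signature": {"anova_f": sig.anova_f, "anova_p": sig.anova_p,
                          "clusters": sig.stats.to_dict(orient="records"),
                          "pairwise": sig.pairwise.to_dict(orient="records")},
            "all_probes": {"anova_f": ctrl.anova_f, "anova_p": ctrl.anova_p,
                           "clusters": ctrl.stats.to_dict(orient="records")},
        },
        outdir / "cluster_summary.json", "cluster", cfg_hash,
    )
    log(f"cluster: signature ANOVA p {sig.anova_p:.2g} vs all-probe {ctrl.anova_p:.2g}")
    if cfg.get("heatmap"):
        _heatmap(X, selected, sig.labels, outdir / "heatmap.png")


def _heatmap(X, selected, labels, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Xs = standardize(X.subset_probes(selected))
    order = labels.sort_values().index
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.imshow(Xs.values[order].to_numpy(), aspect="auto", cmap="RdBu_r",
              vmin=-3, vmax=3)
    ax.set_xlabel("samples (ordered by cluster)")
    ax.set_ylabel("standardized signature probes")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def stage_enrich(cfg: dict, outdir: Path, seed: int, cfg_hash: str, log) -> None:
    X, y = _load_training(outdir)
    gene_expr = summarize_probes_to_genes(X)
    collection = read_gmt(outdir / "genesets.gmt")
    gs = cfg["ssgsea"]
    scores = ssgsea_scores(gene_expr, collection, alpha=gs.get("alpha", 0.25),
                           normalize=gs.get("normalize", True))
    _write_table(scores, outdir / "ssgsea_scores.tsv", "enrich", cfg_hash,
                 index_label="geneset")
    corr = correlate_scores_with_phenotype(scores, y)
    _write_table(corr, outdir / "ssgsea_correlations.tsv", "enrich", cfg_hash,
                 index=False)
    log(f"enrich: {len(collection)} gene sets scored on {gene_expr.shape[0]} genes")


def stage_report(cfg: dict, outdir: Path, seed: int, cfg_hash: str, log) -> None:
    report = {"config_hash": cfg_hash, "config": cfg}
    for name in ["quantification_summary", "threshold_choice", "vip_summary",
                 "model_comparison", "validation_summary", "cluster_summary"]:
        p = outdir / f"{name}.json"
        if p.exists():
            with open(p) as fh:
                report[name] = json.load(fh)["data"]
    _write_json(report, outdir / "run_report.json", "report", cfg_hash)
    log("report: aggregated existing artifacts")


STAGES = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "select": stage_select,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "cluster": stage_cluster,
    "enrich": stage_enrich,
    "report": stage_report,
}


def run_pipeline(config: dict | str | Path | None = None, outdir="results/pipeline",
                 seed: int | None = None, stages=None, verbose: bool = True) -> dict:
    """Run the analysis stages in study order; returns the run report."""
    cfg = config if isinstance(config, dict) else load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(cfg)
    seeds = _stage_seeds(cfg["seed"])
    lines: list[str] = []

    def log(msg: str) -> None:
        lines.append(msg)
        if verbose:
            print(msg)

    t0 = time.time()
    to_run = list(stages) if stages else list(STAGES)
    for name in to_run:
        STAGES[name](cfg, outdir, seeds.get(name, cfg["seed"]), cfg_hash, log)
    log(f"done in {time.time() - t0:.1f}s")
    (outdir / "run.log").write_text("\n".join(lines) + "\n")
    report = {"stage_seeds": seeds, "log": lines}
    if "report" in to_run:
        with open(outdir / "run_report.json") as fh:
            report.update(json.load(fh)["data"])
        report["stage_seeds"] = seeds
        report["log"] = lines
        _write_json(report, outdir / "run_report.json", "report", cfg_hash)
    return report
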