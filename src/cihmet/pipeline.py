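"""End-to-end orchestration: simulate or load data, then run
preprocess -> differential expression -> factor integration -> pathway
enrichment -> correlation network -> biomarker panel -> Mendelian
randomization, writing every stage's tables plus a consolidated report.

A single master seed fans out to named per-stage sub-streams, so re-running
any stage in isolation reproduces its outputs, and two full runs with the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, factors, mr as mr_mod, network, pathway, predict, preprocess, synthio
from ._util import substream, write_matrix

__all__ = ["PipelineConfig", "run_pipeline", "simulate_dataset"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage parameter in one place; round-trips losslessly via YAML."""

    outdir: str = "pipeline_out"
    seed: int = 0
    # --- synthetic cohort (used when synthetic=True) ---
    synthetic: bool = True
    n_total: int = 63
    n_case: int = 19
    view_coverage: dict = field(default_factory=lambda: dict(synthio.DEFAULT_COVERAGE))
    n_features: dict = field(default_factory=lambda: {"CRT": 300, "plasma": 300, "urine": 300})
    n_dems: int = 20
    n_biomarkers: int = 5
    biomarker_log2fc: float = 2.5
    biomarker_module_loading: float = 1.5
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    factor_group_shift: float = 0.0
    loading_scale: float = 0.5
    k_factors_true: int = 3
    n_pathways: int = 15
    pathway_size: tuple = (5, 15)
    enriched_fraction: float = 0.8
    external_n: int = 75
    # --- file inputs (used when synthetic=False) ---
    view_paths: dict | None = None
    metadata_path: str | None = None
    pathway_paths: dict | None = None
    mr_path: str | None = None
    # --- stage parameters ---
    presence_threshold: float = 0.8
    covariates: tuple = ("age", "gender", "bmi")
    alpha_dem: float = 0.05
    k_factors: int = 10
    max_iter: int = 500
    factor_tol: float = 1e-8
    corr_threshold: float = 0.4
    corr_mode: str = "squared"
    weight_quantile: float = 0.5
    top_pathways: int = 3
    min_eligible: int = 10
    n_runs: int = 1000
    top_k: int = 10
    freq_threshold: int = 500
    n_trees: int = 500
    split_ratio: float = 0.7
    mr_enabled: bool = True
    mr_k: int = 50
    mr_true_slope: float = 0.3
    mr_pleiotropy_fraction: float = 0.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("pathway_size", "covariates"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def simulate_dataset(cfg: PipelineConfig):
    """Generate the full synthetic bundle a pipeline run consumes."""
    spec = synthio.CohortSpec(
        n_total=cfg.n_total, n_case=cfg.n_case, view_coverage=cfg.view_coverage, seed=cfg.seed
    )
    truth = synthio.plan_truth(
        spec,
        cfg.n_features,
        n_dems=cfg.n_dems,
        n_biomarkers=cfg.n_biomarkers,
        biomarker_log2fc=cfg.biomarker_log2fc,
        biomarker_module_loading=cfg.biomarker_module_loading,
        k_factors=cfg.k_factors_true,
        loading_scale=cfg.loading_scale,
        factor_group_shift=cfg.factor_group_shift,
        mr_truth={"true_slope": cfg.mr_true_slope, "pleiotropy_fraction": cfg.mr_pleiotropy_fraction, "k": cfg.mr_k},
    )
    views, metadata, mask = synthio.generate_views(
        spec, truth, cfg.n_features, noise_sd=cfg.noise_sd, missing_rate=cfg.missing_rate
    )
    sets = {}
    for v in views:
        sets[v] = synthio.generate_pathway_sets(
            list(views[v].columns),
            cfg.n_pathways,
            cfg.pathway_size,
            enriched=(f"{v}_enriched", truth.dem_ids[v], cfg.enriched_fraction),
            seed=int(substream(cfg.seed, f"pwsets:{v}").integers(2**31)),
        )
    mr_set = synthio.generate_mr_dataset(
        cfg.mr_k,
        cfg.mr_true_slope,
        cfg.mr_pleiotropy_fraction,
        seed=int(substream(cfg.seed, "mrdata").integers(2**31)),
    )
    # external cohort from the same generative truth (plasma-style validation)
    ext_spec = synthio.CohortSpec(
        n_total=cfg.external_n,
        n_case=max(1, int(round(cfg.external_n * cfg.n_case / cfg.n_total))),
        view_coverage={v: cfg.external_n for v in cfg.view_coverage},
        seed=int(substream(cfg.seed, "external").integers(2**31)),
    )
    ext_views, ext_meta, _ = synthio.generate_views(
        ext_spec, truth, cfg.n_features, noise_sd=cfg.noise_sd, missing_rate=cfg.missing_rate
    )
    return {
        "truth": truth,
        "views": views,
        "metadata": metadata,
        "mask": mask,
        "pathway_sets": sets,
        "mr_set": mr_set,
        "external_views": ext_views,
        "external_metadata": ext_meta,
    }


def _load_dataset(cfg: PipelineConfig):
    from ._util import read_gmt, read_matrix

    if not cfg.view_paths or not cfg.metadata_path:
        raise ValueError("non-synthetic runs need view_paths and metadata_path")
    views = {v: read_matrix(p) for v, p in cfg.view_paths.items()}
    metadata = read_matrix(cfg.metadata_path)
    sets = {v: read_gmt(p) for v, p in (cfg.pathway_paths or {}).items()}
    mr_set = pd.read_csv(cfg.mr_path, sep="\t") if cfg.mr_path else None
    return {
        "truth": None,
        "views": views,
        "metadata": metadata,
        "mask": None,
        "pathway_sets": sets,
        "mr_set": mr_set,
        "external_views": None,
        "external_metadata": None,
    }


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> dict:
    """Run every stage in order and return the consolidated report dict."""
    outdir = Path(cfg.outdir)
    data = simulate_dataset(cfg) if cfg.synthetic else _load_dataset(cfg)
    views, metadata = data["views"], data["metadata"]
    report: dict = {"seed": cfg.seed, "stages": {}}
    stage = "setup"
    try:
        # ---- preprocess ----
        stage = "preprocess"
        logged = {v: preprocess.preprocess_view(df, cfg.presence_threshold) for v, df in views.items()}
        report["stages"]["preprocess"] = {
            v: {"n_samples": int(df.shape[0]), "n_features": int(df.shape[1])} for v, df in logged.items()
        }

        # ---- differential expression ----
        stage = "diffexpr"
        dems = {}
        for v, df in logged.items():
            dems[v] = diffexpr.run_dem(df, metadata.loc[df.index], tissue=v, covariates=cfg.covariates, alpha=cfg.alpha_dem)
        dem_ids = {v: list(t.index[t["dem"]]) for v, t in dems.items()}
        report["stages"]["diffexpr"] = {v: {"n_dem": len(ids)} for v, ids in dem_ids.items()}

        # ---- factor integration on the DEM matrices ----
        stage = "factor_integration"
        dem_mats = {v: logged[v][dem_ids[v]] for v in views if len(dem_ids[v]) >= 2}
        k = min(cfg.k_factors, min(df.shape[1] for df in dem_mats.values()))
        fm = factors.fit_factor_model(
            dem_mats, k=k, max_iter=cfg.max_iter, tol=cfg.factor_tol,
            seed=int(substream(cfg.seed, "factor").integers(2**31)), min_factors=1,
        )
        disc = factors.discriminative_factor(fm, metadata["group"])
        report["stages"]["factor_integration"] = {
            "k": k,
            "n_iter": fm.n_iter,
            "converged": fm.converged,
            "discriminative_factor": disc.factor,
            "factor_auc": round(disc.auc, 4),
            "r2_by_view": {v: [round(x, 4) for x in fm.R2[v].tolist()] for v in fm.R2.columns},
        }

        # ---- pathway enrichment with factor weight / direction ----
        stage = "pathway"
        top_paths: dict[str, list[str]] = {}
        pw_report = {}
        for v in dem_mats:
            sets_v = data["pathway_sets"].get(v)
            if sets_v is None or sets_v.empty:
                top_paths[v] = []
                continue
            background = list(logged[v].columns)
            results = pathway.enrich(dem_ids[v], sets_v, background, alpha=0.05, min_hits=3)
            wts = fm.W[v][disc.factor].abs()
            fcs = dems[v]["log2FC"]
            results = [pathway.weight_and_direction(r, wts, fcs) for r in results]
            ranked = pathway.filter_and_rank(results)[: cfg.top_pathways]
            top_paths[v] = [r.pathway_id for r in ranked]
            pw_report[v] = [
                {"pathway_id": r.pathway_id, "p": round(r.p_value, 6), "weight": round(r.weight, 4), "direction": r.direction}
                for r in ranked
            ]
            if write:
                tab = pathway.results_frame(results)
                outdir.mkdir(parents=True, exist_ok=True)
                tab.to_csv(outdir / f"pathways_{v}.tsv", sep="\t", index=False)
            data.setdefault("_pathway_results", {})[v] = results
        report["stages"]["pathway"] = pw_report

        # ---- correlation network and candidate selection ----
        stage = "network"
        candidates: dict[str, list[str]] = {}
        net_report = {}
        for v in dem_mats:
            wts = fm.W[v][disc.factor].abs()
            high_w = set(wts[wts >= wts.quantile(cfg.weight_quantile)].index)
            hits = set()
            for r in data.get("_pathway_results", {}).get(v, []):
                if r.pathway_id in top_paths[v]:
                    hits |= set(r.hits)
            eligible = sorted(high_w & hits) if hits else sorted(high_w)
            if len(eligible) < cfg.min_eligible:
                eligible = sorted(dem_ids[v])  # documented fallback: all DEMs
            net = network.build_network(dem_mats[v][eligible], cfg.corr_threshold, cfg.corr_mode)
            cands = network.select_candidates(net)
            if len(cands) < max(8, cfg.top_k):
                cands = network.select_candidates(net, top_n=min(len(eligible), 25))
            if len(cands) < 3:
                # edgeless network at this threshold: fall back to the
                # highest-|weight| eligible features so the panel stage
                # always has material to rank
                cands = list(wts.loc[eligible].sort_values(ascending=False).index[:15])
            candidates[v] = cands
            net_report[v] = {"n_eligible": len(eligible), "n_edges": net.number_of_edges(), "n_candidates": len(cands)}
            if write and net.number_of_edges():
                network.edge_list(net).to_csv(outdir / f"network_{v}.tsv", sep="\t", index=False)
        report["stages"]["network"] = net_report

        # ---- stability selection + logistic panel + ROC ----
        stage = "predict"
        model_report = {}
        for v in dem_mats:
            cands = candidates[v]
            if len(cands) < 3:
                model_report[v] = {"skipped": f"only {len(cands)} candidates"}
                continue
            X = logged[v][cands]
            y = metadata.loc[X.index, "group"]
            # keep the per-run gate selective: at most half the candidate
            # pool can "appear" in any one run
            top_k = min(cfg.top_k, max(3, len(cands) // 2))
            top_k = min(top_k, len(cands) - 1)
            stab = predict.stability_select(
                X, y, n_runs=cfg.n_runs, top_k=top_k, freq_threshold=cfg.freq_threshold,
                seed=int(substream(cfg.seed, f"stab:{v}").integers(2**31)), n_trees=cfg.n_trees,
            )
            panel = stab.panel
            if len(panel) < 3:  # a multivariate panel needs at least 3 markers
                panel = list(stab.freq.sort_values(ascending=False, kind="mergesort").index[:3])
            train, test = predict.split_train_test(
                X.index, y, cfg.split_ratio, seed=int(substream(cfg.seed, f"split:{v}").integers(2**31))
            )
            model = predict.fit_panel(X.loc[train], y.loc[train], panel)
            model.train_index, model.test_index = train, test
            aucs = {
                "train": predict.roc_auc(model.decision(X.loc[train]), y.loc[train]),
                "test": predict.roc_auc(model.decision(X.loc[test]), y.loc[test]),
                "whole": predict.roc_auc(model.decision(X), y),
            }
            if data.get("external_views") is not None:
                ext = data["external_views"][v]
                ext_log = preprocess.preprocess_view(ext, cfg.presence_threshold)
                have = [f for f in panel if f in ext_log.columns]
                if have == list(panel):
                    aucs["external"] = predict.external_validate(
                        model, ext_log, data["external_metadata"].loc[ext_log.index, "group"]
                    )
            model.auc = {k_: round(a, 4) for k_, a in aucs.items()}
            model_report[v] = {
                "panel": panel,
                "freq": {f: int(stab.freq[f]) for f in panel},
                "separation_flag": model.separation_flag,
                "auc": model.auc,
            }
            if write:
                stab.freq.to_frame().to_csv(outdir / f"stability_{v}.tsv", sep="\t")
                model.to_json(outdir / f"model_{v}.json")
        report["stages"]["predict"] = model_report

        # ---- Mendelian randomization ----
        stage = "mr"
        if cfg.mr_enabled and data.get("mr_set") is not None:
            inst = data["mr_set"]
            suite = mr_mod.mr_suite(inst, seed=int(substream(cfg.seed, "mrboot").integers(2**31)))
            loo = mr_mod.leave_one_out(inst)
            report["stages"]["mr"] = {
                "estimates": [
                    {k_: (round(val, 6) if isinstance(val, float) else val) for k_, val in row.items() if pd.notna(val)}
                    for row in suite.to_dict("records")
                ],
                "n_loo_flags": int(loo["outside_full_ci"].sum()),
            }
            if write:
                suite.to_csv(outdir / "mr_estimates.tsv", sep="\t", index=False)
                loo.to_csv(outdir / "mr_leave_one_out.tsv", sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        for v, df in logged.items():
            write_matrix(df, outdir / f"preprocessed_{v}.tsv")
            dems[v].to_csv(outdir / f"dem_{v}.tsv", sep="\t")
        write_matrix(fm.Z, outdir / "factor_scores.tsv")
        write_matrix(fm.R2, outdir / "factor_r2.tsv")
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        (outdir / "report.txt").write_text(_format_report(report))
    return report


def _format_report(report: dict) -> str:
    lines = [f"pipeline report (seed {report['seed']})", "=" * 40]
    for stage, payload in report["stages"].items():
        lines.append(f"\n[{stage}]")
        lines.append(json.dumps(payload, indent=1, sort_keys=True))
    return "\n".join(lines) + "\n"
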