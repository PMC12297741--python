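"""End-to-end study pipeline: simulate/load -> preprocess -> networks -> report.

A single seeded configuration drives the whole analysis: generate (or load)
the survey tables, prepare them (reverse-scoring, dichotomization, missing-
data exclusion, redundancy screening, SES composite, covariate
residualization), then estimate the Ising symptom network with in-silico
interventions, the domain- and facet-level partial-correlation networks with
centrality / community / bridge metrics, bootstrap stability, and the
SES-moderated network model.  Rerunning with an identical configuration
reproduces every output byte-for-byte.
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

from . import ggm, io, metrics, mnm, nira, preprocess, simulate, stability
from .ising import IsingFitConfig, fit_ising

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)

ALL_STAGES = ("preprocess", "ising", "nira", "ggm", "metrics", "stability", "mnm")


def _jsonable(obj):
    """Recursively convert numpy scalars so json.dumps stays deterministic."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


@dataclass
class PipelineConfig:
    """Flat, documented configuration of a full study run."""

    outdir: str = "lonenet_output"
    seed: int = 0
    # input files; when items_csv is None a synthetic study is generated
    items_csv: str | None = None
    codebook_csv: str | None = None
    scores_csv: str | None = None
    ses_csv: str | None = None
    covariates_csv: str | None = None
    # synthetic study size (used only when generating)
    n_participants: int = 2593
    stages: tuple[str, ...] = ALL_STAGES
    residualize: bool = True
    focal_variable: str = "LON"
    # estimation settings
    ising_gamma: float = 0.25
    ising_n_lambda: int = 100
    ggm_gamma: float = 0.5
    ggm_n_lambda: int = 100
    nira_n_sim: int = 1000
    nira_burn_in: int = 200
    nira_delta: str | float = "sd"
    nira_n_boot: int = 5000
    stability_n_boot: int = 50
    stability_cs_n_boot: int = 20
    stability_n_lambda: int = 30
    mnm_gamma: float = 0.25
    mnm_n_boot: int = 200
    redundancy_p: float = 0.01
    redundancy_proportion: float = 0.25
    redundancy_cor_min: float = 0.50
    missing_threshold: float = 0.30

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)
        if self.residualize and self.items_csv is not None and self.covariates_csv is None:
            raise ValueError("residualization requested but no covariates_csv given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw and raw["stages"] is not None:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _load_inputs(cfg: PipelineConfig) -> dict:
    if cfg.items_csv is None:
        study = simulate.generate_study(n=cfg.n_participants, seed=cfg.seed)
        from .params import LikertSurvey

        survey = LikertSurvey(
            study["cls_responses"],
            simulate.CLS_REVERSE_KEYED,
            {it: "CLS" for it in study["cls_responses"].columns},
        )
        return {
            "survey": survey,
            "facet_scores": study["facet_scores"],
            "ses_indicators": study["ses_indicators"],
            "covariates": study["covariates"],
            "facet_domains": study["facet_domains"],
            "truth": {k: study[k] for k in ("cls_truth", "facet_truth")},
        }
    survey, extra_covariates = io.load_survey(cfg.items_csv, cfg.codebook_csv)
    facet = pd.read_csv(cfg.scores_csv, index_col=0) if cfg.scores_csv else None
    ses = pd.read_csv(cfg.ses_csv, index_col=0) if cfg.ses_csv else None
    cov = (
        pd.read_csv(cfg.covariates_csv, index_col=0)
        if cfg.covariates_csv
        else extra_covariates
    )
    return {
        "survey": survey,
        "facet_scores": facet,
        "ses_indicators": ses,
        "covariates": cov,
        "facet_domains": None,
        "truth": {},
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the in-memory result bundle.

    Writes long-format edge CSVs, node-metric CSVs, per-stage result tables,
    a manifest with content hashes, a seed/decision run log, and a
    machine-readable summary to ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = _load_inputs(cfg)
    survey = inputs["survey"]
    results: dict = {"config": cfg}
    networks: dict = {}
    node_tables: dict = {}
    extra_tables: dict = {}
    summary: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}
    stage = "inputs"
    try:
        # ---------------- preprocess ----------------
        stage = "preprocess"
        if "preprocess" in cfg.stages:
            scored = preprocess.reverse_score(survey)
            filtered, exclusion_log = preprocess.filter_missing(
                scored.responses,
                scale_columns=scored.items,
                item_missing_threshold=cfg.missing_threshold,
            )
            extra_tables["exclusion_log"] = exclusion_log
            redundancy = preprocess.detect_redundant_items(
                filtered.dropna().astype(float),
                p_threshold=cfg.redundancy_p,
                proportion_threshold=cfg.redundancy_proportion,
                cor_min=cfg.redundancy_cor_min,
            )
            extra_tables["redundancy_pairs"] = redundancy.pairs
            kept_items = [c for c in filtered.columns if c not in redundancy.suggested_removals]
            binary = preprocess.dichotomize(filtered[kept_items]).dropna().astype(np.int64)
            results["binary"] = binary
            results["redundancy"] = redundancy
            summary["n_participants_raw"] = survey.n_participants
            summary["n_excluded"] = int(len(exclusion_log))
            summary["removed_items"] = redundancy.suggested_removals
            summary["n_complete_binary"] = int(len(binary))

            if inputs["ses_indicators"] is not None:
                ses_index = preprocess.compute_ses_index(inputs["ses_indicators"])
                results["ses_index"] = ses_index
                extra_tables["ses_index"] = ses_index.scores.to_frame()
                summary["ses_variance_explained"] = ses_index.variance_explained
            if inputs["facet_scores"] is not None:
                facet = inputs["facet_scores"].dropna()
                if cfg.residualize and inputs["covariates"] is not None:
                    facet = preprocess.residualize(
                        facet, inputs["covariates"].loc[facet.index]
                    )
                results["facet_scores"] = facet
                domains = inputs["facet_domains"]
                if domains:
                    dom = pd.DataFrame(
                        {
                            d: facet[[f for f, dd in domains.items() if dd == d]].mean(axis=1)
                            for d in dict.fromkeys(domains.values())
                        }
                    )
                else:
                    dom = facet
                results["domain_scores"] = dom

        # ---------------- Ising network ----------------
        stage = "ising"
        if "ising" in cfg.stages:
            binary = results["binary"]
            fit = fit_ising(
                binary,
                IsingFitConfig(ebic_gamma=cfg.ising_gamma, n_lambda=cfg.ising_n_lambda),
            )
            results["ising"] = fit
            networks["ising"] = fit
            extra_tables["ising_thresholds"] = pd.DataFrame(
                {"node": fit.labels, "threshold": fit.params.tau}
            )
            node_tables["ising_centrality"] = metrics.centrality(fit)
            summary["ising_n_edges"] = int((np.abs(fit.weights) > 0).sum() // 2)
            summary["ising_top_strength"] = (
                node_tables["ising_centrality"]["strength"].idxmax()
            )

        # ---------------- in-silico interventions ----------------
        stage = "nira"
        if "nira" in cfg.stages:
            ss = np.random.SeedSequence([cfg.seed, 1])
            params = results["ising"].params
            for scenario, sub in zip(("alleviating", "aggravating"), ss.spawn(2)):
                sub_seed = int(sub.generate_state(1)[0] % (2**31))
                config = nira.NiraConfig(
                    scenario=scenario,
                    delta=cfg.nira_delta,
                    n_sim=cfg.nira_n_sim,
                    seed=sub_seed,
                    burn_in=cfg.nira_burn_in,
                )
                res = nira.run_nira(params, config)
                boot = nira.bootstrap_nira(
                    params, config, n_boot=cfg.nira_n_boot, result=res
                )
                table = res.effects.join(boot)
                table.insert(0, "scenario", scenario)
                extra_tables[f"nira_{scenario}"] = table
                results[f"nira_{scenario}"] = res
                ranking = nira.rank_targets(res)
                summary[f"nira_top_{scenario}"] = ranking[0]
                summary[f"nira_delta_{scenario}"] = res.delta
            summary["nira_delta_mode"] = str(cfg.nira_delta)

        # ---------------- GGMs ----------------
        stage = "ggm"
        if "ggm" in cfg.stages:
            dom = results["domain_scores"]
            domain_net = ggm.fit_ebicglasso(
                dom, gamma=cfg.ggm_gamma, n_lambda=cfg.ggm_n_lambda
            )
            facet_net = ggm.fit_ebicglasso(
                results["facet_scores"], gamma=cfg.ggm_gamma, n_lambda=cfg.ggm_n_lambda
            )
            results["ggm_domain"] = domain_net
            results["ggm_facet"] = facet_net
            networks["ggm_domain"] = domain_net
            networks["ggm_facet"] = facet_net
            extra_tables["spearman_domain"] = ggm.spearman_matrix(dom)
            focal = cfg.focal_variable
            if focal in facet_net.labels:
                flow = ggm.extract_flow(facet_net, focal)
                results["flow"] = flow
                extra_tables["flow_tiers"] = pd.DataFrame(
                    [(n, "tier1") for n in flow.tier1]
                    + [(n, "tier2") for n in flow.tier2]
                    + [(n, "unconnected") for n in flow.unconnected],
                    columns=["node", "tier"],
                )
                summary["flow_tier1_size"] = len(flow.tier1)
                summary["flow_tier2_size"] = len(flow.tier2)
            summary["ggm_domain_n_edges"] = domain_net.edge_count()
            summary["ggm_facet_n_edges"] = facet_net.edge_count()

        # ---------------- centrality / communities / bridges ----------------
        stage = "metrics"
        if "metrics" in cfg.stages:
            for name in ("ggm_domain", "ggm_facet"):
                if name in results:
                    node_tables[f"{name}_centrality"] = metrics.centrality(results[name])
            if "ggm_facet" in results:
                seed_comm = int(
                    np.random.SeedSequence([cfg.seed, 2]).generate_state(1)[0] % (2**31)
                )
                comm = metrics.spinglass_communities(results["ggm_facet"], seed=seed_comm)
                bridge = metrics.bridge_centrality(results["ggm_facet"], comm)
                results["communities"] = comm
                results["bridge"] = bridge
                node_tables["facet_bridge"] = bridge
                extra_tables["facet_communities"] = comm.membership.to_frame()
                summary["n_communities"] = comm.n_communities
                summary["top_bridge_strength"] = bridge["bridge_strength"].idxmax()
                summary["top_bridge_ei2"] = bridge["bridge_ei2"].idxmax()

        # ---------------- bootstrap stability ----------------
        stage = "stability"
        if "stability" in cfg.stages and "domain_scores" in results:
            seed_stab = int(
                np.random.SeedSequence([cfg.seed, 3]).generate_state(1)[0] % (2**31)
            )
            dom = results["domain_scores"]
            edge_ci = stability.edge_ci_bootstrap(
                dom,
                ggm.fit_ebicglasso,
                n_boot=cfg.stability_n_boot,
                seed=seed_stab,
                gamma=cfg.ggm_gamma,
                n_lambda=cfg.stability_n_lambda,
            )
            cs = stability.case_dropping_cs(
                dom,
                ggm.fit_ebicglasso,
                metric="strength",
                n_boot=cfg.stability_cs_n_boot,
                seed=seed_stab,
                gamma=cfg.ggm_gamma,
                n_lambda=cfg.stability_n_lambda,
            )
            results["edge_ci"] = edge_ci
            results["cs"] = cs
            extra_tables["ggm_domain_edge_ci"] = edge_ci
            extra_tables["cs_curve"] = cs.curve
            summary["cs_strength_domain"] = cs.cs

        # ---------------- moderated network model ----------------
        stage = "mnm"
        if "mnm" in cfg.stages and "domain_scores" in results:
            if "ses_index" not in results:
                raise ValueError("MNM stage requires SES indicators")
            seed_mnm = int(
                np.random.SeedSequence([cfg.seed, 4]).generate_state(1)[0] % (2**31)
            )
            dom = results["domain_scores"]
            moderator = results["ses_index"].scores.loc[dom.index].rename("SES")
            fit = mnm.fit_mnm(dom, moderator, gamma=cfg.mnm_gamma)
            stab = mnm.resample_mnm(
                dom, moderator, n_boot=cfg.mnm_n_boot, seed=seed_mnm, gamma=cfg.mnm_gamma
            )
            results["mnm"] = fit
            results["mnm_stability"] = stab
            pairs = []
            labels = fit.labels
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    pairs.append(
                        (labels[i], labels[j], fit.pairwise[i, j], fit.moderation[i, j])
                    )
            extra_tables["mnm_params"] = pd.DataFrame(
                pairs, columns=["node_i", "node_j", "w0", "m"]
            )
            extra_tables["mnm_stability"] = stab.proportions
            n_mod = int((np.abs(np.triu(fit.moderation, 1)) > 0).sum())
            summary["mnm_n_moderated_pairs"] = n_mod
    except Exception as exc:
        # persist whatever was produced before the failure, then re-raise
        io.write_network_tables(networks, node_tables, extra_tables, outdir)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    run_log = {
        "config": cfg.to_dict(),
        "resolved": {
            k: summary[k]
            for k in ("nira_delta_alleviating", "nira_delta_aggravating", "nira_delta_mode")
            if k in summary
        },
        "package": "lonenet 0.1.0",
    }
    (outdir / "run_log.json").write_text(
        json.dumps(_jsonable(run_log), sort_keys=True, indent=2)
    )
    (outdir / "summary.json").write_text(
        json.dumps(_jsonable(summary), sort_keys=True, indent=2)
    )
    manifest = io.write_network_tables(networks, node_tables, extra_tables, outdir)
    results["summary"] = summary
    results["manifest"] = manifest
    return results
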