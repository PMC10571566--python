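"""End-to-end orchestration: simulate -> ingest -> select -> score -> survival -> cluster.

A single :class:`PipelineConfig` (typically loaded from YAML) drives the
whole analysis.  Every stage derives its randomness from the master seed
via SeedSequence spawning, every intermediate artifact is persisted as a
plain-text file, and ``report.json`` is byte-identical across reruns of
the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .cluster import consensus_cluster, heatmap_order, spearman_distance
from .exceptions import BlcasigError, ConfigError
from .ingest import Cohort, load_cohort
from .selection import consensus_select, max_overlap_select
from .survival import km_estimate, logrank_test, quartile_groups, signature_score

log = logging.getLogger("blcasig.pipeline")


@dataclass
class PipelineConfig:
    out_dir: str = "blcasig_run"
    expression: str | None = None
    clinical: str | None = None
    metadata: str | None = None
    simulate: dict | None = None        # SimConfig fields; generates fixtures
    endpoint: str = "response"          # response | progression
    mode: str = "max_overlap"           # consensus | max_overlap
    cycles: int = 100
    phase1_cycles: int | None = None
    alpha: float = 0.01
    alpha_phase1: float = 0.05
    cutoff: float = 0.7
    ratio: float = 0.7
    folds: int = 10
    mixing: float = 0.5
    top_k: int = 100
    n_lambdas: int = 100
    n_risk_groups: int = 2
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    reps: int = 250
    subsample_fraction: float = 0.8
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict, **overrides) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        merged = {**d, **{k: v for k, v in overrides.items() if v is not None}}
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {}, **overrides)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except BlcasigError as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("ingest")
def _ingest(cfg: PipelineConfig, out: Path) -> Cohort:
    if cfg.simulate is not None:
        simcfg = sim.config_from_dict({"seed": cfg.seed, **cfg.simulate})
        cohort = sim.generate_cohort(simcfg)
        paths = sim.write_fixtures(cohort, out / "fixtures")
        log.info("simulated cohort written to %s", out / "fixtures")
        return load_cohort(paths["expression"], paths["clinical"],
                           paths["metadata"])
    if not (cfg.expression and cfg.clinical and cfg.metadata):
        raise ConfigError("either 'simulate' or all three input paths must be set")
    for p in (cfg.expression, cfg.clinical, cfg.metadata):
        if not Path(p).exists():
            raise ConfigError(f"input file not found: {p}")
    return load_cohort(cfg.expression, cfg.clinical, cfg.metadata)


@_stage("select")
def _select(cfg: PipelineConfig, cohort: Cohort, seed: int, out: Path):
    common = dict(cutoff=cfg.cutoff, cv=cfg.folds, mixing=cfg.mixing,
                  n_lambdas=cfg.n_lambdas)
    if cfg.mode == "consensus":
        outcome = consensus_select(cohort, cfg.endpoint, cycles=cfg.cycles,
                                   alpha=cfg.alpha, top_k=cfg.top_k, seed=seed,
                                   ratio=cfg.ratio, **common)
        outcome.frequencies.rename("count").to_csv(out / "frequencies.tsv",
                                                   sep="\t")
    elif cfg.mode == "max_overlap":
        outcome = max_overlap_select(cohort, cfg.endpoint, cycles=cfg.cycles,
                                     alpha_phase2=cfg.alpha, ratio=cfg.ratio,
                                     seed=seed,
                                     phase1_cycles=cfg.phase1_cycles,
                                     alpha_phase1=cfg.alpha_phase1, **common)
    else:
        raise ConfigError(f"unknown selection mode {cfg.mode!r}")
    pd.Series(outcome.signature, name="gene_id").to_csv(
        out / "signature.tsv", sep="\t", index=False)
    with open(out / "split.json", "w") as fh:
        json.dump({"train_ids": list(outcome.split.train_ids),
                   "test_ids": list(outcome.split.test_ids),
                   "ratio": outcome.split.ratio}, fh, indent=2, sort_keys=True)
    return outcome


@_stage("survival")
def _survival(cfg: PipelineConfig, cohort: Cohort, outcome, out: Path):
    scores = signature_score(outcome.final_fit, cohort.expression)
    scores.to_csv(out / "scores.tsv", sep="\t")
    groups = quartile_groups(scores, n_groups=cfg.n_risk_groups)
    surv = cohort.survival_data()
    labels = groups.labels.reindex(surv.index)

    km_rows = []
    for g in sorted(labels.unique()):
        mask = labels == g
        curve = km_estimate(surv.loc[mask, "time"], surv.loc[mask, "event"])
        for t, ar, ev, s in zip(curve.times, curve.at_risk, curve.events,
                                curve.survival):
            km_rows.append({"group": g, "time": t, "at_risk": int(ar),
                            "events": int(ev), "survival": s})
    pd.DataFrame(km_rows).to_csv(out / "km_table.tsv", sep="\t", index=False)

    logranks = {}
    if labels.nunique() >= 2:
        lr = logrank_test(surv["time"], surv["event"], labels)
        logranks["risk_groups"] = {"statistic": lr.statistic, "df": lr.df,
                                   "p_value": lr.p_value}
    for name, col in [("therapy_response", "response_binary"),
                      ("t_stage", "t2_binary"),
                      ("histology", "histology_group")]:
        g = cohort.clinical.loc[surv.index, col]
        if g.nunique() >= 2:
            lr = logrank_test(surv["time"], surv["event"], g)
            logranks[name] = {"statistic": lr.statistic, "df": lr.df,
                              "p_value": lr.p_value}
    with open(out / "logrank.json", "w") as fh:
        json.dump(_jsonable(logranks), fh, indent=2, sort_keys=True)
    return scores, groups, logranks


@_stage("cluster")
def _cluster(cfg: PipelineConfig, cohort: Cohort, outcome, scores,
             seed: int, out: Path):
    genes = outcome.signature
    if len(genes) < 2:
        log.info("fewer than 2 signature genes; clustering skipped")
        return None
    X = cohort.expression.loc[genes].T.to_numpy()
    n = X.shape[0]
    k_range = [k for k in cfg.k_range if 2 <= k < n]
    results = consensus_cluster(X, k_range, reps=cfg.reps,
                                subsample_fraction=cfg.subsample_fraction,
                                seed=seed)
    # pick K by mean silhouette of the consensus partition on Spearman distance
    from sklearn.metrics import silhouette_score
    D = spearman_distance(X)
    sil = {}
    for k, res in results.items():
        if len(set(res.assignments)) > 1:
            sil[k] = float(silhouette_score(D, res.assignments,
                                            metric="precomputed"))
        else:
            sil[k] = -1.0
    k_sel = max(sil, key=lambda k: (sil[k], -k))
    chosen = results[k_sel]
    pd.DataFrame(chosen.matrix, index=cohort.sample_ids,
                 columns=cohort.sample_ids).to_csv(
        out / "consensus_matrix.tsv", sep="\t", float_format="%.4f")
    assign = pd.Series(chosen.assignments, index=cohort.sample_ids,
                       name="cluster")
    assign.to_csv(out / "assignments.tsv", sep="\t")
    spec = heatmap_order(cohort, genes, assign,
                         annotations=["response_binary", "histology_group",
                                      "stage_group"])
    spec.matrix.to_csv(out / "heatmap_matrix.tsv", sep="\t",
                       float_format="%.4f")
    ann = spec.annotations.copy()
    ann["signature_score"] = scores.reindex(ann.index).round(6)
    ann.to_csv(out / "heatmap_annotations.tsv", sep="\t")
    return {"k_selected": int(k_sel), "silhouettes": sil,
            "cluster_sizes": {int(c): int((assign == c).sum())
                              for c in sorted(set(chosen.assignments))}}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write ``report.json``; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                 for s in np.random.SeedSequence(config.seed).spawn(3)]
        log.info("config: %s", dataclasses.asdict(config))
        log.info("stage seeds: select=%d cluster=%d", seeds[0], seeds[1])

        cohort = _ingest(config, out)
        outcome = _select(config, cohort, seeds[0], out)
        scores, groups, logranks = _survival(config, cohort, outcome, out)
        cluster_report = _cluster(config, cohort, outcome, scores, seeds[1], out)

        report = {
            "endpoint": config.endpoint,
            "mode": config.mode,
            "n_samples": len(cohort.sample_ids),
            "n_genes": len(cohort.gene_ids),
            "signature": sorted(outcome.signature),
            "signature_size": len(outcome.signature),
            "overlap_size": outcome.overlap_size,
            "accuracy": outcome.accuracy,
            "accuracy_ci": list(outcome.accuracy_ci[1:]),
            "auc": outcome.auc,
            "risk_group_thresholds": [groups.q1, groups.q2, groups.q3],
            "logrank": logranks,
            "clustering": cluster_report,
            "seed": config.seed,
        }
        report = _jsonable(report)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
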