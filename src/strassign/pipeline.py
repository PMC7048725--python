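"""End-to-end workflow: ingest -> filter -> sumstats -> cluster -> validate
-> assign, with reproducible seeds and a machine-readable run manifest.

Every stage writes plain CSV; the manifest (JSON) records the package
version, the configuration, and all seeds, so that a rerun from the
manifest reproduces every CSV byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .genotype_db import (
    find_duplicates,
    find_first_order_relatives,
    read_genotype_table,
)
from .sumstats import hwe_matrix, summary_table
from .assignment import assign_batch, leave_one_out_validation
from .clustering import (
    admixture_gibbs,
    align_runs,
    evanno_delta_k,
    localities_to_clusters,
)

log = logging.getLogger("strassign.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``reference`` / ``queries`` are CSV paths (wide dialect unless
    ``dialect`` says otherwise); clustering scale defaults are test-scale —
    raise ``runs_per_k`` / ``iterations`` for production analyses.
    """

    reference: str
    queries: str | None = None
    out_dir: str = "strassign-run"
    dialect: str = "wide"
    localities_csv: str | None = None
    threshold_percent: float = 70.0
    k_range: tuple = (2, 6)
    runs_per_k: int = 5
    iterations: int = 5_000
    burnin: int = 1_000
    correlated_freqs: bool = True
    locprior: bool = False
    exclusion: bool = False
    exclusion_n_sim: int = 10_000
    hwe_chain_length: int = 20_000
    seed: int = 1
    run_clustering: bool = True
    cluster_map: dict | None = None

    def __post_init__(self):
        if not 0 < self.threshold_percent < 100:
            raise ValueError("threshold_percent must lie in (0, 100)")
        lo, hi = self.k_range
        if hi < lo + 2:
            raise ValueError("k_range must span >= 3 consecutive K values")
        if not self.run_clustering and self.cluster_map is None:
            raise ValueError(
                "cluster-level analyses need either run_clustering=True or "
                "an explicit cluster_map"
            )


def _stage(name):
    start = time.perf_counter()
    log.info("stage %s: start", name)
    return start


def _done(name, start):
    log.info("stage %s: done in %.1fs", name, time.perf_counter() - start)


def run_pipeline(config):
    """Execute the full workflow; returns a dict of output paths + results."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}

    t = _stage("ingest")
    db = read_genotype_table(
        config.reference, dialect=config.dialect,
        localities_csv=config.localities_csv,
    )
    queries = None
    if config.queries:
        queries = read_genotype_table(config.queries, dialect=config.dialect)
        if not isinstance(queries, list):
            queries = queries.individuals
    _done("ingest", t)

    t = _stage("filter")
    dupes = find_duplicates(db.individuals)
    relatives = find_first_order_relatives(db.individuals)
    filter_df = pd.DataFrame(
        [{"kind": "duplicate", "id_1": a, "id_2": b} for a, b in dupes]
        + [{"kind": "first-order-relative", "id_1": a, "id_2": b}
           for a, b in relatives]
    )
    filter_path = out / "filter_report.csv"
    filter_df.to_csv(filter_path, index=False)
    results["filter_report"] = filter_path
    _done("filter", t)

    t = _stage("sumstats")
    per_locus, per_pop = summary_table(db)
    per_locus.to_csv(out / "sumstats_per_locus.csv", index=False)
    per_pop.to_csv(out / "sumstats_populations.csv", index=False)
    hwe = hwe_matrix(db, chain_length=config.hwe_chain_length, seed=config.seed)
    hwe.to_csv(out / "hwe_pvalues.csv")
    results["sumstats"] = out / "sumstats_populations.csv"
    _done("sumstats", t)

    if config.run_clustering:
        t = _stage("clustering")
        lo, hi = config.k_range
        runs_by_k = {}
        for k in range(lo, hi + 1):
            runs_by_k[k] = [
                admixture_gibbs(
                    db, k,
                    iterations=config.iterations, burnin=config.burnin,
                    seed=config.seed * 10_000 + k * 100 + r,
                    correlated_freqs=config.correlated_freqs,
                    locprior=config.locprior,
                )
                for r in range(config.runs_per_k)
            ]
        evanno = evanno_delta_k(runs_by_k)
        evanno.table.to_csv(out / "evanno.csv", index=False)
        best_k = evanno.best_k
        aligned, _ = align_runs(runs_by_k[best_k])
        mean_q = sum(r.Q for r in aligned) / len(aligned)
        rep = aligned[0]
        rep_mean = type(rep)(
            K=rep.K, Q=mean_q, P=rep.P, lnP_data=rep.lnP_data,
            seed=rep.seed, iterations=rep.iterations, burnin=rep.burnin,
            individual_ids=rep.individual_ids,
            allele_labels=rep.allele_labels,
        )
        cmap = localities_to_clusters(rep_mean, db)
        pd.DataFrame(
            sorted(cmap.items()), columns=["locality", "cluster"]
        ).to_csv(out / "locality_clusters.csv", index=False)
        q_df = pd.DataFrame(
            mean_q, index=rep.individual_ids,
            columns=[f"Q{k + 1}" for k in range(best_k)],
        )
        q_df.to_csv(out / "membership_Q.csv")
        results["best_k"] = best_k
        results["evanno"] = out / "evanno.csv"
        _done("clustering", t)
    else:
        cmap = config.cluster_map
        best_k = len(set(cmap.values()))
    db = db.with_clusters(cmap)
    results["cluster_map"] = cmap

    t = _stage("validate")
    reports = {}
    for level in ("locality", "cluster"):
        rep = leave_one_out_validation(
            db, grouping=level, threshold_percent=config.threshold_percent,
        )
        rep.per_individual.to_csv(
            out / f"validation_{level}_individuals.csv", index=False
        )
        rep.confusion.to_csv(out / f"validation_{level}_confusion.csv")
        reports[level] = rep
    summary = pd.DataFrame([
        dict(grouping=lvl, n_reference=r.n_reference,
             percent_correct=round(r.percent_correct, 2),
             quality_index=round(r.quality_index, 2))
        for lvl, r in reports.items()
    ])
    summary.to_csv(out / "validation_summary.csv", index=False)
    results["validation"] = reports
    _done("validate", t)

    if queries:
        t = _stage("assign")
        table = assign_batch(
            queries, db,
            grouping_levels=("locality", "cluster"),
            threshold_percent=config.threshold_percent,
            with_exclusion=config.exclusion,
            n_sim=config.exclusion_n_sim,
            seed=config.seed,
        )
        table.to_csv(out / "assignments.csv", index=False)
        results["assignments"] = out / "assignments.csv"
        _done("assign", t)

    manifest = {
        "package": "strassign",
        "version": _version(),
        "config": _jsonable(asdict(config)),
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(asdict(config)), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = out / "manifest.json"
    return results


def _version():
    from . import __version__
    return __version__


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
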