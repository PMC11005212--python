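"""End-to-end orchestration: simulate -> phenotype -> DE -> classify -> enrich.

A run is driven by a :class:`RunConfig` (loadable from a YAML file, with CLI
overrides) and leaves a ``manifest.json`` recording the tool version, config
hash, seed and per-stage row counts; deterministic stages are bit-identical
across reruns with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .classify import classify_trio, profile_summary
from .enrich import AnnotationMap, enrich, read_gmt, write_gmt
from .expression import DEThresholds, de_test, size_factors
from .phenotype import heterosis_report, tolerance_report
from .simulate import (
    PhenoSimConfig,
    TrioSimConfig,
    config_to_dict,
    simulate_annotation,
    simulate_phenotypes,
    simulate_trio_counts,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "phenotype", "de", "classify", "enrich")


@dataclass
class RunConfig:
    outdir: str = "heterosim_run"
    seed: int = 0
    stages: tuple = STAGES
    # thresholds
    min_fold_change: float = 2.0
    max_fdr: float = 0.05
    alpha: float = 0.05
    grade_inner: float = 1.0
    grade_outer: float = 1.64
    universe: str = "deg"
    condition: str = "stress"
    maternal_id: str = "maternal"
    paternal_id: str = "paternal"
    # simulation settings (ignored when explicit inputs are given)
    pheno_sim: dict = field(default_factory=dict)
    trio_sim: dict = field(default_factory=dict)
    annotation_terms: int = 50
    # optional pre-existing inputs
    phenotype_table: str | None = None
    counts: str | None = None
    sample_sheet: str | None = None
    gmt: str | None = None

    def validate(self) -> None:
        if not 0 < self.max_fdr <= 1 or not 0 < self.alpha < 1:
            raise ValueError("FDR/alpha thresholds must lie in (0, 1)")
        if self.min_fold_change < 1:
            raise ValueError("min_fold_change must be >= 1")
        if self.grade_inner <= 0 or self.grade_outer <= self.grade_inner:
            raise ValueError("grade multipliers must satisfy 0 < inner < outer")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir")  # where results go does not change what they are
        blob = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dict."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    manifest: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    thresholds = DEThresholds(cfg.min_fold_change, cfg.max_fdr)
    state: dict = {}

    def record(stage: str, t0: float, **counts):
        manifest["stages"][stage] = {
            "completed": True,
            "seconds": round(time.monotonic() - t0, 3),
            **counts,
        }
        log.info("stage %s done in %.2fs", stage, manifest["stages"][stage]["seconds"])

    if "simulate" in cfg.stages:
        t0 = time.monotonic()
        pheno_cfg = PhenoSimConfig(**{"seed": cfg.seed, **cfg.pheno_sim})
        table, pheno_truth = simulate_phenotypes(pheno_cfg)
        trio_cfg = TrioSimConfig(**{"seed": cfg.seed, **cfg.trio_sim})
        counts, samples, trio_truth = simulate_trio_counts(trio_cfg)
        io.write_table(table, outdir / "phenotypes.csv", meta=meta, index=False)
        io.write_table(pheno_truth, outdir / "phenotype_truth.csv", meta=meta, index=False)
        io.write_table(counts, outdir / "counts.tsv", sep="\t", meta=meta)
        io.write_table(samples, outdir / "samples.tsv", sep="\t", meta=meta, index=False)
        io.write_table(trio_truth, outdir / "trio_truth.csv", meta=meta, index=False)
        with open(outdir / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(
                {"phenotype": config_to_dict(pheno_cfg), "trio": config_to_dict(trio_cfg)},
                fh,
            )
        state.update(pheno_table=table, counts=counts, samples=samples)
        record("simulate", t0, phenotype_rows=len(table), genes=len(counts),
               samples=len(samples))

    def get_pheno():
        if "pheno_table" in state:
            return state["pheno_table"]
        if cfg.phenotype_table is None:
            raise ValueError("phenotype stage needs a table (simulate or input path)")
        return io.read_phenotypes(cfg.phenotype_table)

    def get_counts():
        if "counts" in state:
            return state["counts"], state["samples"]
        if cfg.counts is None or cfg.sample_sheet is None:
            raise ValueError("expression stages need counts + sample sheet")
        counts = io.read_counts(cfg.counts)
        samples = io.read_sample_sheet(cfg.sample_sheet, counts)
        return counts, samples

    if "phenotype" in cfg.stages:
        t0 = time.monotonic()
        table = get_pheno()
        tol = tolerance_report(
            table, cfg.maternal_id, cfg.paternal_id, cfg.grade_inner, cfg.grade_outer
        )
        het = heterosis_report(table, cfg.maternal_id, cfg.paternal_id)
        io.write_table(tol, outdir / "tolerance_report.csv", meta=meta)
        io.write_table(het, outdir / "heterosis_report.csv", meta=meta)
        record("phenotype", t0, lines=len(tol), traits=len(het))

    if "de" in cfg.stages:
        t0 = time.monotonic()
        counts, samples = get_counts()
        cond = samples[samples["condition"] == cfg.condition]
        n_contrasts = 0
        for role_a, role_b in (
            ("hybrid", "maternal"),
            ("hybrid", "paternal"),
            ("maternal", "paternal"),
        ):
            a = cond.loc[cond["role"] == role_a, "sample_id"].tolist()
            b = cond.loc[cond["role"] == role_b, "sample_id"].tolist()
            if len(a) < 2 or len(b) < 2:
                raise ValueError(
                    f"missing replicates for role {role_a if len(a) < 2 else role_b!r}"
                )
            used = cond["sample_id"].tolist()
            res = de_test(
                counts[used], a, b, size_factors(counts[used]), thresholds
            )
            name = f"de_{role_a}_vs_{role_b}_{cfg.condition}.tsv"
            io.write_table(res, outdir / name, sep="\t", meta=meta)
            n_contrasts += 1
        record("de", t0, contrasts=n_contrasts, genes=len(counts))

    if "classify" in cfg.stages:
        t0 = time.monotonic()
        counts, samples = get_counts()
        roles = set(samples.loc[samples["condition"] == cfg.condition, "role"])
        missing = io.ROLES - roles
        if missing:
            raise ValueError(f"sample sheet missing roles {sorted(missing)}")
        assignments = classify_trio(
            counts, samples, cfg.condition, cfg.alpha, cfg.universe, thresholds
        )
        summary = profile_summary(assignments)
        io.write_table(assignments, outdir / "profile_assignments.tsv", sep="\t", meta=meta)
        summary_df = pd.DataFrame(
            sorted(summary["profile_counts"].items()), columns=["profile", "n_genes"]
        )
        io.write_table(summary_df, outdir / "profile_summary.tsv", sep="\t", meta=meta, index=False)
        state["assignments"] = assignments
        record(
            "classify", t0, genes=len(assignments),
            non_additive=summary["non_additive"],
            universe=summary["universe_size"],
            non_additive_pct=round(summary["non_additive_pct"], 2),
        )

    if "enrich" in cfg.stages:
        t0 = time.monotonic()
        if "assignments" not in state:
            raise ValueError("enrich stage needs the classify stage in the same run")
        assignments = state["assignments"]
        gene_list = list(assignments.index[assignments["profile"] == "P5"])
        if cfg.gmt is not None:
            terms = read_gmt(cfg.gmt)
        else:
            terms = simulate_annotation(
                assignments.index,
                n_terms=cfg.annotation_terms,
                enriched_in=gene_list or None,
                n_enriched_terms=3 if gene_list else 0,
                seed=cfg.seed,
            )
            write_gmt(terms, outdir / "annotation.gmt")
        table = enrich(gene_list, AnnotationMap(terms), cfg.max_fdr)
        io.write_table(table, outdir / "enrichment.tsv", sep="\t", meta=meta)
        record("enrich", t0, list_size=len(gene_list), terms=len(table),
               enriched=int(table["enriched"].sum()) if len(table) else 0)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
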