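"""End-to-end orchestration: simulate/ingest -> demographics -> network ->
hubs -> SNP association -> edge validation, driven by one declarative
configuration with a single master seed.

All randomness flows from the master seed through named child streams
(simulation, splits, validation), which are echoed into the run
metadata so a rerun with the same configuration is bit-identical apart
from timestamps.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .association import association_table, validate_edge
from .epi import epi_report
from .ingest import (
    GenotypeMatrix,
    SnpGeneMap,
    compute_gene_scores,
    read_genotypes,
    read_snp_gene_map,
)
from .jdinac import JdinacConfig, build_network, jdinac_importance
from .simulate import PlantedEdge, SimConfig, simulate_cohort, study_like_config

log = logging.getLogger("snpdiffnet")

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    Exactly one of ``simulation`` (a SimConfig, or None with
    ``use_study_like=True``) and ``genotypes_path`` must be given.
    ``scenarios`` lists covariate-adjustment sets; one network is
    inferred per scenario.
    """

    out_dir: Path
    simulation: SimConfig | None = None
    use_study_like: bool = False
    genotypes_path: Path | None = None
    snp_map_path: Path | None = None
    dialect: str = "delimited"
    sample_table: Path | None = None
    covariates: list[str] = field(default_factory=list)
    epi_bins: dict[str, list[float]] = field(default_factory=dict)
    scenarios: list[list[str]] | None = None
    jdinac: JdinacConfig = field(default_factory=JdinacConfig)
    missing_policy: str = "per_snp_mean_impute"
    association_genes: str | list[str] = "hubs"
    bh_correct: bool = False
    master_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        has_sim = self.simulation is not None or self.use_study_like
        has_files = self.genotypes_path is not None
        if has_sim == has_files:
            raise ValueError(
                "exactly one of a simulation block and input paths must be configured"
            )
        if has_files:
            for p in (self.genotypes_path, self.snp_map_path, self.sample_table):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)
            if self.snp_map_path is None:
                raise ValueError("input-path runs need a SNP-gene map")


def _seed_streams(master_seed: int, names: Sequence[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master_seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw: dict[str, Any] = yaml.safe_load(fh)
    sim_cfg = None
    use_study_like = False
    if "simulate" in raw:
        block = raw["simulate"] or {}
        if block.get("study_like", False):
            use_study_like = True
        else:
            if "planted_edges" in block:
                block["planted_edges"] = [PlantedEdge(*e) for e in block["planted_edges"]]
            sim_cfg = SimConfig(**{k: v for k, v in block.items() if k != "study_like"})
    jd = JdinacConfig(**raw.get("jdinac", {}))
    return RunConfig(
        out_dir=Path(raw["out_dir"]),
        simulation=sim_cfg,
        use_study_like=use_study_like,
        genotypes_path=Path(raw["genotypes"]) if "genotypes" in raw else None,
        snp_map_path=Path(raw["snp_map"]) if "snp_map" in raw else None,
        dialect=raw.get("dialect", "delimited"),
        sample_table=Path(raw["sample_table"]) if "sample_table" in raw else None,
        covariates=list(raw.get("covariates", [])),
        epi_bins={k: list(v) for k, v in raw.get("epi_bins", {}).items()},
        scenarios=[list(s) for s in raw["scenarios"]] if "scenarios" in raw else None,
        missing_policy=raw.get("missing_policy", "per_snp_mean_impute"),
        association_genes=raw.get("association_genes", "hubs"),
        bh_correct=bool(raw.get("bh_correct", False)),
        master_seed=int(raw.get("seed", 0)),
        jdinac=jd,
        log_level=raw.get("log_level", "INFO"),
    )


def _scenario_tag(names: Sequence[str]) -> str:
    return "none" if not names else "+".join(names)


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full analysis; returns a manifest of artifact paths.

    Stages: cohort (simulated or read) -> demographic chi-square report
    -> gene scores -> one JDINAC network per covariate scenario (with
    hub list) -> per-SNP association in hub genes -> split-sample
    validation of every retained edge.
    """
    logging.basicConfig(level=cfg.log_level)
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seed_streams(cfg.master_seed, ["simulate", "jdinac", "validate"])
    manifest: dict[str, Any] = {"out_dir": str(out)}

    # --- stage: cohort ---------------------------------------------------
    try:
        if cfg.genotypes_path is not None:
            genotypes = read_genotypes(
                cfg.genotypes_path,
                dialect=cfg.dialect,  # type: ignore[arg-type]
                sample_table=cfg.sample_table,
                covariates=cfg.covariates or None,
            )
            snp_map = read_snp_gene_map(cfg.snp_map_path)
            truth = None
        else:
            sim = cfg.simulation or study_like_config(seed=seeds["simulate"])
            genotypes, truth = simulate_cohort(sim)
            snp_map = sim.snp_gene_map()
            genotypes.write(out / "genotypes.tsv")
            snp_map.write(out / "snp_gene_map.tsv")
            truth.write(out / "truth_edges.tsv")
            manifest["genotypes"] = str(out / "genotypes.tsv")
    except Exception as err:
        raise RuntimeError(f"stage 'cohort' failed: {err}") from err

    # --- stage: demographics ---------------------------------------------
    try:
        if len(genotypes.covariates.columns):
            bins = {k: v for k, v in cfg.epi_bins.items()}
            report = epi_report(genotypes.covariates, genotypes.y, bins=bins)
            report.to_csv(out / "epi_report.tsv", sep="\t", index=False)
            manifest["epi_report"] = str(out / "epi_report.tsv")
    except Exception as err:
        raise RuntimeError(f"stage 'demographics' failed: {err}") from err

    # --- stage: gene scores ----------------------------------------------
    try:
        scores = compute_gene_scores(genotypes, snp_map, cfg.missing_policy)  # type: ignore[arg-type]
        scores.write(out / "gene_scores.tsv")
        manifest["gene_scores"] = str(out / "gene_scores.tsv")
    except Exception as err:
        raise RuntimeError(f"stage 'gene_scores' failed: {err}") from err

    # --- stage: networks (one per covariate scenario) ---------------------
    scenarios = cfg.scenarios if cfg.scenarios is not None else [list(cfg.covariates)]
    all_edges: set[tuple[str, str]] = set()
    hubs_union: list[str] = []
    jd = cfg.jdinac
    try:
        networks = {}
        for scen in scenarios:
            tag = _scenario_tag(scen)
            log.info("network scenario: %s", tag)
            Z = genotypes.covariate_matrix(scen) if scen else None
            scen_cfg = JdinacConfig(**{**asdict_shallow(jd), "seed": seeds["jdinac"]})
            imp = jdinac_importance(scores, genotypes.y, Z, scen_cfg)
            imp.write(out / f"importance_{tag}.tsv")
            net = build_network(imp, scen_cfg.effective_min_score)
            net.min_hub_degree = scen_cfg.min_hub_degree
            net.write_sif(out / f"network_{tag}.sif")
            net.write_graphml(out / f"network_{tag}.graphml")
            (out / f"hubs_{tag}.txt").write_text("\n".join(net.hubs) + "\n")
            networks[tag] = net
            all_edges |= {(a, b) for a, b, _ in net.edges}
            hubs_union += [h for h in net.hubs if h not in hubs_union]
        manifest["networks"] = {t: str(out / f"network_{t}.sif") for t in networks}
        manifest["hubs"] = {t: networks[t].hubs for t in networks}
    except Exception as err:
        raise RuntimeError(f"stage 'network' failed: {err}") from err

    # --- stage: association ----------------------------------------------
    try:
        if cfg.association_genes == "hubs":
            genes: Sequence[str] | None = hubs_union or None
        elif cfg.association_genes == "all":
            genes = None
        else:
            genes = list(cfg.association_genes)
        assoc = association_table(
            genotypes, snp_map, covariates=cfg.covariates or None,
            genes=genes, bh_correct=cfg.bh_correct,
        )
        assoc.to_csv(out / "association.tsv", sep="\t", index=False)
        manifest["association"] = str(out / "association.tsv")
    except Exception as err:
        raise RuntimeError(f"stage 'association' failed: {err}") from err

    # --- stage: edge validation -------------------------------------------
    try:
        rows = []
        for a, b in sorted(all_edges):
            res = validate_edge(
                scores.column(a), scores.column(b), genotypes.y,
                seed=seeds["validate"], gene_i=a, gene_j=b,
            )
            rows.append({"gene1": a, "gene2": b, "p": res.p})
        import pandas as pd

        pd.DataFrame(rows, columns=["gene1", "gene2", "p"]).to_csv(
            out / "edge_validation.tsv", sep="\t", index=False
        )
        manifest["edge_validation"] = str(out / "edge_validation.tsv")
    except Exception as err:
        raise RuntimeError(f"stage 'edge_validation' failed: {err}") from err

    # --- run metadata -----------------------------------------------------
    meta = {
        "version": __version__,
        "timestamp": datetime.datetime.now().isoformat(),
        "master_seed": cfg.master_seed,
        "stream_seeds": seeds,
        "scenarios": [list(s) for s in scenarios],
        "jdinac": asdict_shallow(jd),
        "bandwidth_rule": "per-dimension Silverman (sigma * n^(-1/6)), product Gaussian kernel",
        "missing_policy": cfg.missing_policy,
    }
    with open(out / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, default=str)
    manifest["metadata"] = str(out / "run_metadata.json")
    return manifest


def asdict_shallow(obj: Any) -> dict[str, Any]:
    """dataclasses.asdict without deep-copying nested arrays."""
    return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
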