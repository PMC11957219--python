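"""Pipeline orchestration: simulate → score → QC → models from one config.

A run executes the enabled stages in dependency order, writes each stage's
table under the output directory, and records a manifest (seed, package
version, row counts).  One global seed deterministically derives per-stage
substreams (see :mod:`cnvsleep.simulate`), so re-running a single stage from
cached upstream outputs is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, assoc, io, mediation, qc, ushape
from .burden import burden_scores
from .simulate import SimConfig, simulate_cohort

STAGES = ("simulate", "burden", "qc", "ushape", "scan", "stratified", "mediate")

SCAN_PHENOTYPES = (
    "cognition", "trail_making", "tower",
    "sleep_selfreport", "sleep_accel", "sleep_efficiency", "probable_insomnia",
)


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    stages: tuple = STAGES
    sim: dict = field(default_factory=dict)
    covariates: tuple = tuple(assoc.DEFAULT_COVARIATES)
    sleep_covariates: tuple = ("age", *[f"pc{i}" for i in range(1, 11)])
    alpha: float = 0.05
    n_boot: int = 1000
    drop_medication: bool = False
    drop_over65: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "seed" not in raw:
            raise ValueError("seed is mandatory in pipeline mode")
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("config enables no stages")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


def run(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": int(config.seed),
        "stages": list(config.stages),
        "rows": {},
    }
    enabled = set(config.stages)

    def _require(stage: str, path: Path) -> None:
        if not path.exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs missing upstream output {path.name}; "
                f"enable the producing stage or provide the file"
            )

    sim = None
    if "simulate" in enabled:
        sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
        sim = simulate_cohort(sim_cfg)
        io.write_gene_model(sim.genes, out / "genes.bed", out / "loeuf.tsv")
        io.write_cnv_calls(sim.calls, out / "cnv_calls.tsv")
        io.write_loci(sim.loci, out / "recurrent_loci.tsv")
        io.write_phenotypes(sim.cohort, out / "phenotypes.tsv")
        manifest["rows"]["simulate"] = int(len(sim.cohort))
        manifest["sim_config"] = sim_cfg.to_dict()

    if "burden" in enabled:
        if sim is not None:
            burden = sim.burden
        else:
            from .burden import read_gene_model

            for f in ("genes.bed", "loeuf.tsv", "cnv_calls.tsv", "phenotypes.tsv"):
                _require("burden", out / f)
            genes = read_gene_model(out / "genes.bed", out / "loeuf.tsv")
            calls = io.read_cnv_calls(out / "cnv_calls.tsv")
            ids = io.read_phenotypes(out / "phenotypes.tsv")["individual_id"]
            burden = burden_scores(calls, genes, individual_ids=ids)
        io.write_table(burden, out / "burden.tsv")
        manifest["rows"]["burden"] = int(len(burden))

    cohort = burden_tbl = None

    def _load_cohort(stage: str) -> pd.DataFrame:
        nonlocal cohort
        if cohort is None:
            _require(stage, out / "phenotypes_qc.tsv")
            cohort = io.read_phenotypes(out / "phenotypes_qc.tsv")
        return cohort

    def _load_burden(stage: str) -> pd.DataFrame:
        nonlocal burden_tbl
        if burden_tbl is None:
            _require(stage, out / "burden.tsv")
            burden_tbl = pd.read_csv(out / "burden.tsv", sep="\t",
                                     dtype={"individual_id": str})
        return burden_tbl

    if "qc" in enabled:
        _require("qc", out / "phenotypes.tsv")
        raw = io.read_phenotypes(out / "phenotypes.tsv")
        cohort, report = qc.apply_qc(
            raw,
            drop_medication=config.drop_medication,
            drop_over65=config.drop_over65,
        )
        io.write_phenotypes(cohort, out / "phenotypes_qc.tsv")
        qc.write_qc_report(report, out / "qc_report.json")
        manifest["rows"]["qc"] = int(len(cohort))

    if "ushape" in enabled:
        coh = _load_cohort("ushape")
        bur = _load_burden("ushape")
        merged = coh.merge(bur, on="individual_id")
        rows = []
        pairs = [
            ("sleep_selfreport", "cognition", list(config.sleep_covariates)),
            ("sleep_selfreport", "del_sum_inv_loeuf", list(config.sleep_covariates)),
            ("sleep_selfreport", "dup_sum_inv_loeuf", list(config.sleep_covariates)),
        ]
        for exposure, outcome, covs in pairs:
            lin, quad, lrt = ushape.fit_linear_quadratic(
                merged[exposure], merged[outcome],
                covariates=merged[covs], alpha=config.alpha,
            )
            rows.append(
                {
                    "exposure": exposure, "outcome": outcome, "n": quad.n,
                    "A": quad.A, "B": quad.B, "A_p": quad.A_p,
                    "linear_slope": lin.slope, "linear_p": lin.slope_p,
                    "lrt_stat": lrt.statistic, "lrt_p": lrt.p_value,
                    "preferred": lrt.preferred_model,
                    "vertex": quad.vertex if quad.vertex_defined else float("nan"),
                    "adj_r2_linear": lin.adj_r2, "adj_r2_quadratic": quad.adj_r2,
                }
            )
        tbl = pd.DataFrame(rows)
        io.write_table(tbl, out / "ushape.tsv")
        manifest["rows"]["ushape"] = int(len(tbl))

    if "scan" in enabled:
        coh = _load_cohort("scan")
        _require("scan", out / "recurrent_loci.tsv")
        _require("scan", out / "cnv_calls.tsv")
        loci = io.read_loci(out / "recurrent_loci.tsv")
        calls = io.read_cnv_calls(out / "cnv_calls.tsv")
        carriers = assoc.carrier_status(calls, loci, coh["individual_id"])
        phens = [p for p in SCAN_PHENOTYPES if p in coh.columns]
        res = assoc.scan_loci(
            coh, carriers, loci, phens, covariates=list(config.covariates)
        )
        io.write_table(res, out / "scan.tsv")
        manifest["rows"]["scan"] = int(len(res))

    if "stratified" in enabled:
        coh = _load_cohort("stratified")
        bur = _load_burden("stratified")
        phens = [p for p in ("cognition", "trail_making", "tower", "sleep_selfreport")
                 if p in coh.columns]
        res = assoc.stratified_scan(
            coh, bur, phens, covariates=list(config.covariates)
        )
        io.write_table(res, out / "stratified.tsv")
        manifest["rows"]["stratified"] = int(len(res))

    if "mediate" in enabled:
        coh = _load_cohort("mediate")
        bur = _load_burden("mediate")
        results = {}
        for cnv_type in ("DEL", "DUP"):
            res = mediation.mediate_burden_sleep_cognition(
                coh, bur, cnv_type,
                covariates=list(config.covariates),
                n_boot=config.n_boot, seed=config.seed,
            )
            results[cnv_type] = res.to_dict()
        with open(out / "mediation.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
        manifest["rows"]["mediate"] = len(results)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
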