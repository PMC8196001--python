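"""Configuration-driven orchestration of the full analysis.

Stage order mirrors the analysis flow: simulate -> table1 -> gwas ->
conditional -> finemap -> h2 -> abn -> mr -> meta -> power. Each stage
declares its input files; a stage is skipped on re-run when the SHA-256
digest of its configuration block plus input-file digests is unchanged and
its recorded outputs still verify. The manifest records the config snapshot,
seeds, package version, file digests, realized simulation truth, and
per-stage wall time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, abn, assoc, cohort_stats, finemap, genio, heritability, mr, simdata

logger = logging.getLogger("bilicausal.pipeline")

STAGES = ("simulate", "table1", "gwas", "conditional", "finemap", "h2",
          "abn", "mr", "meta", "power")

#: stage -> (input files, output files); paths relative to out_dir
STAGE_FILES = {
    "simulate": ([], ["cohort.vcf", "pheno.tsv", "truth.json"]),
    "table1": (["pheno.tsv"], ["table1.tsv"]),
    "gwas": (["cohort.vcf", "pheno.tsv"], ["sumstats.tsv", "gwas.json", "pcs.tsv"]),
    "conditional": (["cohort.vcf", "pheno.tsv", "gwas.json", "pcs.tsv"],
                    ["cond_sumstats.tsv", "conditional.json"]),
    "finemap": (["cohort.vcf", "sumstats.tsv", "gwas.json"], ["pip.tsv", "finemap.json"]),
    "h2": (["cohort.vcf", "pheno.tsv"], ["h2.json"]),
    "abn": (["cohort.vcf", "pheno.tsv", "gwas.json"], ["net.json", "net.dot"]),
    "mr": (["cohort.vcf", "pheno.tsv", "gwas.json", "pcs.tsv"], ["mr.json"]),
    "meta": (["mr.json"], ["meta.json"]),
    "power": (["mr.json", "truth.json"], ["power.json"]),
}

DEFAULT_CONFIG: dict = {
    "stages": list(STAGES),
    "seed": 42,
    "simulate": {"n_samples": 1500, "n_variants": 5000, "causal_index": 2500},
    "gwas": {"maf_min": 0.01, "info_min": 0.3, "pc_alpha": 0.05},
    "finemap": {"region_halfwidth_bp": 250_000, "max_causal": 1, "maf_min": 0.01},
    "h2": {"maf_min": 0.05, "window_bp": 1_000_000},
    "abn": {"n_searches": 200, "threshold": 0.5, "max_parents": 4},
    "mr": {"n_pcs": 3},
    "power": {"alpha": 0.05},
}


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: dict = dataclasses.field(default_factory=dict)
    truth: dict = dataclasses.field(default_factory=dict)
    recomputed: list = dataclasses.field(default_factory=list)
    skipped: list = dataclasses.field(default_factory=list)

    def save(self, path: Path) -> None:
        payload = dataclasses.asdict(self)
        path.write_text(json.dumps(payload, indent=2, default=str))

    @property
    def total_wall_time(self) -> float:
        return sum(s.get("wall_time", 0.0) for s in self.stages.values())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_digest(stage_cfg: dict, seed: int, input_paths: list[Path]) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(stage_cfg, sort_keys=True, default=str).encode())
    h.update(str(seed).encode())
    for p in input_paths:
        h.update(_sha256(p).encode())
    return h.hexdigest()


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def validate_config(cfg: dict) -> None:
    """Check stage names and dependency availability before any computation."""
    stages = cfg.get("stages", [])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {', '.join(unknown)}")
    produced = set()
    for s in STAGES:
        if s not in stages:
            continue
        inputs, outputs = STAGE_FILES[s]
        missing = [f for f in inputs if f not in produced]
        if missing:
            raise ValueError(
                f"stage {s!r} requires input(s) {missing} not produced by any "
                "earlier requested stage"
            )
        produced.update(outputs)


# --- stage implementations -------------------------------------------------

def _load_cohort(out: Path):
    g = genio.read_vcf(str(out / "cohort.vcf"))
    p = genio.read_phenotypes(str(out / "pheno.tsv")).aligned_to(g.samples)
    return g, p


def _stage_simulate(cfg, seed, out: Path):
    sim_cfg = simdata.SimConfig(**cfg["simulate"], seed=seed)
    cohort = simdata.simulate_cohort(sim_cfg)
    genio.write_vcf(cohort.genotypes, str(out / "cohort.vcf"))
    genio.write_phenotypes(cohort.phenotypes, str(out / "pheno.tsv"))
    (out / "truth.json").write_text(json.dumps(cohort.truth, indent=2, default=str))
    return cohort.truth


def _stage_table1(cfg, seed, out: Path):
    pheno = genio.read_phenotypes(str(out / "pheno.tsv"))
    tbl = cohort_stats.table1(pheno.df, group="sex")
    tbl.to_csv(out / "table1.tsv", sep="\t", index=False)


def _stage_gwas(cfg, seed, out: Path):
    g, p = _load_cohort(out)
    gc = cfg["gwas"]
    g = genio.filter_variants(g, maf_min=gc["maf_min"], info_min=gc["info_min"])
    y = assoc.prepare_trait(p.df, trait="bilirubin")
    k = assoc.kinship(g)
    pcs, n_pcs = assoc.significant_pcs(g, alpha=gc["pc_alpha"], k=k)
    covs = [np.ones(g.n_samples), p.df["bmi"].to_numpy(float), p.df["t2d"].to_numpy(float)]
    if n_pcs:
        covs.append(pcs)
    c = np.column_stack(covs)
    res = assoc.lmm_assoc(g, y, c, k)
    genio.write_summary_stats(res.df.drop(columns=["collinear"]), str(out / "sumstats.tsv"))
    pcs_df = pd.DataFrame({"sample_id": g.samples})
    for i in range(n_pcs):
        pcs_df[f"pc{i+1}"] = pcs[:, i]
    pcs_df.to_csv(out / "pcs.tsv", sep="\t", index=False)
    top = res.df.loc[res.df["p"].idxmin()]
    (out / "gwas.json").write_text(json.dumps({
        "lambda_gc": res.lambda_gc,
        "h2_null": res.h2_null,
        "n_pcs": n_pcs,
        "n_variants": int(len(res.df)),
        "top_variant": str(top["id"]),
        "top_beta": float(top["beta"]),
        "top_se": float(top["se"]),
        "top_p": float(top["p"]),
    }, indent=2))


def _stage_conditional(cfg, seed, out: Path):
    g, p = _load_cohort(out)
    gc = cfg["gwas"]
    g = genio.filter_variants(g, maf_min=gc["maf_min"], info_min=gc["info_min"])
    meta = json.loads((out / "gwas.json").read_text())
    y = assoc.prepare_trait(p.df, trait="bilirubin")
    k = assoc.kinship(g)
    pcs = pd.read_csv(out / "pcs.tsv", sep="\t").drop(columns=["sample_id"])
    covs = [np.ones(g.n_samples), p.df["bmi"].to_numpy(float), p.df["t2d"].to_numpy(float)]
    if len(pcs.columns):
        covs.append(pcs.to_numpy(float))
    c = np.column_stack(covs)
    res = assoc.conditional_scan(g, y, c, k, condition_on=meta["top_variant"])
    genio.write_summary_stats(res.df.drop(columns=["collinear"]), str(out / "cond_sumstats.tsv"))
    remaining = res.df["p"].dropna()
    (out / "conditional.json").write_text(json.dumps({
        "conditioned_on": meta["top_variant"],
        "min_p_remaining": float(remaining.min()),
        "n_genome_wide_remaining": int((remaining < assoc.GENOME_WIDE_P).sum()),
    }, indent=2))


def _stage_finemap(cfg, seed, out: Path):
    g, _ = _load_cohort(out)
    fc = cfg["finemap"]
    sumstats = genio.read_summary_stats(str(out / "sumstats.tsv"))
    meta = json.loads((out / "gwas.json").read_text())
    top = sumstats.loc[sumstats["id"] == meta["top_variant"]].iloc[0]
    half = fc["region_halfwidth_bp"]
    region = sumstats[(sumstats["chrom"].astype(str) == str(top["chrom"]))
                      & (sumstats["pos"].between(top["pos"] - half, top["pos"] + half))]
    stats_ = finemap.region_stats_from_assoc(region, g, region["id"],
                                             maf_min=fc["maf_min"])
    res = finemap.pip(stats_, max_causal=fc["max_causal"])
    res.df.to_csv(out / "pip.tsv", sep="\t", index=False, float_format="%.17g")
    best = res.df.loc[res.df["pip"].idxmax()]
    (out / "finemap.json").write_text(json.dumps({
        "region_variants": int(len(res.df)),
        "top_pip_variant": str(best["id"]),
        "top_pip": float(best["pip"]),
        "p_null": float(np.exp(res.log_posterior_null)),
    }, indent=2))


def _stage_h2(cfg, seed, out: Path):
    g, p = _load_cohort(out)
    hc = cfg["h2"]
    vc = heritability.h2_pipeline(g, p.df, maf_min=hc["maf_min"],
                                  window_bp=hc["window_bp"])
    (out / "h2.json").write_text(json.dumps({
        "h2_snp": vc.h2_snp, "se_h2": vc.se_h2,
        "sigma_g2": vc.sigma_g2, "sigma_e2": vc.sigma_e2,
        "loglik": vc.loglik, "boundary": vc.boundary,
    }, indent=2))


def _stage_abn(cfg, seed, out: Path):
    g, p = _load_cohort(out)
    ac = cfg["abn"]
    meta = json.loads((out / "gwas.json").read_text())
    dosage = g.dosage[:, g.index_of(meta["top_variant"])]
    data = pd.DataFrame({
        "variant": dosage,
        "bilirubin": p.df["bilirubin"].to_numpy(float),
        "hypertension": p.df["hypertension"].to_numpy(float),
        "sex": p.df["sex"].to_numpy(float),
        "age": p.df["age"].to_numpy(float),
        "bmi": p.df["bmi"].to_numpy(float),
        "t2d": p.df["t2d"].to_numpy(float),
    })
    specs = [
        abn.NodeSpec("variant", "gaussian", can_have_parents=False),
        abn.NodeSpec("bilirubin", "gaussian"),
        abn.NodeSpec("hypertension", "bernoulli"),
        abn.NodeSpec("sex", "bernoulli", can_have_parents=False),
        abn.NodeSpec("age", "gaussian", can_have_parents=False),
        abn.NodeSpec("bmi", "gaussian"),
        abn.NodeSpec("t2d", "bernoulli"),
    ]
    net = abn.consensus(data, specs, n_searches=ac["n_searches"],
                        threshold=ac["threshold"], seed=seed,
                        max_parents=ac["max_parents"])
    (out / "net.json").write_text(json.dumps({
        "consensus_edges": [list(e) for e in net.consensus_edges],
        "edge_frequency": {f"{p_}->{c}": f for (p_, c), f in net.edge_frequency.items()},
        "best_score": net.best_score,
        "n_searches": ac["n_searches"],
        "threshold": ac["threshold"],
    }, indent=2))
    (out / "net.dot").write_text(abn.to_dot(net.consensus_edges, data.columns))


def _stage_mr(cfg, seed, out: Path):
    g, p = _load_cohort(out)
    mc = cfg["mr"]
    meta = json.loads((out / "gwas.json").read_text())
    z = g.dosage[:, g.index_of(meta["top_variant"])]
    x = p.df["bilirubin"].to_numpy(float)
    x = (x - x.mean()) / x.std()  # causal beta on the per-SD-of-exposure scale
    y = p.df["hypertension"].to_numpy(float)
    pcs = pd.read_csv(out / "pcs.tsv", sep="\t").drop(columns=["sample_id"]).to_numpy(float)
    base = np.column_stack([p.df["sex"], p.df["age"], p.df["bmi"]]).astype(float)
    if pcs.size:
        base = np.column_stack([base, pcs[:, : mc["n_pcs"]]])
    n = len(y)
    half = n // 2
    studies = {}
    for name, sl in (("study1", slice(0, half)), ("study2", slice(half, n))):
        res = mr.mr_study(x[sl], z[sl], y[sl], base[sl], n_boot=0, seed=seed)
        studies[name] = {
            "f_stat": res.f_stat, "r2": res.r2, "beta": res.beta, "se": res.se,
            "ci": list(res.ci), "p": res.p, "n": res.n,
            "exclusion_or": res.exclusion_or, "exclusion_ci": list(res.exclusion_ci),
            "exclusion_p": res.exclusion_p,
        }
    (out / "mr.json").write_text(json.dumps({"instrument": meta["top_variant"],
                                             "studies": studies}, indent=2))


def _stage_meta(cfg, seed, out: Path):
    payload = json.loads((out / "mr.json").read_text())
    studies = payload["studies"]
    res = mr.ivw_meta([s["beta"] for s in studies.values()],
                      [s["se"] for s in studies.values()])
    (out / "meta.json").write_text(json.dumps({
        "beta": res.beta, "se": res.se, "ci": list(res.ci), "p": res.p,
        "weights": res.weights.tolist(), "q": res.q, "i2": res.i2,
    }, indent=2))


def _stage_power(cfg, seed, out: Path):
    payload = json.loads((out / "mr.json").read_text())
    truth = json.loads((out / "truth.json").read_text())
    sim_cfg = truth["config"] if isinstance(truth.get("config"), dict) else {}
    n = sum(s["n"] for s in payload["studies"].values())
    r2 = float(np.mean([s["r2"] for s in payload["studies"].values()]))
    params = mr.PowerParams(
        n=n,
        alpha=cfg["power"]["alpha"],
        prevalence=truth.get("realized_prevalence", 0.26),
        or_per_sd=float(np.exp(sim_cfg.get("log_or_per_sd", np.log(0.46)))),
        r2=r2,
    )
    (out / "power.json").write_text(json.dumps({
        "power": mr.mr_power_binary(params),
        "params": dataclasses.asdict(params),
    }, indent=2))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "table1": _stage_table1,
    "gwas": _stage_gwas,
    "conditional": _stage_conditional,
    "finemap": _stage_finemap,
    "h2": _stage_h2,
    "abn": _stage_abn,
    "mr": _stage_mr,
    "meta": _stage_meta,
    "power": _stage_power,
}


def run_pipeline(config, out_dir=None) -> RunManifest:
    """Execute the requested stages in dependency order with digest caching."""
    cfg = load_config(config)
    validate_config(cfg)
    out = Path(out_dir or cfg.get("out_dir", "pipeline_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 42))

    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text()).get("stages", {})
        except json.JSONDecodeError:
            previous = {}

    manifest = RunManifest(config=cfg, seed=seed, version=__version__)
    if (out / "truth.json").exists():
        manifest.truth = json.loads((out / "truth.json").read_text())

    for stage in STAGES:
        if stage not in cfg["stages"]:
            continue
        inputs, outputs = STAGE_FILES[stage]
        in_paths = [out / f for f in inputs]
        digest = _stage_digest(cfg.get(stage, {}), seed, in_paths)
        prev = previous.get(stage, {})
        out_paths = [out / f for f in outputs]
        cached = (
            prev.get("digest") == digest
            and all(p.exists() for p in out_paths)
            and all(_sha256(p) == prev.get("outputs", {}).get(p.name)
                    for p in out_paths)
        )
        if cached:
            logger.info("stage %s: cached, skipping", stage)
            manifest.skipped.append(stage)
            manifest.stages[stage] = {**prev, "wall_time": 0.0, "cached": True}
            continue
        logger.info("stage %s: running", stage)
        t0 = time.perf_counter()
        try:
            result = _STAGE_FUNCS[stage](cfg, seed, out)
        except Exception:
            manifest.save(manifest_path)
            logger.exception("stage %s failed; partial manifest stored", stage)
            raise
        wall = time.perf_counter() - t0
        if stage == "simulate" and result:
            manifest.truth = result
        manifest.recomputed.append(stage)
        manifest.stages[stage] = {
            "digest": digest,
            "outputs": {p.name: _sha256(p) for p in out_paths},
            "wall_time": wall,
            "cached": False,
        }
        manifest.save(manifest_path)
        logger.info("stage %s: done in %.1fs", stage, wall)

    manifest.save(manifest_path)
    return manifest
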