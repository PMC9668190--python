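"""End-to-end pipeline: simulate -> process reads -> quantify -> test -> report.

One YAML config drives every stage; all randomness flows from the
config's mandatory ``seed`` (per-stage generators are spawned from it), so
a rerun with the same config reproduces byte-identical TSV outputs. Each
run writes a manifest with the config hash, package version, and a
checksum for every artifact.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sexfit import __version__
from sexfit import fitness_stats, quant, readproc, reporting, synthetic_data as sd

STAGES = ("simulate", "process_reads", "quantify", "test", "report")


class ConfigError(ValueError):
    """Raised with the offending field path when a config is invalid."""


def _require(cfg: dict, path: str, typ=None):
    node = cfg
    trail = []
    for key in path.split("."):
        trail.append(key)
        if not isinstance(node, dict) or key not in node:
            raise ConfigError(f"missing config field: {'.'.join(trail)}")
        node = node[key]
    if typ is not None and not isinstance(node, typ):
        raise ConfigError(f"config field {path} must be {typ}")
    return node


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    _require(cfg, "seed", int)
    _require(cfg, "genome")
    _require(cfg, "library")
    return cfg


def build_spec(cfg: dict) -> sd.SimGenomeSpec:
    g = cfg["genome"]
    return sd.SimGenomeSpec(
        chrom_lengths=tuple(g.get("chrom_lengths", (500_000,))),
        n_genes=int(g.get("n_genes", 200)),
        gene_length=tuple(g.get("gene_length", (1_000, 2_000))),
        intergenic_fraction=float(g.get("intergenic_fraction", 0.4)),
        seed=int(cfg["seed"]),
    )


def build_library_config(cfg: dict, seed: int) -> sd.LibrarySimConfig:
    l = cfg["library"]
    return sd.LibrarySimConfig(
        n_clones=int(l.get("n_clones", 10_000)),
        placement=l.get("placement", "uniform"),
        dirichlet_concentration=float(l.get("dirichlet_concentration", 10.0)),
        depth=l.get("depth", 500_000),
        pcr_mean_copies=float(l.get("pcr_mean_copies", 2.0)),
        pcr_model=l.get("pcr_model", "geometric"),
        umi_length=int(l.get("umi_length", 10)),
        linker=l.get("linker", sd.DEFAULT_LINKER),
        hermes_end=l.get("hermes_end", sd.DEFAULT_HERMES_END),
        read_length=int(l.get("read_length", 100)),
        substitution_rate=float(l.get("substitution_rate", 0.0)),
        runs=int(l.get("runs", 1)),
        seed=seed,
    )


def build_effects(
    cfg: dict, annotation: pd.DataFrame, rng: np.random.Generator
) -> list[sd.GeneEffectProfile]:
    """Assign effect classes to genes per config; unassigned genes are
    neutral. Class blocks carry a ``count`` plus class parameters."""
    gene_ids = list(
        annotation.loc[annotation["feature_type"] == "gene", "feature_id"]
    )
    spec = (cfg.get("effects") or {}).get("classes") or {}
    order = rng.permutation(len(gene_ids))
    profiles: dict[str, sd.GeneEffectProfile] = {}
    cursor = 0
    makers = {
        "sex_required": lambda gid, p: sd.GeneEffectProfile.sex_required(
            gid, float(p.get("sex_factor", 0.1))
        ),
        "sex_repressor": lambda gid, p: sd.GeneEffectProfile.sex_repressor(
            gid, float(p.get("sex_factor", 2.0))
        ),
        "growth_advantage": lambda gid, p: sd.GeneEffectProfile.growth_advantage(
            gid, float(p.get("factor", 2.0))
        ),
        "growth_impaired_pre": lambda gid, p: sd.GeneEffectProfile.growth_impaired_pre(
            gid, float(p.get("factor", 0.2))
        ),
        "growth_impaired_post": lambda gid, p: sd.GeneEffectProfile.growth_impaired_post(
            gid, float(p.get("factor", 0.2))
        ),
        "essential": lambda gid, p: sd.GeneEffectProfile.essential(gid),
    }
    for cls, params in spec.items():
        if cls not in makers:
            raise ConfigError(f"effects.classes.{cls}: unknown class")
        count = int(params.get("count", 0))
        for _ in range(count):
            if cursor >= len(gene_ids):
                raise ConfigError("effects.classes: more effects than genes")
            gid = gene_ids[order[cursor]]
            profiles[gid] = makers[cls](gid, params)
            cursor += 1
    for gid in gene_ids:
        profiles.setdefault(gid, sd.GeneEffectProfile.neutral(gid))
    return [profiles[g] for g in gene_ids]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config_path: str | Path, out_dir: str | Path) -> dict:
    """Execute all stages in order; any failure raises with the stage name."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg["seed"],
        "config_sha256": hashlib.sha256(
            Path(config_path).read_bytes()
        ).hexdigest(),
        "stages": {},
        "files": {},
    }
    state: dict = {}
    for stage in STAGES:
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](cfg, out, state)
        except Exception as exc:  # noqa: BLE001 - diagnostic naming the stage
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: dict, out: Path, state: dict) -> None:
    seeds = np.random.SeedSequence(cfg["seed"]).spawn(3)
    spec = build_spec(cfg)
    genome, annotation = sd.simulate_genome(spec)
    config = build_library_config(cfg, seed=cfg["seed"])
    effects = build_effects(
        cfg, annotation, np.random.default_rng(seeds[0])
    )
    truth = sd.simulate_library(genome, annotation, effects, config)

    sim_dir = out / "sim"
    sim_dir.mkdir(exist_ok=True)
    sd.write_fasta(genome, sim_dir / "reference.fa")
    sd.write_gff3(annotation, sim_dir / "annotation.gff3")
    annotation.to_csv(sim_dir / "annotation.tsv", sep="\t", index=False)
    truth.to_tsv(sim_dir / "truth_sites.tsv")
    pd.DataFrame(
        [
            {"gene_id": e.gene_id, "fitness_class": e.fitness_class, **e.factors}
            for e in effects
        ]
    ).to_csv(sim_dir / "truth_effects.tsv", sep="\t", index=False)

    count_rng = np.random.default_rng(seeds[1])
    read_rng = np.random.default_rng(seeds[2])
    counts = {}
    fastqs: dict[str, list[Path]] = {}
    for tp in quant.TIMEPOINTS:
        counts[tp] = sd.sample_counts(truth, config, tp, rng=count_rng)
        chunks, sidecar = sd.emit_reads(
            genome, truth, counts[tp], config, sample_id=tp, rng=read_rng
        )
        paths = []
        for ri, chunk in enumerate(chunks):
            p = sim_dir / f"{tp}_run{ri + 1}.fastq"
            p.write_text(chunk)
            paths.append(p)
        sidecar.to_csv(sim_dir / f"{tp}_truth_reads.tsv", sep="\t", index=False)
        fastqs[tp] = paths
    truth_counts = pd.concat(
        [truth.sites, pd.DataFrame({tp: counts[tp] for tp in quant.TIMEPOINTS})],
        axis=1,
    )
    truth_counts.to_csv(sim_dir / "truth_counts.tsv", sep="\t", index=False)

    state.update(
        genome=genome, annotation=annotation, config=config, truth=truth,
        fastqs=fastqs,
    )


def _stage_process_reads(cfg: dict, out: Path, state: dict) -> None:
    config: sd.LibrarySimConfig = state["config"]
    index = readproc.ReferenceIndex(state["genome"])
    calls_dir = out / "calls"
    calls_dir.mkdir(exist_ok=True)
    per_sample_calls: dict[str, list[pd.DataFrame]] = {}
    for tp, paths in state["fastqs"].items():
        per_sample_calls[tp] = []
        for p in paths:
            calls = readproc.process_reads(
                p, index, config.linker, config.umi_length, config.hermes_end
            )
            readproc.write_calls(calls, calls_dir / f"{p.stem}_calls.tsv")
            readproc.write_status_summary(
                calls, calls_dir / f"{p.stem}_status.json"
            )
            per_sample_calls[tp].append(calls)
    state["calls"] = per_sample_calls


def _stage_quantify(cfg: dict, out: Path, state: dict) -> None:
    per_sample = {
        tp: [quant.count_umis(c) for c in runs]
        for tp, runs in state["calls"].items()
    }
    raw = quant.merge_runs(per_sample)
    raw = quant.assign_features(raw, state["annotation"])
    min_products = int((cfg.get("filter") or {}).get("min_products", quant.MIN_PRODUCTS))
    filtered = quant.filter_sites(raw, "T2", min_products)
    qdir = out / "quant"
    qdir.mkdir(exist_ok=True)
    quant.write_table(raw, qdir / "site_counts_raw.tsv")
    quant.write_table(filtered, qdir / "site_counts_filtered.tsv")
    quant.write_summary(
        quant.quantification_summary(raw, filtered), qdir / "summary.json"
    )
    state["raw"] = raw
    state["filtered"] = filtered


def _stage_test(cfg: dict, out: Path, state: dict) -> None:
    tcfg = cfg.get("test") or {}
    res = fitness_stats.analyze(
        state["filtered"],
        alpha=float(tcfg.get("alpha", fitness_stats.ALPHA)),
        min_sites=int(tcfg.get("min_sites", fitness_stats.MIN_SITES)),
        correction=tcfg.get("correction", "bonferroni"),
    )
    tdir = out / "test"
    tdir.mkdir(exist_ok=True)
    res["summary"].to_csv(tdir / "gene_results.tsv", sep="\t", index=False)
    for tag in ("short", "long"):
        res[tag].results.reset_index().to_csv(
            tdir / f"comparison_{tag}.tsv", sep="\t", index=False
        )
    state["results"] = res


def _stage_report(cfg: dict, out: Path, state: dict) -> None:
    res = state["results"]
    rdir = out / "report"
    rdir.mkdir(exist_ok=True)
    summary = res["summary"]
    volcanoes = {}
    tested = summary.loc[summary["classification"] != "too_few_sites"]
    for tag in ("short", "long"):
        if not tested.empty:
            fname = f"volcano_{tag}.svg"
            reporting.volcano_plot(tested, rdir / fname, tag=tag)
            volcanoes[tag] = fname
    stats = reporting.funnel(
        state["raw"], state["filtered"], summary.set_index("gene")
    )
    stats["site_recovery_pct"] = reporting.site_recovery(state["filtered"])
    quant.write_summary(stats, rdir / "funnel.json")
    reporting.html_report(summary, stats, rdir, volcanoes)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "process_reads": _stage_process_reads,
    "quantify": _stage_quantify,
    "test": _stage_test,
    "report": _stage_report,
}
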