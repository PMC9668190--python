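"""Operating-characteristic studies of the screen on simulated libraries.

Reusable simulation experiments that measure how the pipeline behaves
under known truth: family-wise error on fully neutral libraries,
sensitivity and specificity of hit classification under stage-specific
selection, and exact round-trip integrity of the read layer. The study
library emulates the assay's geometry at desk scale: a 0.5 Mb genome with
200 genes of 1-2 kb, an insertion roughly every 38 bp, and unique-product
depths large enough that the pre-sex depth filter retains >= 90% of sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sexfit import fitness_stats as fs
from sexfit import quant, readproc
from sexfit import synthetic_data as sd

#: Desk-scale study geometry: ~1 insertion per 38 bp of a 0.5 Mb genome.
STUDY_N_GENES = 200
STUDY_GENOME = (500_000,)
STUDY_GENE_LENGTH = (1_000, 2_000)
STUDY_INTERGENIC = 0.4
STUDY_N_CLONES = 13_000


def study_spec(seed: int, n_genes: int = STUDY_N_GENES) -> sd.SimGenomeSpec:
    return sd.SimGenomeSpec(
        chrom_lengths=STUDY_GENOME,
        n_genes=n_genes,
        gene_length=STUDY_GENE_LENGTH,
        intergenic_fraction=STUDY_INTERGENIC,
        seed=seed,
    )


def study_config(seed: int, depth: int) -> sd.LibrarySimConfig:
    return sd.LibrarySimConfig(
        n_clones=STUDY_N_CLONES, depth=depth, seed=seed
    )


def fwer_null_study(
    n_replicates: int = 200, depth: int = 1_000_000, seed: int = 0
) -> dict:
    """Family-wise error of the Bonferroni-corrected gene test.

    Every replicate simulates a fully neutral library (all genes factor 1),
    filters sites, and tests each gene's short-outgrowth fold changes
    against the intergenic null. Returns the fraction of replicates with at
    least one Bonferroni-significant gene, which Bonferroni should hold at
    or below alpha.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_replicates * 2).astype(np.int64) % (2**31)
    n_any = 0
    n_genes_tested = []
    for rep in range(n_replicates):
        spec = study_spec(int(child[2 * rep]))
        cfg = study_config(int(child[2 * rep]), depth)
        table, _, _ = sd.simulate_screen(spec, cfg, rng=int(child[2 * rep + 1]))
        table = quant.filter_sites(table, "T2")
        res = fs.test_comparison(table, "T2", "T3")
        n_any += bool(res.results["significant"].any())
        n_genes_tested.append(res.n_tested)
    return {
        "n_replicates": n_replicates,
        "fraction_any_significant": n_any / n_replicates,
        "mean_genes_tested": float(np.mean(n_genes_tested)),
    }


def _recovery_effects(genes: list[str]) -> list[sd.GeneEffectProfile]:
    """20 sex-required genes (sex factor 0.1), 20 growth-advantage genes
    (factor 2 at both vegetative stages), remainder neutral."""
    effects = []
    for i, g in enumerate(genes):
        if i < 20:
            effects.append(sd.GeneEffectProfile.sex_required(g, 0.1))
        elif i < 40:
            effects.append(sd.GeneEffectProfile.growth_advantage(g, 2.0))
        else:
            effects.append(sd.GeneEffectProfile.neutral(g))
    return effects


def recovery_study(
    n_replicates: int = 7, depth: int = 500_000, seed: int = 0
) -> dict:
    """Parameter recovery under known stage-specific selection.

    Per replicate: fraction of sex-required genes (sex factor 0.1,
    >= 20 sites at study density) classified ``required_for_sex``; fraction
    of growth-advantage genes flagged at both vegetative comparisons; count
    of neutral genes mis-classified as hits or repressors; and whether
    every detected sex-required gene moved in the direction of its true
    effect (mean r below the null mean).
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_replicates * 2).astype(np.int64) % (2**31)
    sens, both_flagged, neutral_mis, direction_ok = [], [], [], []
    for rep in range(n_replicates):
        spec = study_spec(int(child[2 * rep]))
        genome, ann = sd.simulate_genome(spec)
        genes = list(ann.loc[ann.feature_type == "gene", "feature_id"])
        effects = _recovery_effects(genes)
        cfg = study_config(int(child[2 * rep]), depth)
        table, truth, _ = sd.simulate_screen(
            spec, cfg, effects, rng=int(child[2 * rep + 1])
        )
        table = quant.filter_sites(table, "T2")
        res = fs.analyze(table)
        cls = res["classification"]["classification"]
        flags = res["growth_flags"]

        sex_genes = [e.gene_id for e in effects if e.fitness_class == "sex_required"]
        adv_genes = [e.gene_id for e in effects if e.fitness_class == "growth_advantage"]
        neutral = [e.gene_id for e in effects if e.fitness_class == "neutral"]

        called = cls.reindex(sex_genes)
        sens.append((called == "required_for_sex").mean())
        both = flags["growth_advantage_suspect"].reindex(adv_genes).fillna(False)
        both_flagged.append(both.mean())
        mis = cls.reindex(neutral).isin(
            ["required_for_sex", "repressor_candidate"]
        )
        neutral_mis.append(int(mis.sum()))
        detected = called[called == "required_for_sex"].index
        mean_r = res["short"].results["mean_r"].reindex(detected)
        direction_ok.append(bool((mean_r < res["short"].null_mean).all()))
    return {
        "n_replicates": n_replicates,
        "sex_required_sensitivity_pct": 100.0 * float(np.mean(sens)),
        "growth_advantage_both_flagged_pct": 100.0 * float(np.mean(both_flagged)),
        "neutral_misclassified_median": float(np.median(neutral_mis)),
        "neutral_misclassified_per_replicate": neutral_mis,
        "detected_direction_consistent": all(direction_ok),
    }


def roundtrip_study(seed: int = 0) -> dict:
    """Exact round-trip of the read layer on a smoke-scale library.

    Emits error-free UMI-barcoded reads for the pre-sex reference sample,
    processes them back through gating, mapping and UMI counting, and
    compares per-site counts with the simulator's sampled truth. Also
    checks the site filter against a brute-force refilter.
    """
    ss = np.random.SeedSequence(seed)
    s = ss.generate_state(4).astype(np.int64) % (2**31)
    spec = sd.SimGenomeSpec(
        chrom_lengths=(100_000,), n_genes=50, gene_length=(800, 1_500),
        intergenic_fraction=0.45, seed=int(s[0]),
    )
    genome, ann = sd.simulate_genome(spec)
    genes = ann.loc[ann.feature_type == "gene", "feature_id"]
    effects = [sd.GeneEffectProfile.neutral(g) for g in genes]
    cfg = sd.LibrarySimConfig(
        n_clones=5_000, depth=100_000, pcr_mean_copies=1.5, runs=2, seed=int(s[1])
    )
    truth = sd.simulate_library(genome, ann, effects, cfg)
    counts = sd.sample_counts(truth, cfg, "T2", rng=int(s[2]))
    chunks, _ = sd.emit_reads(genome, truth, counts, cfg, "T2", rng=int(s[3]))

    import io

    from Bio import SeqIO

    index = readproc.ReferenceIndex(genome)
    calls = pd.concat(
        [
            readproc.process_reads(
                ((r.id, str(r.seq)) for r in SeqIO.parse(io.StringIO(ch), "fastq")),
                index, cfg.linker, cfg.umi_length, cfg.hermes_end,
            )
            for ch in chunks
        ],
        ignore_index=True,
    )
    got = (
        quant.count_umis(calls).set_index(quant.SITE_KEY)["count"].sort_index()
    )
    idx = pd.MultiIndex.from_frame(truth.sites[["chrom", "pos", "strand"]])
    want = pd.Series(counts, index=idx)
    want = want[want > 0].sort_index()
    exact = (len(got) == len(want)) and bool(
        (got.to_numpy() == want.to_numpy()).all()
    )
    n_exact = int((got.to_numpy() == want.to_numpy()).sum()) if len(got) == len(want) else 0

    table = pd.DataFrame({tp: pd.Series(0, index=idx) for tp in quant.TIMEPOINTS})
    table["T2"] = counts
    filtered = quant.filter_sites(table, "T2")
    brute = table[np.asarray([c >= 9 for c in table["T2"]])]
    filter_exact = filtered.equals(brute)
    return {
        "n_sites_sampled": int(len(want)),
        "pct_sites_exact": 100.0 * n_exact / len(want),
        "all_reads_mapped": bool((calls["status"] == "mapped_unique").all()),
        "roundtrip_exact": exact,
        "filter_matches_bruteforce": bool(filter_exact),
        "sites_retained": int(len(filtered)),
    }
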