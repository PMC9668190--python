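import io

import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO

from sexfit import quant, readproc
from sexfit import synthetic_data as sd


@pytest.fixture(scope="session")
def small_spec():
    return sd.SimGenomeSpec(
        chrom_lengths=(100_000,),
        n_genes=25,
        gene_length=(1_000, 2_500),
        intergenic_fraction=0.55,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return sd.simulate_genome(small_spec)


@pytest.fixture(scope="session")
def neutral_effects(small_genome):
    _, ann = small_genome
    genes = ann.loc[ann["feature_type"] == "gene", "feature_id"]
    return [sd.GeneEffectProfile.neutral(g) for g in genes]


@pytest.fixture(scope="session")
def small_config():
    return sd.LibrarySimConfig(
        n_clones=1_500, depth=60_000, pcr_mean_copies=2.0, runs=2, seed=17
    )


@pytest.fixture(scope="session")
def small_truth(small_genome, neutral_effects, small_config):
    genome, ann = small_genome
    return sd.simulate_library(genome, ann, neutral_effects, small_config)


def parse_fastq_text(text: str):
    """Iterate (id, sequence) pairs from a FASTQ text blob."""
    for rec in SeqIO.parse(io.StringIO(text), "fastq"):
        yield rec.id, str(rec.seq)


@pytest.fixture(scope="session")
def roundtrip(small_genome, small_truth, small_config):
    """Error-free reads for T2, processed back to junction calls.

    Shared by the readproc/quant round-trip tests and the acceptance
    round-trip criterion.
    """
    genome, _ = small_genome
    counts = sd.sample_counts(
        small_truth, small_config, "T2", rng=np.random.default_rng(23)
    )
    chunks, sidecar = sd.emit_reads(
        genome, small_truth, counts, small_config, "T2", rng=29
    )
    index = readproc.ReferenceIndex(genome)
    calls = pd.concat(
        [
            readproc.process_reads(
                parse_fastq_text(ch),
                index,
                small_config.linker,
                small_config.umi_length,
                small_config.hermes_end,
            )
            for ch in chunks
        ],
        ignore_index=True,
    )
    return {
        "counts": counts,
        "chunks": chunks,
        "sidecar": sidecar,
        "calls": calls,
        "index": index,
    }


def toy_table(t1, t2, t3, t4, features=None):
    """SiteCountTable from parallel count lists, sites on one chromosome."""
    n = len(t2)
    idx = pd.MultiIndex.from_arrays(
        [["chr1"] * n, list(range(100, 100 + n)), ["+"] * n],
        names=quant.SITE_KEY,
    )
    table = pd.DataFrame({"T1": t1, "T2": t2, "T3": t3, "T4": t4}, index=idx)
    if features is not None:
        table["feature"] = features
    return table
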