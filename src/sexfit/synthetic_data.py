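"""Simulator for TN-seq sexual-reproduction assays.

Generates everything the downstream pipeline consumes — a reference genome,
a gene/intergenic annotation, a dense insertion library with per-gene
stage-specific selection, multinomially sampled unique-barcode counts at
four timepoints, and UMI-barcoded junction reads in FASTQ — together with
a machine-readable truth table, so every stage is testable without any
sequencing download.

The selection model is multiplicative per stage and renormalized: the four
sampled timepoints are T1 (initial library), T2 (revived pre-sex culture,
the filtering reference), T3 (short post-sex outgrowth) and T4 (long
post-sex outgrowth), with

    T2 = T1 * vegetative_pre factors   (renormalized)
    T3 = T2 * sex factors              (renormalized)
    T4 = T3 * vegetative_post factors  (renormalized)

Intergenic insertions always carry factor 1 at every stage. The single
``sex`` factor subsumes mating, meiosis, sporulation and germination
survival; no mating-type or microcolony dynamics are modeled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from sexfit.quant import TIMEPOINTS, assign_site_features

STAGES = ("vegetative_pre", "sex", "vegetative_post")

#: Synthetic stand-in constants for the library chemistry. Both are
#: configurable; real libraries use their own linker and the Hermes
#: terminal sequence.
DEFAULT_LINKER = "CGTAATACGACTCACTATAGG"
DEFAULT_HERMES_END = "TGACTTCAACATAAGCATTT"

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class SimGenomeSpec:
    """Parameters of a synthetic genome with non-overlapping genes.

    ``intergenic_fraction`` is the target fraction of the genome outside
    genes; the drawn gene lengths must land within +/-10% (absolute, on
    the fraction scale) of ``1 - intergenic_fraction`` or genome
    construction refuses, since the caller's library composition
    assumptions would be silently violated.
    """

    chrom_lengths: tuple[int, ...] = (500_000,)
    n_genes: int = 200
    gene_length: tuple[int, int] = (1_000, 2_000)
    intergenic_fraction: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if not self.chrom_lengths or any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.n_genes < 0:
            raise ValueError("gene count must be non-negative")
        lo, hi = self.gene_length
        if not (0 < lo <= hi):
            raise ValueError("gene length range must satisfy 0 < min <= max")
        if not 0.0 <= self.intergenic_fraction <= 1.0:
            raise ValueError("intergenic fraction must be in [0, 1]")


@dataclass(frozen=True)
class GeneEffectProfile:
    """Multiplicative per-stage survival factors for one gene's insertions.

    ``fitness_class`` labels the intent; the factors carry the semantics:
    a clone with an insertion in this gene is reweighted by
    ``factors[stage]`` at each selection stage before renormalization.
    """

    gene_id: str
    fitness_class: str = "neutral"
    factors: Mapping[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in STAGES}
    )

    CLASSES = (
        "neutral",
        "essential",
        "sex_required",
        "sex_repressor",
        "growth_impaired_pre",
        "growth_impaired_post",
        "growth_advantage",
        "pleiotropic",
    )

    def __post_init__(self) -> None:
        if self.fitness_class not in self.CLASSES:
            raise ValueError(f"unknown fitness class {self.fitness_class!r}")
        missing = set(STAGES) - set(self.factors)
        if missing:
            raise ValueError(f"missing stage factors: {sorted(missing)}")
        if any(v < 0 for v in self.factors.values()):
            raise ValueError("stage factors must be >= 0")
        if self.fitness_class == "neutral" and any(
            v != 1.0 for v in self.factors.values()
        ):
            raise ValueError("neutral profile requires all factors = 1")
        if self.fitness_class == "essential" and self.factors["vegetative_pre"] != 0:
            raise ValueError("essential profile requires vegetative_pre factor = 0")
        if self.fitness_class == "sex_required" and not (
            self.factors["sex"] < 1.0
            and self.factors["vegetative_pre"] == 1.0
            and self.factors["vegetative_post"] == 1.0
        ):
            raise ValueError(
                "sex_required profile requires sex factor < 1 and other factors = 1"
            )

    @classmethod
    def neutral(cls, gene_id: str) -> "GeneEffectProfile":
        return cls(gene_id, "neutral")

    @classmethod
    def essential(cls, gene_id: str) -> "GeneEffectProfile":
        return cls(
            gene_id,
            "essential",
            {"vegetative_pre": 0.0, "sex": 1.0, "vegetative_post": 1.0},
        )

    @classmethod
    def sex_required(cls, gene_id: str, sex_factor: float) -> "GeneEffectProfile":
        return cls(
            gene_id,
            "sex_required",
            {"vegetative_pre": 1.0, "sex": sex_factor, "vegetative_post": 1.0},
        )

    @classmethod
    def sex_repressor(cls, gene_id: str, sex_factor: float) -> "GeneEffectProfile":
        return cls(
            gene_id,
            "sex_repressor",
            {"vegetative_pre": 1.0, "sex": sex_factor, "vegetative_post": 1.0},
        )

    @classmethod
    def growth_advantage(cls, gene_id: str, growth_factor: float) -> "GeneEffectProfile":
        """Faster vegetative growth at both outgrowth stages, neutral sex."""
        return cls(
            gene_id,
            "growth_advantage",
            {
                "vegetative_pre": growth_factor,
                "sex": 1.0,
                "vegetative_post": growth_factor,
            },
        )

    @classmethod
    def growth_impaired_pre(cls, gene_id: str, factor: float) -> "GeneEffectProfile":
        return cls(
            gene_id,
            "growth_impaired_pre",
            {"vegetative_pre": factor, "sex": 1.0, "vegetative_post": 1.0},
        )

    @classmethod
    def growth_impaired_post(cls, gene_id: str, factor: float) -> "GeneEffectProfile":
        return cls(
            gene_id,
            "growth_impaired_post",
            {"vegetative_pre": 1.0, "sex": 1.0, "vegetative_post": factor},
        )


@dataclass(frozen=True)
class LibrarySimConfig:
    """Insertion-library and sequencing parameters.

    ``depth`` is the number of unique barcoded ligation products sampled
    per timepoint (a scalar or a per-timepoint mapping). ``pcr_mean_copies``
    is the mean number of reads per unique ligation product; with
    ``pcr_model="constant"`` it must be a positive integer, with
    ``"geometric"`` duplicate counts are drawn geometrically (support >= 1).
    ``runs`` splits emitted reads round-robin into that many FASTQ files to
    exercise downstream run merging.
    """

    n_clones: int = 10_000
    placement: str = "uniform"  # or "hotspot"
    hotspot_rate: float = 0.5
    hotspot_count: int = 10
    dirichlet_concentration: float = 10.0
    depth: int | Mapping[str, int] = 500_000
    pcr_mean_copies: float = 2.0
    pcr_model: str = "geometric"  # or "constant"
    umi_length: int = 10
    linker: str = DEFAULT_LINKER
    hermes_end: str = DEFAULT_HERMES_END
    read_length: int = 100
    substitution_rate: float = 0.0
    runs: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        if self.placement not in ("uniform", "hotspot"):
            raise ValueError("placement must be 'uniform' or 'hotspot'")
        if self.umi_length < 8:
            raise ValueError("UMI length must be >= 8 (collision safety)")
        for tp in TIMEPOINTS:
            if self.depth_for(tp) < 0:
                raise ValueError("sequencing depth must be >= 0")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution rate must be in [0, 1]")
        if self.pcr_mean_copies < 1:
            raise ValueError("pcr_mean_copies must be >= 1")
        if self.pcr_model not in ("constant", "geometric"):
            raise ValueError("pcr_model must be 'constant' or 'geometric'")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.fragment_length < 1:
            raise ValueError(
                "layout infeasible: read length must exceed "
                "linker + UMI + Hermes end"
            )

    def depth_for(self, timepoint: str) -> int:
        if isinstance(self.depth, Mapping):
            return int(self.depth[timepoint])
        return int(self.depth)

    @property
    def fragment_length(self) -> int:
        """Genomic bases carried by each read after layout overhead."""
        return (
            self.read_length
            - len(self.linker)
            - self.umi_length
            - len(self.hermes_end)
        )


@dataclass
class SimTruth:
    """Ground truth of a simulated library.

    ``sites`` has one row per insertion clone (chrom, pos, strand, feature);
    ``abundance`` holds the true clone frequencies at each timepoint
    (columns T1..T4, each summing to 1); ``effects`` maps gene id to its
    :class:`GeneEffectProfile`.
    """

    sites: pd.DataFrame
    abundance: pd.DataFrame
    effects: dict[str, GeneEffectProfile]

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat([self.sites.reset_index(drop=True), self.abundance], axis=1)
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    spec: SimGenomeSpec,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate a random genome and a non-overlapping gene annotation.

    Returns ``(sequences, annotation)`` where ``sequences`` maps chromosome
    name to sequence and ``annotation`` has columns
    ``chrom, start, end, strand, feature_id, feature_type`` with 1-based
    inclusive coordinates; intergenic intervals are emitted as
    ``feature_type == "intergenic"``. Deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genome_len = sum(spec.chrom_lengths)

    lengths = rng.integers(
        spec.gene_length[0], spec.gene_length[1] + 1, size=spec.n_genes
    )
    if lengths.sum() > genome_len:
        raise ValueError("cannot place genes: total gene length exceeds genome")
    genic_fraction = lengths.sum() / genome_len
    if abs(genic_fraction - (1.0 - spec.intergenic_fraction)) > 0.10:
        raise ValueError(
            f"cannot place genes: drawn genic fraction {genic_fraction:.3f} "
            f"is inconsistent with intergenic_fraction={spec.intergenic_fraction}"
        )

    # apportion genes to chromosomes proportionally to length, then place
    # each chromosome's genes with multinomially drawn intergenic gaps
    n_chrom = len(spec.chrom_lengths)
    weights = np.asarray(spec.chrom_lengths, dtype=float)
    weights /= weights.sum()
    chrom_of_gene = rng.choice(n_chrom, size=spec.n_genes, p=weights)

    sequences: dict[str, str] = {}
    rows: list[tuple] = []
    gene_no = 0
    for ci, clen in enumerate(spec.chrom_lengths):
        chrom = f"chr{ci + 1}"
        seq_idx = rng.integers(0, 4, size=clen)
        sequences[chrom] = _BASES[seq_idx].tobytes().decode()

        glens = lengths[chrom_of_gene == ci]
        # retry apportionment overflow on a single chromosome by spilling
        # the surplus genes onto the largest chromosome deterministically
        if glens.sum() > clen:
            raise ValueError(
                f"cannot place genes: {chrom} cannot hold its apportioned genes"
            )
        slack = clen - int(glens.sum())
        gaps = rng.multinomial(slack, np.full(len(glens) + 1, 1.0 / (len(glens) + 1)))
        cursor = 0
        prev_end = 0  # 1-based end of previous feature
        for k, glen in enumerate(glens):
            cursor += int(gaps[k])
            start = cursor + 1
            end = cursor + int(glen)
            if start > prev_end + 1:
                rows.append(
                    (chrom, prev_end + 1, start - 1, ".", f"ig_{chrom}_{k}", "intergenic")
                )
            gene_no += 1
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, start, end, strand, f"gene{gene_no:04d}", "gene"))
            cursor = end
            prev_end = end
        if prev_end < clen:
            rows.append(
                (chrom, prev_end + 1, clen, ".", f"ig_{chrom}_end", "intergenic")
            )

    annotation = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "feature_id", "feature_type"]
    )
    return sequences, annotation


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_gff3(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write the annotation as GFF3 (1-based inclusive); intergenic
    intervals use feature type ``region``."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            gtype = "gene" if row.feature_type == "gene" else "region"
            fh.write(
                f"{row.chrom}\tsexfit_sim\t{gtype}\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.feature_id}\n"
            )


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 or flat-TSV annotation into the internal table."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=[
                "chrom", "source", "type", "start", "end",
                "score", "strand", "phase", "attributes",
            ],
        )
        fid = df["attributes"].str.extract(r"ID=([^;]+)")[0]
        return pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"].astype(int),
                "end": df["end"].astype(int),
                "strand": df["strand"],
                "feature_id": fid,
                "feature_type": np.where(df["type"] == "gene", "gene", "intergenic"),
            }
        )
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# library and selection


def simulate_library(
    genome: Mapping[str, str],
    annotation: pd.DataFrame,
    effects: Iterable[GeneEffectProfile],
    config: LibrarySimConfig,
) -> SimTruth:
    """Place insertion clones and propagate abundances through selection.

    Every annotated gene must have exactly one effect profile. Clones are
    placed at distinct (chrom, pos, strand) sites — uniformly by default,
    or with a fraction concentrated in random hotspots — at least
    ``read_length`` bp from chromosome ends so every junction read carries
    a full genomic fragment. Initial abundances are symmetric-Dirichlet;
    each stage multiplies by the owning gene's factor and renormalizes.
    """
    config.validate()
    effects = {e.gene_id: e for e in effects}
    gene_ids = set(
        annotation.loc[annotation["feature_type"] == "gene", "feature_id"]
    )
    if gene_ids != set(effects):
        missing = gene_ids - set(effects)
        extra = set(effects) - gene_ids
        raise ValueError(
            f"effect profiles must cover genes exactly "
            f"(missing {sorted(missing)[:3]}..., extra {sorted(extra)[:3]}...)"
        )

    rng = np.random.default_rng(config.seed)
    margin = config.read_length
    chroms = list(genome)
    usable = {
        c: (margin + 1, len(genome[c]) - margin) for c in chroms
    }
    for c, (lo, hi) in usable.items():
        if hi < lo:
            raise ValueError(f"chromosome {c} too short for read-length margin")

    sites = _place_sites(rng, usable, config)
    feature = assign_site_features(sites, annotation)
    sites = sites.assign(feature=feature.values)

    alpha = np.full(len(sites), config.dirichlet_concentration)
    t1 = rng.dirichlet(alpha)

    # per-site stage factors from the owning gene(s); a site inside
    # overlapping genes takes the product of their factors
    stage_factors = {s: np.ones(len(sites)) for s in STAGES}
    for i, feat in enumerate(sites["feature"]):
        if feat == "intergenic":
            continue
        for gid in feat.split(";"):
            prof = effects[gid]
            for s in STAGES:
                stage_factors[s][i] *= prof.factors[s]

    abund = {"T1": t1}
    current = t1
    for tp, stage in zip(("T2", "T3", "T4"), STAGES):
        current = current * stage_factors[stage]
        total = current.sum()
        if total <= 0:
            raise ValueError("library extinct: all clone abundances are zero")
        current = current / total
        abund[tp] = current

    abundance = pd.DataFrame(abund, columns=list(TIMEPOINTS))
    return SimTruth(sites=sites.reset_index(drop=True), abundance=abundance,
                    effects=effects)


def _place_sites(
    rng: np.random.Generator,
    usable: Mapping[str, tuple[int, int]],
    config: LibrarySimConfig,
) -> pd.DataFrame:
    """Draw ``n_clones`` distinct (chrom, pos, strand) insertion sites."""
    chroms = list(usable)
    spans = np.array([hi - lo + 1 for lo, hi in usable.values()], dtype=float)
    capacity = int(2 * spans.sum())
    if config.n_clones > capacity:
        raise ValueError("cannot place clones: more clones than distinct sites")

    chosen: set[tuple[int, int, int]] = set()
    hotspots: list[tuple[int, int]] = []
    if config.placement == "hotspot":
        for _ in range(config.hotspot_count):
            ci = rng.choice(len(chroms), p=spans / spans.sum())
            lo, hi = usable[chroms[ci]]
            hotspots.append((ci, int(rng.integers(lo, hi + 1))))

    while len(chosen) < config.n_clones:
        n_left = config.n_clones - len(chosen)
        if config.placement == "hotspot" and hotspots:
            in_hot = rng.random(n_left) < config.hotspot_rate
        else:
            in_hot = np.zeros(n_left, dtype=bool)
        ci = rng.choice(len(chroms), size=n_left, p=spans / spans.sum())
        strands = rng.integers(0, 2, size=n_left)
        for j in range(n_left):
            if in_hot[j]:
                hc, hp = hotspots[rng.integers(0, len(hotspots))]
                lo, hi = usable[chroms[hc]]
                pos = int(np.clip(hp + rng.integers(-50, 51), lo, hi))
                chosen.add((hc, pos, int(strands[j])))
            else:
                lo, hi = usable[chroms[ci[j]]]
                chosen.add((int(ci[j]), int(rng.integers(lo, hi + 1)), int(strands[j])))

    ordered = sorted(chosen)
    return pd.DataFrame(
        {
            "chrom": [chroms[c] for c, _, _ in ordered],
            "pos": [p for _, p, _ in ordered],
            "strand": ["+" if s == 0 else "-" for _, _, s in ordered],
        }
    )


# ---------------------------------------------------------------------------
# sequencing


def sample_counts(
    truth: SimTruth,
    config: LibrarySimConfig,
    timepoint: str,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw per-site unique-barcode counts multinomially at configured depth.

    Emulates sampling of unique ligation products from the clone pool: the
    count vector sums exactly to the timepoint's depth and is reproducible
    under a fixed seed.
    """
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    probs = truth.abundance[timepoint].to_numpy()
    total = probs.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError("truth abundances must sum to 1")
    depth = config.depth_for(timepoint)
    if depth == 0:
        return np.zeros(len(probs), dtype=np.int64)
    return rng.multinomial(depth, probs / total)


def emit_reads(
    genome: Mapping[str, str],
    truth: SimTruth,
    counts: np.ndarray,
    config: LibrarySimConfig,
    sample_id: str,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Render counts as UMI-barcoded junction reads.

    Each unique ligation product gets a distinct UMI (within its site) and
    is emitted ``>=1`` times according to the PCR duplication model. Read
    layout: ``[linker][UMI][Hermes terminal sequence][genomic fragment]``,
    with the genomic fragment starting at the insertion junction on the
    insertion strand. Returns ``(fastq_chunks, sidecar)`` where
    ``fastq_chunks`` holds one FASTQ text blob per configured run and the
    sidecar maps every read id to its truth site and UMI.
    """
    config.validate()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    frag_len = config.fragment_length
    qual = "I" * config.read_length

    buffers = [io.StringIO() for _ in range(config.runs)]
    sidecar_rows: list[tuple] = []
    read_no = 0
    sites = truth.sites
    for i, c in enumerate(counts):
        c = int(c)
        if c == 0:
            continue
        chrom = sites.at[i, "chrom"]
        pos = int(sites.at[i, "pos"])
        strand = sites.at[i, "strand"]
        seq = genome[chrom]
        if strand == "+":
            fragment = seq[pos - 1 : pos - 1 + frag_len]
        else:
            fragment = reverse_complement(seq[pos - frag_len : pos])
        umis = _distinct_umis(rng, c, config.umi_length)
        if config.pcr_model == "constant":
            copy_counts = [int(round(config.pcr_mean_copies))] * c
        else:
            copy_counts = rng.geometric(1.0 / config.pcr_mean_copies, size=c)
        for umi, copies in zip(umis, copy_counts):
            for _ in range(int(copies)):
                read_no += 1
                rid = f"{sample_id}:read{read_no:08d}"
                read = config.linker + umi + config.hermes_end + fragment
                if config.substitution_rate > 0:
                    read = _mutate(rng, read, config.substitution_rate)
                buf = buffers[(read_no - 1) % config.runs]
                buf.write(f"@{rid}\n{read}\n+\n{qual}\n")
                sidecar_rows.append((rid, chrom, pos, strand, umi))

    sidecar = pd.DataFrame(
        sidecar_rows, columns=["read_id", "chrom", "pos", "strand", "umi"]
    )
    return [b.getvalue() for b in buffers], sidecar


def simulate_screen(
    spec: SimGenomeSpec,
    config: LibrarySimConfig,
    effects: Iterable[GeneEffectProfile] | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, SimTruth, pd.DataFrame]:
    """One full screen at the count level (no read emission).

    Simulates genome, library and selection, then samples unique-barcode
    counts at all four timepoints. Returns ``(table, truth, annotation)``
    where ``table`` is a feature-annotated SiteCountTable ready for
    :func:`sexfit.quant.filter_sites`. ``effects=None`` makes every gene
    neutral. Use this for statistical experiments where the sequencing-read
    layer (exercised by :func:`emit_reads` round-trips) is not needed.
    """
    genome, annotation = simulate_genome(spec)
    if effects is None:
        effects = [
            GeneEffectProfile.neutral(g)
            for g in annotation.loc[
                annotation["feature_type"] == "gene", "feature_id"
            ]
        ]
    truth = simulate_library(genome, annotation, effects, config)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    counts = {
        tp: sample_counts(truth, config, tp, rng=rng) for tp in TIMEPOINTS
    }
    table = pd.DataFrame(
        counts,
        index=pd.MultiIndex.from_frame(truth.sites[["chrom", "pos", "strand"]]),
    )
    table["feature"] = truth.sites["feature"].values
    return table, truth, annotation


def _distinct_umis(rng: np.random.Generator, n: int, length: int) -> list[str]:
    umis: dict[str, None] = {}
    while len(umis) < n:
        draw = rng.integers(0, 4, size=(n - len(umis), length))
        flat = _BASES[draw].view(f"S{length}").ravel()
        for u in flat.astype(str):
            umis.setdefault(u)
            if len(umis) == n:
                break
    return list(umis)


def _mutate(rng: np.random.Generator, read: str, rate: float) -> str:
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = np.nonzero(hit)[0]
        # substitute with a uniformly chosen *different* base
        for i in idx:
            base = arr[i]
            choices = [b for b in _BASES if b != base]
            arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()
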