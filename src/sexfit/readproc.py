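"""Junction-read processing: linker gating, UMI extraction, transposon-end
gating, and unique exact mapping.

Each raw read is expected to carry, in order, the constant linker sequence,
a random UMI, the transposon's terminal sequence, and finally genomic
sequence starting at the insertion junction on the insertion strand. Reads
pass only with a perfect (0-mismatch) linker match and a perfect match to
the entire configured transposon end; the remaining genomic fragment must
map to exactly one location across both reference strands. The mapper is an
exact substring search — adequate for error-free synthetic reads; real-data
users can plug in an external aligner and ingest its calls through the same
JunctionCall table contract (read start plus flag-derived strand).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

from sexfit.synthetic_data import reverse_complement

STATUSES = ("mapped_unique", "no_linker", "no_hermes_end", "unmapped", "multi_mapped")

#: Fragments shorter than this are not meaningfully unique and are
#: reported unmapped.
MIN_FRAGMENT = 20


@dataclass(frozen=True)
class JunctionCall:
    read_id: str
    status: str
    chrom: str | None = None
    pos: int | None = None  # 1-based coordinate of the junction base
    strand: str | None = None
    umi: str | None = None


def gate_linker(
    sequence: str, linker: str, umi_length: int, offset: int = 0
) -> tuple[str, str] | None:
    """Require a perfect linker match and peel off the adjacent UMI.

    Returns ``(umi, remainder)`` or ``None`` when the linker (anchored at
    ``offset`` from the read start) does not match exactly or the read is
    too short to hold linker plus UMI.
    """
    if not linker or umi_length <= 0:
        raise ValueError("linker must be non-empty and umi_length > 0")
    end = offset + len(linker)
    if len(sequence) < end + umi_length:
        return None
    if sequence[offset:end] != linker:
        return None
    umi = sequence[end : end + umi_length]
    return umi, sequence[end + umi_length :]


def gate_hermes(fragment: str, hermes_end: str) -> str | None:
    """Require a perfect match to the entire transposon end and trim it."""
    if not fragment.startswith(hermes_end):
        return None
    return fragment[len(hermes_end) :]


class ReferenceIndex:
    """Exact-match search index over both strands of a reference.

    Seeds on the first ``seed_length`` bases of a query and verifies the
    full fragment, reporting at most two occurrences (enough to decide
    unique vs multi-mapped).
    """

    def __init__(self, sequences: Mapping[str, str], seed_length: int = MIN_FRAGMENT):
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self.seed_length = seed_length
        self._index: dict[str, list[tuple[str, int]]] = {}
        k = seed_length
        for chrom, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))

    @classmethod
    def from_fasta(cls, path: str | Path, seed_length: int = MIN_FRAGMENT):
        from sexfit.synthetic_data import read_fasta

        return cls(read_fasta(path), seed_length)

    def occurrences(self, fragment: str, limit: int = 2) -> list[tuple[str, int, str]]:
        """All occurrences of ``fragment`` on either strand, as
        ``(chrom, junction position 1-based, strand)``, up to ``limit``."""
        hits: list[tuple[str, int, str]] = []
        m = len(fragment)
        for chrom, i in self._index.get(fragment[: self.seed_length], []):
            if self.sequences[chrom][i : i + m] == fragment:
                hits.append((chrom, i + 1, "+"))
                if len(hits) >= limit:
                    return hits
        rc = reverse_complement(fragment)
        for chrom, i in self._index.get(rc[: self.seed_length], []):
            if self.sequences[chrom][i : i + m] == rc:
                # fragment's first base sits at the rightmost base of the
                # forward-strand match
                hits.append((chrom, i + m, "-"))
                if len(hits) >= limit:
                    return hits
        return hits


def map_unique(
    fragment: str, index: ReferenceIndex, min_fragment: int = MIN_FRAGMENT
) -> tuple[str, tuple[str, int, str] | None]:
    """Exact unique mapping of a genomic fragment on both strands.

    Returns ``("mapped_unique", (chrom, pos, strand))`` when the fragment
    occurs exactly once across both strands; ``("unmapped", None)`` for
    zero occurrences or fragments shorter than ``min_fragment``;
    ``("multi_mapped", None)`` for two or more.
    """
    if len(fragment) < min_fragment:
        return "unmapped", None
    hits = index.occurrences(fragment, limit=2)
    if not hits:
        return "unmapped", None
    if len(hits) > 1:
        return "multi_mapped", None
    return "mapped_unique", hits[0]


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    path = Path(path)
    handle = gzip.open(path, "rt") if path.suffix == ".gz" else open(path)
    with handle:
        for record in SeqIO.parse(handle, "fastq"):
            yield record.id, str(record.seq).upper()


def process_reads(
    fastq: str | Path | Iterable[tuple[str, str]],
    index: ReferenceIndex,
    linker: str,
    umi_length: int,
    hermes_end: str,
    min_fragment: int = MIN_FRAGMENT,
    linker_offset: int = 0,
) -> pd.DataFrame:
    """Run the full gate-and-map cascade over a FASTQ file or read stream.

    Every read receives exactly one status; the result is a JunctionCall
    table with columns ``read_id, chrom, pos, strand, umi, status``.
    """
    reads = _iter_fastq(fastq) if isinstance(fastq, (str, Path)) else fastq
    rows = []
    for read_id, seq in reads:
        gated = gate_linker(seq, linker, umi_length, linker_offset)
        if gated is None:
            rows.append((read_id, None, None, None, None, "no_linker"))
            continue
        umi, rest = gated
        fragment = gate_hermes(rest, hermes_end)
        if fragment is None:
            rows.append((read_id, None, None, None, umi, "no_hermes_end"))
            continue
        status, hit = map_unique(fragment, index, min_fragment)
        if status != "mapped_unique":
            rows.append((read_id, None, None, None, umi, status))
        else:
            chrom, pos, strand = hit
            rows.append((read_id, chrom, pos, strand, umi, "mapped_unique"))
    calls = pd.DataFrame(
        rows, columns=["read_id", "chrom", "pos", "strand", "umi", "status"]
    )
    calls["pos"] = calls["pos"].astype("Int64")
    return calls


def status_summary(calls: pd.DataFrame) -> dict[str, int]:
    tally = calls["status"].value_counts().to_dict()
    return {s: int(tally.get(s, 0)) for s in STATUSES} | {"total": int(len(calls))}


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"chrom": "object", "strand": "object", "umi": "object"}
    ).astype({"pos": "Int64"})


def write_status_summary(calls: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(json.dumps(status_summary(calls), indent=2) + "\n")
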