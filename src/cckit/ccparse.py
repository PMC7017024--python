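"""Parsing of paired calling-card reads into insertion events.

The inverse-PCR library puts a fixed 31 nt universal primer at the start of
read 1, followed by 39 nt of genomic sequence flanking the transposon
junction; the first 8 nt of read 2 are the unique molecular identifier (UMI)
that distinguishes independent transposition events from PCR duplicates.

Mapping is exact-match against an in-memory index of every 39-mer in the
genome (both strands).  At desk scale this is deterministic and removes any
aligner dependency; reads whose flank differs from the genome by even one
base are reported as unmapped, by design.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

# Read-structure constants of the inverse-PCR library.
PRIMER = "CGTCAATTTTACGCAGACTATCTTTCTAGGG"  # 31 nt universal primer
FLANK_LEN = 39  # genomic flank sequenced after the primer on read 1
UMI_LEN = 8  # first 8 nt of read 2
TTAA = "TTAA"  # piggyBac integration tetranucleotide

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STATUSES = ("ok", "no_primer", "short_flank", "low_quality", "unmapped", "multimapped")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class InsertionEvent:
    """One putative transposition event.

    ``pos`` is the 0-based coordinate of the first base of the TTAA
    integration site.  ``strand`` is the orientation of the inserted
    transposon, which fixes which side of the TTAA was sequenced.
    """

    chrom: str
    pos: int
    strand: str
    umi: str
    sample: str


@dataclass
class ReadPairParse:
    """Outcome of parsing one read pair.

    ``status == "ok"`` if and only if ``flank``, ``umi`` and (after mapping)
    ``location`` are all present.
    """

    status: str
    flank: str | None = None
    umi: str | None = None
    location: tuple[str, int, str] | None = None


@dataclass
class ParseReport:
    """Per-status tallies for a parsed read set; counts sum to input pairs."""

    counts: dict[str, int] = field(default_factory=lambda: {s: 0 for s in STATUSES})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.counts, indent=2, sort_keys=True) + "\n")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def parse_read_pair(
    read1: tuple[str, list[int]],
    read2: tuple[str, list[int]],
    max_primer_mismatches: int = 2,
    min_mean_quality: float = 20.0,
) -> ReadPairParse:
    """Parse one read pair up to (but not including) genome mapping.

    Parameters
    ----------
    read1, read2 : (sequence, phred qualities)
    max_primer_mismatches : substitutions tolerated in the 31 nt primer
        (no indels).
    min_mean_quality : minimum mean phred over read 1.

    Returns a :class:`ReadPairParse` whose status is the first failing check
    among no_primer, short_flank, low_quality; on success the status is
    ``ok`` with ``location`` still absent.
    """
    seq1, qual1 = read1
    seq2, qual2 = read2
    seq1 = seq1.upper()
    seq2 = seq2.upper()

    if len(seq1) < len(PRIMER) or _hamming(seq1[: len(PRIMER)], PRIMER) > max_primer_mismatches:
        return ReadPairParse(status="no_primer")
    if len(seq1) < len(PRIMER) + FLANK_LEN:
        return ReadPairParse(status="short_flank")
    flank = seq1[len(PRIMER) : len(PRIMER) + FLANK_LEN]
    if qual1 and sum(qual1) / len(qual1) < min_mean_quality:
        return ReadPairParse(status="low_quality")
    if "N" in flank or len(seq2) < UMI_LEN:
        return ReadPairParse(status="low_quality")
    umi = seq2[:UMI_LEN]
    if "N" in umi:
        return ReadPairParse(status="low_quality")
    return ReadPairParse(status="ok", flank=flank, umi=umi)


class GenomeIndex:
    """Exact-match index of every genomic 39-mer, both strands.

    A forward 39-mer starting at ``g`` corresponds to the flank of a
    plus-strand event whose TTAA starts at ``g - 4`` (the flank is sequenced
    3' of the TTAA on the event strand); its reverse complement corresponds
    to a minus-strand event whose TTAA starts at ``g + 39``.
    """

    def __init__(self, sequences: dict[str, str], k: int = FLANK_LEN):
        self.k = k
        self.chrom_sizes = {c: len(s) for c, s in sequences.items()}
        index: dict[str, list[tuple[str, int, str]]] = {}
        for chrom, seq in sequences.items():
            seq = seq.upper()
            L = len(seq)
            for g in range(L - k + 1):
                kmer = seq[g : g + k]
                if g - len(TTAA) >= 0:
                    index.setdefault(kmer, []).append((chrom, g - len(TTAA), "+"))
                if g + k + len(TTAA) <= L:
                    index.setdefault(revcomp(kmer), []).append((chrom, g + k, "-"))
        self._index = index

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def locate(self, flank: str) -> list[tuple[str, int, str]]:
        return self._index.get(flank.upper(), [])


def map_flank(flank: str, index: GenomeIndex) -> ReadPairParse:
    """Map a 39 nt flank to its unique insertion-junction location.

    Returns a parse with status ``ok`` and a (chrom, pos, strand) location
    on a unique exact match, ``unmapped`` on zero matches, ``multimapped``
    on two or more.
    """
    if set(flank.upper()) - set("ACGTN"):
        raise ValueError(f"flank contains non-ACGTN characters: {flank!r}")
    hits = index.locate(flank)
    if len(hits) == 1:
        return ReadPairParse(status="ok", flank=flank, location=hits[0])
    if not hits:
        return ReadPairParse(status="unmapped", flank=flank)
    return ReadPairParse(status="multimapped", flank=flank)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path: str | Path) -> Iterator:
    with _open_maybe_gzip(path) as handle:
        yield from SeqIO.parse(handle, "fastq")


def extract_events(
    fastq1: str | Path,
    fastq2: str | Path,
    genome: str | Path | GenomeIndex,
    sample_id: str,
    max_primer_mismatches: int = 2,
    min_mean_quality: float = 20.0,
) -> tuple[list[InsertionEvent], ParseReport]:
    """Stream paired FASTQ files into insertion events.

    One event is emitted per read pair that passes primer, flank, quality
    and unique-mapping checks; every pair is tallied in the report under
    exactly one status.  Unpaired files (unequal record counts or mismatched
    read ids) raise ``ValueError`` naming the offending record index.
    """
    if isinstance(genome, GenomeIndex):
        index = genome
    else:
        index = GenomeIndex.from_fasta(genome)

    events: list[InsertionEvent] = []
    report = ParseReport()
    _SENTINEL = object()

    it1: Iterable = _iter_fastq(fastq1)
    it2: Iterable = _iter_fastq(fastq2)
    from itertools import zip_longest

    for i, (r1, r2) in enumerate(zip_longest(it1, it2, fillvalue=_SENTINEL)):
        if r1 is _SENTINEL or r2 is _SENTINEL:
            raise ValueError(f"unpaired FASTQ input: files diverge at record {i}")
        if _core_id(r1.id) != _core_id(r2.id):
            raise ValueError(
                f"read id mismatch at record {i}: {r1.id!r} vs {r2.id!r}"
            )
        parse = parse_read_pair(
            (str(r1.seq), r1.letter_annotations.get("phred_quality", [])),
            (str(r2.seq), r2.letter_annotations.get("phred_quality", [])),
            max_primer_mismatches=max_primer_mismatches,
            min_mean_quality=min_mean_quality,
        )
        if parse.status == "ok":
            parse = _map_parsed(parse, index)
        report.counts[parse.status] += 1
        if parse.status == "ok":
            chrom, pos, strand = parse.location
            events.append(
                InsertionEvent(chrom=chrom, pos=pos, strand=strand, umi=parse.umi, sample=sample_id)
            )
    return events, report


def _map_parsed(parse: ReadPairParse, index: GenomeIndex) -> ReadPairParse:
    mapped = map_flank(parse.flank, index)
    if mapped.status == "ok":
        return ReadPairParse(status="ok", flank=parse.flank, umi=parse.umi, location=mapped.location)
    return ReadPairParse(status=mapped.status, flank=parse.flank, umi=parse.umi)


def _core_id(read_id: str) -> str:
    return read_id.rsplit("/", 1)[0]


def write_events_tsv(events: Iterable[InsertionEvent], path: str | Path) -> None:
    """Write events as BED-like TSV: chrom, start, start+4, UMI, 1, strand."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tumi\tcount\tstrand\tsample\n")
        for e in sorted(events, key=lambda e: (e.sample, e.chrom, e.pos, e.strand, e.umi)):
            fh.write(f"{e.chrom}\t{e.pos}\t{e.pos + len(TTAA)}\t{e.umi}\t1\t{e.strand}\t{e.sample}\n")


def read_events_tsv(path: str | Path) -> list[InsertionEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, _end, umi, _count, strand, sample = line.rstrip("\n").split("\t")
            events.append(InsertionEvent(chrom, int(start), strand, umi, sample))
    return events
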