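"""Synthetic genomes, insertions, reads and SELEX pools.

Every generator here is a pure function of its arguments including the
seed, so downstream modules can be exercised end to end with no external
data.  The generators emulate the statistical structure the analysis
assumes:

* a genome with uniform i.i.d. base composition plus planted consensus
  binding sites (default TGAAACA, the Ste12 pheromone response element);
* factor-directed transposon insertions at TTAA tetranucleotides near the
  planted sites, on top of a uniform background over all TTAA sites — the
  within-window placement follows a distance-decay kernel because real
  calling-card insertions pile up closest to the bound site;
* paired reads with the inverse-PCR structure (31 nt universal primer +
  39 nt genomic flank on read 1; 8 nt UMI at the start of read 2);
* SELEX pools of 36-mers evolving under a Boltzmann affinity model
  (per-ligand survival weight exp(s * match_fraction)), the simplest model
  that produces a monotone round-wise consensus enrichment.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ccparse import FLANK_LEN, PRIMER, TTAA, UMI_LEN, InsertionEvent, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
CONSENSUS = "TGAAACA"  # Ste12 pheromone response element


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class PlantedSite:
    chrom: str
    start: int
    strand: str
    label: str


@dataclass
class SyntheticGenome:
    """A small genome with known planted motif instances and a TTAA index."""

    sequences: dict[str, str]
    planted_motif_sites: list[PlantedSite]
    ttaa_sites: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.ttaa_sites:
            self.ttaa_sites = self._scan_ttaa()

    def _scan_ttaa(self) -> list[tuple[str, int]]:
        sites = []
        for chrom, seq in self.sequences.items():
            i = seq.find(TTAA)
            while i != -1:
                sites.append((chrom, i))
                i = seq.find(TTAA, i + 1)
        return sites

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def write_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in self.sequences.items()]
        SeqIO.write(records, str(path), "fasta")


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def make_genome(
    n_chrom: int,
    chrom_len: int,
    n_planted_sites: int,
    motif: str = CONSENSUS,
    seed: int = 0,
    ensure_near_ttaa: int | None = None,
) -> SyntheticGenome:
    """Random uniform-composition genome with planted motif instances.

    Planted instances are non-overlapping and recorded with their strand;
    a minus-strand plant writes the reverse complement.  When
    ``ensure_near_ttaa`` is given, a literal TTAA is written within that
    many bp downstream of each planted motif (if none is present), so that
    every planted site has at least one reachable integration site.

    Raises ``ValueError`` for a non-ACGT motif or when the requested number
    of sites cannot be placed without overlap.
    """
    if chrom_len < 1000:
        raise ValueError("chrom_len must be >= 1000")
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif contains non-ACGT characters: {motif!r}")
    if len(motif) > chrom_len:
        raise ValueError("motif longer than chromosome")
    rng = np.random.default_rng(seed)

    chroms = {f"chr{i + 1}": rng.choice(BASES, size=chrom_len) for i in range(n_chrom)}
    planted: list[PlantedSite] = []

    pad = len(motif) + (ensure_near_ttaa or 0) + len(TTAA) + 10
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(planted) < n_planted_sites:
        attempts += 1
        if attempts > 200 * max(1, n_planted_sites):
            raise ValueError(
                f"could not place {n_planted_sites} non-overlapping motif sites "
                f"in {n_chrom} x {chrom_len} bp"
            )
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        start = int(rng.integers(pad, chrom_len - pad))
        if any(start < e and start + pad > s for s, e in occupied[chrom]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        _plant(chroms[chrom], start, motif if strand == "+" else revcomp(motif))
        if ensure_near_ttaa is not None:
            _ensure_ttaa_near(chroms[chrom], start + len(motif), ensure_near_ttaa, rng)
        occupied[chrom].append((start - pad, start + pad))
        planted.append(PlantedSite(chrom, start, strand, motif))

    sequences = {c: _decode(arr) for c, arr in chroms.items()}
    return SyntheticGenome(sequences=sequences, planted_motif_sites=planted)


def _plant(seq: np.ndarray, start: int, text: str) -> None:
    seq[start : start + len(text)] = np.frombuffer(text.encode(), dtype=np.uint8)


def _ensure_ttaa_near(seq: np.ndarray, pos: int, max_dist: int, rng: np.random.Generator) -> None:
    window = _decode(seq[pos : pos + max_dist])
    if TTAA not in window:
        offset = int(rng.integers(2, max(3, max_dist - len(TTAA))))
        _plant(seq, pos + offset, TTAA)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def make_annotation(genome: SyntheticGenome, n_genes: int, seed: int = 0, min_gap: int = 1000) -> pd.DataFrame:
    """Random gene table (gene_id, chrom, strand, tss, span).

    TSSs are placed with at least ``min_gap`` bp between genes on the same
    chromosome and away from chromosome ends; strands are random.
    Deterministic for a seed; raises ``ValueError`` when ``n_genes`` cannot
    be placed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    placed: dict[str, list[int]] = {c: [] for c in genome.sequences}
    chrom_names = sorted(genome.sequences)
    attempts = 0
    restart = 100 * max(1, n_genes)
    while len(rows) < n_genes:
        attempts += 1
        if attempts % restart == 0:
            # greedy placement can wedge itself; restart from scratch
            rows = []
            placed = {c: [] for c in genome.sequences}
        if attempts > 10 * restart:
            raise ValueError(f"could not place {n_genes} genes with gap {min_gap}")
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        L = len(genome.sequences[chrom])
        margin = 1500
        if L <= 2 * margin:
            continue
        tss = int(rng.integers(margin, L - margin))
        if any(abs(tss - t) < min_gap for t in placed[chrom]):
            continue
        placed[chrom].append(tss)
        strand = "+" if rng.random() < 0.5 else "-"
        span = int(rng.integers(500, 2000))
        rows.append((f"gene{len(rows) + 1:04d}", chrom, strand, tss, span))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "span"])
    return df.sort_values(["chrom", "tss"], ignore_index=True)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# insertions
# ---------------------------------------------------------------------------

@dataclass
class InsertionModel:
    """Mixture model for insertion placement.

    A fraction ``p_near`` of events is factor-directed: a planted site is
    chosen uniformly, then a TTAA within ``d_max`` bp of it with weight
    exp(-distance / near_decay_bp).  The remainder lands uniformly over all
    TTAA sites.  ``respect_read_bounds`` restricts eligible TTAAs to those
    with a full 39 bp flank on both sides, so every event is sequenceable.
    """

    p_near: float = 0.5
    d_max: int = 200
    n_events: int = 1000
    near_decay_bp: float = 75.0
    respect_read_bounds: bool = True

    def __post_init__(self):
        if not 0.0 <= self.p_near <= 1.0:
            raise ValueError("p_near must be in [0, 1]")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")


def _random_umis(rng: np.random.Generator, n: int) -> list[str]:
    arr = rng.choice(BASES, size=(n, UMI_LEN))
    return [_decode(row) for row in arr]


def simulate_insertions(
    genome: SyntheticGenome,
    model: InsertionModel,
    sample_id: str,
    seed: int = 0,
) -> list[InsertionEvent]:
    """Draw ``model.n_events`` insertion events from the mixture model.

    Every event's position is a TTAA start; each event carries an
    independent random 8-mer UMI (collisions allowed).  Raises
    ``ValueError`` when no TTAA is eligible, or when ``p_near > 0`` but no
    TTAA lies within ``d_max`` of any planted site.
    """
    rng = np.random.default_rng(seed)
    eligible = _eligible_ttaa(genome, model.respect_read_bounds)
    if model.n_events == 0:
        return []
    if not eligible:
        raise ValueError("genome has no eligible TTAA site")

    near_pools: list[tuple[np.ndarray, np.ndarray]] = []  # (indices into eligible, weights)
    if model.p_near > 0:
        positions = np.array([p for _, p in eligible])
        chrom_of = np.array([c for c, _ in eligible])
        for site in genome.planted_motif_sites:
            center = site.start + len(site.label) / 2
            mask = chrom_of == site.chrom
            d = np.abs(positions + len(TTAA) / 2 - center)
            sel = np.flatnonzero(mask & (d <= model.d_max))
            if sel.size:
                w = np.exp(-d[sel] / model.near_decay_bp)
                near_pools.append((sel, w / w.sum()))
        if not near_pools:
            raise ValueError("p_near > 0 but no TTAA lies within d_max of any planted site")

    n = model.n_events
    is_near = rng.random(n) < model.p_near
    umis = _random_umis(rng, n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    events = []
    for i in range(n):
        if is_near[i]:
            sel, w = near_pools[int(rng.integers(len(near_pools)))]
            idx = int(rng.choice(sel, p=w))
        else:
            idx = int(rng.integers(len(eligible)))
        chrom, pos = eligible[idx]
        events.append(InsertionEvent(chrom=chrom, pos=pos, strand=str(strands[i]), umi=umis[i], sample=sample_id))
    return events


def _eligible_ttaa(genome: SyntheticGenome, respect_read_bounds: bool) -> list[tuple[str, int]]:
    if not respect_read_bounds:
        return list(genome.ttaa_sites)
    sizes = genome.chrom_sizes
    out = []
    for chrom, pos in genome.ttaa_sites:
        if pos >= FLANK_LEN and pos + len(TTAA) + FLANK_LEN <= sizes[chrom]:
            out.append((chrom, pos))
    return out


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    events: Sequence[InsertionEvent],
    genome: SyntheticGenome,
    seed: int = 0,
    read2_len: int = 28,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Paired reads for a list of events.

    Read 1 is the 31 nt universal primer followed by the 39 bp of genome 3'
    of the TTAA on the event's strand; read 2 starts with the event's 8 nt
    UMI followed by random filler.  Base qualities are constant high
    (phred 40).  Raises ``ValueError`` for events too close to a chromosome
    end for a full flank.
    """
    rng = np.random.default_rng(seed)
    r1_records, r2_records = [], []
    quals1 = [40] * (len(PRIMER) + FLANK_LEN)
    for i, e in enumerate(events):
        seq = genome.sequences[e.chrom]
        if e.strand == "+":
            start = e.pos + len(TTAA)
            if start + FLANK_LEN > len(seq):
                raise ValueError(f"event {i} at {e.chrom}:{e.pos}(+) lacks a full 3' flank")
            flank = seq[start : start + FLANK_LEN]
        else:
            if e.pos - FLANK_LEN < 0:
                raise ValueError(f"event {i} at {e.chrom}:{e.pos}(-) lacks a full 3' flank")
            flank = revcomp(seq[e.pos - FLANK_LEN : e.pos])
        filler = _decode(rng.choice(BASES, size=read2_len - UMI_LEN))
        rid = f"sim:{e.sample}:{i}"
        r1 = SeqRecord(Seq(PRIMER + flank), id=rid, description="")
        r1.letter_annotations["phred_quality"] = quals1
        r2 = SeqRecord(Seq(e.umi + filler), id=rid, description="")
        r2.letter_annotations["phred_quality"] = [40] * read2_len
        r1_records.append(r1)
        r2_records.append(r2)
    return r1_records, r2_records


def write_fastq_pair(
    r1_records: Sequence[SeqRecord],
    r2_records: Sequence[SeqRecord],
    path1: str | Path,
    path2: str | Path,
) -> None:
    """Write paired FASTQ, gzip-compressed when the path ends in .gz."""
    for records, path in ((r1_records, path1), (r2_records, path2)):
        path = Path(path)
        if path.suffix == ".gz":
            with gzip.open(path, "wt") as fh:
                SeqIO.write(records, fh, "fastq")
        else:
            SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# SELEX
# ---------------------------------------------------------------------------

@dataclass
class SelexModel:
    """Affinity-based selection over rounds of a random 36-mer pool.

    Surviving round r applies a Boltzmann factor exp(s * best_match_fraction)
    per round, where best_match_fraction is the best fraction of consensus
    positions matched at any offset on either strand; the round-r pool is an
    i.i.d. sample from the resulting exponentially tilted ligand
    distribution.  This emulates selection on the real 36N library, whose
    ~1e12-molecule diversity is effectively infinite at sequencing depth:
    distinct winners share the consensus but not their flanks, so only
    consensus-containing k-mers aggregate.  (Resampling a desk-scale finite
    pool instead lets a few founder clones take over and spuriously enriches
    their flank k-mers.)  At ``selection_strength = 0`` the tilt is flat and
    every pool is uniform random.
    """

    consensus: str = CONSENSUS
    selection_strength: float = 5.0
    rounds: int = 5
    pool_size: int = 20_000
    ligand_length: int = 36

    def __post_init__(self):
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.ligand_length != 36:
            raise ValueError("ligand_length is fixed at 36")


def _encode_pool(pool: Sequence[str]) -> np.ndarray:
    flat = "".join(pool).encode("ascii")
    return np.frombuffer(flat, dtype=np.uint8).reshape(len(pool), -1)


def best_match_scores(pool: np.ndarray, consensus: str) -> np.ndarray:
    """Best consensus match fraction per ligand, over offsets and strands."""
    w = len(consensus)
    fwd = np.frombuffer(consensus.encode(), dtype=np.uint8)
    rev = np.frombuffer(revcomp(consensus).encode(), dtype=np.uint8)
    n, L = pool.shape
    best = np.zeros(n, dtype=np.int64)
    for off in range(L - w + 1):
        window = pool[:, off : off + w]
        np.maximum(best, (window == fwd).sum(axis=1), out=best)
        np.maximum(best, (window == rev).sum(axis=1), out=best)
    return best / w


def _sample_tilted_pool(
    rng: np.random.Generator,
    n: int,
    length: int,
    consensus: str,
    log_tilt: float,
    chunk: int = 200_000,
    max_candidates: int = 50_000_000,
) -> np.ndarray:
    """Rejection-sample ``n`` ligands with density prop. to exp(log_tilt * score).

    Acceptance probability is exp(log_tilt * (score - 1)), which is exact
    since score <= 1.  Candidates are drawn in chunks until enough survive.
    """
    if log_tilt == 0:
        return rng.choice(BASES, size=(n, length))
    accepted: list[np.ndarray] = []
    total = 0
    drawn = 0
    while total < n:
        if drawn >= max_candidates:
            raise RuntimeError("selection too strong: rejection sampling stalled")
        cand = rng.choice(BASES, size=(chunk, length))
        drawn += chunk
        scores = best_match_scores(cand, consensus)
        keep = rng.random(chunk) < np.exp(log_tilt * (scores - 1.0))
        got = cand[keep]
        accepted.append(got)
        total += len(got)
    return np.concatenate(accepted)[:n]


def simulate_selex(model: SelexModel, seed: int = 0) -> list[list[str]]:
    """Per-round 36-mer pools; element 0 is the random input pool.

    Round r is an i.i.d. sample of ``pool_size`` ligands from the
    distribution proportional to exp(r * s * best_match_fraction) over
    uniform 36-mers (see :class:`SelexModel`).  Returns ``model.rounds + 1``
    pools of exactly ``model.pool_size`` sequences each; deterministic per
    seed.
    """
    rng = np.random.default_rng(seed)
    n = model.pool_size
    pools = [rng.choice(BASES, size=(n, model.ligand_length))]
    for r in range(1, model.rounds + 1):
        pools.append(
            _sample_tilted_pool(
                rng, n, model.ligand_length, model.consensus, r * model.selection_strength
            )
        )
    return [[_decode(row) for row in p] for p in pools]


def write_pool(pool: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(pool) + "\n")


def read_pool(path: str | Path) -> list[str]:
    """Read a SELEX pool from line-per-sequence text or FASTQ."""
    path = Path(path)
    if path.suffix in {".fastq", ".fq"}:
        return [str(r.seq) for r in SeqIO.parse(str(path), "fastq")]
    return [line.strip().upper() for line in path.read_text().splitlines() if line.strip()]


# ---------------------------------------------------------------------------
# study-scale scenario
# ---------------------------------------------------------------------------

@dataclass
class CallingCardScenario:
    """A self-contained calling-card study: genome + genes + planted signal.

    ``bound_genes`` carry a planted consensus inside their promoter window
    (1000 bp 5' to 200 bp 3' of the TSS) with a guaranteed nearby TTAA.
    """

    genome: SyntheticGenome
    annotation: pd.DataFrame
    bound_genes: list[str]
    model: InsertionModel


def make_callingcard_scenario(
    seed: int = 0,
    genome_len: int = 200_000,
    n_genes: int = 40,
    n_bound: int = 12,
    n_events: int = 5000,
    p_near: float = 0.8,
    d_max: int = 200,
    motif: str = CONSENSUS,
) -> CallingCardScenario:
    """Build the standard synthetic study used throughout the test suite.

    One chromosome of ``genome_len`` bp, ``n_genes`` genes, and a consensus
    motif planted 400 bp upstream of the TSS of ``n_bound`` of them (well
    inside the promoter assignment window), each with a TTAA within 40 bp
    of the motif.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(BASES, size=genome_len)

    margin = 1500
    min_gap = 3000
    spacing = (genome_len - 2 * margin) / n_genes
    if spacing < min_gap + 100:
        raise ValueError("could not place genes; increase genome_len")
    jitter_span = int(spacing - min_gap)
    chosen = [
        int(margin + i * spacing + rng.integers(0, jitter_span)) for i in range(n_genes)
    ]

    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    rows = [(f"gene{i + 1:04d}", "chr1", strands[i], chosen[i], int(rng.integers(500, 2000))) for i in range(n_genes)]
    annotation = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "span"])

    bound_idx = sorted(rng.choice(n_genes, size=n_bound, replace=False).tolist())
    planted: list[PlantedSite] = []
    for i in bound_idx:
        tss = chosen[i]
        start = tss - 400 if strands[i] == "+" else tss + 400 - len(motif)
        plant_strand = "+" if rng.random() < 0.5 else "-"
        _plant(seq, start, motif if plant_strand == "+" else revcomp(motif))
        _ensure_ttaa_near(seq, start + len(motif), 40, rng)
        planted.append(PlantedSite("chr1", start, plant_strand, motif))

    genome = SyntheticGenome(sequences={"chr1": _decode(seq)}, planted_motif_sites=planted)
    model = InsertionModel(p_near=p_near, d_max=d_max, n_events=n_events)
    bound_genes = [rows[i][0] for i in bound_idx]
    return CallingCardScenario(genome=genome, annotation=annotation, bound_genes=bound_genes, model=model)
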