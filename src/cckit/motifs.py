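"""K-mer and PWM analyses of binding regions.

Covers the sequence analyses run on calling-card binding regions: 7-mer
enrichment over the genome background, nearest-consensus-site distances,
consensus frequency enrichment, extraction and merging of 300 bp windows
around high-count insertions, log-odds scanning of known position weight
matrices with exact p-values, motif-pair coincidence counting, and a
dispersion-aware differential test of motif-pair frequencies across
samples with replicates.

PWM scan p-values are exact: the null distribution of the integer-scaled
log-odds score under the (strand-symmetrised) background is computed by
dynamic programming over positions, so a hit's p-value is the true
probability that a random background word scores at least as high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio import motifs as bio_motifs

from .ccparse import revcomp
from .simdata import CONSENSUS, SyntheticGenome

logger = logging.getLogger(__name__)

SCORE_SCALE = 100  # integer score grid: centibits
PSEUDOCOUNT = 0.5  # enrichment-ratio pseudocount, used throughout

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _sequences(genome) -> dict[str, str]:
    if isinstance(genome, SyntheticGenome):
        return genome.sequences
    return dict(genome)


def _fetch(seqs: dict[str, str], chrom: str, start: int, end: int) -> str:
    return seqs[chrom][max(0, start) : end]


# ---------------------------------------------------------------------------
# k-mer enrichment
# ---------------------------------------------------------------------------

def _count_kmers_both_strands(texts: Iterable[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for text in texts:
        for s in (text.upper(), revcomp(text.upper())):
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if "N" in kmer:
                    continue
                counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_enrichment(
    regions: pd.DataFrame,
    genome,
    k: int = 7,
    flank: int = 50,
) -> pd.DataFrame:
    """Per-k-mer enrichment of target regions over the genome background.

    Every region is widened to ``2 * flank`` bp around its midpoint
    (clipped at chromosome ends), k-mers are counted on both strands, and
    the expected count of each k-mer is its genome-wide (both-strand)
    frequency times the number of k-mer windows in the targets.  Enrichment
    is (observed + 0.5) / (expected + 0.5); k-mers and their reverse
    complements stay separate rows.

    Returns a DataFrame (kmer, observed, expected, enrichment) sorted by
    enrichment descending; empty regions give an empty frame.
    """
    seqs = _sequences(genome)
    cols = ["kmer", "observed", "expected", "enrichment"]
    if len(regions) == 0:
        return pd.DataFrame(columns=cols)
    texts = []
    for _, r in regions.iterrows():
        mid = (int(r["start"]) + int(r["end"])) // 2
        text = _fetch(seqs, r["chrom"], mid - flank, mid + flank)
        if len(text) < k:
            raise ValueError(f"region at {r['chrom']}:{r['start']} shorter than k after expansion")
        texts.append(text)
    observed = _count_kmers_both_strands(texts, k)
    background = _count_kmers_both_strands(seqs.values(), k)
    bg_total = sum(background.values())
    target_total = sum(observed.values())

    kmers = sorted(set(observed) | set(background))
    obs = np.array([observed.get(m, 0) for m in kmers], dtype=float)
    exp = np.array([background.get(m, 0) / bg_total * target_total for m in kmers])
    enr = (obs + PSEUDOCOUNT) / (exp + PSEUDOCOUNT)
    out = pd.DataFrame({"kmer": kmers, "observed": obs.astype(int), "expected": exp, "enrichment": enr})
    return out.sort_values(["enrichment", "kmer"], ascending=[False, True], ignore_index=True)


# ---------------------------------------------------------------------------
# consensus-site geometry
# ---------------------------------------------------------------------------

def consensus_occurrences(genome, consensus: str = CONSENSUS) -> list[tuple[str, int]]:
    """Start positions of exact consensus matches on either strand."""
    seqs = _sequences(genome)
    rc = revcomp(consensus)
    out = []
    for chrom, seq in seqs.items():
        seq = seq.upper()
        for pattern in {consensus, rc}:
            i = seq.find(pattern)
            while i != -1:
                out.append((chrom, i))
                i = seq.find(pattern, i + 1)
    return sorted(set(out))


def nearest_motif_distance(
    peaks: pd.DataFrame,
    genome,
    consensus: str = CONSENSUS,
    cap: int = 1000,
) -> tuple[pd.Series, float]:
    """Distance from each peak midpoint to the nearest consensus-site centre.

    Distances are capped at ``cap``; the summary is the fraction of peaks
    with a consensus site within 200 bp.  A genome with no consensus
    instance yields all-capped distances and fraction 0.
    """
    occ = consensus_occurrences(genome, consensus)
    centers: dict[str, np.ndarray] = {}
    for chrom, pos in occ:
        centers.setdefault(chrom, [])
    for chrom, pos in occ:
        centers[chrom].append(pos + len(consensus) / 2)
    centers = {c: np.sort(np.array(v)) for c, v in centers.items()}

    dists = []
    for _, r in peaks.iterrows():
        mid = (int(r["start"]) + int(r["end"])) / 2
        cs = centers.get(r["chrom"])
        if cs is None or cs.size == 0:
            dists.append(float(cap))
            continue
        dists.append(float(min(np.min(np.abs(cs - mid)), cap)))
    dist = pd.Series(dists, name="distance")
    fraction = float((dist <= 200).mean()) if len(dist) else 0.0
    return dist, fraction


def consensus_frequency_enrichment(
    regions: pd.DataFrame,
    genome,
    consensus: str = CONSENSUS,
) -> float:
    """Per-bp consensus match rate in regions over the genome-wide rate.

    Matches are exact, counted on both strands; counts carry a pseudocount
    of 0.5 so region sets with zero matches get a finite value.
    """
    seqs = _sequences(genome)
    rc = revcomp(consensus)

    def _count(text: str) -> int:
        n = 0
        for pattern in {consensus, rc}:
            i = text.find(pattern)
            while i != -1:
                n += 1
                i = text.find(pattern, i + 1)
        return n

    region_bp = 0
    region_hits = 0
    for _, r in regions.iterrows():
        text = _fetch(seqs, r["chrom"], int(r["start"]), int(r["end"])).upper()
        region_bp += len(text)
        region_hits += _count(text)
    genome_bp = sum(len(s) for s in seqs.values())
    genome_hits = sum(_count(s.upper()) for s in seqs.values())
    if region_bp == 0:
        raise ValueError("empty region set")
    expected = genome_hits / genome_bp * region_bp
    return (region_hits + PSEUDOCOUNT) / (expected + PSEUDOCOUNT)


# ---------------------------------------------------------------------------
# high-count insertion windows
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Union of half-open intervals; overlapping or touching spans merge."""
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
        else:
            out.append((chrom, start, end))
    return out


def high_count_windows(
    sites: pd.DataFrame,
    percentile: float = 85.0,
    window: int = 300,
) -> pd.DataFrame:
    """Merged windows around insertions with counts at or above a percentile.

    The threshold is the given percentile of per-site distinct-UMI counts
    (linear interpolation); qualifying sites get a ``window`` bp interval
    centred on them, and overlapping or touching windows are merged.

    Returns a DataFrame (chrom, start, end), sorted and pairwise disjoint;
    ``len(result)`` is the window count used to normalise pair counts.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    if sites.empty:
        raise ValueError("need at least one site")
    threshold = float(np.percentile(sites["umis"].to_numpy(), percentile))
    qual = sites[sites["umis"] >= threshold]
    half = window // 2
    intervals = [
        (r["chrom"], max(0, int(r["pos"]) + 2 - half), int(r["pos"]) + 2 + half) for _, r in qual.iterrows()
    ]
    merged = merge_intervals(intervals)
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# PWMs: MEME minimal format and exact-p-value scanning
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """A position weight matrix: probabilities, rows = positions, cols = ACGT."""

    name: str
    probs: np.ndarray  # (w, 4), rows sum to 1

    @property
    def width(self) -> int:
        return len(self.probs)

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.probs[::-1, ::-1].copy())


class MemeParseError(ValueError):
    pass


def parse_meme(path_or_text: str | Path) -> list[PWM]:
    """Parse PWMs from MEME minimal text format.

    Probability rows are validated first (field count, numeric values, row
    sums within 1e-3 of 1) so malformed files fail with the offending line
    number; the actual parsing is delegated to Bio.motifs.
    """
    if isinstance(path_or_text, Path) or "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    _validate_meme(text)
    try:
        records = bio_motifs.parse(StringIO(text), "minimal")
    except Exception as exc:  # pragma: no cover - validation catches most
        raise MemeParseError(f"malformed MEME file: {exc}") from exc
    out = []
    for m in records:
        probs = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
        out.append(PWM(name=m.name, probs=probs))
    return out


def _validate_meme(text: str) -> None:
    in_matrix = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("letter-probability matrix"):
            in_matrix = True
            continue
        if in_matrix:
            if not stripped or stripped.startswith(("MOTIF", "URL")):
                in_matrix = False
                continue
            fields = stripped.split()
            try:
                values = [float(f) for f in fields]
            except ValueError as exc:
                raise MemeParseError(f"line {lineno}: non-numeric matrix entry") from exc
            if len(values) != 4:
                raise MemeParseError(f"line {lineno}: expected 4 probabilities, got {len(values)}")
            if abs(sum(values) - 1.0) > 1e-3:
                raise MemeParseError(f"line {lineno}: probabilities sum to {sum(values):.4f}, not 1")


def write_meme(pwms: Sequence[PWM], path: str | Path, background: Sequence[float] = (0.25,) * 4) -> None:
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    lines += ["Background letter frequencies", " ".join(f"{b} {f:.5f}" for b, f in zip("ACGT", background)), ""]
    for pwm in pwms:
        lines.append(f"MOTIF {pwm.name}")
        lines.append(f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20 E= 0")
        for row in pwm.probs:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def consensus_pwm(name: str, consensus: str, match_prob: float = 0.85) -> PWM:
    """PWM with ``match_prob`` on the consensus base at each position."""
    w = len(consensus)
    probs = np.full((w, 4), (1 - match_prob) / 3)
    for i, b in enumerate(consensus):
        probs[i, _BASE_INDEX[b]] = match_prob
    return PWM(name=name, probs=probs)


def toy_motif_library() -> list[PWM]:
    """Five consensus-derived PWMs for tests: Ste12, Tec1, Mcm1 + 2 decoys."""
    return [
        consensus_pwm("STE12", "TGAAACA"),
        consensus_pwm("TEC1", "GAATGT"),
        consensus_pwm("MCM1", "TTTCCTAATTAGGAAA", match_prob=0.7),
        consensus_pwm("DECOY1", "ACGCGTAC"),
        consensus_pwm("DECOY2", "CATGGCAT"),
    ]


def genome_background(genome) -> np.ndarray:
    """Strand-symmetric base frequencies (A=T, C=G averaged) of a genome."""
    seqs = _sequences(genome)
    counts = np.zeros(4)
    for seq in seqs.values():
        for b, i in _BASE_INDEX.items():
            counts[i] += seq.count(b)
    freq = counts / counts.sum()
    at = (freq[0] + freq[3]) / 2
    cg = (freq[1] + freq[2]) / 2
    return np.array([at, cg, cg, at])


@dataclass
class ScoredPWM:
    """A PWM with integer log-odds scores and its exact null tail.

    Scores are log2(p / bg) in centibits, rounded to integers; the exact
    distribution of a random background word's total score is computed by
    DP, and ``pvalue(s)`` is P(score >= s) under that null.
    """

    pwm: PWM
    int_scores: np.ndarray  # (w, 4)
    _tail: np.ndarray
    _min_sum: int

    @classmethod
    def build(cls, pwm: PWM, background: np.ndarray, regularize: float = 1e-4) -> "ScoredPWM":
        probs = pwm.probs + regularize
        probs = probs / probs.sum(axis=1, keepdims=True)
        bits = np.log2(probs / background)
        int_scores = np.rint(bits * SCORE_SCALE).astype(np.int64)
        # exact null: convolve the per-position 4-point score distributions
        cur = np.array([1.0])
        cur_min = 0
        for i in range(pwm.width):
            row = int_scores[i]
            rmin, rmax = int(row.min()), int(row.max())
            new = np.zeros(len(cur) + rmax - rmin)
            for b in range(4):
                shift = int(row[b]) - rmin
                new[shift : shift + len(cur)] += background[b] * cur
            cur = new
            cur_min += rmin
        tail = np.cumsum(cur[::-1])[::-1]
        return cls(pwm=pwm, int_scores=int_scores, _tail=tail, _min_sum=cur_min)

    def score_word(self, encoded: np.ndarray) -> int:
        return int(self.int_scores[np.arange(self.pwm.width), encoded].sum())

    def pvalue(self, int_score: int) -> float:
        idx = int_score - self._min_sum
        if idx < 0:
            return 1.0
        if idx >= len(self._tail):
            return 0.0
        return float(self._tail[idx])


@dataclass
class MotifHit:
    window_id: str
    motif_id: str
    position: int  # offset within the window
    strand: str
    score: float  # log-odds, bits
    p_value: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def scan_sequence(
    seq: str,
    scored: ScoredPWM,
    p_threshold: float = 1e-4,
    window_id: str = "w0",
) -> list[MotifHit]:
    """All above-threshold hits of one PWM on both strands of a sequence."""
    hits = []
    enc = _encode(seq)
    w = scored.pwm.width
    for strand, sp in (("+", scored), ("-", None)):
        if strand == "-":
            sp = ScoredPWM(
                pwm=scored.pwm.reverse_complement(),
                int_scores=scored.int_scores[::-1, ::-1],
                _tail=scored._tail,
                _min_sum=scored._min_sum,
            )
        for off in range(len(enc) - w + 1):
            word = enc[off : off + w]
            if (word < 0).any():
                continue
            s = sp.score_word(word)
            p = sp.pvalue(s)
            if p <= p_threshold:
                hits.append(
                    MotifHit(window_id, scored.pwm.name, off, strand, s / SCORE_SCALE, p)
                )
    return hits


def _dedup_hits(hits: list[MotifHit], width: int) -> list[MotifHit]:
    """Keep the best-scoring hit per run of overlapping positions."""
    out = []
    for key in sorted({(h.window_id, h.motif_id) for h in hits}):
        group = sorted((h for h in hits if (h.window_id, h.motif_id) == key), key=lambda h: h.position)
        run: list[MotifHit] = []
        run_end = None
        for h in group:
            if run and h.position < run_end:
                run.append(h)
                run_end = max(run_end, h.position + width)
            else:
                if run:
                    out.append(max(run, key=lambda h: (h.score, -h.position)))
                run = [h]
                run_end = h.position + width
        if run:
            out.append(max(run, key=lambda h: (h.score, -h.position)))
    return sorted(out, key=lambda h: (h.window_id, h.motif_id, h.position))


def scan_pwms(
    windows: pd.DataFrame,
    genome,
    pwms: Sequence[PWM],
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    dedup: bool = True,
) -> pd.DataFrame:
    """Scan merged windows for PWM hits with exact p-values.

    Both strands are scanned at every offset; a hit is emitted where the
    exact p-value of its log-odds score under the background is at or
    below ``p_threshold``.  Per window and motif, overlapping hit runs are
    deduplicated to the best-scoring position.

    Returns a DataFrame (window_id, motif_id, position, strand, score,
    p_value); window ids are "chrom:start-end".
    """
    seqs = _sequences(genome)
    if background is None:
        background = genome_background(genome)
    else:
        # strand-symmetrise so one null distribution serves both strands
        background = np.asarray(background, dtype=float)
        at = (background[0] + background[3]) / 2
        cg = (background[1] + background[2]) / 2
        background = np.array([at, cg, cg, at])
    scored = [ScoredPWM.build(p, background) for p in pwms]
    all_hits: list[MotifHit] = []
    for _, r in windows.iterrows():
        wid = f"{r['chrom']}:{int(r['start'])}-{int(r['end'])}"
        text = _fetch(seqs, r["chrom"], int(r["start"]), int(r["end"]))
        for sp in scored:
            hits = scan_sequence(text, sp, p_threshold=p_threshold, window_id=wid)
            if dedup:
                hits = _dedup_hits(hits, sp.pwm.width)
            all_hits.extend(hits)
    return pd.DataFrame(
        [(h.window_id, h.motif_id, h.position, h.strand, h.score, h.p_value) for h in all_hits],
        columns=["window_id", "motif_id", "position", "strand", "score", "p_value"],
    )


# ---------------------------------------------------------------------------
# motif-pair coincidence
# ---------------------------------------------------------------------------

def motif_pair_counts(hits: pd.DataFrame, n_windows: int) -> pd.DataFrame:
    """Coincidence counts of unordered motif pairs across windows.

    Each window where two distinct motifs both hit contributes 1 to that
    pair; a motif hitting >= 2 distinct positions in one window contributes
    1 to its self-pair.  Counts are normalised by the number of merged
    windows.
    """
    if n_windows == 0 and len(hits):
        raise ValueError("n_windows is zero but hits are present")
    pair_counts: dict[tuple[str, str], int] = {}
    if len(hits):
        for _, group in hits.groupby("window_id"):
            motifs_here = sorted(group["motif_id"].unique())
            for i, a in enumerate(motifs_here):
                for b in motifs_here[i + 1 :]:
                    pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
                if group[group["motif_id"] == a]["position"].nunique() >= 2:
                    pair_counts[(a, a)] = pair_counts.get((a, a), 0) + 1
    rows = [(a, b, c, c / n_windows if n_windows else np.nan) for (a, b), c in sorted(pair_counts.items())]
    return pd.DataFrame(rows, columns=["motif_a", "motif_b", "raw", "normalized"])


def _running_median_trend(means: np.ndarray, disps: np.ndarray, frac: float = 0.3) -> np.ndarray:
    """Running median of dispersion vs mean, evaluated at each pair's mean."""
    n = len(means)
    order = np.argsort(means)
    half = max(2, int(np.ceil(frac * n / 2)))
    trend_sorted = np.empty(n)
    for rank in range(n):
        lo, hi = max(0, rank - half), min(n, rank + half + 1)
        trend_sorted[rank] = np.median(disps[order][lo:hi])
    trend = np.empty(n)
    trend[order] = trend_sorted
    return trend


def diff_motif_pairs(
    counts: pd.DataFrame,
    sample_of: Mapping[str, str],
    mean_log10_threshold: float = 1.0,
) -> pd.DataFrame:
    """Motif pairs whose frequency varies across samples beyond expectation.

    ``counts`` has one row per motif pair (index or columns motif_a /
    motif_b) and one column per replicate; ``sample_of`` maps replicate
    column to sample.  Per pair, the mean raw count over all replicates and
    a method-of-moments negative-binomial dispersion are computed; the
    expected dispersion at a given mean is a running median over pairs
    ordered by mean.  A pair is reported as differential when
    log10(mean) > threshold AND dispersion > trend; a per-pair
    negative-binomial Wald test of the sample effect supplies the
    significance column.  All-zero rows are dropped with a log entry.
    """
    value_cols = [c for c in counts.columns if c in sample_of]
    if len(value_cols) < 4 or len(set(sample_of.values())) < 2:
        raise ValueError("need >= 2 samples with >= 2 replicates each")
    data = counts[value_cols].to_numpy(dtype=float)
    keep = data.sum(axis=1) > 0
    if (~keep).any():
        logger.info("dropping %d all-zero motif-pair rows", int((~keep).sum()))
    counts = counts.loc[keep].reset_index(drop=True)
    data = data[keep]

    mean = data.mean(axis=1)
    var = data.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.clip((var - mean) / mean**2, 0.0, None)
    trend = _running_median_trend(mean, dispersion)
    passes = (np.log10(mean) > mean_log10_threshold) & (dispersion > trend)

    samples = sorted(set(sample_of.values()))
    design = np.zeros((len(value_cols), len(samples)))
    for j, col in enumerate(value_cols):
        design[j, samples.index(sample_of[col])] = 1.0
    X = np.column_stack([np.ones(len(value_cols)), design[:, 1:]])

    wald_p = np.full(len(counts), np.nan)
    for i in range(len(counts)):
        y = data[i]
        try:
            fam = sm.families.NegativeBinomial(alpha=max(dispersion[i], 1e-4))
            res = sm.GLM(y, X, family=fam).fit()
            R = np.zeros((len(samples) - 1, X.shape[1]))
            R[:, 1:] = np.eye(len(samples) - 1)
            wald_p[i] = float(res.wald_test(R, scalar=True).pvalue)
        except Exception:  # noqa: BLE001 - singular fits on degenerate rows
            pass

    out = counts[["motif_a", "motif_b"]].copy() if "motif_a" in counts else pd.DataFrame(index=counts.index)
    out["mean_count"] = mean
    out["dispersion"] = dispersion
    out["trend_dispersion"] = trend
    out["passes_filter"] = passes
    out["wald_p"] = wald_p
    return out.sort_values(["passes_filter", "wald_p"], ascending=[False, True], ignore_index=True)
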