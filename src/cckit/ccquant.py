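"""UMI quantification, peak calling and gene-level binding matrices.

Events are collapsed to insertion sites by counting distinct UMIs per
(sample, chromosome, position).  Peaks are called with a transparent
Poisson window scan: sliding windows are scored by the upper-tail Poisson
probability of their UMI total under a uniform genome-wide rate, windows
are corrected with Benjamini-Hochberg, and overlapping significant windows
merge into peaks.  Peaks or sites are assigned to a gene when their
midpoint falls within 1000 bp 5' to 200 bp 3' of the gene's transcription
start site, and gene-level UMI counts are normalised per million total
UMIs and log2-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ccparse import TTAA, UMI_LEN, InsertionEvent

UPSTREAM_BP = 1000  # promoter window 5' of the TSS
DOWNSTREAM_BP = 200  # promoter window 3' of the TSS


# ---------------------------------------------------------------------------
# UMI collapse
# ---------------------------------------------------------------------------

def collapse_umis(events: Iterable[InsertionEvent]) -> pd.DataFrame:
    """Collapse events to sites with distinct-UMI counts.

    Returns a DataFrame with columns (sample, chrom, pos, umis) where
    ``umis`` is the number of distinct UMI strings seen at that position in
    that sample.  Duplicate (position, UMI) observations — PCR duplicates —
    collapse to one.  UMIs of the wrong length raise ``ValueError``.
    """
    rows = [(e.sample, e.chrom, e.pos, e.umi) for e in events]
    if not rows:
        return pd.DataFrame(columns=["sample", "chrom", "pos", "umis"])
    df = pd.DataFrame(rows, columns=["sample", "chrom", "pos", "umi"])
    bad = df["umi"].str.len() != UMI_LEN
    if bad.any():
        raise ValueError(f"{int(bad.sum())} events carry a UMI of length != {UMI_LEN}")
    sites = (
        df.groupby(["sample", "chrom", "pos"], sort=True)["umi"]
        .nunique()
        .rename("umis")
        .reset_index()
    )
    return sites


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

def ttaa_positions(sequences: Mapping[str, str]) -> list[tuple[str, int]]:
    """All (chrom, 0-based start) occurrences of the TTAA tetranucleotide."""
    out = []
    for chrom, seq in sequences.items():
        seq = seq.upper()
        i = seq.find(TTAA)
        while i != -1:
            out.append((chrom, i))
            i = seq.find(TTAA, i + 1)
    return out


def window_pvalue(umi_total: int, rate: float) -> float:
    """Poisson upper-tail probability P(X >= umi_total) at the given rate."""
    return float(stats.poisson.sf(umi_total - 1, rate))


def scan_windows(
    sites: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    window: int = 300,
    step: int | None = None,
    ttaa_sites: Sequence[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Score every sliding window by its Poisson upper-tail p-value.

    Windows of ``window`` bp tile each chromosome at ``step`` bp (default
    ``window // 2``).  With ``ttaa_sites`` given, the null is uniform over
    integration sites: a window's rate is
    total_UMIs * (TTAAs in window / TTAAs genome-wide), which calibrates
    correctly even where TTAA tetranucleotides cluster by chance.  Without
    it, the rate falls back to the per-bp uniform
    lambda = total_UMIs / genome_size * window.

    Returns a DataFrame (chrom, start, umi_total, p_value) covering every
    tested window, the input to BH correction in :func:`call_peaks`.
    """
    step = step or max(1, window // 2)
    genome_size = sum(chrom_sizes.values())
    total_umis = int(sites["umis"].sum())
    flat_lam = total_umis / genome_size * window

    ttaa_by_chrom: dict[str, np.ndarray] = {}
    n_ttaa_total = 0
    if ttaa_sites is not None:
        for chrom, pos in ttaa_sites:
            ttaa_by_chrom.setdefault(chrom, []).append(pos)
        ttaa_by_chrom = {c: np.sort(np.asarray(v)) for c, v in ttaa_by_chrom.items()}
        n_ttaa_total = sum(len(v) for v in ttaa_by_chrom.values())

    frames = []
    for chrom, size in chrom_sizes.items():
        sub = sites[sites["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        counts = sub["umis"].to_numpy()
        starts = np.arange(0, max(size - window, 0) + 1, step)
        if pos.size:
            order = np.argsort(pos)
            pos, counts = pos[order], counts[order]
            csum = np.concatenate([[0], np.cumsum(counts)])
            lo = np.searchsorted(pos, starts, side="left")
            hi = np.searchsorted(pos, starts + window, side="left")
            totals = csum[hi] - csum[lo]
        else:
            totals = np.zeros(starts.size, dtype=int)
        if ttaa_sites is not None and n_ttaa_total > 0:
            tp = ttaa_by_chrom.get(chrom, np.array([], dtype=int))
            n_in = np.searchsorted(tp, starts + window, side="left") - np.searchsorted(
                tp, starts, side="left"
            )
            lams = total_umis * n_in / n_ttaa_total
        else:
            lams = np.full(starts.size, flat_lam)
        pvals = [
            window_pvalue(int(t), max(float(l), 1e-12)) if t > 0 else 1.0
            for t, l in zip(totals, lams)
        ]
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts.astype(int), "umi_total": totals.astype(int), "p_value": pvals}
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_peaks(
    sites: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    window: int = 300,
    step: int | None = None,
    alpha: float = 0.05,
    ttaa_sites: Sequence[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Poisson window scan for regions of elevated insertion density.

    Sliding windows of ``window`` bp (step ``window // 2`` by default) tile
    every chromosome; each is scored by the Poisson upper tail of its UMI
    total under a uniform background (per TTAA site when ``ttaa_sites`` is
    given, per bp otherwise; see :func:`scan_windows`).  BH correction
    runs across all tested windows, significant windows (q <= alpha) merge
    when they overlap or touch, and a merged peak inherits its best
    window's p and q.

    Returns a DataFrame (chrom, start, end, n_sites, umi_total, p_value,
    q_value) sorted by position; empty input gives an empty frame.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    genome_size = sum(chrom_sizes.values())
    if genome_size <= window:
        raise ValueError("genome size must exceed the window")
    cols = ["chrom", "start", "end", "n_sites", "umi_total", "p_value", "q_value"]
    if sites.empty:
        return pd.DataFrame(columns=cols)

    scanned = scan_windows(sites, chrom_sizes, window=window, step=step, ttaa_sites=ttaa_sites)
    pvals = scanned["p_value"].to_numpy()
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    sig = [
        (scanned.loc[i, "chrom"], int(scanned.loc[i, "start"]), int(scanned.loc[i, "start"]) + window, pvals[i], qvals[i])
        for i in np.flatnonzero(qvals <= alpha)
    ]
    merged = _merge_scored(sig)

    rows = []
    for chrom, start, end, p, q in merged:
        sub = sites[(sites["chrom"] == chrom) & (sites["pos"] >= start) & (sites["pos"] < end)]
        rows.append((chrom, start, end, len(sub), int(sub["umis"].sum()), p, q))
    return pd.DataFrame(rows, columns=cols).sort_values(["chrom", "start"], ignore_index=True)


def _merge_scored(windows: Sequence[tuple[str, int, int, float, float]]):
    """Merge overlapping/adjacent scored windows, keeping the best p and q."""
    out = []
    for chrom, start, end, p, q in sorted(windows):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end), min(prev[3], p), min(prev[4], q))
        else:
            out.append((chrom, start, end, p, q))
    return out


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------

def assign_genes(
    intervals: pd.DataFrame,
    annotation: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign intervals to genes by the promoter-window rule.

    An interval is assigned to a gene when its midpoint lies within
    [TSS - 1000, TSS + 200] for plus-strand genes, mirrored for minus
    strand.  An interval may hit several genes (divergent promoters).

    ``intervals`` needs columns (chrom, start, end); sites can be passed as
    intervals of [pos, pos + 4).  Returns (links, unassigned) where links
    has one row per (interval, gene) pair.
    """
    if annotation["strand"].isna().any():
        raise ValueError("annotation has genes with missing strand")
    ivals = intervals.reset_index(drop=True).copy()
    ivals["midpoint"] = (ivals["start"] + ivals["end"]) // 2

    link_rows = []
    assigned_idx = set()
    for _, g in annotation.iterrows():
        tss = int(g["tss"])
        if g["strand"] == "+":
            lo, hi = tss - UPSTREAM_BP, tss + DOWNSTREAM_BP
        else:
            lo, hi = tss - DOWNSTREAM_BP, tss + UPSTREAM_BP
        hit = ivals[(ivals["chrom"] == g["chrom"]) & (ivals["midpoint"] >= lo) & (ivals["midpoint"] <= hi)]
        for idx, row in hit.iterrows():
            assigned_idx.add(idx)
            link_rows.append((g["gene_id"], row["chrom"], int(row["start"]), int(row["end"]), int(row["midpoint"])))
    links = pd.DataFrame(link_rows, columns=["gene_id", "chrom", "start", "end", "midpoint"])
    unassigned = ivals.loc[sorted(set(ivals.index) - assigned_idx)].reset_index(drop=True)
    return links, unassigned


def sites_as_intervals(sites: pd.DataFrame) -> pd.DataFrame:
    """View sites as [pos, pos+4) intervals, carrying counts through."""
    out = sites.rename(columns={"pos": "start"}).copy()
    out["end"] = out["start"] + len(TTAA)
    return out


# ---------------------------------------------------------------------------
# gene matrix
# ---------------------------------------------------------------------------

@dataclass
class GeneBindingMatrix:
    """Genes x samples UMI counts with per-million and log2 views.

    ``totals`` are each sample's total UMIs over *all* sites, assigned or
    not, and are the normalisation denominators.
    """

    raw: pd.DataFrame
    totals: pd.Series

    @property
    def normalized(self) -> pd.DataFrame:
        return self.raw / self.totals * 1e6

    @property
    def log(self) -> pd.DataFrame:
        return np.log2(self.normalized + 1.0)

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    def write_tsv(self, path: str | Path, view: str = "raw") -> None:
        df = {"raw": self.raw, "normalized": self.normalized, "log": self.log}[view]
        df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def gene_matrix(sites: pd.DataFrame, annotation: pd.DataFrame) -> GeneBindingMatrix:
    """Build the gene x sample distinct-UMI count matrix.

    Cell (g, s) sums the distinct-UMI counts of sample s's sites whose
    midpoint falls in g's promoter window.  Duplicate sample ids in the
    site table are impossible by construction (groupby), but an empty
    sample list raises.
    """
    samples = sorted(sites["sample"].unique())
    if not samples:
        raise ValueError("no samples in site table")
    genes = list(annotation["gene_id"])
    raw = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"), columns=samples, dtype=int)
    totals = sites.groupby("sample")["umis"].sum().reindex(samples).fillna(0).astype(int)

    for sample in samples:
        sub = sites[sites["sample"] == sample]
        links, _ = assign_genes(sites_as_intervals(sub), annotation)
        if links.empty:
            continue
        merged = links.merge(
            sites_as_intervals(sub)[["chrom", "start", "umis"]], on=["chrom", "start"], how="left"
        )
        per_gene = merged.groupby("gene_id")["umis"].sum()
        raw.loc[per_gene.index, sample] = per_gene.astype(int)
    return GeneBindingMatrix(raw=raw, totals=totals)


def replicate_correlation(matrix: GeneBindingMatrix, sample_a: str, sample_b: str) -> float:
    """Pearson r between two samples on the log2 per-million view."""
    log = matrix.log
    if sample_a not in log.columns or sample_b not in log.columns:
        raise KeyError("sample not present in matrix")
    if len(log) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    r, _ = stats.pearsonr(log[sample_a], log[sample_b])
    return float(r)


def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, row in peaks.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\tpeak{i + 1}\t"
                f"{row['umi_total']}\t.\t{row['p_value']:.6g}\t{row['q_value']:.6g}\n"
            )
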