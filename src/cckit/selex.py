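"""HT-SELEX k-mer enrichment analysis.

K-mers of the round-5 (or any output) pool are counted at every offset of
every 36-mer ligand and normalised to the same k-mer's frequency in the
random input pool; the strongly bound sequence set is taken as those
k-mers whose enrichment exceeds the mean by three standard deviations.
Ligands are sequenced stranded, so counting is single-strand.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simdata import CONSENSUS

PSEUDOCOUNT = 0.5


def count_kmers(pool: Sequence[str], k: int) -> Counter:
    """Count every k-mer at every offset of every ligand (single strand).

    All ligands must share one length L; the counts sum to
    ``len(pool) * (L - k + 1)``.
    """
    if not pool:
        return Counter()
    L = len(pool[0])
    if any(len(s) != L for s in pool):
        raise ValueError("ragged pool: all sequences must share one length")
    if k > L:
        raise ValueError(f"k={k} exceeds ligand length {L}")
    counts: Counter = Counter()
    for seq in pool:
        seq = seq.upper()
        for i in range(L - k + 1):
            counts[seq[i : i + k]] += 1
    return counts


def selex_enrichment(
    output_pool: Sequence[str],
    input_pool: Sequence[str],
    k: int = 10,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-k-mer enrichment of an output pool over the input pool.

    Counts are put on a common per-window scale using each pool's total
    k-mer windows, with a symmetric pseudocount:

        enrichment = ((out + c) / total_out) / ((in + c) / total_in)

    The table covers exactly the k-mers observed in either pool, sorted by
    enrichment descending.
    """
    if not output_pool or not input_pool:
        raise ValueError("pools must be nonempty")
    if len(output_pool[0]) != len(input_pool[0]):
        raise ValueError("pools have different ligand lengths")
    out_counts = count_kmers(output_pool, k)
    in_counts = count_kmers(input_pool, k)
    total_out = sum(out_counts.values())
    total_in = sum(in_counts.values())
    kmers = sorted(set(out_counts) | set(in_counts))
    oc = np.array([out_counts.get(m, 0) for m in kmers], dtype=float)
    ic = np.array([in_counts.get(m, 0) for m in kmers], dtype=float)
    enr = ((oc + pseudocount) / total_out) / ((ic + pseudocount) / total_in)
    df = pd.DataFrame({"kmer": kmers, "output_count": oc.astype(int), "input_count": ic.astype(int), "enrichment": enr})
    return df.sort_values(["enrichment", "kmer"], ascending=[False, True], ignore_index=True)


def top_enriched(table: pd.DataFrame, sd_multiplier: float = 3.0) -> pd.DataFrame:
    """K-mers whose enrichment is >= mean + ``sd_multiplier`` * SD.

    Mean and SD are taken over all table rows (population SD).  In the
    degenerate all-equal case the SD is zero and every row ties at the
    threshold; all rows are returned with a warning, since ">= mean + 0"
    holds for each.
    """
    if len(table) < 2:
        raise ValueError("need at least two k-mers")
    enr = table["enrichment"].to_numpy()
    mean = enr.mean()
    sd = enr.std(ddof=0)
    if sd == 0.0:
        warnings.warn("degenerate enrichment table: SD is zero, returning all rows", stacklevel=2)
    threshold = mean + sd_multiplier * sd
    return table[table["enrichment"] >= threshold].reset_index(drop=True)


def _count_one_kmer(pool: Sequence[str], kmer: str) -> int:
    """Occurrences of one k-mer over all offsets (overlapping included)."""
    n = 0
    for seq in pool:
        seq = seq.upper()
        i = seq.find(kmer)
        while i != -1:
            n += 1
            i = seq.find(kmer, i + 1)
    return n


def kmer_enrichment_value(
    output_pool: Sequence[str],
    input_pool: Sequence[str],
    kmer: str,
    pseudocount: float = PSEUDOCOUNT,
) -> float:
    """Enrichment of one specific k-mer, computed directly from counts.

    Counts only the k-mer of interest, so trajectories over large pools
    avoid building full k-mer tables.
    """
    k = len(kmer)
    total_out = len(output_pool) * (len(output_pool[0]) - k + 1)
    total_in = len(input_pool) * (len(input_pool[0]) - k + 1)
    return float(
        ((_count_one_kmer(output_pool, kmer) + pseudocount) / total_out)
        / ((_count_one_kmer(input_pool, kmer) + pseudocount) / total_in)
    )


def consensus_trajectory(
    pools: Sequence[Sequence[str]] | Mapping[int, Sequence[str]],
    consensus: str = CONSENSUS,
) -> list[float]:
    """Consensus 7-mer enrichment of each round against the input pool.

    ``pools`` is the per-round list with the random input pool first (or a
    mapping with key 0 present); the result has one value per selection
    round, in order.
    """
    if isinstance(pools, Mapping):
        if 0 not in pools:
            raise ValueError("round 0 (input pool) missing")
        ordered = [pools[r] for r in sorted(pools)]
    else:
        ordered = list(pools)
    if len(ordered) < 2:
        raise ValueError("need the input pool and at least one round")
    input_pool = ordered[0]
    return [kmer_enrichment_value(p, input_pool, consensus) for p in ordered[1:]]
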