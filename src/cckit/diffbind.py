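"""Differential binding by two-sample proportion tests.

For each gene, the fraction of a sample's total UMIs that map to the gene
is compared between a variant and wild-type with a two-sided two-sample
proportion test: a chi-square test of the 2x2 table with continuity
correction, falling back to Fisher's exact test whenever any expected cell
is below 5.  Benjamini-Hochberg q-values are computed within each variant
across genes; both raw p and q are reported so either threshold can be
applied downstream.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ccquant import GeneBindingMatrix

EXPECTED_CELL_MIN = 5.0  # chi-square validity rule of thumb


def _expected_cells(k1: int, n1: int, k2: int, n2: int) -> np.ndarray:
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    return rows * cols / table.sum()


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided p-value for H0: the two binomial proportions are equal.

    Chi-square with Yates continuity correction when all expected cells are
    >= 5, else Fisher's exact test.  Symmetric in its two samples.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("k must satisfy 0 <= k <= n")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    expected = _expected_cells(k1, n1, k2, n2)
    if (expected < EXPECTED_CELL_MIN).any():
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    _, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(p)


def proportion_test_array(
    k1: np.ndarray, n1: np.ndarray, k2: np.ndarray, n2: np.ndarray
) -> np.ndarray:
    """Vectorised version of :func:`proportion_test`.

    Applies the Yates-corrected chi-square closed form to every table and
    replaces the p-value with Fisher's exact wherever an expected cell
    falls below 5 (an element-wise loop over only those tables).
    """
    a = np.asarray(k1, dtype=float)
    b = np.asarray(n1, dtype=float) - a
    c = np.asarray(k2, dtype=float)
    d = np.asarray(n2, dtype=float) - c
    N = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        num = N * np.maximum(np.abs(a * d - b * c) - N / 2.0, 0.0) ** 2
        chi2 = np.where(denom > 0, num / denom, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    expected_min = np.minimum.reduce([r1 * c1, r1 * c2, r2 * c1, r2 * c2]) / N
    exact = np.flatnonzero(expected_min < EXPECTED_CELL_MIN)
    for i in exact:
        p.flat[i] = stats.fisher_exact(
            [[a.flat[i], b.flat[i]], [c.flat[i], d.flat[i]]], alternative="two-sided"
        )[1]
    return p


def diff_binding_table(
    matrix: GeneBindingMatrix,
    wt_sample: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene proportion tests of every variant sample against wild-type.

    k = the gene's UMIs in the sample, n = the sample's total UMIs over all
    sites.  q-values are BH-corrected within each variant across genes.
    Direction is "gain" when the variant fraction exceeds wild-type, "loss"
    when below, "none" on a tie.
    """
    if wt_sample not in matrix.raw.columns:
        raise KeyError(f"wild-type sample {wt_sample!r} not in matrix")
    n_wt = int(matrix.totals[wt_sample])
    if n_wt == 0:
        raise ValueError("wild-type sample has zero total UMIs")
    k_wt = matrix.raw[wt_sample].to_numpy()

    frames = []
    for sample in matrix.samples:
        if sample == wt_sample:
            continue
        n_var = int(matrix.totals[sample])
        if n_var == 0:
            raise ValueError(f"variant sample {sample!r} has zero total UMIs")
        k_var = matrix.raw[sample].to_numpy()
        p = proportion_test_array(k_var, np.full_like(k_var, n_var), k_wt, np.full_like(k_wt, n_wt))
        _, q, _, _ = multipletests(p, method="fdr_bh")
        frac_var = k_var / n_var
        frac_wt = k_wt / n_wt
        direction = np.where(frac_var > frac_wt, "gain", np.where(frac_var < frac_wt, "loss", "none"))
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": matrix.raw.index,
                    "variant": sample,
                    "k_variant": k_var,
                    "n_variant": n_var,
                    "k_wt": k_wt,
                    "n_wt": n_wt,
                    "fraction_variant": frac_var,
                    "fraction_wt": frac_wt,
                    "p_value": p,
                    "q_value": q,
                    "direction": direction,
                    "significant": q <= alpha,
                }
            )
        )
    if not frames:
        raise ValueError("matrix has no variant samples besides wild-type")
    return pd.concat(frames, ignore_index=True)


def intersect_gene_sets(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Venn cardinalities for every non-empty membership pattern.

    Keys are sorted tuples of set names; values count the elements whose
    membership is exactly that pattern.  Pattern counts sum to |union|.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(sets)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set.union(set(), *(set(sets[n]) for n in names if n not in combo))
            out[combo] = len(inside - outside)
    return out
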