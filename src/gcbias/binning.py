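"""Gene binning and bin-level correlation statistics.

Genes are sorted by a key (GC3 or recombination rate, ties broken by gene
id for determinism) and cut into k bins of equal gene count or equal SNP
weight. Bin-level Spearman correlations use an exact permutation p-value
for up to ten bins; families of tests are adjusted by Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneBinning", "make_bins", "spearman_table", "fdr_adjust"]

EXACT_PERM_MAX = 10


@dataclass
class GeneBinning:
    sort_key: str  # "GC3" | "r"
    scheme: str  # "equal_genes" | "equal_snps"
    k: int
    assignment: dict  # gene_id -> bin index (0-based, increasing key)

    def bins(self) -> list[list]:
        out: list[list] = [[] for _ in range(self.k)]
        for gene, b in self.assignment.items():
            out[b].append(gene)
        return out


def make_bins(
    genes: dict,
    scheme: str = "equal_genes",
    k: int = 10,
    weights: dict | None = None,
    sort_key: str = "GC3",
) -> GeneBinning:
    """Assign genes to k bins of increasing key.

    ``genes`` maps gene_id -> key value. For ``equal_snps``, ``weights``
    maps gene_id -> SNP count and bins are cut greedily so cumulative
    weights per bin differ by at most the largest single-gene weight.
    """
    if k > len(genes):
        raise ValueError("more bins than genes")
    order = sorted(genes, key=lambda g: (genes[g], g))
    assignment: dict = {}
    if scheme == "equal_genes":
        for b, chunk in enumerate(np.array_split(order, k)):
            for g in chunk:
                assignment[g] = b
    elif scheme == "equal_snps":
        if weights is None:
            raise ValueError("equal_snps binning needs per-gene SNP weights")
        total = sum(weights.get(g, 0) for g in order)
        target = total / k
        b = 0
        acc = 0.0
        for g in order:
            assignment[g] = b
            acc += weights.get(g, 0)
            # advance once this bin's cumulative share is reached
            while b < k - 1 and acc >= target * (b + 1):
                b += 1
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    return GeneBinning(sort_key, scheme, k, assignment)


@lru_cache(maxsize=8)
def _exact_rho_null(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of |Spearman rho| over all n! rank pairings.

    Computed once per n by chunked enumeration (n <= 10); returns unique
    |rho| values and their permutation counts.
    """
    ranks = np.arange(1, n + 1, dtype=float)
    denom = n * (n * n - 1) / 6.0
    counts: dict[float, int] = {}
    chunk = []

    def flush():
        if not chunk:
            return
        arr = np.array(chunk, dtype=float)
        d2 = ((arr - ranks[None, :]) ** 2).sum(axis=1)
        rho = np.abs(1.0 - d2 / denom)
        for v in np.round(rho, 12):
            counts[v] = counts.get(v, 0) + 1
        chunk.clear()

    for perm in itertools.permutations(range(1, n + 1)):
        chunk.append(perm)
        if len(chunk) >= 200_000:
            flush()
    flush()
    vals = np.array(sorted(counts))
    return vals, np.array([counts[v] for v in vals])


def spearman_table(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p on bin-level values.

    For <= 10 untied points the p-value is exact (full permutation
    enumeration of the rho null); otherwise scipy's asymptotic p is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 bins with defined values")
    if np.all(y == y[0]) or np.all(x == x[0]):
        return math.nan, math.nan
    rho, p_asym = stats.spearmanr(x, y)
    n = len(x)
    no_ties = len(set(x)) == n and len(set(y)) == n
    if n <= EXACT_PERM_MAX and no_ties:
        vals, counts = _exact_rho_null(n)
        total = counts.sum()
        p = counts[vals >= abs(round(rho, 12)) - 1e-9].sum() / total
        return float(rho), float(p)
    return float(rho), float(p_asym)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
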