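"""SNP orientation, classification, unfolded SFS and nucleotide diversity.

SNPs are polarised with the focal species' parent-node ancestral sequence,
classified as synonymous/nonsynonymous and by W->S / S->W / GC-conservative
category, and aggregated into unfolded site frequency spectra with matching
opportunity and divergence totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .codon import (
    ALL,
    BASES,
    ChangeCategory,
    CodonAlignment,
    GENETIC_CODE,
    STOP_CODONS,
    classify_change,
    mutate_codon,
)
from .opportunities import OpportunityCounts

__all__ = [
    "SNPRecord",
    "SFSPair",
    "OrientationLog",
    "orient_and_classify",
    "build_sfs",
    "pi",
    "mean_derived_freq",
    "project_sfs",
]


@dataclass(frozen=True)
class SNPRecord:
    gene_id: str
    column: int  # 0-based alignment column
    ancestral_base: str
    derived_base: str
    derived_count: int
    n: int  # sampled chromosomes
    synonymous: bool
    category: ChangeCategory

    def __post_init__(self) -> None:
        if not 1 <= self.derived_count <= self.n - 1:
            raise ValueError("derived_count must be in [1, n-1]")
        if self.ancestral_base == self.derived_base:
            raise ValueError("ancestral and derived alleles must differ")


@dataclass
class OrientationLog:
    retained: int = 0
    unorientable: int = 0
    masked_or_gapped: int = 0
    triallelic: int = 0
    stop_involved: int = 0
    monomorphic: int = 0


@dataclass
class SFSPair:
    """Unfolded syn and nonsyn spectra with opportunity/divergence totals."""

    category: object
    n: int
    syn_sfs: np.ndarray  # length n-1, class i at index i-1
    nonsyn_sfs: np.ndarray
    L_syn: float
    L_nonsyn: float
    D_syn: float = 0.0
    D_nonsyn: float = 0.0

    def __post_init__(self) -> None:
        self.syn_sfs = np.asarray(self.syn_sfs, dtype=float)
        self.nonsyn_sfs = np.asarray(self.nonsyn_sfs, dtype=float)
        if len(self.syn_sfs) != self.n - 1 or len(self.nonsyn_sfs) != self.n - 1:
            raise ValueError("SFS vectors must have length n-1")
        if self.L_syn <= 0 or self.L_nonsyn <= 0:
            raise ValueError("opportunity totals must be positive")


def orient_and_classify(
    snps,
    alignments: dict[str, CodonAlignment],
    focal_species: str,
    log: OrientationLog | None = None,
):
    """Polarise raw SNPs against the focal species' parent-node sequence.

    ``snps`` is an iterable of dict-like rows with keys ``gene_id``,
    ``column`` (0-based alignment coordinate), ``allele1``, ``allele2``,
    ``count1``, ``count2``. Returns the retained :class:`SNPRecord` list;
    drop reasons are tallied in ``log``.
    """
    if log is None:
        log = OrientationLog()
    records: list[SNPRecord] = []
    for row in snps:
        gene = row["gene_id"]
        aln = alignments.get(gene)
        if aln is None:
            continue
        col = int(row["column"])
        a1, a2 = row["allele1"], row["allele2"]
        c1, c2 = int(row["count1"]), int(row["count2"])
        if a1 not in BASES or a2 not in BASES or a1 == a2:
            log.triallelic += 1
            continue
        if c1 == 0 or c2 == 0:
            log.monomorphic += 1
            continue
        tree = aln.tree
        parent = tree.parent(focal_species) if tree is not None else None
        if parent is None:
            raise ValueError("focal species has no parent node in the tree")
        anc_seq = aln.sequence(parent)
        focal_seq = aln.sequence(focal_species)
        codon_idx, codon_pos = divmod(col, 3)
        focal_codon = focal_seq[3 * codon_idx : 3 * codon_idx + 3]
        anc_base = anc_seq[col]
        if anc_base not in BASES or any(b not in BASES for b in focal_codon):
            log.masked_or_gapped += 1
            continue
        if anc_base == a1:
            derived, dcount, acount = a2, c2, c1
        elif anc_base == a2:
            derived, dcount, acount = a1, c1, c2
        else:
            log.unorientable += 1
            continue
        n = c1 + c2
        # codon context: focal codon with the SNP position set to ancestral
        codon = mutate_codon(focal_codon, codon_pos, anc_base)
        mutated = mutate_codon(codon, codon_pos, derived)
        if codon in STOP_CODONS or mutated in STOP_CODONS:
            log.stop_involved += 1
            continue
        records.append(
            SNPRecord(
                gene_id=gene,
                column=col,
                ancestral_base=anc_base,
                derived_base=derived,
                derived_count=dcount,
                n=n,
                synonymous=GENETIC_CODE[codon] == GENETIC_CODE[mutated],
                category=classify_change((anc_base, derived)),
            )
        )
        log.retained += 1
    return records


def _category_matches(record: SNPRecord, category) -> bool:
    return category == ALL or record.category is category


def build_sfs(
    records: list[SNPRecord],
    opportunities: list[OpportunityCounts],
    category=ALL,
    n: int | None = None,
    D_syn: float = 0.0,
    D_nonsyn: float = 0.0,
) -> SFSPair:
    """Aggregate oriented SNPs into an unfolded syn/nonsyn SFS pair."""
    sizes = {r.n for r in records}
    if n is None:
        if len(sizes) > 1:
            raise ValueError(
                "records carry mixed sample sizes; project to a common n first"
            )
        n = sizes.pop() if sizes else 2
    elif sizes and sizes != {n}:
        raise ValueError("records do not match requested n; project first")
    syn = np.zeros(n - 1)
    nonsyn = np.zeros(n - 1)
    for r in records:
        if not _category_matches(r, category):
            continue
        (syn if r.synonymous else nonsyn)[r.derived_count - 1] += 1
    L_syn = sum(o.n_syn[category] for o in opportunities)
    L_nonsyn = sum(o.n_nonsyn[category] for o in opportunities)
    return SFSPair(category, n, syn, nonsyn, L_syn, L_nonsyn, D_syn, D_nonsyn)


def pi(
    records: list[SNPRecord],
    opportunities: list[OpportunityCounts],
    category=ALL,
) -> tuple[float, float, float | None]:
    """Per-site nonsynonymous and synonymous diversity and their ratio.

    Each SNP contributes 2*i*(n-i)/(n*(n-1)) pairwise differences.
    """
    pin = pis = 0.0
    for r in records:
        if not _category_matches(r, category):
            continue
        h = 2.0 * r.derived_count * (r.n - r.derived_count) / (r.n * (r.n - 1))
        if r.synonymous:
            pis += h
        else:
            pin += h
    L_syn = sum(o.n_syn[category] for o in opportunities)
    L_nonsyn = sum(o.n_nonsyn[category] for o in opportunities)
    if L_syn <= 0 or L_nonsyn <= 0:
        raise ValueError("zero opportunity total")
    pi_n = pin / L_nonsyn
    pi_s = pis / L_syn
    ratio = pi_n / pi_s if pi_s > 0 else None
    return pi_n, pi_s, ratio


def mean_derived_freq(records: list[SNPRecord], category=ALL, synonymous: bool | None = None) -> float:
    """Mean derived allele frequency over the selected records."""
    freqs = [
        r.derived_count / r.n
        for r in records
        if _category_matches(r, category)
        and (synonymous is None or r.synonymous == synonymous)
    ]
    if not freqs:
        raise ValueError("no records selected")
    return float(np.mean(freqs))


def project_sfs(sfs: SFSPair, n_target: int) -> SFSPair:
    """Hypergeometric down-projection of both spectra to n_target samples.

    Entries projected to frequency 0 or n_target (invisible classes) are
    discarded, as in standard SFS projection.
    """
    n = sfs.n
    if n_target > n:
        raise ValueError("can only project downward")
    if n_target == n:
        return sfs

    def project(vec: np.ndarray) -> np.ndarray:
        out = np.zeros(n_target - 1)
        for i, count in enumerate(vec, start=1):
            if count == 0:
                continue
            for j in range(1, n_target):
                out[j - 1] += count * hypergeom.pmf(j, n, i, n_target)
        return out

    return SFSPair(
        sfs.category,
        n_target,
        project(sfs.syn_sfs),
        project(sfs.nonsyn_sfs),
        sfs.L_syn,
        sfs.L_nonsyn,
        sfs.D_syn,
        sfs.D_nonsyn,
    )
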