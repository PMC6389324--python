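"""Mutational-opportunity ("number of sites") counting.

For each codon position there are three alternative states, weighted in
proportion to a transition/transversion ratio kappa (transition: kappa,
each transversion: 1) and normalised to sum to one per position, so each
position contributes one site in total. Each alternative's weight is
attributed to its (category, synonymous|nonsynonymous) cell; alternatives
that would create a stop codon are dropped after normalisation and their
weight reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .codon import (
    ALL,
    BASES,
    BaseChange,
    CATEGORIES,
    ChangeCategory,
    CodonAlignment,
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    TRANSITION_OF,
    classify_change,
    mutate_codon,
    usable_codons,
)

__all__ = ["SiteWeights", "OpportunityCounts", "site_weights", "count_opportunities", "estimate_kappa"]


_FOURFOLD_PREFIXES = frozenset(
    p for p in {c[:2] for c in SENSE_CODONS}
    if len({GENETIC_CODE[p + b] for b in BASES}) == 1
    and all(p + b not in STOP_CODONS for b in BASES)
)


def _zero_cats() -> dict[ChangeCategory, float]:
    return {cat: 0.0 for cat in CATEGORIES}


@dataclass
class SiteWeights:
    """Per-codon opportunity weights split by category and synonymy."""

    syn: dict[ChangeCategory, float] = field(default_factory=_zero_cats)
    nonsyn: dict[ChangeCategory, float] = field(default_factory=_zero_cats)
    stop: float = 0.0  # weight dropped because the alternative is a stop

    def add(self, other: "SiteWeights") -> None:
        for cat in CATEGORIES:
            self.syn[cat] += other.syn[cat]
            self.nonsyn[cat] += other.nonsyn[cat]
        self.stop += other.stop

    def total(self) -> float:
        return sum(self.syn.values()) + sum(self.nonsyn.values())


@dataclass
class OpportunityCounts:
    """Per-gene synonymous / nonsynonymous site counts per change category."""

    gene_id: str
    kappa: float
    n_syn: dict
    n_nonsyn: dict
    stop_weight: float = 0.0
    n_codons: int = 0

    @classmethod
    def from_weights(cls, gene_id: str, kappa: float, w: SiteWeights, n_codons: int) -> "OpportunityCounts":
        n_syn = {cat: w.syn[cat] for cat in CATEGORIES}
        n_syn[ALL] = sum(w.syn.values())
        n_nonsyn = {cat: w.nonsyn[cat] for cat in CATEGORIES}
        n_nonsyn[ALL] = sum(w.nonsyn.values())
        return cls(gene_id, kappa, n_syn, n_nonsyn, w.stop, n_codons)


def site_weights(codon: str, kappa: float) -> SiteWeights:
    """Opportunity weights of one sense codon under a kappa neutral model."""
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no opportunity weights")
    if codon not in SENSE_CODONS:
        raise ValueError(f"{codon!r} is not a sense codon")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    out = SiteWeights()
    denom = kappa + 2.0  # one transition (kappa) + two transversions (1 each)
    for pos in range(3):
        base = codon[pos]
        for alt in BASES:
            if alt == base:
                continue
            w = (kappa if TRANSITION_OF[base] == alt else 1.0) / denom
            mutated = mutate_codon(codon, pos, alt)
            if mutated in STOP_CODONS:
                out.stop += w
                continue
            change = BaseChange(base, alt, codon, pos)
            cat = classify_change(change)
            if GENETIC_CODE[codon] == GENETIC_CODE[mutated]:
                out.syn[cat] += w
            else:
                out.nonsyn[cat] += w
    return out


def count_opportunities(
    alignment: CodonAlignment, species: str, kappa: float
) -> OpportunityCounts:
    """Sum site weights over the analysed codons of one extant sequence."""
    seq = alignment.sequence(species)
    total = SiteWeights()
    n = 0
    for c in usable_codons(alignment):
        codon = seq[3 * c : 3 * c + 3]
        total.add(site_weights(codon, kappa))
        n += 1
    if n == 0:
        raise ValueError(f"{alignment.gene_id}: no usable codons for {species}")
    return OpportunityCounts.from_weights(alignment.gene_id, kappa, total, n)


def estimate_kappa(
    alignments, species: str | None = None, cap: float = 100.0
) -> float:
    """Pooled ts/tv ratio from 4-fold degenerate third positions.

    Counts parent->child differences on terminal branches of each
    alignment's tree at third positions of 4-fold codon families (judged on
    the parent codon, requiring the child codon to stay in the family at
    positions 1-2). Each such site offers one transition and two
    transversion opportunities, hence kappa = 2 * ts / tv.
    """
    ts = 0
    tv = 0
    for aln in alignments:
        if aln.tree is None:
            raise ValueError(f"{aln.gene_id}: alignment has no tree")
        branches = aln.tree.terminal_branches()
        if species is not None:
            branches = [(p, c) for p, c in branches if c == species]
        usable = usable_codons(aln)
        for parent, child in branches:
            pseq = aln.sequence(parent)
            cseq = aln.sequence(child)
            for c in usable:
                pc = pseq[3 * c : 3 * c + 3]
                cc = cseq[3 * c : 3 * c + 3]
                if pc[:2] not in _FOURFOLD_PREFIXES or cc[:2] != pc[:2]:
                    continue
                if pc[2] == cc[2]:
                    continue
                if TRANSITION_OF[pc[2]] == cc[2]:
                    ts += 1
                else:
                    tv += 1
    if ts == 0 and tv == 0:
        raise ValueError("no substitutions at 4-fold degenerate sites")
    if tv == 0:
        import warnings

        warnings.warn("no transversions observed; kappa capped", stacklevel=2)
        return cap
    return min(cap, 2.0 * ts / tv)
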