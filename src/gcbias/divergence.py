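"""Per-branch substitution counting and category-resolved dN/dS.

Substitutions are obtained by direct differencing of a child sequence
against its supplied ancestral (parent-node) sequence. Codons differing at
more than one position are decomposed by averaging the synonymous /
nonsynonymous and category attribution over all minimal mutational paths
that avoid stop codons. Rates are ratios of sums (pooled substitutions over
pooled opportunities), never means of per-gene ratios, with gene-bootstrap
confidence intervals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .codon import (
    ALL,
    CATEGORIES,
    ChangeCategory,
    CodonAlignment,
    GENETIC_CODE,
    STOP_CODONS,
    STRONG,
    WEAK,
    classify_change,
    mutate_codon,
    usable_codons,
)
from .opportunities import OpportunityCounts

__all__ = [
    "ChangeRecord",
    "SubstitutionSet",
    "RateEstimate",
    "count_substitutions",
    "substitution_totals",
    "rate_estimate",
    "bootstrap_ci",
    "gc3_star",
]


@dataclass(frozen=True)
class ChangeRecord:
    """One (possibly fractionally weighted) base change."""

    column: int  # 0-based alignment column
    codon_pos: int
    from_base: str
    to_base: str
    synonymous: bool
    category: ChangeCategory
    weight: float = 1.0


@dataclass
class SubstitutionSet:
    """Substitutions on one branch of one gene."""

    gene_id: str
    branch: tuple[str, str]  # (parent_node, child_node)
    records: list[ChangeRecord] = field(default_factory=list)
    dropped_codons: int = 0  # multi-hit codons with no stop-free path

    def totals(self) -> dict:
        """Weighted substitution counts keyed (syn|nonsyn, category|ALL)."""
        out = {
            (kind, key): 0.0
            for kind in ("syn", "nonsyn")
            for key in (*CATEGORIES, ALL)
        }
        for r in self.records:
            kind = "syn" if r.synonymous else "nonsyn"
            out[(kind, r.category)] += r.weight
            out[(kind, ALL)] += r.weight
        return out


@dataclass
class RateEstimate:
    category: object
    dN: float
    dS: float
    omega: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    n_genes: int = 0


def _codon_paths(parent: str, child: str) -> list[list[tuple[int, str, str]]]:
    """Minimal stop-free mutational paths from parent codon to child codon.

    Each path is a list of steps (pos, intermediate_codon, alt_base) applied
    in order; intermediate codons (excluding endpoints) must be sense.
    """
    diff = [i for i in range(3) if parent[i] != child[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur = parent
        steps = []
        ok = True
        for k, pos in enumerate(order):
            nxt = mutate_codon(cur, pos, child[pos])
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append((pos, cur, child[pos]))
            cur = nxt
        if ok:
            paths.append(steps)
    return paths


def count_substitutions(
    alignment: CodonAlignment, branch: tuple[str, str]
) -> SubstitutionSet:
    """Diff parent-node sequence against child sequence codon by codon."""
    parent_name, child_name = branch
    pseq = alignment.sequence(parent_name)
    cseq = alignment.sequence(child_name)
    if len(pseq) != len(cseq):
        raise ValueError("frame mismatch between parent and child sequences")
    out = SubstitutionSet(alignment.gene_id, branch)
    for c in usable_codons(alignment):
        pc = pseq[3 * c : 3 * c + 3]
        cc = cseq[3 * c : 3 * c + 3]
        if pc == cc:
            continue
        paths = _codon_paths(pc, cc)
        if not paths:
            out.dropped_codons += 1
            continue
        w = 1.0 / len(paths)
        for path in paths:
            for pos, codon, alt in path:
                syn = GENETIC_CODE[codon] == GENETIC_CODE[mutate_codon(codon, pos, alt)]
                out.records.append(
                    ChangeRecord(
                        column=3 * c + pos,
                        codon_pos=pos,
                        from_base=codon[pos],
                        to_base=alt,
                        synonymous=syn,
                        category=classify_change((codon[pos], alt)),
                        weight=w,
                    )
                )
    return out


def substitution_totals(subs: SubstitutionSet) -> dict:
    return subs.totals()


def _pooled_rates(
    sub_totals: list[dict], opps: list[OpportunityCounts], category
) -> tuple[float, float, float | None]:
    Dn = sum(t[("nonsyn", category)] for t in sub_totals)
    Ds = sum(t[("syn", category)] for t in sub_totals)
    Ln = sum(o.n_nonsyn[category] for o in opps)
    Ls = sum(o.n_syn[category] for o in opps)
    if Ln <= 0 or Ls <= 0:
        raise ValueError(f"zero opportunity total for category {category}")
    dN = Dn / Ln
    dS = Ds / Ls
    omega = dN / dS if dS > 0 else None
    return dN, dS, omega


def bootstrap_ci(
    genes: list, statistic, n_reps: int = 1000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float]:
    """Percentile bootstrap over genes (resampled with replacement)."""
    rng = np.random.default_rng(seed)
    n = len(genes)
    vals = []
    for _ in range(n_reps):
        idx = rng.integers(0, n, size=n)
        v = statistic([genes[i] for i in idx])
        if v is not None and math.isfinite(v):
            vals.append(v)
    if not vals:
        return (math.nan, math.nan)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def rate_estimate(
    subs: list[SubstitutionSet],
    opps: list[OpportunityCounts],
    category=ALL,
    n_boot: int = 1000,
    seed: int = 0,
    ci_statistic: str = "omega",
) -> RateEstimate:
    """Pooled dN, dS, dN/dS for one category with gene-bootstrap CI."""
    if len(subs) != len(opps):
        raise ValueError("substitution and opportunity lists must align per gene")
    if not subs:
        raise ValueError("empty gene set")
    totals = [s.totals() for s in subs]
    dN, dS, omega = _pooled_rates(totals, opps, category)
    ci = (None, None)
    if n_boot > 0 and len(subs) >= 2:
        pairs = list(zip(totals, opps))

        def stat(resampled):
            t = [p[0] for p in resampled]
            o = [p[1] for p in resampled]
            try:
                dn, ds, om = _pooled_rates(t, o, category)
            except ValueError:
                return None
            return {"omega": om, "dN": dn, "dS": ds}[ci_statistic]

        ci = bootstrap_ci(pairs, stat, n_reps=n_boot, seed=seed)
    return RateEstimate(category, dN, dS, omega, ci[0], ci[1], n_genes=len(subs))


def gc3_star(
    subs: list[SubstitutionSet],
    alignments: list[CodonAlignment],
    species: str,
    kappa: float = 1.0,
) -> float:
    """Equilibrium GC at third positions: r_WS / (r_WS + r_SW).

    r_WS is the third-position W->S substitution count per W->S opportunity
    (W third-position bases, times the kappa-normalised chance of mutating
    to a strong base); r_SW analogous. The kappa factor (kappa+1)/(kappa+2)
    is common to both rates and cancels, but is kept for clarity.
    """
    ws = sw = 0.0
    n_w = n_s = 0
    for sub, aln in zip(subs, alignments):
        for r in sub.records:
            if r.codon_pos != 2:
                continue
            if r.category is ChangeCategory.WS:
                ws += r.weight
            elif r.category is ChangeCategory.SW:
                sw += r.weight
        seq = aln.sequence(species)
        for c in usable_codons(aln):
            b = seq[3 * c + 2]
            if b in WEAK:
                n_w += 1
            elif b in STRONG:
                n_s += 1
    factor = (kappa + 1.0) / (kappa + 2.0)
    if n_w == 0 or n_s == 0:
        raise ValueError("need both weak and strong third-position bases")
    r_ws = ws / (n_w * factor)
    r_sw = sw / (n_s * factor)
    if r_ws + r_sw == 0:
        raise ValueError("no third-position WS/SW substitutions: GC3* undefined")
    return r_ws / (r_ws + r_sw)
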