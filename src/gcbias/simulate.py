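"""Synthetic data with known truth for every stage of the pipeline.

Codon alignments are evolved along a tree by a Gillespie substitution
process whose per-change rate is mutation (kappa-structured) times the
relative fixation factor f(S_eff) = S/(1 - e^{-S}) (f(0) = 1), with
S_eff combining a per-gene GC-fixation bias B (+B for W->S, -B for S->W,
0 for GC-conservative) and a per-site selection coefficient for
nonsynonymous changes. SNP panels are drawn from the Poisson random field
expected SFS under the same fixation model, and Marey maps from a
piecewise-constant true recombination rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .codon import (
    BASES,
    CATEGORIES,
    ChangeCategory,
    CodonAlignment,
    GENETIC_CODE,
    STOP_CODONS,
    Tree,
    TRANSITION_OF,
    classify_change,
    mutate_codon,
)
from .divergence import ChangeRecord, SubstitutionSet
from .dfe import DFEModel, expected_sfs, fixation_factor, gamma_grid
from .marey import MareyMap

__all__ = [
    "SimulationConfig",
    "SimulatedGene",
    "canonical_config",
    "simulate_alignment",
    "simulate_dataset",
    "simulate_sfs_counts",
    "simulate_snp_table",
    "simulate_divergence_counts",
    "solve_adaptive_fraction",
    "simulate_marey",
]

#: 6-taxon tree with named internal nodes; branch lengths are expected
#: neutral substitutions per site.
DEFAULT_TREE = (
    "((sp1:0.06,sp2:0.06)anc12:0.04,((sp3:0.06,sp4:0.06)anc34:0.04,"
    "(sp5:0.06,sp6:0.06)anc56:0.04)anc36:0.02)root;"
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world; all randomness flows from ``seed``."""

    seed: int = 0
    tree: str = DEFAULT_TREE
    n_genes: int = 100
    codons_per_gene: int = 100
    kappa: float = 2.0
    #: per-gene GC-fixation bias, linear gradient across genes
    b_min: float = 0.0
    b_max: float = 0.0
    #: hotspot turnover: polymorphism-era bias = b_poly_factor * B. The
    #: divergence-era B is a long-term average; where the recombination
    #: landscape moves, current polymorphism sees a weaker bias. 1.0 means
    #: a time-constant landscape.
    b_poly_factor: float = 1.0
    #: initial GC3; if None, each gene starts at its own equilibrium
    gc3_init: float | None = None
    #: deleterious DFE truth (None = fully neutral nonsynonymous sites)
    dfe: DFEModel | None = None
    #: HRI-like relaxation: selection strength scales from hri_min (gene
    #: with lowest B) to 1 (highest B); 1.0 disables the gradient
    hri_min: float = 1.0
    #: adaptive class: target fraction of adaptive nonsyn substitutions
    alpha_true: float = 0.0
    s_adv: float = 25.0
    #: polymorphism sampling
    n_chromosomes: int = 20
    theta: float = 0.01
    cpg_rate: float = 0.0
    focal_species: str = "sp1"


def canonical_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The documented dataset driving the acceptance experiments.

    Scaled to run a full pipeline pass in well under a minute; individual
    experiments override fields (B gradient, DFE truth, adaptation) on top.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_genes=100,
        codons_per_gene=100,
        kappa=2.0,
        b_min=0.0,
        b_max=5.0,
        dfe=DFEModel("GammaZero", shape=0.4, s_mean=400.0),
        hri_min=0.15,
        n_chromosomes=20,
        theta=0.01,
    )
    return replace(cfg, **overrides)


@dataclass
class SimulatedGene:
    alignment: CodonAlignment
    true_substitutions: dict  # child node -> SubstitutionSet
    B: float
    sel_scale: float  # HRI selection-strength multiplier
    site_s: np.ndarray  # per-nt-site deleterious |S| (0 where neutral)


# ---------------------------------------------------------------------------
# gene-level helpers
# ---------------------------------------------------------------------------


def gene_bias(config: SimulationConfig, g: int) -> float:
    if config.n_genes == 1:
        return config.b_min
    frac = g / (config.n_genes - 1)
    return config.b_min + frac * (config.b_max - config.b_min)


def gene_sel_scale(config: SimulationConfig, g: int) -> float:
    if config.n_genes == 1 or config.hri_min >= 1.0:
        return 1.0
    frac = g / (config.n_genes - 1)
    return config.hri_min + frac * (1.0 - config.hri_min)


def equilibrium_gc(B: float) -> float:
    """Stationary strong-base frequency under fixation bias B: logistic(B)."""
    return 1.0 / (1.0 + math.exp(-B))


def _random_root_codons(
    n: int, gc3: float, cpg_rate: float, rng: np.random.Generator
) -> list[str]:
    codons = []
    while len(codons) < n:
        if cpg_rate > 0 and rng.random() < cpg_rate:
            # seed a CpG dinucleotide inside the codon (arginine CGx family)
            codons.append("CG" + rng.choice(list("ACGT")))
            continue
        b1 = BASES[rng.integers(4)]
        b2 = BASES[rng.integers(4)]
        pool = ("G", "C") if rng.random() < gc3 else ("A", "T")
        b3 = pool[rng.integers(2)]
        codon = b1 + b2 + b3
        if codon not in STOP_CODONS:
            codons.append(codon)
    return codons


def _fix_scalar(s: float) -> float:
    """Scalar fixation factor s/(1-e^{-s}); fast path for the Gillespie loop."""
    if abs(s) < 1e-8:
        return 1.0 + s / 2.0
    if s < 0:
        es = math.exp(s)
        return s * es / (es - 1.0)
    return s / -math.expm1(-s)


def _change_rate(
    codon: str,
    pos: int,
    alt: str,
    B: float,
    kappa: float,
    site_s: float,
) -> float:
    """Substitution rate of one codon change under mutation x fixation."""
    base = codon[pos]
    if alt == base:
        return 0.0
    mutated = mutate_codon(codon, pos, alt)
    if mutated in STOP_CODONS:
        return 0.0
    mu = (kappa if TRANSITION_OF[base] == alt else 1.0) / (kappa + 2.0)
    cat = classify_change((base, alt))
    s_eff = B if cat is ChangeCategory.WS else (-B if cat is ChangeCategory.SW else 0.0)
    if GENETIC_CODE[codon] != GENETIC_CODE[mutated]:
        s_eff += site_s
    return mu * _fix_scalar(s_eff)


def _codon_rate_table(
    codon: str, B: float, kappa: float, site_s3
) -> np.ndarray:
    """3x4 rate array (position x target base) for the current codon."""
    rates = np.zeros((3, 4))
    for pos in range(3):
        for bi, alt in enumerate(BASES):
            rates[pos, bi] = _change_rate(codon, pos, alt, B, kappa, site_s3[pos])
    return rates


def _evolve_branch(
    codons: list[str],
    t: float,
    B: float,
    kappa: float,
    site_s: np.ndarray,
    rng: np.random.Generator,
    record: SubstitutionSet | None,
    memo: dict | None = None,
) -> list[str]:
    """Gillespie substitution process along one branch of length t.

    ``memo`` caches (codon, codon_index) -> rate table within one gene,
    where B, kappa and the per-site selection coefficients are constant.
    """
    codons = list(codons)
    n = len(codons)
    if n == 0 or t <= 0:
        return codons
    if memo is None:
        memo = {}

    def table(c: int) -> np.ndarray:
        key = (codons[c], c)
        tab = memo.get(key)
        if tab is None:
            tab = _codon_rate_table(codons[c], B, kappa, site_s[3 * c : 3 * c + 3])
            memo[key] = tab
        return tab

    rates = np.stack([table(c) for c in range(n)])
    codon_tot = rates.sum(axis=(1, 2))
    elapsed = 0.0
    while True:
        total = codon_tot.sum()
        if total <= 0:
            break
        elapsed += rng.exponential(1.0 / total)
        if elapsed >= t:
            break
        c = int(np.searchsorted(np.cumsum(codon_tot), rng.random() * total))
        c = min(c, n - 1)
        flat = rates[c].ravel()
        j = int(np.searchsorted(np.cumsum(flat), rng.random() * flat.sum()))
        j = min(j, 11)
        pos, bi = divmod(j, 4)
        old = codons[c]
        alt = BASES[bi]
        new = mutate_codon(old, pos, alt)
        if record is not None:
            syn = GENETIC_CODE[old] == GENETIC_CODE[new]
            record.records.append(
                ChangeRecord(
                    column=3 * c + pos,
                    codon_pos=pos,
                    from_base=old[pos],
                    to_base=alt,
                    synonymous=syn,
                    category=classify_change((old[pos], alt)),
                )
            )
        codons[c] = new
        rates[c] = table(c)
        codon_tot[c] = rates[c].sum()
    return codons


def simulate_alignment(
    config: SimulationConfig, gene_index: int, rng: np.random.Generator | None = None
) -> SimulatedGene:
    """Evolve one gene along the tree; returns alignment + true substitutions."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(config.n_genes)[gene_index]
        )
    tree = Tree.from_newick(config.tree)
    B = gene_bias(config, gene_index)
    scale = gene_sel_scale(config, gene_index)
    gc3 = config.gc3_init if config.gc3_init is not None else equilibrium_gc(B)
    root_codons = _random_root_codons(
        config.codons_per_gene, gc3, config.cpg_rate, rng
    )
    n_sites = 3 * config.codons_per_gene

    # per-site selection coefficient applied to nonsynonymous changes
    site_s = np.zeros(n_sites)
    p_adapt = 0.0
    if config.dfe is not None:
        site_s = -scale * rng.gamma(
            config.dfe.shape, config.dfe.s_mean / config.dfe.shape, size=n_sites
        )
        if config.alpha_true > 0:
            p_adapt = solve_adaptive_fraction(
                config.alpha_true,
                config.dfe.shape,
                scale * config.dfe.s_mean,
                config.s_adv,
                B=0.0,
            )
            adaptive = rng.random(n_sites) < p_adapt
            site_s[adaptive] = config.s_adv
    elif config.alpha_true > 0:
        raise ValueError("alpha_true > 0 requires a deleterious DFE truth")

    gene_id = f"g{gene_index:04d}"
    node_seqs: dict[str, list[str]] = {tree.root: root_codons}
    subs: dict[str, SubstitutionSet] = {}
    memo: dict = {}

    def recurse(node: str) -> None:
        for child in tree.children(node):
            rec = SubstitutionSet(gene_id, (node, child))
            node_seqs[child] = _evolve_branch(
                node_seqs[node],
                tree.branch_length(child),
                B,
                config.kappa,
                site_s,
                rng,
                rec,
                memo,
            )
            subs[child] = rec
            recurse(child)

    recurse(tree.root)
    sequences = {
        leaf: "".join(node_seqs[leaf]) for leaf in tree.leaves
    }
    ancestors = {
        node: "".join(node_seqs[node]) for node in tree.internal
    }
    aln = CodonAlignment(gene_id, sequences, ancestors, tree)
    return SimulatedGene(aln, subs, B, scale, site_s)


def simulate_dataset(config: SimulationConfig) -> list[SimulatedGene]:
    """All genes of one replicate, deterministically from ``config.seed``."""
    streams = np.random.SeedSequence(config.seed).spawn(config.n_genes)
    return [
        simulate_alignment(config, g, np.random.default_rng(streams[g]))
        for g in range(config.n_genes)
    ]


# ---------------------------------------------------------------------------
# Polymorphism simulation (PRF sampling)
# ---------------------------------------------------------------------------


def _category_bias(category, B: float) -> float:
    if category is ChangeCategory.WS:
        return B
    if category is ChangeCategory.SW:
        return -B
    return 0.0


def expected_sfs_counts(
    category,
    L_syn: float,
    L_nonsyn: float,
    theta: float,
    n: int,
    B: float = 0.0,
    dfe: DFEModel | None = None,
    sel_scale: float = 1.0,
    p_adapt: float = 0.0,
    s_adv: float = 10.0,
    grid: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected unfolded SFS class counts (syn, nonsyn) for one category."""
    b = _category_bias(category, B)
    syn = theta * L_syn * expected_sfs(b, n)
    if dfe is None:
        nonsyn_shape = expected_sfs(b, n)
    else:
        s = gamma_grid(dfe.shape, sel_scale * dfe.s_mean, grid)
        nonsyn_shape = expected_sfs(b - s, n).mean(axis=0)
    if p_adapt > 0:
        nonsyn_shape = (1 - p_adapt) * nonsyn_shape + p_adapt * expected_sfs(
            b + s_adv, n
        )
    return syn, theta * L_nonsyn * nonsyn_shape


def simulate_sfs_counts(
    rng: np.random.Generator,
    category,
    L_syn: float,
    L_nonsyn: float,
    theta: float,
    n: int,
    B: float = 0.0,
    dfe: DFEModel | None = None,
    sel_scale: float = 1.0,
    p_adapt: float = 0.0,
    s_adv: float = 10.0,
    distortion: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson draw of SFS class counts; optional shared r_i distortion."""
    syn_mean, nonsyn_mean = expected_sfs_counts(
        category, L_syn, L_nonsyn, theta, n, B, dfe, sel_scale, p_adapt, s_adv
    )
    if distortion is not None:
        d = np.asarray(distortion, dtype=float)
        syn_mean = syn_mean * d
        nonsyn_mean = nonsyn_mean * d
    return rng.poisson(syn_mean).astype(float), rng.poisson(nonsyn_mean).astype(float)


def simulate_snp_table(
    gene: SimulatedGene, config: SimulationConfig, rng: np.random.Generator
) -> list[dict]:
    """Place PRF-sampled SNPs onto the focal species' sequence.

    Rows carry raw alleles and counts exactly as the polymorphism module's
    orientation step expects; the true derived allele is the alternative
    base, the ancestral allele being the (homoplasy-free) parent state.
    """
    aln = gene.alignment
    focal = config.focal_species
    tree = aln.tree
    parent = tree.parent(focal)
    fseq = aln.sequence(focal)
    pseq = aln.sequence(parent)
    n = config.n_chromosomes

    # eligible single-base changes keyed (category, synonymous)
    pools: dict[tuple, list[tuple[int, str]]] = {}
    for c in range(aln.n_codons):
        codon = fseq[3 * c : 3 * c + 3]
        if any(b not in BASES for b in codon) or codon in STOP_CODONS:
            continue
        for pos in range(3):
            col = 3 * c + pos
            if pseq[col] != fseq[col]:
                continue  # avoid homoplasy with the orientation ancestor
            base = codon[pos]
            for alt in BASES:
                if alt == base:
                    continue
                mutated = mutate_codon(codon, pos, alt)
                if mutated in STOP_CODONS:
                    continue
                syn = GENETIC_CODE[codon] == GENETIC_CODE[mutated]
                cat = classify_change((base, alt))
                pools.setdefault((cat, syn), []).append((col, alt))

    rows: list[dict] = []
    used_columns: set[int] = set()
    p_adapt = 0.0
    if config.alpha_true > 0 and config.dfe is not None:
        p_adapt = solve_adaptive_fraction(
            config.alpha_true,
            config.dfe.shape,
            gene.sel_scale * config.dfe.s_mean,
            config.s_adv,
            B=0.0,
        )
    for cat in CATEGORIES:
        for syn in (True, False):
            pool = pools.get((cat, syn), [])
            if not pool:
                continue
            L = len(pool) / 3.0  # three alternatives share one site
            syn_mean, nonsyn_mean = expected_sfs_counts(
                cat,
                L_syn=L,
                L_nonsyn=L,
                theta=config.theta,
                n=n,
                B=gene.B * config.b_poly_factor,
                dfe=config.dfe,
                sel_scale=gene.sel_scale,
                p_adapt=p_adapt,
                s_adv=config.s_adv,
            )
            mean = syn_mean if syn else nonsyn_mean
            counts = rng.poisson(mean)
            for i, k in enumerate(counts, start=1):
                for _ in range(int(k)):
                    col, alt = pool[rng.integers(len(pool))]
                    if col in used_columns:
                        continue  # one SNP per column
                    used_columns.add(col)
                    rows.append(
                        {
                            "gene_id": aln.gene_id,
                            "column": col,
                            "allele1": fseq[col],
                            "allele2": alt,
                            "count1": n - i,
                            "count2": i,
                        }
                    )
    return rows


# ---------------------------------------------------------------------------
# Divergence-count simulation and adaptive-fraction calibration
# ---------------------------------------------------------------------------


def _deleterious_fixation(shape: float, s_mean: float, B: float = 0.0, grid: int = 200) -> float:
    s = gamma_grid(shape, s_mean, grid)
    return float(np.mean(fixation_factor(B - s)))


def solve_adaptive_fraction(
    alpha: float, shape: float, s_mean: float, s_adv: float, B: float = 0.0
) -> float:
    """Mutation fraction p of an adaptive class giving target substitution
    fraction alpha: p/(1-p) = alpha*f_del / ((1-alpha)*f_adv)."""
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    if alpha == 0:
        return 0.0
    f_del = _deleterious_fixation(shape, s_mean, B)
    f_adv = float(fixation_factor(B + s_adv))
    ratio = alpha * f_del / ((1.0 - alpha) * f_adv)
    return ratio / (1.0 + ratio)


def simulate_divergence_counts(
    rng: np.random.Generator,
    L_syn: float,
    L_nonsyn: float,
    d: float,
    B: float = 0.0,
    dfe: DFEModel | None = None,
    sel_scale: float = 1.0,
    p_adapt: float = 0.0,
    s_adv: float = 10.0,
    category=None,
) -> tuple[int, int]:
    """Poisson substitution counts (D_syn, D_nonsyn) on one branch.

    ``d`` is the expected neutral synonymous divergence per site; the
    category bias B multiplies the synonymous rate by f(B) and shifts every
    nonsynonymous selection coefficient by B.
    """
    b = _category_bias(category, B) if category is not None else B
    syn_rate = d * float(fixation_factor(b))
    if dfe is None:
        nonsyn_factor = float(fixation_factor(b))
    else:
        nonsyn_factor = _deleterious_fixation(dfe.shape, sel_scale * dfe.s_mean, b)
    if p_adapt > 0:
        nonsyn_factor = (1 - p_adapt) * nonsyn_factor + p_adapt * float(
            fixation_factor(b + s_adv)
        )
    D_syn = int(rng.poisson(L_syn * syn_rate))
    D_nonsyn = int(rng.poisson(L_nonsyn * d * nonsyn_factor))
    return D_syn, D_nonsyn


# ---------------------------------------------------------------------------
# Marey maps
# ---------------------------------------------------------------------------


def simulate_marey(
    length_bp: float,
    segments: list[tuple[float, float]] | None = None,
    n_markers: int = 200,
    noise_cm: float = 0.0,
    seed: int = 0,
    chromosome: str = "chr1",
) -> tuple[MareyMap, callable]:
    """Marey map from a piecewise-constant true rate.

    ``segments`` is a list of (fraction_of_chromosome, rate_cM_per_Mb);
    fractions must sum to 1. Returns the (optionally noisy) marker map and
    the true rate function rate(bp) -> cM/Mb.
    """
    if segments is None:
        segments = [(1.0, 1.0)]
    fracs = np.array([s[0] for s in segments], dtype=float)
    rates = np.array([s[1] for s in segments], dtype=float)
    if not math.isclose(fracs.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("segment fractions must sum to 1")
    edges = np.concatenate([[0.0], np.cumsum(fracs) * length_bp])
    cum_cm = np.concatenate(
        [[0.0], np.cumsum(rates * np.diff(edges) / 1e6)]
    )

    def genetic(bp: np.ndarray) -> np.ndarray:
        bp = np.asarray(bp, dtype=float)
        seg = np.clip(np.searchsorted(edges, bp, side="right") - 1, 0, len(rates) - 1)
        return cum_cm[seg] + rates[seg] * (bp - edges[seg]) / 1e6

    def rate(bp: float) -> float:
        seg = min(max(np.searchsorted(edges, bp, side="right") - 1, 0), len(rates) - 1)
        return float(rates[seg])

    rng = np.random.default_rng(seed)
    pos = np.sort(rng.uniform(0, length_bp, size=n_markers))
    pos[0], pos[-1] = 0.0, length_bp
    gen = genetic(pos)
    if noise_cm > 0:
        gen = gen + rng.normal(0, noise_cm, size=n_markers)
    return MareyMap(chromosome, pos, gen), rate
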