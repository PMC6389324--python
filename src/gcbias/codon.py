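"""Codon-level sequence semantics.

Genetic code, synonymy of single-base changes, weak/strong base classes,
change-category assignment (W->S, S->W, GC-conservative), GC3/GC2 content
and CpG column masking of codon alignments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "GENETIC_CODE",
    "SENSE_CODONS",
    "STOP_CODONS",
    "BASES",
    "WEAK",
    "STRONG",
    "TRANSITION_OF",
    "ChangeCategory",
    "BaseChange",
    "CodonAlignment",
    "Tree",
    "classify_change",
    "is_transition",
    "is_synonymous",
    "mutate_codon",
    "gc_fraction_at",
    "gc3",
    "gc2",
    "mask_cpg_columns",
    "usable_codons",
]

BASES = ("A", "C", "G", "T")
WEAK = frozenset("AT")
STRONG = frozenset("GC")
GAP = "-"
MASK = "N"

#: purine<->purine and pyrimidine<->pyrimidine partner of each base
TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}

# Standard nuclear genetic code, hand-written (tests cross-check it
# against an independent translation library).
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))


class ChangeCategory(enum.Enum):
    """Trichotomy of single-base changes with respect to GC content."""

    WS = "WS"      # weak (A/T) -> strong (G/C)
    SW = "SW"      # strong -> weak
    CONS = "CONS"  # GC-conservative: A<->T or G<->C

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CATEGORIES = (ChangeCategory.WS, ChangeCategory.SW, ChangeCategory.CONS)
ALL = "ALL"


@dataclass(frozen=True)
class BaseChange:
    """A single-base change inside a sense codon.

    ``codon_pos`` is 0-based; ``from_base`` must equal ``codon[codon_pos]``.
    """

    from_base: str
    to_base: str
    codon: str
    codon_pos: int

    def __post_init__(self) -> None:
        if self.from_base not in BASES or self.to_base not in BASES:
            raise ValueError(
                f"invalid nucleotide in change {self.from_base}->{self.to_base}"
            )
        if self.from_base == self.to_base:
            raise ValueError("from_base and to_base must differ")
        if self.codon not in SENSE_CODONS:
            raise ValueError(f"{self.codon!r} is not a sense codon")
        if self.codon_pos not in (0, 1, 2):
            raise ValueError("codon_pos must be 0, 1 or 2")
        if self.codon[self.codon_pos] != self.from_base:
            raise ValueError("from_base does not match codon at codon_pos")

    @property
    def mutated_codon(self) -> str:
        return mutate_codon(self.codon, self.codon_pos, self.to_base)


def mutate_codon(codon: str, pos: int, base: str) -> str:
    return codon[:pos] + base + codon[pos + 1 :]


def classify_change(change: BaseChange | tuple[str, str]) -> ChangeCategory:
    """Assign a change to the W->S / S->W / GC-conservative trichotomy."""
    if isinstance(change, BaseChange):
        a, b = change.from_base, change.to_base
    else:
        a, b = change
        if a not in BASES or b not in BASES:
            raise ValueError(f"invalid nucleotide in change {a}->{b}")
        if a == b:
            raise ValueError("bases must differ")
    if a in WEAK and b in STRONG:
        return ChangeCategory.WS
    if a in STRONG and b in WEAK:
        return ChangeCategory.SW
    return ChangeCategory.CONS


def is_transition(a: str, b: str) -> bool:
    return TRANSITION_OF[a] == b


def is_synonymous(change: BaseChange) -> bool:
    """True iff the change leaves the encoded amino acid unchanged.

    Raises ``ValueError`` if the mutated codon is a stop; callers exclude
    such changes from both opportunity and substitution counts.
    """
    mutated = change.mutated_codon
    if mutated in STOP_CODONS:
        raise ValueError(f"change {change.codon}->{mutated} creates a stop codon")
    return GENETIC_CODE[change.codon] == GENETIC_CODE[mutated]


# ---------------------------------------------------------------------------
# Codon alignments and trees
# ---------------------------------------------------------------------------


class Tree:
    """Rooted tree with named internal nodes, backed by a parent map.

    Parsed from newick via :mod:`dendropy`; every internal node must carry a
    label so ancestral sequences can be keyed by node name.
    """

    def __init__(self, parent: dict[str, str | None], lengths: dict[str, float]):
        self._parent = dict(parent)
        self._lengths = dict(lengths)
        roots = [n for n, p in parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = roots[0]
        children: dict[str, list[str]] = {n: [] for n in parent}
        for n, p in parent.items():
            if p is not None:
                children[p].append(n)
        self._children = children
        self.leaves = tuple(sorted(n for n, c in children.items() if not c))
        self.internal = tuple(sorted(n for n, c in children.items() if c))

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        parent: dict[str, str | None] = {}
        lengths: dict[str, float] = {}
        counter = 0
        for node in tree.preorder_node_iter():
            if node.taxon is not None:
                name = node.taxon.label
            elif node.label:
                name = node.label
            else:
                counter += 1
                name = f"node{counter}"
                node.label = name
            node._gcbias_name = name
            par = node.parent_node
            parent[name] = par._gcbias_name if par is not None else None
            lengths[name] = node.edge.length if node.edge.length is not None else 0.0
        return cls(parent, lengths)

    def parent(self, node: str) -> str | None:
        return self._parent[node]

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(self._children[node])

    def branch_length(self, child: str) -> float:
        return self._lengths[child]

    def branches(self) -> list[tuple[str, str]]:
        """All (parent, child) pairs, preorder-ish."""
        return [(p, c) for c, p in self._parent.items() if p is not None]

    def terminal_branches(self) -> list[tuple[str, str]]:
        return [(self._parent[l], l) for l in self.leaves]

    def nodes(self) -> tuple[str, ...]:
        return tuple(self._parent)


@dataclass
class CodonAlignment:
    """Gapped codon alignment plus ancestral node sequences.

    All sequences have equal length divisible by 3; gaps are whole-codon
    ``---`` triplets and masked sites are ``N``.
    """

    gene_id: str
    sequences: dict[str, str]
    ancestors: dict[str, str] = field(default_factory=dict)
    tree: Tree | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()} | {
            len(s) for s in self.ancestors.values()
        }
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: sequences differ in length")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise ValueError(f"{self.gene_id}: length not divisible by 3")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def n_codons(self) -> int:
        return self.n_columns // 3

    def rows(self) -> dict[str, str]:
        """Extant and ancestral sequences together."""
        return {**self.sequences, **self.ancestors}

    def sequence(self, name: str) -> str:
        if name in self.sequences:
            return self.sequences[name]
        return self.ancestors[name]


def _valid_codon(codon: str) -> bool:
    return all(b in BASES for b in codon)


def gc_fraction_at(seq: str, codon_pos: int) -> float:
    """GC fraction at one codon position, ignoring gaps and masked bases."""
    bases = [seq[i] for i in range(codon_pos, len(seq), 3) if seq[i] in BASES]
    if not bases:
        raise ValueError("no valid base at requested codon position")
    return sum(b in STRONG for b in bases) / len(bases)


def gc3(alignment: CodonAlignment, species: str) -> float:
    """GC content at third codon positions of one species."""
    return gc_fraction_at(alignment.sequence(species), 2)


def gc2(alignment: CodonAlignment, species: str) -> float:
    return gc_fraction_at(alignment.sequence(species), 1)


def mask_cpg_columns(alignment: CodonAlignment) -> CodonAlignment:
    """Mask every column participating in a CpG dinucleotide in any row.

    A column ``i`` is masked when any row (extant or ancestral) has ``C`` at
    ``i`` and ``G`` at ``i+1`` — both members of the dinucleotide are masked.
    Idempotent: masked symbols cannot form new CpGs.
    """
    ncol = alignment.n_columns
    to_mask = set()
    for seq in alignment.rows().values():
        for i in range(ncol - 1):
            if seq[i] == "C" and seq[i + 1] == "G":
                to_mask.add(i)
                to_mask.add(i + 1)
    if not to_mask:
        return alignment

    def apply(seq: str) -> str:
        chars = list(seq)
        for i in to_mask:
            if chars[i] != GAP:
                chars[i] = MASK
        return "".join(chars)

    return CodonAlignment(
        gene_id=alignment.gene_id,
        sequences={k: apply(v) for k, v in alignment.sequences.items()},
        ancestors={k: apply(v) for k, v in alignment.ancestors.items()},
        tree=alignment.tree,
    )


def usable_codons(alignment: CodonAlignment) -> list[int]:
    """Codon indices where every row is a valid unmasked sense codon.

    Columns with a gap or mask in any row are excluded from opportunity and
    substitution counting to avoid frame/orientation ambiguity; codons that
    are stops in any row are excluded too.
    """
    out = []
    rows = list(alignment.rows().values())
    for c in range(alignment.n_codons):
        ok = True
        for seq in rows:
            codon = seq[3 * c : 3 * c + 3]
            if not _valid_codon(codon) or codon in STOP_CODONS:
                ok = False
                break
        if ok:
            out.append(c)
    return out
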