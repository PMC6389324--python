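"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA codon alignments (gap '-', mask 'N'), newick trees with named
internal nodes, SNP tables, Marey map TSVs, opportunity/rate tables and a
dadi/Grapes-style SFS text layout.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon import ALL, CATEGORIES, CodonAlignment, Tree
from .marey import MareyMap
from .opportunities import OpportunityCounts
from .polymorphism import SFSPair

__all__ = [
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_tree",
    "read_snp_table",
    "write_snp_table",
    "read_marey_tsv",
    "write_marey_tsv",
    "write_opportunities_tsv",
    "write_sfs",
    "read_sfs",
]


def read_alignment_fasta(
    path, gene_id: str | None = None, tree: Tree | None = None
) -> CodonAlignment:
    """Load a codon alignment; records named after internal tree nodes are
    treated as ancestral sequences."""
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no sequences in {path}")
    internal = set(tree.internal) if tree is not None else set()
    sequences = {k: v for k, v in records.items() if k not in internal}
    ancestors = {k: v for k, v in records.items() if k in internal}
    return CodonAlignment(
        gene_id or Path(path).stem, sequences, ancestors, tree
    )


def write_alignment_fasta(alignment: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in alignment.rows().items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tree(path_or_string) -> Tree:
    text = str(path_or_string)
    if not text.strip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    return Tree.from_newick(text)


SNP_COLUMNS = ["gene_id", "column", "allele1", "allele2", "count1", "count2"]


def read_snp_table(path) -> list[dict]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = []
        for row in reader:
            rows.append(
                {
                    "gene_id": row["gene_id"],
                    "column": int(row["column"]),
                    "allele1": row["allele1"],
                    "allele2": row["allele2"],
                    "count1": int(row["count1"]),
                    "count2": int(row["count2"]),
                }
            )
    return rows


def write_snp_table(rows: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=SNP_COLUMNS, delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row[k] for k in SNP_COLUMNS})


def read_marey_tsv(path) -> dict[str, MareyMap]:
    """TSV with columns chrom, marker_id, phys_bp, gen_cM."""
    chroms: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            chroms.setdefault(row["chrom"], []).append(
                (float(row["phys_bp"]), float(row["gen_cM"]))
            )
    return {
        chrom: MareyMap(
            chrom,
            np.array([m[0] for m in markers]),
            np.array([m[1] for m in markers]),
        )
        for chrom, markers in chroms.items()
    }


def write_marey_tsv(maps: dict[str, MareyMap], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["chrom", "marker_id", "phys_bp", "gen_cM"])
        for chrom, m in maps.items():
            for i, (bp, cm) in enumerate(zip(m.physical_bp, m.genetic_cm)):
                writer.writerow([chrom, f"{chrom}_m{i}", f"{bp:.0f}", f"{cm:.6f}"])


def write_opportunities_tsv(opps: list[OpportunityCounts], path) -> None:
    keys = [*CATEGORIES, ALL]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        header = ["gene_id", "kappa"]
        header += [f"n_syn_{k}" for k in keys] + [f"n_nonsyn_{k}" for k in keys]
        writer.writerow(header)
        for o in opps:
            row = [o.gene_id, f"{o.kappa:.6g}"]
            row += [f"{o.n_syn[k]:.6f}" for k in keys]
            row += [f"{o.n_nonsyn[k]:.6f}" for k in keys]
            writer.writerow(row)


def write_sfs(sfs: SFSPair, path) -> None:
    """Grapes/dadi-style text layout: header line, then syn and nonsyn rows
    with opportunity and divergence totals."""
    with open(path, "w") as fh:
        fh.write(f"# unfolded SFS, category={sfs.category}, n={sfs.n}\n")
        fh.write(f"n\t{sfs.n}\n")
        syn = "\t".join(f"{v:.6g}" for v in sfs.syn_sfs)
        nonsyn = "\t".join(f"{v:.6g}" for v in sfs.nonsyn_sfs)
        fh.write(f"syn\t{sfs.L_syn:.6f}\t{sfs.D_syn:.6g}\t{syn}\n")
        fh.write(f"nonsyn\t{sfs.L_nonsyn:.6f}\t{sfs.D_nonsyn:.6g}\t{nonsyn}\n")


def read_sfs(path, category=ALL) -> SFSPair:
    n = None
    data = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "n":
                n = int(parts[1])
            elif parts[0] in ("syn", "nonsyn"):
                data[parts[0]] = (
                    float(parts[1]),
                    float(parts[2]),
                    np.array([float(v) for v in parts[3:]]),
                )
    if n is None or set(data) != {"syn", "nonsyn"}:
        raise ValueError(f"malformed SFS file {path}")
    return SFSPair(
        category,
        n,
        data["syn"][2],
        data["nonsyn"][2],
        L_syn=data["syn"][0],
        L_nonsyn=data["nonsyn"][0],
        D_syn=data["syn"][1],
        D_nonsyn=data["nonsyn"][1],
    )
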