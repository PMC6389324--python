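"""End-to-end orchestration: simulate/ingest -> classify -> opportunities ->
divergence -> polymorphism -> bins -> DFE-alpha -> tables.

Every stage communicates through plain TSV/FASTA files in the output
directory; a manifest records the config hash, seed and output checksums so
that a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .binning import fdr_adjust, make_bins, spearman_table
from .codon import ALL, CATEGORIES, gc3, mask_cpg_columns
from .dfe import fit as dfe_fit
from .dfe import profile_ci
from .divergence import count_substitutions, rate_estimate
from .io import write_alignment_fasta, write_opportunities_tsv, write_sfs, write_snp_table
from .opportunities import count_opportunities, estimate_kappa
from .polymorphism import OrientationLog, build_sfs, mean_derived_freq, orient_and_classify, pi
from .simulate import SimulationConfig, simulate_dataset, simulate_snp_table

logger = logging.getLogger("gcbias")

__all__ = ["RunManifest", "run"]


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: dict  # path -> sha256

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: SimulationConfig, options: dict) -> str:
    payload = json.dumps(
        {"config": dataclasses.asdict(config), "options": options},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run(
    config: SimulationConfig,
    outdir,
    k_bins: int = 10,
    bin_scheme: str = "equal_genes",
    mask_cpg: bool = False,
    model: str = "GammaZero",
    kappa: float | None = None,
    n_boot: int = 200,
    with_ci: bool = False,
) -> RunManifest:
    """Run the full synthetic pipeline; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    options = {
        "k_bins": k_bins,
        "bin_scheme": bin_scheme,
        "mask_cpg": mask_cpg,
        "model": model,
        "kappa": kappa,
        "n_boot": n_boot,
    }
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    # --- stage: simulate -------------------------------------------------
    genes = simulate_dataset(config)
    focal = config.focal_species
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for g in genes:
        write_alignment_fasta(g.alignment, aln_dir / f"{g.alignment.gene_id}.fasta")
    (outdir / "tree.nwk").write_text(config.tree + "\n")

    # --- stage: classify / mask ------------------------------------------
    alignments = {g.alignment.gene_id: g.alignment for g in genes}
    if mask_cpg:
        alignments = {k: mask_cpg_columns(v) for k, v in alignments.items()}
    gene_ids = sorted(alignments)

    # --- stage: opportunities --------------------------------------------
    kappa_used = kappa if kappa is not None else estimate_kappa(
        alignments.values(), species=focal
    )
    opps = {gid: count_opportunities(alignments[gid], focal, kappa_used) for gid in gene_ids}
    write_opportunities_tsv([opps[g] for g in gene_ids], outdir / "opportunities.tsv")
    logger.info(
        "stop-excluded opportunity weight: %.3f",
        sum(o.stop_weight for o in opps.values()),
    )

    # --- stage: divergence ------------------------------------------------
    tree = genes[0].alignment.tree
    parent = tree.parent(focal)
    subs = {
        gid: count_substitutions(alignments[gid], (parent, focal)) for gid in gene_ids
    }
    gc3_by_gene = {gid: gc3(alignments[gid], focal) for gid in gene_ids}

    binning = make_bins(gc3_by_gene, scheme="equal_genes", k=k_bins, sort_key="GC3")
    bins = binning.bins()
    div_rows = []
    for b, members in enumerate(bins):
        mean_gc3 = float(np.mean([gc3_by_gene[g] for g in members]))
        for cat in (*CATEGORIES, ALL):
            est = rate_estimate(
                [subs[g] for g in members],
                [opps[g] for g in members],
                category=cat,
                n_boot=n_boot,
                seed=config.seed + b,
            )
            div_rows.append(
                {
                    "bin": b,
                    "mean_gc3": mean_gc3,
                    "category": str(cat),
                    "dN": est.dN,
                    "dS": est.dS,
                    "omega": est.omega,
                    "omega_ci_low": est.ci_low,
                    "omega_ci_high": est.ci_high,
                }
            )
    _write_tsv(outdir / "divergence_bins.tsv", div_rows)

    # Table-1-style bin-level Spearman correlations with FDR
    corr_rows = []
    for stat in ("dN", "dS", "omega"):
        for cat in (*CATEGORIES, ALL):
            xs = [r["mean_gc3"] for r in div_rows if r["category"] == str(cat)]
            ys = [r[stat] for r in div_rows if r["category"] == str(cat)]
            try:
                rho, p = spearman_table(xs, ys)
            except ValueError:
                rho, p = float("nan"), float("nan")
            corr_rows.append({"statistic": stat, "category": str(cat), "rho": rho, "p": p})
    adj = fdr_adjust([r["p"] for r in corr_rows])
    for r, q in zip(corr_rows, adj):
        r["p_fdr"] = q
    _write_tsv(outdir / "table1_divergence_correlations.tsv", corr_rows)

    # --- stage: polymorphism ----------------------------------------------
    snp_rows = []
    for g in genes:
        snp_rows.extend(simulate_snp_table(g, config, rng))
    write_snp_table(snp_rows, outdir / "snps.tsv")
    olog = OrientationLog()
    records = orient_and_classify(snp_rows, alignments, focal, log=olog)
    logger.info("orientation: %s", olog)
    poly_rows = []
    for cat in (*CATEGORIES, ALL):
        try:
            pi_n, pi_s, ratio = pi(records, list(opps.values()), category=cat)
        except ValueError:
            pi_n = pi_s = ratio = float("nan")
        try:
            mdf_s = mean_derived_freq(records, category=cat, synonymous=True)
        except ValueError:
            mdf_s = float("nan")
        poly_rows.append(
            {
                "category": str(cat),
                "pi_n": pi_n,
                "pi_s": pi_s,
                "pi_n_pi_s": ratio,
                "mean_derived_freq_syn": mdf_s,
            }
        )
    _write_tsv(outdir / "polymorphism.tsv", poly_rows)

    # --- stage: SFS + DFE-alpha -------------------------------------------
    table3_rows = []
    for cat in (*CATEGORIES, ALL):
        totals = [subs[g].totals() for g in gene_ids]
        D_syn = sum(t[("syn", cat)] for t in totals)
        D_nonsyn = sum(t[("nonsyn", cat)] for t in totals)
        try:
            sfs = build_sfs(
                records,
                list(opps.values()),
                category=cat,
                n=config.n_chromosomes,
                D_syn=D_syn,
                D_nonsyn=D_nonsyn,
            )
        except ValueError:
            continue
        write_sfs(sfs, outdir / f"sfs_{cat}.tsv")
        f = dfe_fit(sfs, model, seed=config.seed)
        row = {
            "category": str(cat),
            "model": model,
            "shape": f.model.shape,
            "s_mean": f.model.s_mean,
            "p_pos": f.model.p_pos,
            "loglik": f.loglik,
            "converged": f.converged,
            "alpha": f.alpha,
            "omega_a": f.omega_a,
            "omega_na": f.omega_na,
        }
        if with_ci and f.alpha is not None:
            ci = profile_ci(f, "omega_a")
            row["omega_a_ci_low"], row["omega_a_ci_high"] = ci.low, ci.high
        table3_rows.append(row)
    _write_tsv(outdir / "table3_dfe_alpha.tsv", table3_rows)

    # --- manifest -----------------------------------------------------------
    outputs = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(_config_hash(config, options), config.seed, __version__, outputs)
    manifest.write(outdir / "manifest.json")
    return manifest


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _write_tsv(path, rows: list[dict]) -> None:
    if not rows:
        Path(path).write_text("")
        return
    keys = list(rows[0])
    lines = ["\t".join(keys)]
    for row in rows:
        lines.append("\t".join(_fmt(row.get(k)) for k in keys))
    Path(path).write_text("\n".join(lines) + "\n")
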