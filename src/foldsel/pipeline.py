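"""End-to-end orchestration: files in, group summaries and tests out.

The analysis chain: read genome -> classify and filter SNPs -> transfer
essentiality (direct label table or reciprocal best hits against a
second catalog) -> per mutated gene: ancestor MFE, observed-mutant MFE,
synonymous null family MFEs, percentile -> group summaries (SNP-count
and synonymy tables, MFE sign summary, percentile quartiles, ECDFs),
Mann-Whitney U on percentiles and the binomial test on synonymous-SNP
fractions.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import genome_io
from .essentiality import (bidirectional_best_hits, read_essentiality_table,
                           transfer_essentiality)
from .genome_io import GeneCatalog, SnpRecord
from .mfe import FoldingConfig, abs_delta_mfe, fold_mfe_many
from .stats import (PercentileRecord, ecdf_points, exact_binomial_test,
                    mann_whitney_u, mfe_sign_summary, percentile_for_gene,
                    quartile_summary, snp_count_table, synonymy_table)
from .synmut import SubstitutionSpectrum, build_mutant_family, ts_tv_ratio
from .synthetic import gene_rng

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "analyze", "run_full_analysis",
           "render_summary_tables", "plot_ecdfs"]


@dataclass
class RunConfig:
    """File-level configuration of a full run."""

    genome: str
    snps: str
    output_dir: str
    gene_table: str | None = None          # FASTA + table input mode
    essentiality: str | None = None        # label TSV for the analysed genome
    genome_b: str | None = None            # or: second genome for BBH ...
    gene_table_b: str | None = None
    essentiality_b: str | None = None      # ... with labels on its gene ids
    engine: str = "reference"
    no_lonely_pairs: bool = True
    cap: int = 1000
    seed: int = 0
    ties: str = "strict"
    binomial_convention: str = "minlike"

    def fold_config(self) -> FoldingConfig:
        return FoldingConfig(engine=self.engine,
                             no_lonely_pairs=self.no_lonely_pairs)


def analyze(catalog: GeneCatalog, snp_rows, labels: dict[str, str] | None = None,
            catalog_b: GeneCatalog | None = None,
            labels_b: dict[str, str] | None = None,
            fold_cfg: FoldingConfig | None = None,
            cap: int = 1000, seed: int = 0, ties: str = "strict",
            binomial_convention: str = "minlike",
            target_spectrum: SubstitutionSpectrum | None = None) -> dict:
    """Run the analysis on in-memory inputs.

    ``snp_rows`` are raw (0-based position, ref, alt) tuples.  Labels
    come either directly (``labels``: gene_id -> essential/dispensable)
    or through reciprocal best hits against ``catalog_b`` carrying
    ``labels_b``.  Returns a dict with per-gene percentile records, the
    exclusion report and the group summary.
    """
    fold_cfg = fold_cfg or FoldingConfig()
    records, mismatches = genome_io.classify_snps(snp_rows, catalog)
    retained, report = genome_io.filter_snps(records, catalog,
                                             n_ref_mismatch=len(mismatches))

    if labels is not None:
        gene_labels = {g.gene_id: labels.get(g.gene_id, "unknown")
                       for g in catalog}
        for g in catalog:
            lab = gene_labels[g.gene_id]
            g.essentiality = {"essential": "essential",
                              "dispensable": "nonessential"}.get(lab, "unknown")
    elif catalog_b is not None and labels_b is not None:
        pairs = bidirectional_best_hits(catalog, catalog_b)
        transfer_essentiality(catalog, pairs, labels_b)
    else:
        raise ValueError("need either labels or (catalog_b, labels_b)")
    class_of = {g.gene_id: g.essentiality for g in catalog}

    by_gene: dict[str, list[SnpRecord]] = {}
    for snp in retained:
        by_gene.setdefault(snp.gene_id, []).append(snp)

    percentile_records: list[PercentileRecord] = []
    tstv_by_class: dict[str, list[float]] = {"essential": [],
                                             "nonessential": []}
    skipped: list[str] = []
    for gene_id in sorted(by_gene):
        cls = class_of[gene_id]
        if cls not in ("essential", "nonessential"):
            continue
        gene = catalog.get(gene_id)
        gsnps = by_gene[gene_id]
        mutated = genome_io.apply_snps(gene, gsnps)
        try:
            family = build_mutant_family(
                gene.cds, k=len(gsnps), cap=cap,
                target_spectrum=target_spectrum,
                rng=gene_rng(seed, gene_id), gene_id=gene_id)
        except ValueError as exc:
            log.warning("gene %s skipped: %s", gene_id, exc)
            skipped.append(gene_id)
            continue
        anc, obs = fold_mfe_many([gene.cds, mutated], fold_cfg)
        fam_mfe = fold_mfe_many(family.mutated_sequences(gene.cds), fold_cfg)
        delta = abs_delta_mfe(anc, obs)
        fam_deltas = [abs_delta_mfe(anc, m).abs for m in fam_mfe]
        pct = percentile_for_gene(delta.abs, fam_deltas, ties=ties)
        percentile_records.append(PercentileRecord(
            gene_id, cls, delta.abs, delta.signed, family.size, pct))
        tstv_by_class[cls].append(ts_tv_ratio(
            [(gene.cds[p], a) for m in family.members for p, a in m]))

    summary = summarize(percentile_records, retained, class_of,
                        binomial_convention=binomial_convention)
    finite = {c: [t for t in v if np.isfinite(t)]
              for c, v in tstv_by_class.items()}
    if finite["essential"] and finite["nonessential"]:
        _, p = mann_whitney_u(finite["essential"], finite["nonessential"])
        summary["tstv_mann_whitney_p"] = p
    return {"percentiles": percentile_records,
            "exclusions": report,
            "skipped_genes": skipped,
            "summary": summary}


def summarize(percentile_records, retained_snps, class_of,
              binomial_convention: str = "minlike") -> dict:
    """Group-level tables and tests from per-gene records."""
    snps_per_gene: dict[str, int] = {}
    for snp in retained_snps:
        snps_per_gene[snp.gene_id] = snps_per_gene.get(snp.gene_id, 0) + 1
    summary: dict = {
        "snp_count_table": snp_count_table(snps_per_gene, class_of),
        "synonymy_table": synonymy_table(retained_snps, class_of),
    }
    syn = summary["synonymy_table"]
    ess_tot = syn["essential"]["synonymous"] + syn["essential"]["nonsynonymous"]
    non_tot = (syn["nonessential"]["synonymous"]
               + syn["nonessential"]["nonsynonymous"])
    if ess_tot and non_tot and 0 < syn["nonessential"]["synonymous"] < non_tot:
        summary["binomial_p"] = exact_binomial_test(
            syn["essential"]["synonymous"], ess_tot,
            syn["nonessential"]["synonymous"] / non_tot,
            convention=binomial_convention)

    per_class = {"essential": [r for r in percentile_records
                               if r.essentiality == "essential"],
                 "nonessential": [r for r in percentile_records
                                  if r.essentiality == "nonessential"]}
    summary["sign_table"] = {
        cls: mfe_sign_summary([r.signed_delta for r in recs])
        for cls, recs in per_class.items() if recs}
    summary["quartile_table"] = {}
    summary["ecdf"] = {}
    for cls, recs in per_class.items():
        if not recs:
            continue
        pcts = [r.percentile for r in recs]
        lq, med, uq = quartile_summary(pcts)
        summary["quartile_table"][cls] = {
            "n": len(recs), "lower_quartile_pct": lq,
            "median_pct": med, "upper_quartile_pct": uq}
        summary["ecdf"][cls] = ecdf_points(pcts)
    if per_class["essential"] and per_class["nonessential"]:
        u, p = mann_whitney_u([r.percentile for r in per_class["essential"]],
                              [r.percentile for r in per_class["nonessential"]])
        summary["mann_whitney_u"] = u
        summary["mann_whitney_p"] = p
    return summary


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run from files, write per-gene TSV, summary JSON and a manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = genome_io.read_genome(cfg.genome, cfg.gene_table)
    snp_rows = genome_io.read_snp_table(cfg.snps)
    labels = catalog_b = labels_b = None
    if cfg.essentiality:
        labels = read_essentiality_table(cfg.essentiality)
    elif cfg.genome_b and cfg.essentiality_b:
        catalog_b = genome_io.read_genome(cfg.genome_b, cfg.gene_table_b)
        labels_b = read_essentiality_table(cfg.essentiality_b)
    else:
        raise ValueError("config must provide an essentiality source")
    result = analyze(catalog, snp_rows, labels=labels, catalog_b=catalog_b,
                     labels_b=labels_b, fold_cfg=cfg.fold_config(),
                     cap=cfg.cap, seed=cfg.seed, ties=cfg.ties,
                     binomial_convention=cfg.binomial_convention)

    with open(out / "per_gene.tsv", "w") as fh:
        fh.write("gene_id\tessentiality\tobserved_abs_delta\tsigned_delta\t"
                 "family_size\tpercentile\n")
        for r in result["percentiles"]:
            fh.write(f"{r.gene_id}\t{r.essentiality}\t"
                     f"{r.observed_abs_delta:.6f}\t{r.signed_delta:.6f}\t"
                     f"{r.family_size}\t{r.percentile:.6f}\n")
    with open(out / "exclusions.tsv", "w") as fh:
        fh.write("category\tcount\n")
        for cat, n in result["exclusions"]["counts"].items():
            fh.write(f"{cat}\t{n}\n")
    with open(out / "exclusion_reasons.tsv", "w") as fh:
        fh.write("position\tgene_id\treason\n")
        for snp, reason in result["exclusions"]["reasons"]:
            fh.write(f"{snp.position + 1}\t{snp.gene_id or '.'}\t{reason}\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(result["summary"], fh, indent=2, sort_keys=True)
    if result["summary"].get("ecdf"):
        plot_ecdfs(result["summary"], out / "ecdf.png")
    manifest = {"config": asdict(cfg),
                "n_genes": len(catalog),
                "n_snps_in": len(snp_rows),
                "exclusion_counts": result["exclusions"]["counts"],
                "n_percentile_records": len(result["percentiles"])}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result


def plot_ecdfs(summary: dict, path) -> None:
    """Plot the two percentile ECDF curves (essential solid,
    nonessential dashed) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    styles = {"essential": "-", "nonessential": "--"}
    for cls, pts in summary.get("ecdf", {}).items():
        xs = [0.0] + [p[0] for p in pts] + [1.0]
        ys = [0.0] + [p[1] for p in pts] + [1.0]
        ax.step(xs, ys, where="post", linestyle=styles.get(cls, "-"),
                label=cls, color="black")
    ax.set_xlabel("percentile of observed |dMFE| in null family")
    ax.set_ylabel("cumulative fraction of genes")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_summary_tables(summary: dict) -> str:
    """Human-readable rendering of the four group tables and tests."""
    lines: list[str] = []
    t1 = summary.get("snp_count_table", {})
    if t1:
        lines.append("Genes by number of SNPs")
        lines.append(f"{'class':<14}{'1':>6}{'2':>6}{'3+':>6}{'total':>8}")
        for cls, row in t1.items():
            lines.append(f"{cls:<14}{row['1']:>6}{row['2']:>6}"
                         f"{row['3']:>6}{row['total']:>8}")
        lines.append("")
    t2 = summary.get("synonymy_table", {})
    if t2:
        lines.append("Synonymous / nonsynonymous SNPs")
        lines.append(f"{'class':<14}{'syn':>6}{'nonsyn':>8}")
        for cls, row in t2.items():
            lines.append(f"{cls:<14}{row['synonymous']:>6}"
                         f"{row['nonsynonymous']:>8}")
        lines.append("")
    t3 = summary.get("sign_table", {})
    if t3:
        lines.append("MFE change sign (observed mutation)")
        lines.append(f"{'class':<14}{'down':>12}{'same':>12}{'up':>12}"
                     f"{'total':>7}")
        for cls, row in t3.items():
            lines.append(
                f"{cls:<14}"
                f"{row['decreased']:>5} ({row['decreased_pct']:4.1f}%)"
                f"{row['unchanged']:>5} ({row['unchanged_pct']:4.1f}%)"
                f"{row['increased']:>5} ({row['increased_pct']:4.1f}%)"
                f"{row['total']:>7}")
        lines.append("")
    t4 = summary.get("quartile_table", {})
    if t4:
        lines.append("Percentile distribution (percent)")
        lines.append(f"{'class':<14}{'n':>5}{'Q1':>8}{'median':>8}{'Q3':>8}")
        for cls, row in t4.items():
            lines.append(f"{cls:<14}{row['n']:>5}"
                         f"{row['lower_quartile_pct']:>8.1f}"
                         f"{row['median_pct']:>8.1f}"
                         f"{row['upper_quartile_pct']:>8.1f}")
        lines.append("")
    if "mann_whitney_p" in summary:
        lines.append(f"Mann-Whitney U (percentiles): "
                     f"P = {summary['mann_whitney_p']:.4g}")
    if "binomial_p" in summary:
        lines.append(f"Binomial test (synonymous fractions): "
                     f"P = {summary['binomial_p']:.4g}")
    if "tstv_mann_whitney_p" in summary:
        lines.append(f"Ts/Tv spectra between classes: "
                     f"P = {summary['tstv_mann_whitney_p']:.4g}")
    empty = [cls for t in (t1, t2, t3, t4) for cls in ("essential",
             "nonessential") if t and cls not in t]
    if empty:
        lines.append(f"warning: empty class rows: {sorted(set(empty))}")
    return "\n".join(lines) + "\n"
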