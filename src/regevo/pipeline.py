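"""End-to-end orchestration: catalog → scan → turnover → rates → architecture → stats.

``run_cohort`` executes the whole analysis on an in-memory bundle and
returns every intermediate and summary table; ``write_report`` serializes
them as TSV/JSON together with a run manifest (config snapshot, seed, row
counts, output checksums) so a rerun with the same manifest is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog, evorate, motifs, nucarch, stats, turnover
from .io import CohortBundle


@dataclass
class CohortResult:
    retained: list
    filter_audit: dict
    promoters: dict  # gene_id -> catalog.Promoter (retained genes)
    hits: list  # curated, turnover-labeled MotifHits
    regulation: pd.DataFrame  # per-gene n_tfs / n_tfbs
    regulation_summary: pd.DataFrame  # group mean ± SEM
    turnover_per_gene: pd.DataFrame
    turnover_by_group: pd.DataFrame
    rates: pd.DataFrame  # per-gene promoter substitution rates
    neutral_rate: float
    neutral_sites: int
    architectures: list
    architecture_summary: pd.DataFrame
    enrichment: pd.DataFrame
    comparisons: pd.DataFrame  # every group-vs-de-novo test
    contrasts: dict  # the four planted contrasts, name -> TestResult
    audit: dict = field(default_factory=dict)

    def significant_contrasts(self, alpha: float = 0.01) -> dict:
        return {k: v.p_value < alpha for k, v in self.contrasts.items()}


def _extract_promoters(bundle: CohortBundle) -> dict:
    genome = bundle.genome
    promoters = {}
    for gene in bundle.genes:
        promoters[gene.gene_id] = catalog.extract_promoter(gene, genome, bundle.genes)
    return promoters


def run_cohort(
    bundle: CohortBundle,
    alpha: float | None = None,
    bin_width: float | None = None,
) -> CohortResult:
    """Run the full analysis on a bundle (simulated or read from disk)."""
    cfg = bundle.config
    alpha = alpha if alpha is not None else (cfg.alpha if cfg else 0.001)
    bin_width = bin_width if bin_width is not None else (cfg.bin_width if cfg else 0.01)
    background = cfg.background() if cfg else None
    species = list(cfg.outgroups) if cfg else list(bundle.species)
    if not species:
        raise ValueError("bundle provides no outgroup alignments")
    primary_species = species[0]

    # --- gene catalog: origin categories and promoter filters
    for gene in bundle.genes:
        gene.category = catalog.classify_origin(bundle.evidence[gene.gene_id])
    categories = bundle.categories
    promoters = _extract_promoters(bundle)
    primary_alignments = {
        gid: aln
        for (gid, sp), aln in bundle.promoter_alignments.items()
        if sp == primary_species
    }
    retained, audit = catalog.apply_promoter_filters(
        bundle.genes, promoters, primary_alignments
    )
    retained_set = set(retained)
    retained_promoters = {gid: promoters[gid] for gid in retained}

    # --- motif scan + curation filter
    scanners = {
        pfm.tf_id: motifs.PwmScanner(
            motifs.pfm_to_pwm(pfm, background), alpha, background, bin_width
        )
        for pfm in bundle.pfms
    }
    all_hits: list = []
    for gid in retained:
        promoter = retained_promoters[gid]
        for scanner in scanners.values():
            all_hits.extend(motifs.scan_promoter(scanner, promoter))
    curated = motifs.filter_by_curation(all_hits, bundle.curation)

    regulation = motifs.summarize_regulation(curated, retained)
    regulation["category"] = [categories[g] for g in regulation.index]
    reg_summary = pd.concat(
        [
            stats.group_summary(
                {c: sub["n_tfs"] for c, sub in regulation.groupby("category")}
            ).add_prefix("n_tfs_"),
            stats.group_summary(
                {c: sub["n_tfbs"] for c, sub in regulation.groupby("category")}
            ).add_prefix("n_tfbs_"),
        ],
        axis=1,
    )

    # --- turnover against both outgroups
    lengths = {gid: retained_promoters[gid].length for gid in retained}
    turnover.classify_hits(
        curated, bundle.promoter_alignments, scanners, species, lengths
    )
    turnover_per_gene, turnover_by_group = turnover.turnover_summary(curated, categories)

    # --- promoter substitution rates + neutral reference
    rate_results = []
    for gid in retained:
        aln = primary_alignments.get(gid)
        if aln is None:
            continue
        try:
            rate_results.append(evorate.p_distance(aln))
        except ValueError:
            audit.setdefault("rate_excluded", []).append(gid)
    rates = evorate.rate_table(rate_results, categories)
    site_sets = {
        gid: evorate.find_fourfold_sites(gid, cds)
        for gid, cds in bundle.cds_seqs.items()
    }
    if bundle.cds_alignments:
        neutral, _, n_sites = evorate.neutral_rate(
            bundle.cds_alignments.values(), site_sets
        )
    else:
        neutral, n_sites = float("nan"), 0

    # --- nucleosome architecture + TATA
    gene_by_id = {g.gene_id: g for g in bundle.genes}
    architectures = nucarch.classify_cohort(
        [gene_by_id[gid] for gid in retained], bundle.nucleosomes, lengths
    )
    for arch in architectures:
        flag, _ = motifs.find_tata(retained_promoters[arch.gene_id])
        arch.tata_containing = flag
    arch_summary = nucarch.architecture_summary(architectures, categories)

    # --- TF enrichment in de novo genes (gene-level binomial, BH-FDR)
    de_novo = [g for g in retained if categories[g] == "de_novo"]
    background_genes = [g for g in retained if categories[g] != "de_novo"]
    tf_to_genes: dict[str, set] = {pfm.tf_id: set() for pfm in bundle.pfms}
    for hit in curated:
        tf_to_genes[hit.tf_id].add(hit.gene_id)
    if de_novo and background_genes:
        enrichment = stats.enrichment_table(tf_to_genes, de_novo, background_genes)
    else:
        enrichment = pd.DataFrame(columns=["x", "n", "p0", "p_value", "q_value"])

    comparisons, contrasts = _comparisons(
        regulation, turnover_per_gene, turnover_by_group, rates, arch_summary
    )

    return CohortResult(
        retained=retained,
        filter_audit=audit,
        promoters=retained_promoters,
        hits=curated,
        regulation=regulation,
        regulation_summary=reg_summary,
        turnover_per_gene=turnover_per_gene,
        turnover_by_group=turnover_by_group,
        rates=rates,
        neutral_rate=neutral,
        neutral_sites=n_sites,
        architectures=architectures,
        architecture_summary=arch_summary,
        enrichment=enrichment,
        comparisons=comparisons,
        contrasts=contrasts,
        audit={"n_scanned_hits": len(all_hits), "n_curated_hits": len(curated)},
    )


def _comparisons(regulation, turnover_per_gene, turnover_by_group, rates, arch_summary):
    """Group comparison tables mirroring the four figure families.

    Returns (all comparisons DataFrame, four planted de-novo-vs-orthologous
    contrasts): pooled gained proportion (greater), promoter substitution
    rate (Wilcoxon, greater), DPN proportion (greater), TATA proportion
    (less).
    """
    rows = []
    contrasts = {}

    def add(name, result, group_a, group_b):
        rows.append(
            {
                "comparison": name,
                "group1": group_a,
                "group2": group_b,
                "test": result.test_name,
                "alternative": result.alternative,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "n1": result.n1,
                "n2": result.n2,
            }
        )
        return result

    others = ("duplicated_new", "orthologous", "other")

    def values(df, col, cat):
        return df.loc[df["category"] == cat, col].to_numpy()

    for col in ("n_tfs", "n_tfbs"):
        for cat in others:
            x = values(regulation, col, "de_novo")
            y = values(regulation, col, cat)
            if len(x) and len(y):
                add(col, stats.wilcoxon_rank_sum(x, y, "two_sided"), "de_novo", cat)

    for cat in others:
        x = values(turnover_per_gene, "gained_fraction", "de_novo")
        y = values(turnover_per_gene, "gained_fraction", cat)
        if len(x) and len(y):
            alt = "two_sided" if cat == "duplicated_new" else "one_sided_greater"
            add("gained_fraction_per_gene", stats.wilcoxon_rank_sum(x, y, alt),
                "de_novo", cat)
        if "de_novo" in turnover_by_group.index and cat in turnover_by_group.index:
            dn = turnover_by_group.loc["de_novo"]
            gb = turnover_by_group.loc[cat]
            alt = "two_sided" if cat == "duplicated_new" else "one_sided_less"
            res = add(
                "preexisting_proportion_pooled",
                stats.two_proportion_test(
                    int(dn.preexisting), int(dn.classified),
                    int(gb.preexisting), int(gb.classified), alt,
                ),
                "de_novo", cat,
            )
            if cat == "orthologous":
                # planted contrast: higher pooled gained fraction in de novo
                contrasts["gained_fraction"] = stats.two_proportion_test(
                    int(dn.gained), int(dn.classified),
                    int(gb.gained), int(gb.classified), "one_sided_greater",
                )

    for cat in others:
        x = values(rates, "rate", "de_novo")
        y = values(rates, "rate", cat)
        if len(x) and len(y):
            alt = "two_sided" if cat == "duplicated_new" else "one_sided_greater"
            res = add("promoter_substitution_rate",
                      stats.wilcoxon_rank_sum(x, y, alt), "de_novo", cat)
            if cat == "orthologous":
                contrasts["substitution_rate"] = res

    for cat in others:
        if "de_novo" not in arch_summary.index or cat not in arch_summary.index:
            continue
        dn = arch_summary.loc["de_novo"]
        gb = arch_summary.loc[cat]
        dn_cls = int(dn.n_opn + dn.n_dpn)
        gb_cls = int(gb.n_opn + gb.n_dpn)
        if dn_cls and gb_cls:
            res = add(
                "dpn_proportion",
                stats.two_proportion_test(
                    int(dn.n_dpn), dn_cls, int(gb.n_dpn), gb_cls, "one_sided_greater"
                ),
                "de_novo", cat,
            )
            if cat == "orthologous":
                contrasts["dpn_proportion"] = res
        res = add(
            "tata_proportion",
            stats.two_proportion_test(
                int(dn.n_tata), int(dn.n_genes),
                int(gb.n_tata), int(gb.n_genes), "one_sided_less",
            ),
            "de_novo", cat,
        )
        if cat == "orthologous":
            contrasts["tata_proportion"] = res

    return pd.DataFrame(rows), contrasts


# --- report serialization ---------------------------------------------------


def hits_table(result: CohortResult) -> pd.DataFrame:
    rows = []
    for h in result.hits:
        rows.append(
            {
                "gene_id": h.gene_id,
                "tf_id": h.tf_id,
                "tss_relative_start": h.tss_relative_start,
                "strand": h.strand,
                "score_bits": round(h.score, 4),
                "p_value": h.p_value,
                "curated": int(h.curated),
                "turnover_label": h.turnover_label,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["gene_id", "tss_relative_start", "tf_id"]).reset_index(drop=True)
    return df


def hits_bed(result: CohortResult, width_by_tf: dict) -> pd.DataFrame:
    """Curated hits in genomic BED6 coordinates."""
    rows = []
    for h in result.hits:
        prom = result.promoters[h.gene_id]
        w = width_by_tf[h.tf_id]
        local = h.local_start(prom.length)
        if prom.strand == "+":
            start = prom.interval[0] + local
        else:
            start = prom.interval[1] - local - w
        rows.append(
            {
                "chrom": prom.chrom,
                "start": start,
                "end": start + w,
                "name": f"{h.gene_id}|{h.tf_id}",
                "score": int(round(min(h.score, 15.0) * 60)),
                "strand": h.strand if prom.strand == "+" else ("-" if h.strand == "+" else "+"),
            }
        )
    return pd.DataFrame(rows)


def write_report(result: CohortResult, outdir, config=None, seed=None) -> dict:
    """Write all result tables and the run manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    arch_df = pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "proximal_occupied": int(a.proximal_occupied),
                "distal_occupied": int(a.distal_occupied),
                "label": a.label,
                "tata_containing": int(bool(a.tata_containing)),
            }
            for a in result.architectures
        ]
    )
    neutral_df = pd.DataFrame(
        [{"neutral_rate": result.neutral_rate, "n_fourfold_sites": result.neutral_sites}]
    )
    tables = {
        "hits.tsv": hits_table(result),
        "regulation.tsv": result.regulation.reset_index(),
        "regulation_summary.tsv": result.regulation_summary.reset_index(),
        "turnover_per_gene.tsv": result.turnover_per_gene.reset_index(),
        "turnover_groups.tsv": result.turnover_by_group.reset_index(),
        "rates.tsv": result.rates.reset_index(),
        "neutral_rate.tsv": neutral_df,
        "architecture.tsv": arch_df,
        "architecture_groups.tsv": result.architecture_summary.reset_index(),
        "enrichment.tsv": result.enrichment.reset_index(),
        "comparisons.tsv": result.comparisons,
    }
    for name, df in tables.items():
        df.to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")

    manifest = {
        "seed": seed,
        "config": config.to_dict() if config is not None else None,
        "n_genes_input": result.filter_audit.get("input"),
        "funnel": result.filter_audit.get("funnel"),
        "n_retained": len(result.retained),
        "n_curated_hits": len(result.hits),
        "row_counts": {name: int(len(df)) for name, df in tables.items()},
        "contrasts": {
            k: {"statistic": v.statistic, "p_value": v.p_value, "alternative": v.alternative}
            for k, v in result.contrasts.items()
        },
        "checksums": {
            name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            for name in tables
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_pipeline(config, outdir=None, bundle: CohortBundle | None = None):
    """Simulate (unless a bundle is given), analyze, optionally write a report."""
    from .simulate import simulate_cohort

    if bundle is None:
        bundle = simulate_cohort(config)
    result = run_cohort(bundle)
    if outdir is not None:
        write_report(result, outdir, config=bundle.config, seed=getattr(config, "seed", None))
    return result
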