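"""Cohort bundle container and on-disk round trip.

A bundle holds everything one analysis run consumes: genome FASTA, gene
annotation (GFF3, 1-based at the boundary), TSS BED, per-gene per-species
promoter alignments and CDS alignments (aligned FASTA pairs, focal record
first), a JASPAR-style PFM library, the curated TF→gene association table,
duplicate pairs, homology evidence, a nucleosome map (BED6, score =
occupancy × 1000), and — for synthetic cohorts — the planted truth table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .alignment import PromoterAlignment, read_pairwise_fasta, write_pairwise_fasta
from .catalog import GeneRecord, HomologyEvidence
from .config import SimulationConfig
from .motifs import PositionFrequencyMatrix, read_pfms, write_pfms
from .nucarch import NucleosomeCall, read_nucleosome_bed, write_nucleosome_bed


@dataclass
class TruthTable:
    """Planted ground truth of a synthetic cohort.

    ``motifs``: one row per planted motif instance (gene_id, tf_id,
    tss_relative_start, strand, turnover_truth).  ``genes``: one row per gene
    (gene_id, category, tata_truth, tata_position, architecture_truth,
    true_substitution_rate, promoter_length).
    """

    motifs: pd.DataFrame
    genes: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "motifs": self.motifs.to_dict(orient="records"),
            "genes": self.genes.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(pd.DataFrame(payload["motifs"]), pd.DataFrame(payload["genes"]))


@dataclass
class CohortBundle:
    config: SimulationConfig | None
    genome: dict  # chrom -> sequence
    genes: list  # list[GeneRecord]
    evidence: dict  # gene_id -> HomologyEvidence
    duplicate_pairs: list  # list[(gene_id, gene_id)]
    pfms: list  # list[PositionFrequencyMatrix]
    curation: set  # {(tf_id, gene_id)}
    promoter_alignments: dict  # (gene_id, species) -> PromoterAlignment
    cds_seqs: dict  # gene_id -> focal CDS string
    cds_alignments: dict  # gene_id -> PromoterAlignment (CDS frame)
    nucleosomes: list  # list[NucleosomeCall]
    truth: TruthTable | None = None

    @property
    def categories(self) -> dict:
        return {g.gene_id: g.category for g in self.genes}

    @property
    def species(self) -> tuple:
        return tuple(sorted({sp for (_, sp) in self.promoter_alignments}))


# --- writing ---------------------------------------------------------------


def _write_fasta(path, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _read_fasta(path) -> dict:
    from Bio import SeqIO

    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_bundle(bundle: CohortBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "alignments" / "promoter").mkdir(parents=True, exist_ok=True)
    (outdir / "alignments" / "cds").mkdir(parents=True, exist_ok=True)

    _write_fasta(outdir / "genome.fa", bundle.genome)

    with open(outdir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in bundle.genes:
            start = g.feature_start + 1
            end = g.feature_end
            fh.write(
                f"{g.chrom}\tregevo\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};category={g.category}\n"
            )
            for s, e in g.cds_intervals:
                fh.write(
                    f"{g.chrom}\tregevo\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"Parent={g.gene_id}\n"
                )

    with open(outdir / "tss.bed", "w") as fh:
        for g in bundle.genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")

    write_pfms(bundle.pfms, outdir / "motifs.pfm")

    with open(outdir / "curation.tsv", "w") as fh:
        fh.write("tf_id\tgene_id\n")
        for tf, gene in sorted(bundle.curation):
            fh.write(f"{tf}\t{gene}\n")

    with open(outdir / "duplicate_pairs.tsv", "w") as fh:
        fh.write("gene_id\tparalog_id\n")
        for a, b in sorted(bundle.duplicate_pairs):
            fh.write(f"{a}\t{b}\n")

    ev_rows = []
    for gid in sorted(bundle.evidence):
        ev = bundle.evidence[gid]
        ev_rows.append(
            {
                "gene_id": ev.gene_id,
                "has_cross_species_blast_hit": int(ev.has_cross_species_blast_hit),
                "has_self_hit": int(ev.has_self_hit),
                "expressed": int(ev.expressed),
                "in_ygob_or_orthomcl": int(ev.in_ygob_or_orthomcl),
                "max_identity_vs_six_species": ev.max_identity_vs_six_species,
                "has_paralog": int(ev.has_paralog),
                "ortholog_in_all_six": int(ev.ortholog_in_all_six),
            }
        )
    pd.DataFrame(ev_rows).to_csv(outdir / "homology.tsv", sep="\t", index=False)

    for (gid, sp), aln in sorted(bundle.promoter_alignments.items()):
        write_pairwise_fasta(
            outdir / "alignments" / "promoter" / f"{gid}__{sp}.afa",
            f"{gid}|focal", aln.focal_row, f"{gid}|{sp}", aln.outgroup_row,
        )
    for gid, aln in sorted(bundle.cds_alignments.items()):
        write_pairwise_fasta(
            outdir / "alignments" / "cds" / f"{gid}__{aln.species}.afa",
            f"{gid}|focal", aln.focal_row, f"{gid}|{aln.species}", aln.outgroup_row,
        )
    if bundle.cds_seqs:
        _write_fasta(outdir / "cds.fa", dict(sorted(bundle.cds_seqs.items())))

    write_nucleosome_bed(bundle.nucleosomes, outdir / "nucleosomes.bed")

    if bundle.truth is not None:
        bundle.truth.to_json(outdir / "truth.json")
    if bundle.config is not None:
        import yaml

        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=True)


# --- reading ---------------------------------------------------------------


def _read_genes(outdir: Path) -> list:
    tss_by_gene = {}
    strand_by_gene = {}
    with open(outdir / "tss.bed") as fh:
        for line in fh:
            chrom, start, _end, name, _score, strand = line.split("\t")[:6]
            tss_by_gene[name] = int(start)
            strand_by_gene[name] = strand.strip()
    genes: dict[str, GeneRecord] = {}
    with open(outdir / "genes.gff3") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = fields["ID"]
                genes[gid] = GeneRecord(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    tss=tss_by_gene[gid],
                    cds_intervals=[],
                    category=fields.get("category", "other"),
                )
            elif ftype == "CDS":
                gid = fields["Parent"]
                genes[gid].cds_intervals.append((int(start) - 1, int(end)))
    return list(genes.values())


def read_bundle(outdir) -> CohortBundle:
    outdir = Path(outdir)
    genome = _read_fasta(outdir / "genome.fa")
    genes = _read_genes(outdir)

    ev = pd.read_csv(outdir / "homology.tsv", sep="\t")
    evidence = {
        r.gene_id: HomologyEvidence(
            gene_id=r.gene_id,
            has_cross_species_blast_hit=bool(r.has_cross_species_blast_hit),
            has_self_hit=bool(r.has_self_hit),
            expressed=bool(r.expressed),
            in_ygob_or_orthomcl=bool(r.in_ygob_or_orthomcl),
            max_identity_vs_six_species=float(r.max_identity_vs_six_species),
            has_paralog=bool(r.has_paralog),
            ortholog_in_all_six=bool(r.ortholog_in_all_six),
        )
        for r in ev.itertuples()
    }

    dup = pd.read_csv(outdir / "duplicate_pairs.tsv", sep="\t")
    duplicate_pairs = [(r.gene_id, r.paralog_id) for r in dup.itertuples()]

    cur = pd.read_csv(outdir / "curation.tsv", sep="\t")
    curation = {(r.tf_id, r.gene_id) for r in cur.itertuples()}

    promoter_alignments = {}
    for path in sorted((outdir / "alignments" / "promoter").glob("*.afa")):
        gid, sp = path.stem.split("__")
        _, frow, _, orow = read_pairwise_fasta(path)
        promoter_alignments[(gid, sp)] = PromoterAlignment(gid, sp, frow, orow)

    cds_alignments = {}
    cds_dir = outdir / "alignments" / "cds"
    if cds_dir.exists():
        for path in sorted(cds_dir.glob("*.afa")):
            gid, sp = path.stem.split("__")
            _, frow, _, orow = read_pairwise_fasta(path)
            cds_alignments[gid] = PromoterAlignment(gid, sp, frow, orow)

    cds_seqs = _read_fasta(outdir / "cds.fa") if (outdir / "cds.fa").exists() else {}

    truth = None
    if (outdir / "truth.json").exists():
        truth = TruthTable.from_json(outdir / "truth.json")
    config = None
    if (outdir / "config.yaml").exists():
        import yaml

        with open(outdir / "config.yaml") as fh:
            config = SimulationConfig.from_dict(yaml.safe_load(fh))

    return CohortBundle(
        config=config,
        genome=genome,
        genes=genes,
        evidence=evidence,
        duplicate_pairs=duplicate_pairs,
        pfms=read_pfms(outdir / "motifs.pfm"),
        curation=curation,
        promoter_alignments=promoter_alignments,
        cds_seqs=cds_seqs,
        cds_alignments=cds_alignments,
        nucleosomes=read_nucleosome_bed(outdir / "nucleosomes.bed"),
        truth=truth,
    )


def bundle_checksums(outdir) -> dict:
    """SHA-256 of every file in a written bundle, keyed by relative path."""
    outdir = Path(outdir)
    sums = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file():
            sums[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return sums
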