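"""Gene origin classification and promoter extraction/filtering.

Genes are classified by origin from precomputed homology evidence into
species-specific de novo genes (no cross-species protein hits, expressed, no
paralog), duplicated new genes (same but with a paralog), orthologous genes
(orthologs in all six comparison species), or other.  Promoters are the
intergenic regions (at most 1000 bp) upstream of the TSS, and three
eligibility filters are applied before any downstream analysis:

(a) promoters shorter than 100 bp;
(b) head-to-head gene pairs whose 250 bp core promoters overlap;
(c) promoters whose pairwise alignment to the first outgroup species has a
    gap rate greater than 50% (strictly greater: a rate of exactly 0.5 is
    retained), or no alignment at all.

Coordinates are 0-based half-open internally; TSS-relative positions use -1
for the first base upstream of the TSS (there is no position 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .alignment import PromoterAlignment, gap_rate

CATEGORIES = ("de_novo", "duplicated_new", "orthologous", "other")

MAX_PROMOTER = 1000
MIN_PROMOTER = 100
CORE_PROMOTER = 250
MAX_GAP_RATE = 0.5
MAX_ORTHOLOG_IDENTITY = 0.70


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int  # 0-based genomic coordinate of the TSS base
    cds_intervals: list[tuple[int, int]]  # 0-based half-open
    category: str = "other"

    @property
    def feature_start(self) -> int:
        return min(s for s, _ in self.cds_intervals)

    @property
    def feature_end(self) -> int:
        return max(e for _, e in self.cds_intervals)


@dataclass
class HomologyEvidence:
    """Precomputed homology/expression evidence consumed, not recomputed."""

    gene_id: str
    has_cross_species_blast_hit: bool | None = None
    has_self_hit: bool | None = None
    expressed: bool | None = None
    in_ygob_or_orthomcl: bool | None = None
    max_identity_vs_six_species: float | None = None
    has_paralog: bool | None = None
    ortholog_in_all_six: bool | None = None


@dataclass
class Promoter:
    """Promoter sequence reading 5'->3' toward the TSS.

    ``interval`` is genomic (0-based half-open); for minus-strand genes the
    sequence is the reverse complement of the genomic slice.  Promoter-local
    index ``i`` corresponds to TSS-relative position ``i - length``.
    """

    gene_id: str
    chrom: str
    strand: str
    interval: tuple[int, int]
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def tss_relative(self, local_index: int) -> int:
        return local_index - self.length


def classify_origin(evidence: HomologyEvidence) -> str:
    """Assign exactly one origin category from homology evidence.

    A species-specific new gene has no cross-species BLASTP hit, at least one
    self hit, expression evidence, no curated homolog, and <=70% nucleotide
    identity to each of the six comparison species; it is de novo without a
    paralog and duplicated-new with one.  Non-new genes with orthologs in all
    six species are orthologous; everything else is other.
    """
    required = (
        "has_cross_species_blast_hit",
        "has_self_hit",
        "expressed",
        "in_ygob_or_orthomcl",
        "max_identity_vs_six_species",
        "has_paralog",
        "ortholog_in_all_six",
    )
    missing = [f for f in required if getattr(evidence, f) is None]
    if missing:
        raise ValueError(
            f"incomplete homology evidence for {evidence.gene_id}: "
            f"missing {', '.join(missing)}"
        )
    is_new = (
        not evidence.has_cross_species_blast_hit
        and evidence.has_self_hit
        and evidence.expressed
        and not evidence.in_ygob_or_orthomcl
        and evidence.max_identity_vs_six_species <= MAX_ORTHOLOG_IDENTITY
    )
    if is_new:
        return "duplicated_new" if evidence.has_paralog else "de_novo"
    if evidence.ortholog_in_all_six:
        return "orthologous"
    return "other"


def extract_promoter(
    gene: GeneRecord,
    genome: Mapping[str, str],
    neighbors: Sequence[GeneRecord],
    max_length: int = MAX_PROMOTER,
) -> Promoter:
    """Intergenic region (<= ``max_length`` bp) upstream of the TSS.

    The promoter runs from the TSS upstream to the nearest annotated gene
    feature boundary on either strand (or the chromosome edge), capped at
    ``max_length``.  Minus-strand promoters are reverse-complemented so the
    returned sequence reads 5'->3' toward the TSS.
    """
    from .motifs import reverse_complement

    chrom_seq = genome[gene.chrom]
    others = [n for n in neighbors if n.gene_id != gene.gene_id and n.chrom == gene.chrom]
    if gene.strand == "+":
        lo = gene.tss - max_length
        for n in others:
            if n.feature_end <= gene.tss:
                lo = max(lo, n.feature_end)
        lo = max(lo, 0)
        interval = (lo, gene.tss)
        seq = chrom_seq[lo : gene.tss]
    else:
        start = gene.tss + 1
        hi = start + max_length
        for n in others:
            if n.feature_start >= start:
                hi = min(hi, n.feature_start)
        hi = min(hi, len(chrom_seq))
        interval = (start, max(start, hi))
        seq = reverse_complement(chrom_seq[start:hi]) if hi > start else ""
    return Promoter(gene.gene_id, gene.chrom, gene.strand, interval, seq.upper())


def _core_promoter_interval(gene: GeneRecord) -> tuple[int, int]:
    """Genomic interval of the 250 bp core promoter upstream of the TSS."""
    if gene.strand == "+":
        return (max(0, gene.tss - CORE_PROMOTER), gene.tss)
    return (gene.tss + 1, gene.tss + 1 + CORE_PROMOTER)


def head_to_head_pairs(genes: Sequence[GeneRecord]) -> list[tuple[str, str]]:
    """Opposite-strand gene pairs whose core promoters overlap by >=1 bp."""
    pairs = []
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1 :]:
            if g1.chrom != g2.chrom or g1.strand == g2.strand:
                continue
            a1, b1 = _core_promoter_interval(g1)
            a2, b2 = _core_promoter_interval(g2)
            if max(a1, a2) < min(b1, b2):
                pairs.append((g1.gene_id, g2.gene_id))
    return pairs


def apply_promoter_filters(
    genes: Sequence[GeneRecord],
    promoters: Mapping[str, Promoter],
    alignments: Mapping[str, PromoterAlignment],
) -> tuple[list[str], dict]:
    """Apply the three promoter-eligibility filters in funnel order.

    ``alignments`` maps gene_id to the promoter alignment against the first
    outgroup species; genes with no alignment are removed by filter (c) and
    logged.  Returns (retained gene ids, audit) where the audit records the
    genes removed by each filter and the funnel counts after each step.
    """
    audit: dict = {"input": len(genes), "removed": {}, "funnel": []}
    retained = [g.gene_id for g in genes]
    by_id = {g.gene_id: g for g in genes}

    short = [
        gid for gid in retained
        if gid not in promoters or promoters[gid].length < MIN_PROMOTER
    ]
    retained = [gid for gid in retained if gid not in set(short)]
    audit["removed"]["short_promoter"] = sorted(short)
    audit["funnel"].append(("short_promoter", len(retained)))

    pairs = head_to_head_pairs([by_id[gid] for gid in retained])
    shared = sorted({gid for pair in pairs for gid in pair})
    retained = [gid for gid in retained if gid not in set(shared)]
    audit["removed"]["shared_core_promoter"] = shared
    audit["funnel"].append(("shared_core_promoter", len(retained)))

    poor = []
    for gid in retained:
        aln = alignments.get(gid)
        if aln is None:
            poor.append(gid)
        elif gap_rate(aln) > MAX_GAP_RATE:
            poor.append(gid)
    retained = [gid for gid in retained if gid not in set(poor)]
    audit["removed"]["poor_alignment"] = sorted(poor)
    audit["funnel"].append(("poor_alignment", len(retained)))

    return retained, audit
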