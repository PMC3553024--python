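"""Promoter nucleosome architecture: OPN vs DPN classification.

From a genome-wide map of positioned nucleosomes with occupancy, promoters
are classified by the presence of a well-occupied nucleosome (occupancy
strictly above 50%) in two TSS-relative windows: the TSS-proximal region
[-100, -1] and the TSS-distal region [-400, -301].  Genes with a proximal
but no distal nucleosome are OPN (occupied proximal nucleosome); genes with
a distal but no proximal nucleosome are DPN (depleted proximal nucleosome);
every other combination is unclassified.  A nucleosome counts as inside a
region when its midpoint falls there after strand-aware conversion to
TSS-relative coordinates (an any-overlap rule is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .catalog import GeneRecord

PROXIMAL_REGION = (-100, -1)
DISTAL_REGION = (-400, -301)
MIN_OCCUPANCY = 0.5
MIN_PROMOTER_FOR_DISTAL = 400


@dataclass
class NucleosomeCall:
    chrom: str
    start: int  # 0-based half-open genomic interval
    end: int
    occupancy: float  # fraction in [0, 1]

    def __post_init__(self) -> None:
        if not 0 <= self.occupancy <= 1:
            raise ValueError("occupancy must lie in [0, 1]")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PromoterArchitecture:
    gene_id: str
    proximal_occupied: bool
    distal_occupied: bool
    label: str  # OPN | DPN | unclassified
    tata_containing: bool | None = None


def tss_relative_position(gene: GeneRecord, genomic: int) -> int:
    """Strand-aware TSS-relative coordinate (no position 0).

    -1 is the first base upstream of the TSS; +1 is the TSS base itself.
    """
    if gene.strand == "+":
        delta = genomic - gene.tss
    else:
        delta = gene.tss - genomic
    return delta if delta < 0 else delta + 1


def region_occupied(
    calls: Sequence[NucleosomeCall],
    gene: GeneRecord,
    region: tuple[int, int],
    min_occupancy: float = MIN_OCCUPANCY,
    rule: str = "midpoint",
) -> bool:
    """True iff a nucleosome with occupancy > ``min_occupancy`` lies in region.

    ``region`` is a closed TSS-relative interval.  With the default
    ``midpoint`` rule a nucleosome is in the region iff its midpoint maps
    there; ``overlap`` accepts any overlap of the nucleosome span.
    """
    lo, hi = min(region), max(region)
    for call in calls:
        if call.chrom != gene.chrom or call.occupancy <= min_occupancy:
            continue
        if rule == "midpoint":
            rel = tss_relative_position(gene, call.midpoint)
            if lo <= rel <= hi:
                return True
        elif rule == "overlap":
            rels = sorted(
                (
                    tss_relative_position(gene, call.start),
                    tss_relative_position(gene, call.end - 1),
                )
            )
            if rels[0] <= hi and rels[1] >= lo:
                return True
        else:
            raise ValueError(f"unknown rule {rule!r}")
    return False


def classify_architecture(
    gene: GeneRecord,
    calls: Sequence[NucleosomeCall],
    promoter_length: int | None = None,
    min_occupancy: float = MIN_OCCUPANCY,
    rule: str = "midpoint",
) -> PromoterArchitecture:
    """OPN/DPN/unclassified label for one gene.

    Promoters shorter than 400 bp have no distal region and are always
    unclassified.
    """
    if promoter_length is not None and promoter_length < MIN_PROMOTER_FOR_DISTAL:
        return PromoterArchitecture(gene.gene_id, False, False, "unclassified")
    proximal = region_occupied(calls, gene, PROXIMAL_REGION, min_occupancy, rule)
    distal = region_occupied(calls, gene, DISTAL_REGION, min_occupancy, rule)
    if proximal and not distal:
        label = "OPN"
    elif distal and not proximal:
        label = "DPN"
    else:
        label = "unclassified"
    return PromoterArchitecture(gene.gene_id, proximal, distal, label)


def classify_cohort(
    genes: Sequence[GeneRecord],
    calls: Sequence[NucleosomeCall],
    promoter_lengths: Mapping[str, int] | None = None,
    min_occupancy: float = MIN_OCCUPANCY,
) -> list[PromoterArchitecture]:
    """Midpoint-rule OPN/DPN classification for a whole cohort.

    Equivalent to calling :func:`classify_architecture` per gene, but uses
    sorted per-chromosome midpoint arrays (binary search per region), which
    matters for large cohorts.
    """
    import numpy as np

    mids_by_chrom: dict[str, "np.ndarray"] = {}
    for chrom in {c.chrom for c in calls}:
        mids = np.sort(
            np.array(
                [c.midpoint for c in calls if c.chrom == chrom and c.occupancy > min_occupancy]
            )
        )
        mids_by_chrom[chrom] = mids

    def occupied(gene: GeneRecord, region: tuple[int, int]) -> bool:
        mids = mids_by_chrom.get(gene.chrom)
        if mids is None or len(mids) == 0:
            return False
        lo, hi = min(region), max(region)
        # genomic span whose TSS-relative midpoints fall in [lo, hi]
        if gene.strand == "+":
            g_lo, g_hi = gene.tss + lo, gene.tss + hi
        else:
            g_lo, g_hi = gene.tss - hi, gene.tss - lo
        i = np.searchsorted(mids, g_lo, side="left")
        j = np.searchsorted(mids, g_hi, side="right")
        return j > i

    out = []
    for gene in genes:
        plen = None if promoter_lengths is None else promoter_lengths.get(gene.gene_id)
        if plen is not None and plen < MIN_PROMOTER_FOR_DISTAL:
            out.append(PromoterArchitecture(gene.gene_id, False, False, "unclassified"))
            continue
        proximal = occupied(gene, PROXIMAL_REGION)
        distal = occupied(gene, DISTAL_REGION)
        if proximal and not distal:
            label = "OPN"
        elif distal and not proximal:
            label = "DPN"
        else:
            label = "unclassified"
        out.append(PromoterArchitecture(gene.gene_id, proximal, distal, label))
    return out


def architecture_summary(
    architectures: Iterable[PromoterArchitecture],
    categories: Mapping[str, str],
):
    """Per-group OPN/DPN and TATA proportions.

    Unclassified genes are excluded from the OPN/DPN denominator but counted
    in the audit column; the TATA denominator is all genes in the group.
    """
    import pandas as pd

    rows = [
        {
            "gene_id": a.gene_id,
            "category": categories.get(a.gene_id, "other"),
            "label": a.label,
            "tata": bool(a.tata_containing),
        }
        for a in architectures
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no architectures to summarize")
    out = []
    for cat, sub in df.groupby("category"):
        n_opn = int((sub.label == "OPN").sum())
        n_dpn = int((sub.label == "DPN").sum())
        classified = n_opn + n_dpn
        out.append(
            {
                "category": cat,
                "n_genes": len(sub),
                "n_opn": n_opn,
                "n_dpn": n_dpn,
                "n_unclassified": int((sub.label == "unclassified").sum()),
                "dpn_proportion": n_dpn / classified if classified else float("nan"),
                "opn_proportion": n_opn / classified if classified else float("nan"),
                "n_tata": int(sub.tata.sum()),
                "tata_proportion": float(sub.tata.mean()),
            }
        )
    return pd.DataFrame(out).set_index("category")


def read_nucleosome_bed(path) -> list[NucleosomeCall]:
    """Read a BED6 nucleosome map; score column = occupancy x 1000."""
    import pandas as pd

    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return [
        NucleosomeCall(r.chrom, int(r.start), int(r.end), float(r.score) / 1000.0)
        for r in df.itertuples()
    ]


def write_nucleosome_bed(calls: Sequence[NucleosomeCall], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            score = int(round(c.occupancy * 1000))
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tnuc{i:05d}\t{score}\t.\n")
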