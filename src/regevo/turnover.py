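"""Gained vs preexisting TFBS classification against two outgroup species.

Each curated TFBS in the focal promoter is projected through the pairwise
alignment into each outgroup species; the aligned interval extended by 25 bp
on each side (the "corresponding region") is rescanned with the same PWM and
p-value threshold on both strands.  A TFBS is preexisting when at least one
outgroup corresponding region contains a threshold-passing occurrence of the
motif, gained when neither does, and unclassifiable when no corresponding
region can be located in either species.  Losses are not modeled: a de novo
gene has no ancestral gene in which a site could have been lost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment import PromoterAlignment, insertion_point, project_interval
from .motifs import MotifHit, PwmScanner

FLANK = 25


@dataclass
class CorrespondingRegion:
    """Outgroup interval aligned to a focal TFBS, extended by the flank."""

    species: str
    interval: tuple[int, int]  # outgroup promoter coordinates, clipped
    sequence: str

    @property
    def is_empty(self) -> bool:
        return self.interval[1] <= self.interval[0]


def corresponding_region(
    alignment: PromoterAlignment,
    focal_interval: tuple[int, int],
    flank: int = FLANK,
) -> CorrespondingRegion | None:
    """Project a focal interval and extend it ±``flank`` bp in the outgroup.

    For intervals aligned entirely to outgroup gaps the region is centered on
    the insertion point between the flanking aligned columns.  Returns None
    when no outgroup anchor exists at all (fully unalignable).
    """
    projected = project_interval(alignment, focal_interval)
    if projected is None:
        point = insertion_point(alignment, focal_interval)
        if point is None:
            return None
        projected = (point, point)
    out_len = len(alignment.outgroup_seq)
    lo = max(0, projected[0] - flank)
    hi = min(out_len, projected[1] + flank)
    return CorrespondingRegion(
        species=alignment.species,
        interval=(lo, hi),
        sequence=alignment.outgroup_seq[lo:hi],
    )


def classify_turnover(
    hit: MotifHit,
    regions: Sequence[CorrespondingRegion | None],
    scanner: PwmScanner,
) -> str:
    """Label one hit as gained / preexisting / unclassifiable.

    ``regions`` holds one corresponding region per outgroup species (None when
    the projection failed entirely).  The occurrence criterion in outgroups is
    the same p-value threshold used in the focal scan, applied on both strands.
    """
    if scanner.pwm.tf_id != hit.tf_id:
        raise ValueError(
            f"scanner PWM {scanner.pwm.tf_id} does not match hit TF {hit.tf_id}"
        )
    usable = [r for r in regions if r is not None and not r.is_empty]
    if not usable:
        return "unclassifiable"
    for region in usable:
        if scanner.has_passing_window(region.sequence):
            return "preexisting"
    return "gained"


def classify_hits(
    hits: Iterable[MotifHit],
    alignments: Mapping[tuple[str, str], PromoterAlignment],
    scanners: Mapping[str, PwmScanner],
    species: Sequence[str],
    promoter_lengths: Mapping[str, int],
    flank: int = FLANK,
) -> list[MotifHit]:
    """Classify every curated hit in place; returns the same hit objects.

    ``alignments`` maps (gene_id, species) to the promoter alignment in
    promoter-local coordinates (focal row ungapped sequence == promoter
    sequence).  Hits whose gene lacks all alignments are unclassifiable.
    """
    hits = list(hits)
    for hit in hits:
        scanner = scanners[hit.tf_id]
        width = scanner.pwm.width
        local = hit.local_start(promoter_lengths[hit.gene_id])
        regions = []
        for sp in species:
            aln = alignments.get((hit.gene_id, sp))
            if aln is None:
                regions.append(None)
                continue
            regions.append(corresponding_region(aln, (local, local + width), flank))
        hit.turnover_label = classify_turnover(hit, regions, scanner)
    return hits


def turnover_summary(hits: Iterable[MotifHit], categories: Mapping[str, str]):
    """Per-gene gained fractions and per-group pooled proportions.

    Unclassifiable hits are excluded from all denominators and reported in the
    audit columns.  Returns (per_gene, per_group) DataFrames; genes with zero
    classified hits are excluded from per-gene statistics.
    """
    import pandas as pd

    rows = []
    for hit in hits:
        rows.append((hit.gene_id, hit.turnover_label))
    df = pd.DataFrame(rows, columns=["gene_id", "label"])
    if df.empty:
        raise ValueError("no labeled hits to summarize")

    per_gene = (
        df.assign(
            gained=lambda d: d.label == "gained",
            preexisting=lambda d: d.label == "preexisting",
            unclassifiable=lambda d: d.label == "unclassifiable",
        )
        .groupby("gene_id")[["gained", "preexisting", "unclassifiable"]]
        .sum()
    )
    per_gene["classified"] = per_gene.gained + per_gene.preexisting
    per_gene = per_gene[per_gene.classified > 0].copy()
    per_gene["gained_fraction"] = per_gene.gained / per_gene.classified
    per_gene["category"] = [categories.get(g, "other") for g in per_gene.index]

    grouped = per_gene.groupby("category")[["gained", "preexisting", "unclassifiable"]].sum()
    grouped["classified"] = grouped.gained + grouped.preexisting
    grouped["pooled_gained_fraction"] = grouped.gained / grouped.classified
    grouped["pooled_preexisting_fraction"] = grouped.preexisting / grouped.classified
    return per_gene, grouped
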