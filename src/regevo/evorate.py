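"""Promoter substitution rates and the four-fold degenerate neutral reference.

The promoter evolution rate is the raw p-distance of the focal/outgroup
pairwise alignment: mismatching non-gap columns over all non-gap columns,
ignoring indels entirely (no multiple-hit correction by default; a JC69
option is provided).  The neutral reference is the pooled substitution rate
at four-fold degenerate third-codon positions — sites where any base encodes
the same amino acid, so substitutions there are (to first order) invisible
to protein-level selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .alignment import PromoterAlignment

AMBIGUOUS = set("NRYSWKMBDHV")


@dataclass
class SubstitutionRateResult:
    gene_id: str
    aligned_columns: int  # non-gap, unambiguous columns counted
    mismatches: int
    rate: float
    skipped_ambiguous: int = 0

    def jc69(self) -> float:
        """Jukes-Cantor corrected distance (optional, off by default)."""
        if self.rate >= 0.75:
            return math.inf
        return -0.75 * math.log(1 - 4 * self.rate / 3)


def _column_classes(row1: str, row2: str) -> tuple[int, int, int]:
    """(usable columns, mismatches, ambiguous-skipped) over non-gap columns."""
    usable = mism = ambig = 0
    for a, b in zip(row1.upper(), row2.upper()):
        if a == "-" or b == "-":
            continue
        if a in AMBIGUOUS or b in AMBIGUOUS:
            ambig += 1
            continue
        usable += 1
        if a != b:
            mism += 1
    return usable, mism, ambig


def p_distance(alignment: PromoterAlignment) -> SubstitutionRateResult:
    """Proportion of mismatching non-gap columns (case-insensitive).

    Columns with a gap in either row are skipped; ambiguous bases (N etc.)
    are skipped and counted in the audit.  Zero usable columns is an error:
    such genes are excluded downstream.
    """
    usable, mism, ambig = _column_classes(alignment.focal_row, alignment.outgroup_row)
    if usable == 0:
        raise ValueError(f"{alignment.gene_id}: no usable non-gap columns")
    return SubstitutionRateResult(
        gene_id=alignment.gene_id,
        aligned_columns=usable,
        mismatches=mism,
        rate=mism / usable,
        skipped_ambiguous=ambig,
    )


@dataclass
class FourfoldSiteSet:
    """Third positions of four-fold degenerate codons, CDS-local (0-based)."""

    gene_id: str
    sites: list[int]


def _fourfold_prefixes(table=standard_dna_table) -> frozenset[str]:
    """Codon prefixes whose four completions encode one amino acid."""
    prefixes = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = set()
            ok = True
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                if codon in table.stop_codons:
                    ok = False
                    break
                aas.add(table.forward_table[codon])
            if ok and len(aas) == 1:
                prefixes.add(b1 + b2)
    return frozenset(prefixes)


FOURFOLD_PREFIXES = _fourfold_prefixes()


def find_fourfold_sites(gene_id: str, cds: str) -> FourfoldSiteSet:
    """Four-fold degenerate third-codon positions of a focal CDS.

    Degeneracy is judged on the focal codon only, under the standard nuclear
    code.  Internal stop codons are skipped with a warning; the terminal stop
    (if present) is skipped silently.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"{gene_id}: CDS length {len(cds)} not divisible by 3")
    sites = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in standard_dna_table.stop_codons:
            if i < n_codons - 1:
                warnings.warn(f"{gene_id}: internal stop codon at codon {i}, skipped")
            continue
        if any(c in AMBIGUOUS for c in codon):
            continue
        if codon[:2] in FOURFOLD_PREFIXES:
            sites.append(3 * i + 2)
    return FourfoldSiteSet(gene_id, sites)


def neutral_rate(
    cds_alignments: Iterable[PromoterAlignment],
    site_sets: Mapping[str, FourfoldSiteSet],
) -> tuple[float, int, int]:
    """Pooled substitution rate at four-fold sites across genes.

    Sites are taken in focal CDS coordinates, restricted to alignment columns
    that are non-gap in both rows and unambiguous in both.  Returns
    (rate, mismatches, counted sites).
    """
    total = mism = 0
    for aln in cds_alignments:
        sites = site_sets.get(aln.gene_id)
        if sites is None:
            continue
        focal = aln.focal_row.upper()
        out = aln.outgroup_row.upper()
        col_of_focal = aln.column_of_focal
        out_nongap = aln._outgroup_nongap
        for pos in sites.sites:
            col = col_of_focal[pos]
            if not out_nongap[col]:
                continue
            a, b = focal[col], out[col]
            if a in AMBIGUOUS or b in AMBIGUOUS:
                continue
            total += 1
            if a != b:
                mism += 1
    if total == 0:
        raise ValueError("no usable four-fold degenerate sites")
    return mism / total, mism, total


def rate_table(results: Iterable[SubstitutionRateResult], categories: Mapping[str, str]):
    """Per-gene rate DataFrame with origin categories attached."""
    import pandas as pd

    rows = [
        {
            "gene_id": r.gene_id,
            "aligned_columns": r.aligned_columns,
            "mismatches": r.mismatches,
            "rate": r.rate,
            "category": categories.get(r.gene_id, "other"),
        }
        for r in results
    ]
    return pd.DataFrame(rows).set_index("gene_id")
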