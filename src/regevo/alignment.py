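"""Gapped pairwise promoter/CDS alignments and coordinate projection.

Alignments are two equal-length gapped rows, focal species first.  All
coordinates are ungapped positions within each row's own sequence (0-based,
half-open intervals).  Projection maps a focal interval to the minimal
outgroup interval spanning every outgroup base aligned to it; intervals that
fall entirely in outgroup gaps project to an insertion point instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

GAP = "-"


@dataclass
class PromoterAlignment:
    """Pairwise gapped alignment of a focal promoter to one outgroup species."""

    gene_id: str
    species: str
    focal_row: str
    outgroup_row: str

    def __post_init__(self) -> None:
        if len(self.focal_row) != len(self.outgroup_row):
            raise ValueError("alignment rows must have equal length")
        if len(self.focal_row) == 0:
            raise ValueError("alignment must have at least one column")

    @property
    def n_columns(self) -> int:
        return len(self.focal_row)

    @cached_property
    def focal_seq(self) -> str:
        return self.focal_row.replace(GAP, "")

    @cached_property
    def outgroup_seq(self) -> str:
        return self.outgroup_row.replace(GAP, "")

    @cached_property
    def _focal_nongap(self) -> np.ndarray:
        return np.frombuffer(self.focal_row.encode(), dtype=np.uint8) != ord(GAP)

    @cached_property
    def _outgroup_nongap(self) -> np.ndarray:
        return np.frombuffer(self.outgroup_row.encode(), dtype=np.uint8) != ord(GAP)

    @cached_property
    def focal_offsets(self) -> np.ndarray:
        """Per-column focal ungapped position, -1 at focal gaps."""
        off = np.cumsum(self._focal_nongap) - 1
        return np.where(self._focal_nongap, off, -1)

    @cached_property
    def outgroup_offsets(self) -> np.ndarray:
        off = np.cumsum(self._outgroup_nongap) - 1
        return np.where(self._outgroup_nongap, off, -1)

    @cached_property
    def column_of_focal(self) -> np.ndarray:
        """Alignment column of each focal position."""
        return np.nonzero(self._focal_nongap)[0]

    @cached_property
    def column_of_outgroup(self) -> np.ndarray:
        return np.nonzero(self._outgroup_nongap)[0]


def gap_rate(alignment: PromoterAlignment) -> float:
    """Fraction of alignment columns with a gap in either row."""
    if alignment.n_columns == 0:
        raise ValueError("alignment has zero columns")
    gappy = ~(alignment._focal_nongap & alignment._outgroup_nongap)
    return float(gappy.sum()) / alignment.n_columns


def project_interval(
    alignment: PromoterAlignment, focal_interval: tuple[int, int]
) -> tuple[int, int] | None:
    """Project a focal [start, end) interval to outgroup coordinates.

    Returns the minimal outgroup interval covering all outgroup positions
    aligned to the focal interval's columns, or None when every such column
    is an outgroup gap.
    """
    start, end = focal_interval
    n_focal = len(alignment.focal_seq)
    if start < 0 or end > n_focal or start >= end:
        raise ValueError(
            f"focal interval [{start}, {end}) outside alignment span [0, {n_focal})"
        )
    cols = alignment.column_of_focal[start:end]
    outpos = alignment.outgroup_offsets[cols]
    outpos = outpos[outpos >= 0]
    if len(outpos) == 0:
        return None
    return (int(outpos.min()), int(outpos.max()) + 1)


def insertion_point(
    alignment: PromoterAlignment, focal_interval: tuple[int, int]
) -> int | None:
    """Outgroup position between the aligned columns flanking a deleted interval.

    Used when a focal interval projects entirely into outgroup gaps: the
    returned outgroup coordinate is where the deleted material would sit.
    None if the outgroup row has no aligned base on either side.
    """
    start, end = focal_interval
    cols = alignment.column_of_focal[start:end]
    if len(cols) == 0:
        return None
    left_cols = alignment.column_of_outgroup[alignment.column_of_outgroup < cols[0]]
    if len(left_cols):
        return int(alignment.outgroup_offsets[left_cols[-1]]) + 1
    right_cols = alignment.column_of_outgroup[alignment.column_of_outgroup > cols[-1]]
    if len(right_cols):
        return int(alignment.outgroup_offsets[right_cols[0]])
    return None


def read_pairwise_fasta(path) -> tuple[str, str, str, str]:
    """Read a 2-record aligned FASTA (focal first): ids and gapped rows."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned records")
    return (
        records[0].id,
        str(records[0].seq).upper(),
        records[1].id,
        str(records[1].seq).upper(),
    )


def write_pairwise_fasta(path, focal_id, focal_row, outgroup_id, outgroup_row) -> None:
    with open(path, "w") as fh:
        fh.write(f">{focal_id}\n{focal_row}\n>{outgroup_id}\n{outgroup_row}\n")
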