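"""Position weight matrices with exact score distributions and promoter scanning.

A position frequency matrix (PFM) counts observed bases at each position of a
transcription-factor binding motif.  It is converted to a log-odds position
weight matrix (PWM) against a background base composition, and putative binding
sites are windows whose PWM score exceeds the score threshold at which the
probability of a random background word scoring as high falls below a p-value
cutoff (0.001 by default).

The null score distribution is computed exactly by dynamic programming over
per-position scores discretized to a fixed bin width (0.01 bits by default):
the distribution of the sum of independent per-position scores of a random
background-distributed word.  Scanning uses the same discretized matrix, so
window scores, thresholds and per-hit p-values are mutually consistent and the
reported p-values are exact for the discretized score model (conservative to
bin resolution with respect to the continuous one).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

UNIFORM_BACKGROUND = np.full(4, 0.25)

#: Core-promoter TATA element consensus TATA(A/T)A(A/T)(A/G).
TATA_CONSENSUS = ("T", "A", "T", "A", "AT", "A", "AT", "AG")
TATA_REGEX = re.compile("TATA[AT]A[AT][AG]")
#: TSS-relative window (closed, no position 0) searched for the TATA element.
TATA_WINDOW = (-200, -50)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; any other symbol (N, gaps) becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts for one TF motif (rows A, C, G, T)."""

    tf_id: str
    counts: np.ndarray  # shape (width, 4), non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (width, 4)")
        if self.width < 1:
            raise ValueError("PFM width must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError("PFM counts must be non-negative")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError("every PFM column must have a positive total")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=1))


@dataclass
class PositionWeightMatrix:
    """Log-odds matrix (bits) with its background model."""

    tf_id: str
    log_odds: np.ndarray  # shape (width, 4), bits
    background: np.ndarray
    pseudocount: float

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    def quantize(self, bin_width: float) -> np.ndarray:
        """Integer score matrix: log-odds rounded to units of ``bin_width``."""
        return np.rint(self.log_odds / bin_width).astype(np.int64)

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            tf_id=self.tf_id,
            log_odds=self.log_odds[::-1, ::-1].copy(),
            background=self.background,
            pseudocount=self.pseudocount,
        )

    def score(self, word: str) -> float:
        idx = encode_sequence(word)
        if len(idx) != self.width or np.any(idx < 0):
            raise ValueError("word must be ACGT of the PWM width")
        return float(self.log_odds[np.arange(self.width), idx].sum())


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    background: Sequence[float] | None = None,
    pseudocount: float = 1.0,
) -> PositionWeightMatrix:
    """Convert counts to a log-odds PWM in bits.

    ``log2((c[i,b] + pc * bg[b]) / (total_i + pc)) - log2(bg[b])``; the
    pseudocount is distributed proportionally to the background so that the
    matrix stays finite even for zero counts.
    """
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 positive probabilities")
    bg = bg / bg.sum()
    totals = pfm.counts.sum(axis=1, keepdims=True)
    probs = (pfm.counts + pseudocount * bg) / (totals + pseudocount)
    log_odds = np.log2(probs) - np.log2(bg)
    return PositionWeightMatrix(pfm.tf_id, log_odds, bg, pseudocount)


@dataclass
class ScoreDistribution:
    """Exact distribution of the PWM score of a random background word.

    Scores are discretized integers in units of ``bin_width`` bits; the public
    ``scores`` attribute exposes them in bits.
    """

    qscores: np.ndarray  # ascending integers
    probabilities: np.ndarray
    bin_width: float

    @property
    def scores(self) -> np.ndarray:
        return self.qscores * self.bin_width

    def tail(self) -> np.ndarray:
        """P(score >= qscores[i]) for each support value, non-increasing."""
        return np.cumsum(self.probabilities[::-1])[::-1]

    def pvalue(self, qscore: int) -> float:
        """P(score >= qscore) for an arbitrary integer score."""
        tails = self.tail()
        i = np.searchsorted(self.qscores, qscore, side="left")
        if i >= len(self.qscores):
            return 0.0
        return float(tails[i])


def exact_score_distribution(
    pwm: PositionWeightMatrix,
    background: Sequence[float] | None = None,
    bin_width: float = 0.01,
) -> ScoreDistribution:
    """Position-wise convolution of discretized per-position score atoms."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    q = pwm.quantize(bin_width)
    probs = np.ones(1)
    offset = 0
    for i in range(pwm.width):
        lo, hi = int(q[i].min()), int(q[i].max())
        new = np.zeros(len(probs) + (hi - lo))
        for b in range(4):
            shift = int(q[i, b]) - lo
            new[shift : shift + len(probs)] += probs * bg[b]
        probs = new
        offset += lo
    support = offset + np.arange(len(probs))
    keep = probs > 0
    return ScoreDistribution(support[keep], probs[keep], bin_width)


def _threshold_qscore(dist: ScoreDistribution, alpha: float) -> int | None:
    """Minimal discretized score s with P(score >= s) < alpha, or None."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if alpha > 1 - 1e-9:  # no filtering: every word passes
        return int(dist.qscores[0])
    tails = dist.tail()
    idx = np.nonzero(tails < alpha)[0]
    if len(idx) == 0:
        return None
    return int(dist.qscores[idx[0]])


def threshold_for_pvalue(dist: ScoreDistribution, alpha: float) -> float:
    """Score threshold (bits) for the given p-value cutoff.

    Returns ``+inf`` when even the maximal score has tail probability >= alpha
    (no window can ever pass).
    """
    qthr = _threshold_qscore(dist, alpha)
    if qthr is None:
        return math.inf
    return qthr * dist.bin_width


@dataclass
class MotifHit:
    """One PWM match in a promoter.

    ``tss_relative_start`` is the 5'-most promoter position of the matched
    window in TSS-relative coordinates (-1 = first base upstream of the TSS,
    no position 0); for minus-strand hits it still refers to the window start
    on the promoter (sense) strand.
    """

    tf_id: str
    gene_id: str
    tss_relative_start: int
    strand: str  # '+' or '-'
    score: float  # bits
    p_value: float
    curated: bool = False
    turnover_label: str = "not_assessed"

    def local_start(self, promoter_length: int) -> int:
        """Promoter-local (0-based) window start."""
        return self.tss_relative_start + promoter_length


class PwmScanner:
    """Reusable scanner for one PWM: caches the distribution and threshold."""

    def __init__(
        self,
        pwm: PositionWeightMatrix,
        alpha: float = 0.001,
        background: Sequence[float] | None = None,
        bin_width: float = 0.01,
    ) -> None:
        self.pwm = pwm
        self.alpha = alpha
        self.bin_width = bin_width
        self.dist = exact_score_distribution(pwm, background, bin_width)
        self.qthr = _threshold_qscore(self.dist, alpha)
        self.qmat_fwd = pwm.quantize(bin_width)
        self.qmat_rev = pwm.reverse_complement().quantize(bin_width)

    @property
    def threshold(self) -> float:
        return math.inf if self.qthr is None else self.qthr * self.bin_width

    def window_scores(self, encoded: np.ndarray, strand: str) -> np.ndarray:
        """Quantized scores of every window; invalid windows (with N) -> min."""
        w = self.pwm.width
        if len(encoded) < w:
            return np.zeros(0, dtype=np.int64)
        qmat = self.qmat_fwd if strand == "+" else self.qmat_rev
        windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
        valid = np.all(windows >= 0, axis=1)
        safe = np.where(windows >= 0, windows, 0)
        scores = qmat[np.arange(w), safe].sum(axis=1)
        scores[~valid] = np.iinfo(np.int64).min
        return scores

    def passing_starts(self, seq: str) -> list[tuple[int, str, int]]:
        """(start, strand, qscore) for every threshold-passing window."""
        if self.qthr is None:
            return []
        encoded = encode_sequence(seq)
        out: list[tuple[int, str, int]] = []
        for strand in "+-":
            scores = self.window_scores(encoded, strand)
            for i in np.nonzero(scores >= self.qthr)[0]:
                out.append((int(i), strand, int(scores[i])))
        out.sort(key=lambda t: (t[0], t[1]))
        return out

    def has_passing_window(self, seq: str) -> bool:
        if self.qthr is None:
            return False
        encoded = encode_sequence(seq)
        for strand in "+-":
            scores = self.window_scores(encoded, strand)
            if len(scores) and scores.max() >= self.qthr:
                return True
        return False


def scan_promoter(
    pwm_or_scanner: PositionWeightMatrix | PwmScanner,
    promoter,
    alpha: float = 0.001,
    background: Sequence[float] | None = None,
    bin_width: float = 0.01,
) -> list[MotifHit]:
    """Scan both strands of a promoter; hits sorted by position.

    ``promoter`` needs ``sequence``, ``length`` and ``gene_id`` attributes
    (see :class:`regevo.catalog.Promoter`).  Windows containing ambiguous
    bases are skipped.
    """
    if isinstance(pwm_or_scanner, PwmScanner):
        scanner = pwm_or_scanner
    else:
        scanner = PwmScanner(pwm_or_scanner, alpha, background, bin_width)
    length = promoter.length
    hits = []
    for start, strand, qscore in scanner.passing_starts(promoter.sequence):
        hits.append(
            MotifHit(
                tf_id=scanner.pwm.tf_id,
                gene_id=promoter.gene_id,
                tss_relative_start=start - length,
                strand=strand,
                score=qscore * scanner.bin_width,
                p_value=scanner.dist.pvalue(qscore),
            )
        )
    return hits


def filter_by_curation(
    hits: Iterable[MotifHit], associations: set[tuple[str, str]]
) -> list[MotifHit]:
    """Keep only hits whose (tf_id, gene_id) pair is a curated association."""
    curated = []
    for hit in hits:
        if (hit.tf_id, hit.gene_id) in associations:
            hit.curated = True
            curated.append(hit)
    return curated


def summarize_regulation(hits: Iterable[MotifHit], gene_ids: Sequence[str]):
    """Per-gene distinct-TF and TFBS counts from curated hits.

    Returns a pandas DataFrame indexed by gene_id with columns n_tfs, n_tfbs;
    genes without hits get zeros.
    """
    import pandas as pd

    tfs: dict[str, set[str]] = {g: set() for g in gene_ids}
    counts: dict[str, int] = {g: 0 for g in gene_ids}
    for hit in hits:
        if hit.gene_id in counts:
            tfs[hit.gene_id].add(hit.tf_id)
            counts[hit.gene_id] += 1
    return pd.DataFrame(
        {
            "n_tfs": [len(tfs[g]) for g in gene_ids],
            "n_tfbs": [counts[g] for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def find_tata(
    promoter, window: tuple[int, int] = TATA_WINDOW
) -> tuple[bool, list[int]]:
    """Detect the TATA consensus TATA(A/T)A(A/T)(A/G) on the sense strand.

    A promoter is TATA-containing iff at least one consensus 8-mer *starts*
    at a TSS-relative position inside the closed ``window`` (default
    [-200, -50]).  Returns the flag and all matching start positions
    (TSS-relative, window-restricted).
    """
    length = promoter.length
    seq = promoter.sequence.upper()
    lo, hi = min(window), max(window)
    positions = _all_tata_starts(seq, length, lo, hi)
    return (len(positions) > 0, positions)


def _all_tata_starts(seq: str, length: int, lo: int, hi: int) -> list[int]:
    """All (possibly overlapping) consensus match starts in the window."""
    out = []
    for i in range(len(seq) - 7):
        rel = i - length
        if rel < lo or rel > hi:
            continue
        word = seq[i : i + 8]
        if all(word[j] in TATA_CONSENSUS[j] for j in range(8)):
            out.append(rel)
    return out


# --- PFM file I/O (JASPAR-style text) -------------------------------------


def write_pfms(pfms: Sequence[PositionFrequencyMatrix], path) -> None:
    """Write matrices as JASPAR-format text (rows A, C, G, T)."""
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.tf_id} {pfm.tf_id}\n")
            for b in range(4):
                row = " ".join(f"{v:.0f}" for v in pfm.counts[:, b])
                fh.write(f"{BASES[b]} [ {row} ]\n")


def read_pfms(path) -> list[PositionFrequencyMatrix]:
    """Read JASPAR-format matrices via Bio.motifs."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float).T
            out.append(PositionFrequencyMatrix(m.matrix_id or m.name, counts))
    return out
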