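"""Synthetic promoter cohorts with planted ground truth.

The generator emits a complete, self-contained fixture set — genome,
annotation, homology evidence, per-gene pairwise promoter and CDS alignments
to two independently evolved outgroup species, a PFM library, a curated
TF→gene association table, and a nucleosome occupancy map — with every
analysis-relevant feature planted under control:

* gene origin categories with homology evidence that decodes back to them;
* motif instances (PWM consensus words) planted at known TSS-relative
  positions, each labeled gained (absent from both outgroup corresponding
  regions) or preexisting (word protected in both outgroups);
* group-specific promoter substitution and indel rates, realised by a
  per-site mutation process that returns the true gapped alignment;
* TATA consensus words planted at a group-specific frequency inside the
  detection window, with accidental consensus matches scrubbed from
  TATA-less promoters;
* OPN/DPN nucleosome architecture planted per gene (well-occupied nucleosome
  in exactly one of the TSS-proximal/TSS-distal windows, plus low-occupancy
  decoys), and a neutral substitution rate planted at four-fold degenerate
  CDS sites.

Genes are laid out head-to-tail on the forward strand of one chromosome so
that promoter extraction recovers exactly the designed promoters; strand
handling elsewhere in the package is exercised by the hand-built toy
fixture (:func:`toy_bundle`) and unit tests.

"gained" labels are enforced by rejection: the outgroup corresponding region
is re-mutated from the focal sequence (at the group's substitution rate)
until no threshold-passing window remains, falling back to shuffling the
region after 100 tries (the only option when the substitution rate is zero).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import PromoterAlignment
from .catalog import GeneRecord, HomologyEvidence, Promoter
from .config import CATEGORIES, ConfigError, SimulationConfig
from .evorate import find_fourfold_sites
from .io import CohortBundle, TruthTable
from .motifs import (
    BASES,
    PositionFrequencyMatrix,
    PwmScanner,
    pfm_to_pwm,
    reverse_complement,
)
from .nucarch import NucleosomeCall
from .turnover import corresponding_region

_NONSTOP_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_sequence(length: int, rng, background=None) -> str:
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    idx = rng.choice(4, size=length, p=bg / bg.sum())
    return "".join(BASES[i] for i in idx)


# --- per-site mutation with true alignment ---------------------------------


def _mutate_segment(seq: str, sub_rate: float, indel_rate: float, rng):
    """(focal_row, outgroup_row) for one unprotected segment."""
    n = len(seq)
    if n == 0:
        return "", ""
    arr = np.array([BASES.index(c) if c in BASES else -1 for c in seq])
    sub_mask = rng.random(n) < sub_rate
    shift = rng.integers(1, 4, n)
    mutated = np.where(sub_mask & (arr >= 0), (arr + shift) % 4, arr)
    mut_chars = [BASES[i] if i >= 0 else seq[j] for j, i in enumerate(mutated)]

    if indel_rate == 0:
        return seq, "".join(mut_chars)

    event = rng.random(n) < indel_rate
    is_insertion = rng.random(n) < 0.5
    lengths = np.minimum(rng.geometric(0.5, n), 3)

    f_parts: list[str] = []
    o_parts: list[str] = []
    prev = 0
    for i in np.nonzero(event)[0]:
        if i < prev:
            continue
        f_parts.append(seq[prev:i])
        o_parts.append("".join(mut_chars[prev:i]))
        ell = int(lengths[i])
        if is_insertion[i]:
            inserted = "".join(BASES[b] for b in rng.integers(0, 4, ell))
            f_parts.append("-" * ell)
            o_parts.append(inserted)
            prev = i
        else:
            ell = min(ell, n - i)
            f_parts.append(seq[i : i + ell])
            o_parts.append("-" * ell)
            prev = i + ell
    f_parts.append(seq[prev:])
    o_parts.append("".join(mut_chars[prev:]))
    return "".join(f_parts), "".join(o_parts)


def mutate_sequence(
    seq: str, sub_rate: float, indel_rate: float, seed
) -> tuple[str, PromoterAlignment]:
    """Mutate a sequence site-wise and return the true gapped alignment.

    Each site is substituted to a uniformly chosen *different* base with
    probability ``sub_rate``; indel events occur per site with probability
    ``indel_rate`` (insertion or deletion equally likely, lengths 1-3 from a
    truncated geometric).  Returns the mutated string and the alignment
    (focal row first).
    """
    if len(seq) == 0:
        raise ValueError("cannot mutate an empty sequence")
    for name, rate in (("sub_rate", sub_rate), ("indel_rate", indel_rate)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must lie in [0, 1)")
    rng = _as_rng(seed)
    frow, orow = _mutate_segment(seq, sub_rate, indel_rate, rng)
    aln = PromoterAlignment("seq", "mutant", frow, orow)
    return aln.outgroup_seq, aln


def mutate_with_protected(
    seq: str,
    protected: Sequence[tuple[int, int]],
    sub_rate: float,
    indel_rate: float,
    rng,
) -> tuple[str, str]:
    """Mutate a sequence leaving the given [start, end) intervals untouched.

    Protected intervals are copied verbatim into the mutant (no substitutions,
    no indels), keeping planted preexisting motif words intact and aligned.
    Returns (focal_row, outgroup_row).
    """
    rng = _as_rng(rng)
    protected = sorted(protected)
    f_parts, o_parts = [], []
    prev = 0
    for start, end in protected:
        if start < prev:
            raise ValueError("protected intervals must be sorted and disjoint")
        frow, orow = _mutate_segment(seq[prev:start], sub_rate, indel_rate, rng)
        f_parts.append(frow)
        o_parts.append(orow)
        f_parts.append(seq[start:end])
        o_parts.append(seq[start:end])
        prev = end
    frow, orow = _mutate_segment(seq[prev:], sub_rate, indel_rate, rng)
    f_parts.append(frow)
    o_parts.append(orow)
    return "".join(f_parts), "".join(o_parts)


# --- TATA planting ----------------------------------------------------------


def plant_tata(
    promoter: str, window: tuple[int, int] = (-200, -50), seed=None
) -> tuple[str, int]:
    """Insert one consensus TATA(A/T)A(A/T)(A/G) word into the window.

    The word start is uniform over TSS-relative positions at which the whole
    8-mer fits inside the (closed) window.  Returns the modified promoter and
    the planted TSS-relative start.
    """
    rng = _as_rng(seed)
    length = len(promoter)
    lo, hi = min(window), max(window)
    if hi - lo + 1 < 8:
        raise ValueError("TATA window shorter than 8 bp")
    if lo < -length or hi > -1:
        raise ValueError("TATA window must lie inside the promoter")
    rel = int(rng.integers(lo, hi - 7 + 1))
    word = "TATA" + rng.choice(list("AT")) + "A" + rng.choice(list("AT")) + rng.choice(list("AG"))
    local = rel + length
    return promoter[:local] + word + promoter[local + 8 :], rel


def _scrub_tata(promoter: str, window: tuple[int, int] = (-200, -50)) -> str:
    """Destroy accidental consensus matches starting inside the window.

    The obligate T at consensus position 3 is replaced by C (C occurs nowhere
    in the consensus, so scrubbing cannot create new matches).
    """
    from .motifs import _all_tata_starts

    length = len(promoter)
    lo, hi = min(window), max(window)
    chars = list(promoter)
    for _ in range(64):
        starts = _all_tata_starts("".join(chars), length, lo, hi)
        if not starts:
            break
        local = starts[0] + length
        chars[local + 2] = "C"
    return "".join(chars)


# --- motif library ----------------------------------------------------------


def make_motif_library(config: SimulationConfig, rng) -> list[PositionFrequencyMatrix]:
    """Sharp synthetic PFMs: one dominant base per position, 100 observations."""
    pfms = []
    minor = (1.0 - config.motif_dominance) / 3.0
    for i in range(config.motif_library_size):
        consensus = rng.integers(0, 4, config.motif_width)
        counts = np.full((config.motif_width, 4), 100.0 * minor)
        counts[np.arange(config.motif_width), consensus] = 100.0 * config.motif_dominance
        pfms.append(PositionFrequencyMatrix(f"TF{i:03d}", counts))
    return pfms


# --- gained-label enforcement ----------------------------------------------


def _enforce_absent(
    frow: str,
    orow_chars: list,
    gene_id: str,
    species: str,
    interval_local: tuple[int, int],
    scanner: PwmScanner,
    sub_rate: float,
    rng,
    max_tries: int = 100,
) -> None:
    """Rewrite the outgroup corresponding region until the motif is absent.

    Re-mutates the region from the focal sequence at ``sub_rate`` (a draw
    from the mutation process conditioned on site absence); after
    ``max_tries`` failures — and immediately when ``sub_rate`` is 0, where
    re-mutation is the identity — falls back to shuffling the region.
    Mutates ``orow_chars`` in place; the alignment gap structure is untouched.
    """
    aln = PromoterAlignment(gene_id, species, frow, "".join(orow_chars))
    region = corresponding_region(aln, interval_local)
    if region is None or region.is_empty:
        return
    lo, hi = region.interval
    cols = aln.column_of_outgroup[lo:hi]
    if len(cols) < scanner.pwm.width:
        return

    def region_seq() -> str:
        return "".join(orow_chars[c] for c in cols)

    tries = max_tries if sub_rate > 0 else 0
    for _ in range(tries):
        if not scanner.has_passing_window(region_seq()):
            return
        for c in cols:
            fch = frow[c]
            if fch not in BASES:
                orow_chars[c] = BASES[rng.integers(0, 4)]
            elif rng.random() < sub_rate:
                orow_chars[c] = BASES[(BASES.index(fch) + rng.integers(1, 4)) % 4]
            else:
                orow_chars[c] = fch
    for _ in range(max_tries):
        if not scanner.has_passing_window(region_seq()):
            return
        letters = [orow_chars[c] for c in cols]
        perm = rng.permutation(len(letters))
        for c, j in zip(cols, perm):
            orow_chars[c] = letters[j]
    warnings.warn(
        f"{gene_id}/{species}: could not enforce motif absence at {interval_local}"
    )


# --- cohort simulation ------------------------------------------------------


def _assign_categories(config: SimulationConfig, rng) -> list[str]:
    """Largest-remainder allocation of gene counts to categories, shuffled."""
    n = config.n_genes
    exact = {c: n * config.group_fractions.get(c, 0.0) for c in CATEGORIES}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    short = n - sum(counts.values())
    for c in sorted(CATEGORIES, key=lambda c: exact[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    cats = [c for c in CATEGORIES for _ in range(counts[c])]
    return [cats[i] for i in rng.permutation(n)]


def _make_evidence(gene_id: str, category: str, rng) -> HomologyEvidence:
    if category in ("de_novo", "duplicated_new"):
        return HomologyEvidence(
            gene_id=gene_id,
            has_cross_species_blast_hit=False,
            has_self_hit=True,
            expressed=True,
            in_ygob_or_orthomcl=False,
            max_identity_vs_six_species=round(float(rng.uniform(0.10, 0.60)), 3),
            has_paralog=(category == "duplicated_new"),
            ortholog_in_all_six=False,
        )
    if category == "orthologous":
        return HomologyEvidence(
            gene_id=gene_id,
            has_cross_species_blast_hit=True,
            has_self_hit=True,
            expressed=True,
            in_ygob_or_orthomcl=True,
            max_identity_vs_six_species=round(float(rng.uniform(0.75, 0.98)), 3),
            has_paralog=False,
            ortholog_in_all_six=True,
        )
    variant = int(rng.integers(0, 3))
    if variant == 0:  # candidate excluded by the >70% identity filter
        return HomologyEvidence(
            gene_id=gene_id,
            has_cross_species_blast_hit=False,
            has_self_hit=True,
            expressed=True,
            in_ygob_or_orthomcl=False,
            max_identity_vs_six_species=round(float(rng.uniform(0.705, 0.90)), 3),
            has_paralog=bool(rng.integers(0, 2)),
            ortholog_in_all_six=False,
        )
    if variant == 1:  # no expression evidence
        return HomologyEvidence(
            gene_id=gene_id,
            has_cross_species_blast_hit=False,
            has_self_hit=True,
            expressed=False,
            in_ygob_or_orthomcl=False,
            max_identity_vs_six_species=round(float(rng.uniform(0.10, 0.60)), 3),
            has_paralog=False,
            ortholog_in_all_six=False,
        )
    return HomologyEvidence(  # conserved but not in all six species
        gene_id=gene_id,
        has_cross_species_blast_hit=True,
        has_self_hit=True,
        expressed=True,
        in_ygob_or_orthomcl=bool(rng.integers(0, 2)),
        max_identity_vs_six_species=round(float(rng.uniform(0.40, 0.70)), 3),
        has_paralog=False,
        ortholog_in_all_six=False,
    )


def _random_cds(rng, length_range) -> str:
    lo, hi = length_range
    total = max(9, (int(rng.integers(lo, hi + 1)) // 3) * 3)
    n_internal = total // 3 - 2
    idx = rng.integers(0, len(_NONSTOP_CODONS), n_internal)
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in idx) + "TAA"


def _feasible_slot_count(length: int, k: int, width: int) -> int:
    """Largest motif count <= k that fits the planting zone (see below)."""
    min_gap = width + 51
    zone_lo, zone_hi = 5, length - 220
    while k > 0 and zone_hi - zone_lo - (k - 1) * min_gap < 0:
        k -= 1
    return max(k, 0)


def _plant_motif_slots(length: int, k: int, width: int, rng) -> list[int]:
    """k non-overlapping starts in [5, length-220], spaced >= width+51.

    The spacing keeps every ±25 bp corresponding region clear of neighboring
    planted words; the upper bound keeps planted motifs out of the TATA
    detection window.
    """
    min_gap = width + 51
    zone_lo, zone_hi = 5, length - 220
    if k <= 0:
        return []
    slack = zone_hi - zone_lo - (k - 1) * min_gap
    u = np.sort(rng.integers(0, slack + 1, k))
    return [int(zone_lo + u[j] + j * min_gap) for j in range(k)]


def _allocate_exact_fraction(
    groups: Sequence[str], fraction_by_group: dict, rng
) -> np.ndarray:
    """Boolean flags with *exactly* round(fraction x group size) set per group.

    Planted fractions are allocated by count rather than drawn per item, so
    noise-free recovery reproduces the configured fractions exactly and the
    planted group contrasts are not attenuated by allocation noise.
    """
    groups = np.asarray(groups)
    flags = np.zeros(len(groups), dtype=bool)
    for cat in sorted(set(groups.tolist())):
        idx = np.nonzero(groups == cat)[0]
        m = int(round(len(idx) * fraction_by_group.get(cat, 0.0)))
        chosen = idx[rng.permutation(len(idx))[:m]]
        flags[chosen] = True
    return flags


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full synthetic cohort bundle with its truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    bg = config.background()

    pfms = make_motif_library(config, rng)
    scanners = {
        p.tf_id: PwmScanner(
            pfm_to_pwm(p, bg), config.alpha, bg, config.bin_width
        )
        for p in pfms
    }
    categories = _assign_categories(config, rng)

    # promoter lengths and planted-feature allocations are fixed up front so
    # every configured fraction is realised exactly per group (not Bernoulli)
    lengths = np.clip(
        rng.normal(config.mean_intergenic, config.intergenic_sd, config.n_genes),
        config.min_promoter,
        config.max_promoter,
    ).astype(int)
    slot_counts = [
        _feasible_slot_count(int(L), config.motifs_per_gene, config.motif_width)
        for L in lengths
    ]
    dpn_flags = _allocate_exact_fraction(categories, config.dpn_fraction_by_group, rng)
    tata_flags = _allocate_exact_fraction(categories, config.tata_fraction_by_group, rng)
    instance_groups = [
        categories[i] for i in range(config.n_genes) for _ in range(slot_counts[i])
    ]
    gained_flags = iter(
        _allocate_exact_fraction(instance_groups, config.gained_fraction_by_group, rng)
    )

    genes: list[GeneRecord] = []
    evidence: dict[str, HomologyEvidence] = {}
    promoters: dict[str, str] = {}
    motif_truth_rows = []
    gene_truth_rows = []
    chrom_parts: list[str] = []
    cursor = 0
    planted_by_gene: dict[str, list[dict]] = {}

    for i in range(config.n_genes):
        gid = f"G{i:04d}"
        cat = categories[i]
        length = int(lengths[i])
        promoter = random_sequence(length, rng, bg)

        # plant motifs upstream of the TATA window
        slots = _plant_motif_slots(length, slot_counts[i], config.motif_width, rng)
        tf_ids = rng.choice(config.motif_library_size, size=len(slots), replace=False)
        planted = []
        chars = list(promoter)
        for slot, tf_idx in zip(slots, tf_ids):
            tf = f"TF{int(tf_idx):03d}"
            word = pfms[int(tf_idx)].consensus()
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                word = reverse_complement(word)
            chars[slot : slot + config.motif_width] = word
            gained = bool(next(gained_flags))
            planted.append(
                {
                    "gene_id": gid,
                    "tf_id": tf,
                    "local_start": slot,
                    "tss_relative_start": slot - length,
                    "strand": strand,
                    "turnover_truth": "gained" if gained else "preexisting",
                }
            )
        promoter = "".join(chars)

        # TATA planting / scrubbing inside the detection window
        tata_truth = bool(tata_flags[i])
        tata_pos = None
        if tata_truth:
            promoter, tata_pos = plant_tata(promoter, seed=rng)
        else:
            promoter = _scrub_tata(promoter)

        cds = _random_cds(rng, config.cds_length_range)
        tss = cursor + length
        genes.append(
            GeneRecord(
                gene_id=gid,
                chrom=config.chrom_name,
                strand="+",
                tss=tss,
                cds_intervals=[(tss, tss + len(cds))],
                category=cat,
            )
        )
        evidence[gid] = _make_evidence(gid, cat, rng)
        promoters[gid] = promoter
        planted_by_gene[gid] = planted
        motif_truth_rows.extend(planted)

        dpn = bool(dpn_flags[i])
        gene_truth_rows.append(
            {
                "gene_id": gid,
                "category": cat,
                "tata_truth": tata_truth,
                "tata_position": tata_pos,
                "architecture_truth": "DPN" if dpn else "OPN",
                "true_substitution_rate": config.substitution_rate_by_group.get(cat, 0.0),
                "promoter_length": length,
            }
        )
        chrom_parts.append(promoter)
        chrom_parts.append(cds)
        cursor = tss + len(cds)

    genome = {config.chrom_name: "".join(chrom_parts)}
    if config.chrom_length is not None and cursor > config.chrom_length:
        raise ConfigError(
            f"chrom_length {config.chrom_length} too small for layout ({cursor} bp)"
        )

    # outgroup promoters: protect preexisting words, enforce gained absence
    promoter_alignments: dict[tuple[str, str], PromoterAlignment] = {}
    for gene in genes:
        gid = gene.gene_id
        cat = gene.category
        sub_rate = config.substitution_rate_by_group.get(cat, 0.0)
        protected = sorted(
            (p["local_start"], p["local_start"] + config.motif_width)
            for p in planted_by_gene[gid]
            if p["turnover_truth"] == "preexisting"
        )
        for sp in config.outgroups:
            frow, orow = mutate_with_protected(
                promoters[gid], protected, sub_rate, config.indel_rate, rng
            )
            orow_chars = list(orow)
            for p in planted_by_gene[gid]:
                if p["turnover_truth"] != "gained":
                    continue
                _enforce_absent(
                    frow,
                    orow_chars,
                    gid,
                    sp,
                    (p["local_start"], p["local_start"] + config.motif_width),
                    scanners[p["tf_id"]],
                    sub_rate,
                    rng,
                )
            promoter_alignments[(gid, sp)] = PromoterAlignment(
                gid, sp, frow, "".join(orow_chars)
            )

    # CDS orthologs: neutral rate at four-fold sites, lower elsewhere
    cds_seqs: dict[str, str] = {}
    cds_alignments: dict[str, PromoterAlignment] = {}
    for gene in genes:
        gid = gene.gene_id
        s, e = gene.cds_intervals[0]
        cds = genome[config.chrom_name][s:e]
        cds_seqs[gid] = cds
        fourfold = set(find_fourfold_sites(gid, cds).sites)
        rates = np.where(
            np.isin(np.arange(len(cds)), list(fourfold)),
            config.cds_fourfold_rate,
            config.cds_other_rate,
        )
        arr = np.array([BASES.index(c) for c in cds])
        mask = rng.random(len(cds)) < rates
        shift = rng.integers(1, 4, len(cds))
        mut = np.where(mask, (arr + shift) % 4, arr)
        orow = "".join(BASES[b] for b in mut)
        cds_alignments[gid] = PromoterAlignment(gid, config.outgroups[0], cds, orow)

    # duplicate pairs: each duplicated-new gene paired with an orthologous parent
    ortho_ids = [g.gene_id for g in genes if g.category == "orthologous"]
    duplicate_pairs = []
    for gene in genes:
        if gene.category == "duplicated_new" and ortho_ids:
            parent = ortho_ids[int(rng.integers(0, len(ortho_ids)))]
            duplicate_pairs.append((gene.gene_id, parent))
            evidence[parent].has_paralog = True

    # curation: every planted pair, plus spurious associations
    curation = {(p["tf_id"], p["gene_id"]) for p in motif_truth_rows}
    spurious = rng.random((config.n_genes, config.motif_library_size))
    for i in range(config.n_genes):
        for t in range(config.motif_library_size):
            if spurious[i, t] < config.spurious_association_rate:
                curation.add((f"TF{t:03d}", f"G{i:04d}"))

    # nucleosome map: one well-occupied nucleosome in the planted region,
    # low-occupancy decoys elsewhere
    nucleosomes: list[NucleosomeCall] = []
    for gene, row in zip(genes, gene_truth_rows):
        if row["architecture_truth"] == "OPN":
            real_rel = -int(rng.integers(1, 101))
            decoy_rel = -int(rng.integers(301, 401))
        else:
            real_rel = -int(rng.integers(301, 401))
            decoy_rel = -int(rng.integers(1, 101))
        mid = gene.tss + real_rel
        nucleosomes.append(
            NucleosomeCall(
                gene.chrom, mid - 73, mid + 74, float(rng.uniform(0.60, 0.95))
            )
        )
        if rng.random() < 0.5:  # relatively depleted nucleosome, ignored downstream
            mid = gene.tss + decoy_rel
            nucleosomes.append(
                NucleosomeCall(
                    gene.chrom, mid - 73, mid + 74, float(rng.uniform(0.15, 0.45))
                )
            )
        mid = gene.tss + 200  # +1-like genic nucleosome, outside both windows
        nucleosomes.append(
            NucleosomeCall(gene.chrom, mid - 73, mid + 74, float(rng.uniform(0.60, 0.95)))
        )
    nucleosomes.sort(key=lambda c: (c.chrom, c.start))

    truth = TruthTable(
        motifs=pd.DataFrame(motif_truth_rows).drop(columns=["local_start"]),
        genes=pd.DataFrame(gene_truth_rows),
    )
    return CohortBundle(
        config=config,
        genome=genome,
        genes=genes,
        evidence=evidence,
        duplicate_pairs=duplicate_pairs,
        pfms=pfms,
        curation=curation,
        promoter_alignments=promoter_alignments,
        cds_seqs=cds_seqs,
        cds_alignments=cds_alignments,
        nucleosomes=nucleosomes,
        truth=truth,
    )


def simulate_to_dir(config: SimulationConfig, outdir) -> CohortBundle:
    from .io import write_bundle

    bundle = simulate_cohort(config)
    write_bundle(bundle, outdir)
    return bundle


# --- truth-table evaluation -------------------------------------------------


def match_hits_to_truth(hits, truth: TruthTable) -> pd.DataFrame:
    """Join scanned hits onto planted motifs by (gene, TF, position).

    Returns the truth motif table with an ``assigned_label`` column holding
    the pipeline's turnover label (``missed`` for planted motifs with no
    matching hit).
    """
    hit_rows = pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "tf_id": h.tf_id,
                "tss_relative_start": h.tss_relative_start,
                "assigned_label": h.turnover_label,
            }
            for h in hits
        ]
    )
    merged = truth.motifs.merge(
        hit_rows, on=["gene_id", "tf_id", "tss_relative_start"], how="left"
    )
    merged["assigned_label"] = merged["assigned_label"].fillna("missed")
    return merged


# --- packaged 10-gene toy fixture -------------------------------------------


def toy_bundle() -> CohortBundle:
    """Hand-built 10-gene cohort exercising every promoter filter.

    Layout (one 4.4 kb chromosome, coordinates 0-based):

    * G06  + TSS 150  — promoter bounded by the chromosome start (150 bp)
    * G01  + TSS 263  — 80 bp promoter, removed by the short-promoter filter
    * G02  − TSS 428 / G03 + TSS 729 — divergent pair, TSSs 301 bp apart, so
      the 250 bp core promoters overlap: both removed (head-to-head filter)
    * G04  + TSS 1162 — alignment gap rate 0.60, removed (poor alignment)
    * G05  + TSS 1595 — alignment gap rate exactly 0.50, retained
    * G07  + TSS 2128 — clean
    * G08  − TSS 2293 — minus-strand promoter (1000 bp cap applies)
    * G09  + TSS 3494 — promoter capped at 1000 bp by the neighbor boundary
    * G10  + TSS 4327 — clean

    The expected funnel is 10 → 9 → 7 → 6 with retained set
    {G05, G06, G07, G08, G09, G10}.
    """
    from .catalog import extract_promoter

    rng = np.random.default_rng(42)
    chrom = "chrT"
    seq = list(random_sequence(4400, rng))

    def cds_at(start: int) -> list[tuple[int, int]]:
        word = "ATG" + "".join(
            _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), 9)
        ) + "TAA"
        seq[start : start + 33] = word
        return [(start, start + 33)]

    genes = [
        GeneRecord("G06", chrom, "+", 150, cds_at(150)),
        GeneRecord("G01", chrom, "+", 263, cds_at(263)),
        GeneRecord("G02", chrom, "-", 428, cds_at(396)),
        GeneRecord("G03", chrom, "+", 729, cds_at(729)),
        GeneRecord("G04", chrom, "+", 1162, cds_at(1162)),
        GeneRecord("G05", chrom, "+", 1595, cds_at(1595)),
        GeneRecord("G07", chrom, "+", 2128, cds_at(2128)),
        GeneRecord("G08", chrom, "-", 2293, cds_at(2261)),
        GeneRecord("G09", chrom, "+", 3494, cds_at(3494)),
        GeneRecord("G10", chrom, "+", 4327, cds_at(4327)),
    ]
    genome = {chrom: "".join(seq)}

    categories = {
        "G01": "de_novo", "G02": "de_novo", "G03": "other", "G04": "de_novo",
        "G05": "de_novo", "G06": "de_novo", "G07": "duplicated_new",
        "G08": "orthologous", "G09": "other", "G10": "orthologous",
    }
    for g in genes:
        g.category = categories[g.gene_id]
    evidence = {}
    ev_rng = np.random.default_rng(7)
    for g in genes:
        evidence[g.gene_id] = _make_evidence(g.gene_id, g.category, ev_rng)
    # pin G09 to the >70% identity exclusion case
    evidence["G09"] = HomologyEvidence(
        gene_id="G09",
        has_cross_species_blast_hit=False,
        has_self_hit=True,
        expressed=True,
        in_ygob_or_orthomcl=False,
        max_identity_vs_six_species=0.75,
        has_paralog=False,
        ortholog_in_all_six=False,
    )

    sp = "outgroup1"
    alignments = {}
    for g in genes:
        prom = extract_promoter(g, genome, genes)
        if prom.length == 0:
            continue
        if g.gene_id == "G04":  # gap rate 0.60: 240 of 400 columns gapped
            frow = prom.sequence
            orow = prom.sequence[:160] + "-" * 240
        elif g.gene_id == "G05":  # gap rate exactly 0.50
            frow = prom.sequence
            orow = prom.sequence[:200] + "-" * 200
        else:
            frow = orow = prom.sequence
        alignments[(g.gene_id, sp)] = PromoterAlignment(g.gene_id, sp, frow, orow)

    pfm = PositionFrequencyMatrix(
        "TF000",
        np.array([[94, 2, 2, 2]] * 4 + [[2, 2, 2, 94]] * 4, dtype=float),
    )
    nucs = [
        NucleosomeCall(chrom, 1595 - 50 - 73, 1595 - 50 + 74, 0.85),  # G05 proximal
        NucleosomeCall(chrom, 2128 - 350 - 73, 2128 - 350 + 74, 0.80),  # G07 distal
    ]
    truth = TruthTable(
        motifs=pd.DataFrame(
            columns=["gene_id", "tf_id", "tss_relative_start", "strand", "turnover_truth"]
        ),
        genes=pd.DataFrame(
            [{"gene_id": g.gene_id, "category": g.category} for g in genes]
        ),
    )
    return CohortBundle(
        config=None,
        genome=genome,
        genes=genes,
        evidence=evidence,
        duplicate_pairs=[("G07", "G08")],
        pfms=[pfm],
        curation={("TF000", g.gene_id) for g in genes},
        promoter_alignments=alignments,
        cds_seqs={},
        cds_alignments={},
        nucleosomes=nucs,
        truth=truth,
    )
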