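# Methods

## Scope and model

`regevo` analyzes how promoters of newly originated genes acquire
cis-regulatory content, contrasting three gene classes in a compact
(yeast-like) genome: **de novo genes** (species-specific, expressed, no
paralog), **duplicated new genes** (species-specific with a paralog), and
**orthologous genes** (conserved across six comparison species), with
everything else as background ("other"). Four quantities are compared across
classes: the number of TFs/TFBSs per promoter, the fraction of TFBSs gained
since divergence from two close outgroup species, the promoter substitution
rate relative to a neutral reference, and promoter architecture (nucleosome
configuration and TATA-box content).

All heavy external evidence — protein homology searches, curated homolog
databases, expression maps, multiple-genome alignments, nucleosome maps —
enters as precomputed input tables; the package never recomputes it.

## Coordinates

Internally all intervals are 0-based half-open; GFF3 output is 1-based
inclusive. TSS-relative positions have no zero: −1 is the first base
upstream of the TSS, +1 the TSS base itself. Promoter sequences always read
5'→3' toward the TSS (minus-strand promoters are reverse-complemented), so
promoter-local index `i` in a promoter of length `L` is TSS-relative
position `i − L`. Planted-motif and four-fold-site coordinates in the truth
table are kept in these promoter-local/CDS-local frames (the genomic frame
is recoverable through the GFF), which keeps every downstream comparison a
pure integer match.

## PWM scanning with exact p-values

A PFM column with counts `c_b` and total `T` becomes a log-odds weight
`log2((c_b + κ·π_b)/(T + κ)) − log2(π_b)` in bits, with background `π`
(uniform by default, AT-rich 0.31/0.19 available) and pseudocount `κ = 1`
spread proportionally to the background so weights stay finite.

Per-position weights are discretized to integer multiples of `bin_width`
(default 0.01 bits). The null distribution of the score of a random
background word is then computed *exactly* by convolving the four-atom
per-position score distributions — O(width × support) — and the scan
threshold for significance level α (default 0.001) is the smallest support
value whose upper tail is < α. Scanning uses the same quantized matrix, so
window scores, the threshold, and reported per-hit p-values are mutually
consistent and exact for the quantized model (conservative to bin
resolution against the continuous scores). When even the best word has tail
≥ α the threshold is +∞ and the scan returns nothing; for α within 1e−9 of
1 every word passes by convention. Both strands are scanned; overlapping
hits of one TF count separately (a practical choice; the per-gene distinct-TF
count is insensitive to it).

Note a discreteness consequence: under a uniform background a width-w PWM
can never pass α = 0.001 unless 4^w > 1000, i.e. width ≥ 5.

## Turnover classification

Each curated hit's promoter interval is projected through the true pairwise
alignment into each outgroup: the minimal outgroup interval covering all
aligned bases, or — if the site falls entirely in an outgroup gap — the
insertion point between the flanking aligned columns. The region is extended
25 bp each side, clipped to the outgroup promoter, and rescanned on both
strands with the same PWM and the same α. *Preexisting* = at least one
outgroup region contains a passing window; *gained* = neither does;
*unclassifiable* = no anchor in either species. Losses are not modeled (a
de novo gene has no ancestral promoter to lose sites from). Outgroup region
coordinates are outgroup-sequence coordinates, not alignment columns.

## Substitution rates

Promoter rate = raw p-distance against the first outgroup: mismatching
non-gap columns over non-gap columns, case-insensitive, ambiguity codes
skipped and audited. No multiple-hit correction is applied by default (the
divergences involved are small); a Jukes–Cantor transform is available on
the result object. The neutral reference pools mismatches at four-fold
degenerate third-codon positions (judged on the focal codon under the
standard nuclear code) across all genes, restricted to columns ungapped in
both rows.

## Nucleosome architecture and TATA

Only nucleosome calls with occupancy strictly above 0.5 count. A nucleosome
is "in" a region iff its midpoint maps into it after strand-aware
TSS-relative conversion (midpoint rule; an any-overlap rule is available but
lets one 147 bp nucleosome straddle regions). OPN = proximal [−100,−1]
occupied and distal [−400,−301] empty; DPN = the reverse; both-or-neither =
unclassified, excluded from OPN/DPN denominators but reported. Promoters
shorter than 400 bp have no distal region and are always unclassified. The
TATA call requires a TATA(A/T)A(A/T)(A/G) word *starting* at a TSS-relative
position in the closed window [−200, −50], sense strand only (the consensus
is defined on the coding-strand orientation).

## Statistical tests

* Wilcoxon rank-sum: exact null by enumeration when n1+n2 ≤ 12 without
  ties (scipy backend; verified against independent subset enumeration),
  otherwise normal approximation with tie and continuity corrections.
* Two-sample proportion test: pooled-variance z without continuity
  correction.
* TFBS enrichment: per TF, upper-tail binomial on the number of de novo
  genes containing ≥1 curated hit, null probability = fraction of all other
  genes containing one; Benjamini–Hochberg FDR across TFs.
* "±" summaries are mean ± SEM (sample SD/√n), undefined and flagged at
  n = 1.

The headline group contrasts are one-sided in the direction under study:
higher gained fraction (pooled proportions), higher promoter substitution
rate (Wilcoxon), higher DPN proportion, and lower TATA proportion in
de novo versus orthologous genes.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes; its
defaults are the study conditions, not tuning knobs.

* **Layout.** One chromosome, all genes forward-strand, head-to-tail:
  `[promoter][CDS][promoter][CDS]…` with promoter length drawn from
  N(700, 120²) clipped to [500, 1000] bp (compact, yeast-like spacing while
  leaving room for the distal nucleosome window). This makes promoter
  extraction recover the designed promoters exactly; strand-dependent code
  paths are exercised instead by the hand-built 10-gene toy fixture, which
  contains minus-strand genes, a divergent head-to-head pair with TSSs
  301 bp apart, an 80 bp promoter, and alignments with gap rates 0.60 and
  exactly 0.50.
* **Motifs.** A library of sharp synthetic PFMs (width 8, dominant base
  weight 0.94, 100 observations); planted instances are consensus words on
  a random strand, at starts spaced ≥ width+51 bp so corresponding regions
  of neighboring sites never overlap, and kept out of the TATA window.
* **Planted fractions are exact.** Gained/preexisting labels, TATA content,
  and OPN/DPN architecture are allocated per group by count
  (round(fraction × group size), randomly assigned), not by per-item coin
  flips, so noise-free recovery reproduces the configured fractions exactly
  and planted contrasts are not attenuated by allocation noise.
* **Divergence.** Outgroup promoters are generated independently per
  species by a per-site process: substitution to a uniformly chosen other
  base with the group's rate, indels (1–3 bp, truncated geometric, 50/50
  insertion/deletion) at `indel_rate` per site; the true gapped alignment is
  returned. Preexisting motif words are protected from mutation in both
  outgroups (word intact and aligned, as conservation would leave it).
  Gained labels are enforced by rejection: the outgroup corresponding
  region is re-mutated from the focal sequence at the group's rate until no
  threshold-passing window remains (a draw from the mutation process
  conditioned on site absence — gained sites arise by substitution); at
  zero substitution rate, where re-mutation is the identity, the region is
  shuffled instead, and after 100 failed tries the shuffle fallback applies
  regardless.
* **Defaults.** Group fractions 0.25/0.15/0.35/0.25 (de novo/duplicated/
  orthologous/other); gained fractions 0.468/0.581/0.347/0.378 (one minus
  the preexisting fractions under study); TATA fractions
  0.121/0.714/0.359/0.233; DPN fractions 0.65/0.30/0.35/0.40 (direction:
  DPN-dominated de novo genes, OPN-dominated duplicated/orthologous);
  promoter substitution rates 0.10/0.09/0.05/0.06 with indel rate 0.005,
  all below the neutral four-fold rate of 0.12 planted in the CDS
  orthologs (non-degenerate sites mutate at 0.03). Five motifs per promoter
  from a 25-TF library; the curation table covers 100% of planted pairs
  plus spurious associations at rate 0.05. 300 genes by default.
* **TATA hygiene.** TATA-less promoters are scrubbed of accidental
  consensus matches inside the detection window (the obligate T at
  consensus position 3 is flipped to C, which occurs nowhere in the
  consensus and so cannot create new matches).
* **Nucleosomes.** One well-occupied (0.60–0.95) 147 bp nucleosome with its
  midpoint in the planted region, a low-occupancy (0.15–0.45) decoy in the
  opposite region half the time, and a well-occupied genic nucleosome at
  +200 that must be ignored by the windows.

### What the generator does not emulate

Realistic codon usage and base composition (uniform by default), expression
levels, overlapping or nested genes, promoter sharing between divergent
genes, rate heterogeneity along promoters, alignment error (alignments are
true by construction), and TF motif families with correlated PWMs. Passing
recovery tests therefore demonstrates correctness of the *computational
procedure* under the stated model, not robustness to real-data artifacts
such as misalignment or motif redundancy — the curation filter and the
gap-rate filter are exercised mechanically, not adversarially.

## Problem sizes and determinism

Verification runs use cohorts of 40–300 genes (≥500 planted motifs for
turnover recovery, 10 kb of pooled sequence per substitution-rate point,
10,000 random kilobase promoters for the TATA oracle, 2,000 replicates for
Wilcoxon null calibration, 100 zero-effect cohorts of 120 genes for the
false-positive rate), sizes at which every planted effect is comfortably
detectable and the binomial error bars of the recovery checks are tight.
A single `numpy` Generator seeded from the config drives all randomness;
a fixed seed makes every output file byte-identical, and each run manifest
records the config snapshot, seed, row counts, and output checksums.

## Known limitations

* The exact-count allocation of planted fractions makes group proportions
  slightly under-dispersed relative to a Bernoulli world; the pooled
  proportion tests on simulated nulls are therefore mildly conservative.
* Spurious (unplanted) curated hits are an inherent product of p<0.001
  scanning and dilute pooled gained fractions relative to the planted
  values; truth-table comparisons match hits to planted positions for this
  reason.
* The gained-site rejection step locally conditions the outgroup mutation
  process, adding ≈2 extra substitutions per enforced site; with ≤5 planted
  sites per ~700 bp promoter this inflates per-promoter p-distance by well
  under 0.01 and is shared across groups.
* p-distance without correction underestimates true divergence as rates
  grow; at the simulated rates (≤0.12) the bias is below the binomial noise
  of a single promoter.
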