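# regevo

**Cis-regulatory evolution of de novo and duplicated new genes in yeast.**

New genes enter a genome either by duplication of an existing gene — promoter
included — or de novo, from sequence that was never coding. How does a de
novo gene, with no parental promoter to inherit, acquire a full complement of
transcription-factor binding sites (TFBSs)? `regevo` implements the
comparative-genomics analysis that addresses this question in
*Saccharomyces cerevisiae*–like data:

* **Gene catalog** — classify genes as *de novo*, *duplicated new*,
  *orthologous*, or *other* from precomputed homology evidence (BLASTP
  cross-species hits, expression, curated homolog databases, ≤70% identity
  to six sister species, duplicate-pair membership), and extract promoters
  (intergenic sequence ≤1000 bp upstream of the TSS) with three eligibility
  filters: length ≥100 bp, no shared 250 bp core promoter between
  head-to-head genes, and an outgroup alignment gap rate ≤50%.
* **Motif scanning** — convert position frequency matrices to log-odds PWMs,
  compute each PWM's exact null score distribution by dynamic programming
  over discretized scores, scan both promoter strands keeping windows with
  p < 0.001, and retain only hits backed by a curated TF→gene association
  table. The TATA box is called by the consensus TATA(A/T)A(A/T)(A/G) within
  −200..−50 of the TSS.
* **TFBS turnover** — project each TFBS through pairwise alignments into two
  outgroup species, rescan the aligned region ±25 bp ("corresponding
  region"), and label the site *preexisting* if either outgroup still
  harbors a threshold-passing occurrence, else *gained*.
* **Promoter evolution rate** — per-promoter p-distance (mismatching non-gap
  columns / non-gap columns, indels ignored) against a neutral reference:
  the pooled substitution rate at four-fold degenerate third-codon positions.
* **Nucleosome architecture** — OPN/DPN classification from a nucleosome
  occupancy map: a well-occupied (>50%) nucleosome in the TSS-proximal
  window [−100,−1] versus the TSS-distal window [−400,−301].
* **Statistics** — Wilcoxon rank-sum (exact for small tie-free samples),
  pooled-z two-sample proportion tests, gene-level binomial TFBS enrichment
  with BH-FDR, and mean ± SEM group summaries.

Because the original data sources are neither desk-scale nor version-stable,
the package ships a first-class **synthetic cohort generator** that emits a
complete fixture set (genome FASTA, GFF3, TSS BED, per-gene outgroup
alignments, PFM library, curation table, nucleosome BED) with planted ground
truth — gained/preexisting motifs, group-wise substitution rates, TATA and
OPN/DPN fractions — so that every stage can be validated by recovery of what
was planted.

## Worked example

```python
from regevo import SimulationConfig
from regevo.simulate import simulate_cohort
from regevo.pipeline import run_cohort

bundle = simulate_cohort(SimulationConfig(seed=0))   # 300 genes, 2 outgroups
result = run_cohort(bundle)

print(result.turnover_by_group[["classified", "pooled_gained_fraction"]])
for name, test in result.contrasts.items():
    print(f"{name}: p = {test.p_value:.3g}")
```

prints:

```
                classified  pooled_gained_fraction
category
de_novo                615                0.401626
duplicated_new         370                0.459459
orthologous            892                0.256726
other                  595                0.289076
gained_fraction: p = 1.36e-09
substitution_rate: p = 4.56e-28
dpn_proportion: p = 3.37e-05
tata_proportion: p = 0.000135
```

i.e. de novo genes show a higher pooled gained-TFBS fraction and promoter
substitution rate than orthologous genes, more DPN (depleted proximal
nucleosome) promoters, and fewer TATA boxes — the planted contrasts, each
detected in the planted direction at α = 0.01.

The same analysis is available from the shell:

```bash
regevo run --seed 0 --outdir runs/demo         # simulate + full report
regevo simulate --seed 0 --outdir runs/bundle  # fixture bundle only
regevo catalog --bundle runs/bundle --outdir runs/catalog
```

Stage subcommands (`catalog`, `scan`, `turnover`, `evorate`, `nucarch`,
`stats-report`) each write their module's tables plus a JSON manifest with a
config snapshot, seed, row counts, and output checksums; a rerun with the
same manifest is byte-identical.

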