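"""Statistical tests for group comparisons.

Wilcoxon rank-sum (exact by enumeration for small tie-free samples, normal
approximation with tie and continuity corrections otherwise), the pooled-z
two-sample proportion test, upper-tail binomial TFBS enrichment with
Benjamini-Hochberg correction, and mean ± SEM group summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

EXACT_WILCOXON_MAX_N = 12

ALTERNATIVES = ("one_sided_less", "one_sided_greater", "two_sided")
_SCIPY_ALT = {
    "one_sided_less": "less",
    "one_sided_greater": "greater",
    "two_sided": "two-sided",
}


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    alternative: str
    n1: int
    n2: int


@dataclass
class EnrichmentResult:
    tf_id: str
    x: int  # de novo genes with >=1 TFBS of this TF
    n: int  # de novo gene count
    p0: float  # background fraction of genes with >=1 TFBS of this TF
    p_value: float
    q_value: float = float("nan")


def _check_alternative(alternative: str) -> None:
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when n1+n2 <= 12 with no ties; otherwise the
    normal approximation with tie correction and continuity correction.
    The statistic reported is the Mann-Whitney U of the first sample.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        warnings.warn("all values identical across both samples; p = 1")
        return TestResult("wilcoxon_rank_sum", len(x) * len(y) / 2, 1.0,
                          alternative, len(x), len(y))
    has_ties = len(np.unique(combined)) < len(combined)
    small = len(x) + len(y) <= EXACT_WILCOXON_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=_SCIPY_ALT[alternative], method=method)
    return TestResult(
        "wilcoxon_rank_sum", float(res.statistic), float(min(res.pvalue, 1.0)),
        alternative, len(x), len(y),
    )


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, alternative: str = "two_sided"
) -> TestResult:
    """Pooled-variance z test for two proportions (no continuity correction).

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    """
    _check_alternative(alternative)
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1) or not (0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        warnings.warn("degenerate pooled proportion (0 or 1); p = 1")
        z = 0.0
    else:
        z = (p1 - p2) / se
    if alternative == "one_sided_greater":
        p = sps.norm.sf(z)
    elif alternative == "one_sided_less":
        p = sps.norm.cdf(z)
    else:
        p = 2 * sps.norm.sf(abs(z))
    return TestResult("two_proportion", float(z), float(min(p, 1.0)),
                      alternative, n1, n2)


def binomial_enrichment(
    tf_id: str,
    de_novo_genes: Sequence[str],
    background_genes: Sequence[str],
    genes_with_hit: set[str],
) -> EnrichmentResult:
    """Upper-tail binomial test for TFBS enrichment in de novo genes.

    The unit is a gene containing >=1 curated TFBS of the TF.  The null is
    that the probability of a de novo gene containing the TFBS is at most the
    background fraction p0 observed among all other genes;
    p = P(X >= x | n, p0).
    """
    de_novo = set(de_novo_genes)
    background = set(background_genes)
    if de_novo & background:
        raise ValueError("background set must be disjoint from de novo set")
    if not background:
        raise ValueError("background set must be non-empty")
    n = len(de_novo)
    x = len(de_novo & genes_with_hit)
    p0 = len(background & genes_with_hit) / len(background)
    if p0 == 0.0:
        if x > 0:
            warnings.warn(f"{tf_id}: degenerate null p0=0 with x>0; p-value 0")
            p = 0.0
        else:
            p = 1.0
    else:
        p = float(sps.binom.sf(x - 1, n, p0))
    return EnrichmentResult(tf_id, x, n, p0, min(p, 1.0))


def enrichment_table(
    tf_to_genes_with_hit: Mapping[str, set[str]],
    de_novo_genes: Sequence[str],
    background_genes: Sequence[str],
):
    """Binomial enrichment over all TFs with BH-FDR q-values."""
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    results = [
        binomial_enrichment(tf, de_novo_genes, background_genes, genes)
        for tf, genes in sorted(tf_to_genes_with_hit.items())
    ]
    if results:
        pvals = [r.p_value for r in results]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q_value = float(q)
    return pd.DataFrame(
        [
            {"tf_id": r.tf_id, "x": r.x, "n": r.n, "p0": r.p0,
             "p_value": r.p_value, "q_value": r.q_value}
            for r in results
        ]
    ).set_index("tf_id")


def group_summary(values_by_group: Mapping[str, Sequence[float]]):
    """Mean and standard error of the mean per group.

    SEM = sample SD (ddof=1) / sqrt(n); undefined (NaN) for n = 1, flagged
    with a warning.
    """
    import pandas as pd

    rows = []
    for group, values in values_by_group.items():
        values = np.asarray(list(values), dtype=float)
        if len(values) == 0:
            raise ValueError(f"group {group!r} is empty")
        if len(values) == 1:
            warnings.warn(f"group {group!r} has n=1; SEM undefined")
            sem = float("nan")
        else:
            sem = float(np.std(values, ddof=1) / np.sqrt(len(values)))
        rows.append({"group": group, "n": len(values),
                     "mean": float(values.mean()), "sem": sem})
    return pd.DataFrame(rows).set_index("group")
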