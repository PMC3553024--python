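import itertools

import numpy as np
import pytest

from regevo.catalog import Promoter
from regevo.config import CATEGORIES, SimulationConfig
from regevo.motifs import PositionFrequencyMatrix, pfm_to_pwm
from regevo.simulate import simulate_cohort


def make_promoter(sequence: str, gene_id: str = "g1", strand: str = "+") -> Promoter:
    return Promoter(gene_id, "chr1", strand, (0, len(sequence)), sequence)


def random_pfm(rng, width: int, tf_id: str = "TFX") -> PositionFrequencyMatrix:
    counts = rng.uniform(0.5, 100.0, size=(width, 4))
    return PositionFrequencyMatrix(tf_id, counts)


def enumerate_distribution(pwm, bin_width=0.01, background=None):
    """Brute-force oracle: exact quantized score distribution over all words."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    q = pwm.quantize(bin_width)
    probs: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=pwm.width):
        s = int(sum(q[i, b] for i, b in enumerate(word)))
        p = float(np.prod([bg[b] for b in word]))
        probs[s] = probs.get(s, 0.0) + p
    support = np.array(sorted(probs))
    pvec = np.array([probs[s] for s in support])
    return support, pvec


def oracle_threshold(support, probs, alpha):
    """Minimal support value with P(score >= s) < alpha, else None."""
    tails = np.cumsum(probs[::-1])[::-1]
    for s, t in zip(support, tails):
        if t < alpha:
            return int(s)
    return None


@pytest.fixture(scope="session")
def small_bundle():
    """Default-rates cohort, small enough for fast shared use."""
    cfg = SimulationConfig(
        n_genes=60, motif_library_size=10, motifs_per_gene=3, seed=7
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free cohort: zero divergence, no spurious associations."""
    cfg = SimulationConfig(
        n_genes=40,
        motif_library_size=8,
        motifs_per_gene=3,
        seed=4,
        substitution_rate_by_group={c: 0.0 for c in CATEGORIES},
        indel_rate=0.0,
        spurious_association_rate=0.0,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_result(small_bundle):
    from regevo.pipeline import run_cohort

    return run_cohort(small_bundle)


@pytest.fixture(scope="session")
def clean_result(clean_bundle):
    from regevo.pipeline import run_cohort

    return run_cohort(clean_bundle)
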