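"""Simulation configuration for synthetic promoter cohorts.

Every generator parameter is surfaced here rather than hard-coded.  The
defaults encode the study conditions the pipeline is meant to reproduce on
synthetic data: group-wise preexisting-TFBS fractions of 53.2% (de novo),
41.9% (duplicated new), 65.3% (orthologous) and 62.2% (other) — i.e. gained
fractions of 1 minus those — TATA-containing fractions of 12.1% / 71.4% /
35.9% / 23.3%, promoter substitution rates below the four-fold-degenerate
neutral rate, and DPN predominance in de novo genes with OPN predominance in
duplicated-new and orthologous genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

CATEGORIES = ("de_novo", "duplicated_new", "orthologous", "other")


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _default_group_fractions() -> dict:
    return {"de_novo": 0.25, "duplicated_new": 0.15, "orthologous": 0.35, "other": 0.25}


def _default_substitution_rates() -> dict:
    return {"de_novo": 0.10, "duplicated_new": 0.09, "orthologous": 0.05, "other": 0.06}


def _default_gained_fractions() -> dict:
    # 1 - preexisting fractions 53.2% / 41.9% / 65.3% / 62.2%
    return {"de_novo": 0.468, "duplicated_new": 0.581, "orthologous": 0.347, "other": 0.378}


def _default_tata_fractions() -> dict:
    return {"de_novo": 0.121, "duplicated_new": 0.714, "orthologous": 0.359, "other": 0.233}


def _default_dpn_fractions() -> dict:
    return {"de_novo": 0.65, "duplicated_new": 0.30, "orthologous": 0.35, "other": 0.40}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Rates are per-site probabilities; fractions lie in [0, 1];
    ``group_fractions`` must sum to 1.  A fixed seed makes every output
    byte-identical across runs.
    """

    n_genes: int = 300
    chrom_name: str = "chrS"
    chrom_length: int | None = None  # derived from the layout when None
    mean_intergenic: int = 700  # mean promoter (intergenic) length, bp
    intergenic_sd: int = 120
    min_promoter: int = 500
    max_promoter: int = 1000
    group_fractions: dict = field(default_factory=_default_group_fractions)
    substitution_rate_by_group: dict = field(default_factory=_default_substitution_rates)
    indel_rate: float = 0.005
    gained_fraction_by_group: dict = field(default_factory=_default_gained_fractions)
    tata_fraction_by_group: dict = field(default_factory=_default_tata_fractions)
    dpn_fraction_by_group: dict = field(default_factory=_default_dpn_fractions)
    motif_library_size: int = 25
    motifs_per_gene: int = 5
    motif_width: int = 8
    motif_dominance: float = 0.94  # PFM weight of the consensus base
    spurious_association_rate: float = 0.05
    cds_length_range: tuple = (300, 900)
    cds_fourfold_rate: float = 0.12  # neutral rate planted at 4-fold sites
    cds_other_rate: float = 0.03
    alpha: float = 0.001
    bin_width: float = 0.01
    at_rich: bool = False  # uniform background by default; AT-rich option
    outgroups: tuple = ("outgroup1", "outgroup2")
    seed: int = 0

    def background(self):
        import numpy as np

        if self.at_rich:
            return np.array([0.31, 0.19, 0.19, 0.31])
        return np.full(4, 0.25)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        for name in ("group_fractions", "gained_fraction_by_group",
                     "tata_fraction_by_group", "dpn_fraction_by_group"):
            mapping = getattr(self, name)
            for cat, frac in mapping.items():
                if cat not in CATEGORIES:
                    raise ConfigError(f"{name}: unknown category {cat!r}")
                if not 0.0 <= frac <= 1.0:
                    raise ConfigError(f"{name}[{cat}] = {frac} not in [0, 1]")
        total = sum(self.group_fractions.get(c, 0.0) for c in CATEGORIES)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"group_fractions must sum to 1 (got {total})")
        for cat, rate in self.substitution_rate_by_group.items():
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"substitution_rate_by_group[{cat}] = {rate} not in [0, 1)")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ConfigError(f"indel_rate = {self.indel_rate} not in [0, 1)")
        if not 0.0 <= self.spurious_association_rate <= 1.0:
            raise ConfigError("spurious_association_rate not in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if self.min_promoter > self.max_promoter:
            raise ConfigError("min_promoter must not exceed max_promoter")
        if self.max_promoter > 1000:
            raise ConfigError("max_promoter must be <= 1000 (promoter definition)")
        if not 0.25 < self.motif_dominance < 1.0:
            raise ConfigError("motif_dominance must lie in (0.25, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cds_length_range"] = list(self.cds_length_range)
        d["outgroups"] = list(self.outgroups)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "cds_length_range" in d:
            d["cds_length_range"] = tuple(d["cds_length_range"])
        if "outgroups" in d:
            d["outgroups"] = tuple(d["outgroups"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def zero_effect(cls, **overrides) -> "SimulationConfig":
        """A null configuration: identical parameters in every group."""
        cfg = cls(
            substitution_rate_by_group={c: 0.06 for c in CATEGORIES},
            gained_fraction_by_group={c: 0.40 for c in CATEGORIES},
            tata_fraction_by_group={c: 0.25 for c in CATEGORIES},
            dpn_fraction_by_group={c: 0.40 for c in CATEGORIES},
            indel_rate=0.0,
        )
        for key, value in overrides.items():
            setattr(cfg, key, value)
        cfg.validate()
        return cfg
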