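"""Parameter blocks for every pipeline stage.

Defaults follow the published analysis settings where the study states them
(island-calling window/gap/FDR, the <250 bp consensus merge, the >25%
H3K27me3 co-occupancy requirement, the fold >= 1.5 / p <= 1e-20 differential
cut, and the FDR <= 0.01 / |log2FC| >= 1 / maxTPM >= 1 expression criteria);
remaining knobs are exposed with documented defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass(frozen=True)
class IslandParams:
    """Broad-mark island-calling parameters (per mark).

    ``fragment_size_bp`` parameterises single-end read extension in the
    original tool; with true fragment intervals as input it is accepted but
    unused (a notice is logged by the caller).
    """

    window_size_bp: int = 200
    gap_size_bp: int = 400            # 400 for EZH2, 600 for H3K27me3
    effective_genome_fraction: float = 0.75
    redundancy_threshold: int = 1
    eligibility_p: float = 0.2
    island_fdr: float = 1e-4
    fragment_size_bp: int = 110       # accepted-but-ignored with fragment input

    def __post_init__(self) -> None:
        if self.window_size_bp <= 0:
            raise ValueError("window_size_bp must be positive")
        if self.gap_size_bp % self.window_size_bp != 0:
            raise ValueError("gap_size_bp must be a multiple of window_size_bp")
        if not 0 < self.effective_genome_fraction <= 1:
            raise ValueError("effective_genome_fraction must lie in (0, 1]")
        if not 0 < self.island_fdr < 1:
            raise ValueError("island_fdr must lie in (0, 1)")
        if self.redundancy_threshold < 1:
            raise ValueError("redundancy_threshold must be >= 1")


# per-mark gap-size convention of the study
GAP_SIZE_BY_MARK = {"EZH2": 400, "H3K27me3": 600}


def island_params_for_mark(mark: str, **overrides) -> IslandParams:
    """IslandParams with the mark-appropriate gap size (400 EZH2 / 600 H3K27me3)."""
    gap = overrides.pop("gap_size_bp", GAP_SIZE_BY_MARK.get(mark, 400))
    return IslandParams(gap_size_bp=gap, **overrides)


@dataclass(frozen=True)
class DiffParams:
    """Large-magnitude differential-binding thresholds.

    Classification thresholds are inclusive (>= fc_min, <= p_max); the display
    floor caps volcano p-values only and never affects classification.
    """

    fc_min: float = 1.5
    p_max: float = 1e-20
    norm_depth: float = 1e7           # tags per ten million
    pseudocount: float = 1.0
    display_p_floor: float = 1e-100

    def __post_init__(self) -> None:
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must lie in (0, 1)")


@dataclass(frozen=True)
class DEThresholds:
    """Significance criteria for EZH2i-sensitive genes and between-state DE."""

    fdr_max: float = 0.01
    abs_log2fc_min: float = 1.0
    max_tpm_min: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic-data generator.

    The generator emulates the study design: two or three cellular states
    (untransformed-like ``UT``, optional pre-neoplastic ``PN``,
    transformed-like ``TR``), two ChIP replicates per state and mark, broad
    background coverage plus shared and state-specific enriched domains with
    EZH2 domains nested inside wider H3K27me3 domains, RNA counts with
    EZH2i-responsive genes, and state-concordant "switch" genes whose
    promoter domain gain/loss matches their expression shift.

    ``background_rate`` (fragments per bp per million library fragments) is
    used to derive a library size only when ``library_size`` is None;
    otherwise ``library_size`` is authoritative.
    """

    n_chroms: int = 2
    chrom_length_bp: int = 5_000_000
    n_states: int = 2
    replicates_per_mark: int = 2
    n_genes: int = 400
    background_rate: float = 0.1
    enrichment_factor: float = 8.0
    n_common_domains: int = 20
    n_state_specific_domains: int = 10
    domain_width_bp: int = 10_000
    k27_margin_bp: int = 2_000        # H3K27me3 domain extends EZH2 by this on each side
    fragment_length_bp: int = 200
    library_size: Optional[int] = 200_000
    rna_replicates: int = 3
    de_log2fc: float = 2.0            # planted EZH2i effect
    switch_log2fc: float = 2.0        # planted between-state effect at switch genes
    nb_dispersion: float = 0.05
    n_sensitive_genes: int = 30
    n_switch_genes: tuple[int, int] = (3, 2)   # (gained-in-last-state, lost-in-last-state)
    gene_length_bp: int = 2_000
    methylation_beta_params: tuple[tuple[float, float], tuple[float, float]] = (
        (2.0, 8.0),   # EZH2i-sensitive genes: low promoter methylation
        (8.0, 2.0),   # insensitive genes: high promoter methylation
    )
    library_jitter: float = 0.20      # replicate-specific ChIP library-size jitter
    rna_size_factor_jitter: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_chroms, self.n_states, self.replicates_per_mark, self.n_genes,
                  self.n_common_domains, self.n_state_specific_domains,
                  self.n_sensitive_genes, self.rna_replicates)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if not 2 <= self.n_states <= 3:
            raise ValueError("n_states must be 2 or 3")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.domain_width_bp >= self.chrom_length_bp:
            raise ValueError("domain_width_bp must be smaller than chrom_length_bp")
        if isinstance(self.n_switch_genes, int):
            object.__setattr__(self, "n_switch_genes",
                               (self.n_switch_genes - self.n_switch_genes // 2,
                                self.n_switch_genes // 2))

    @property
    def states(self) -> list[str]:
        return ["UT", "PN", "TR"][: self.n_states] if self.n_states == 3 else ["UT", "TR"]

    @property
    def genome_length_bp(self) -> int:
        return self.n_chroms * self.chrom_length_bp

    def resolved_library_size(self) -> int:
        if self.library_size is not None:
            return int(self.library_size)
        # background_rate r: fragments per bp per million library fragments
        # depth L satisfies L = r * genome_length * L / 1e6 only at r*G = 1e6;
        # instead interpret r as the desired background coverage and solve for
        # the library that yields it outside domains.
        return int(round(self.background_rate * self.genome_length_bp))


@dataclass
class RunConfig:
    """Full-run configuration: stage parameter blocks plus direction labels.

    ``state_a`` is the reference (untransformed-like) state, ``state_b`` the
    transformed-like state in which domain gain implies silencing.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    islands_ezh2: IslandParams = field(default_factory=lambda: island_params_for_mark("EZH2"))
    islands_k27: IslandParams = field(default_factory=lambda: island_params_for_mark("H3K27me3"))
    diff: DiffParams = field(default_factory=DiffParams)
    de: DEThresholds = field(default_factory=DEThresholds)
    merge_gap_bp: int = 250
    cooccupancy_min_fraction: float = 0.25
    tss_max_dist_bp: int = 5_000
    state_a: str = "UT"
    state_b: str = "TR"
    seed: int = 0

    _KNOWN = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        """Build from a nested mapping (e.g. parsed YAML); unknown keys rejected."""
        d = dict(d)
        kwargs = {}
        block_types = {
            "sim": SimConfig, "islands_ezh2": IslandParams, "islands_k27": IslandParams,
            "diff": DiffParams, "de": DEThresholds,
        }
        for key, typ in block_types.items():
            if key in d:
                block = d.pop(key)
                if isinstance(block, dict):
                    valid = {f for f in typ.__dataclass_fields__}
                    unknown = set(block) - valid
                    if unknown:
                        raise ValueError(f"unknown keys in {key!r}: {sorted(unknown)}")
                    if key == "sim" and "n_switch_genes" in block and isinstance(block["n_switch_genes"], list):
                        block["n_switch_genes"] = tuple(block["n_switch_genes"])
                    if key == "sim" and "methylation_beta_params" in block:
                        block["methylation_beta_params"] = tuple(
                            tuple(x) for x in block["methylation_beta_params"])
                    block = typ(**block)
                kwargs[key] = block
        scalar_fields = {"merge_gap_bp", "cooccupancy_min_fraction", "tss_max_dist_bp",
                         "state_a", "state_b", "seed"}
        for key in list(d):
            if key in scalar_fields:
                kwargs[key] = d.pop(key)
        if d:
            raise ValueError(f"unknown configuration keys: {sorted(d)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = asdict(self)
        return out
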