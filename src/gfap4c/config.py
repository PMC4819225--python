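"""Configuration objects: pipeline thresholds and synthetic-study design.

``PipelineConfig`` collects every numeric constant of the published screen
(log2 ratio cutoff of 2 over a 200-bp sliding window, 50-kb gene mapping,
two-fold / one-copy expression filters, 500-nm FISH association threshold,
5-kb STAT3 promoter window). ``SyntheticConfig`` defines the simulated study
that stands in for the deposited arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

CONDITIONS = ("NPC", "LIF+", "LIF-")

#: Published per-condition nuclear diameters, mean +/- sd in micrometres.
NUCLEAR_DIAMETER_UM = {
    "NPC": (10.4, 1.5),
    "LIF+": (10.1, 1.1),
    "LIF-": (10.2, 1.2),
}

BGLII_SITE = "AGATCT"
NLAIII_SITE = "CATG"


@dataclass
class PipelineConfig:
    """Thresholds of the hit-calling, mapping, expression and FISH stages."""

    window_bp: int = 200          # sliding-window width for ratio smoothing
    ratio_cutoff: float = 2.0     # log2(e4C/genomic control) hit cutoff
    pseudocount: float = 1.0      # intensity-unit guard for zero channels
    max_gap_bp: int = 0           # hit-to-peak merge distance
    gene_distance_bp: int = 50_000
    expr_fold: float = 2.0
    expr_floor_copies: float = 1.0
    fish_threshold_um: float = 0.5   # 500 nm
    stat3_window_bp: int = 5_000
    pwm_score_fraction: float = 0.8

    def __post_init__(self) -> None:
        positive = (
            "window_bp ratio_cutoff max_gap_bp gene_distance_bp expr_fold "
            "expr_floor_copies fish_threshold_um stat3_window_bp "
            "pwm_score_fraction"
        ).split()
        for name in positive:
            value = getattr(self, name)
            if name == "max_gap_bp":
                if value < 0:
                    raise ValueError("max_gap_bp must be >= 0")
            elif value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass
class SyntheticConfig:
    """Design of the synthetic study the generator emulates.

    The defaults reproduce the desk-scale study conditions: 3 chromosomes of
    10 Mb, 300 genes, a BglII/NlaIII fragment array, 20 genes planted as both
    Gfap-associated and LIF+-expressed, interaction strength of 3 log2 units
    with 0.5 sd replicate noise, a five-fold planted expression effect, and
    200 nuclei per condition.
    """

    n_chromosomes: int = 3
    chrom_length: int = 10_000_000
    n_genes: int = 300
    gene_length_bp: tuple[int, int] = (5_000, 30_000)

    # planted gene sets (counts; the planting plan partitions the genes)
    n_planted_assoc_genes: int = 30      # Gfap-associated exclusively in LIF+
    n_planted_expr_genes: int = 30       # upregulated exclusively in LIF+
    n_planted_overlap: int = 20          # associated AND expressed (the truth set)
    n_assoc_other: int = 10              # per-condition exclusive assoc (NPC, LIF-)
    n_assoc_shared: int = 5              # associated in all three conditions
    n_expr_lifminus: int = 10            # upregulated exclusively in LIF-
    n_expr_shared: int = 10              # upregulated in both LIF+ and LIF-
    n_bait_peaks: int = 100              # cis contact cluster around the bait
    bait_peak_bp: int = 10_000           # width of each cis contact region

    # e4C signal model (log2 scale)
    interaction_signal_log2: float = 3.0
    noise_sd: float = 0.5

    # expression model
    spike_copies: tuple[float, ...] = (0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0)
    expr_fold_planted: float = 5.0
    base_copies_log10_mean: float = 0.6   # median ~4 copies/cell
    base_copies_log10_sd: float = 0.5
    expr_noise_sd: float = 0.25           # log2-scale intensity noise
    gain: float = 50.0                    # intensity units per copy
    background_floor: float = 5.0         # intensity floor

    # FISH model
    n_nuclei: int = 200
    nucleus_diameter: float = 10.1        # um, LIF+ default; per-condition means
    assoc_fraction: float = 0.4
    fish_threshold_um: float = 0.5

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.chrom_length <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name in ("n_planted_assoc_genes", "n_planted_expr_genes"):
            if getattr(self, name) > self.n_genes:
                raise ValueError(f"{name} exceeds n_genes")
        if self.n_planted_overlap > min(
            self.n_planted_assoc_genes, self.n_planted_expr_genes
        ):
            raise ValueError("n_planted_overlap exceeds a planted set size")
        if not 0.0 <= self.assoc_fraction <= 1.0:
            raise ValueError("assoc_fraction must lie in [0, 1]")
        if self.nucleus_diameter <= 1.0:
            raise ValueError("nucleus_diameter must exceed 1 um")
        if self.interaction_signal_log2 < 0 or self.noise_sd < 0:
            raise ValueError("signal parameters must be nonnegative")


def load_config(path: str | Path) -> tuple[SyntheticConfig, PipelineConfig]:
    """Read a YAML file with optional ``synthetic:`` and ``defaults:`` blocks."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    syn = raw.get("synthetic", {}) or {}
    if "spike_copies" in syn:
        syn["spike_copies"] = tuple(syn["spike_copies"])
    if "gene_length_bp" in syn:
        syn["gene_length_bp"] = tuple(syn["gene_length_bp"])
    return SyntheticConfig(**syn), PipelineConfig(**(raw.get("defaults", {}) or {}))


def dump_config(syn: SyntheticConfig, pipe: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {"synthetic": asdict(syn), "defaults": asdict(pipe)},
            sort_keys=False,
        )
    )
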