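"""End-to-end screen: e4C calling → gene mapping → expression filters →
candidate integration, with a run manifest and input validation."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import CONDITIONS, PipelineConfig
from .e4c import call_condition, peak_density_by_chromosome
from .expression import (
    fit_spike_calibration,
    percellome_normalize,
    upregulated_genes,
)
from .integrate import exclusive_association_sets, integrate_candidates
from .mapping import map_peaks_to_genes
from .motifs import PWM, scan_stat3
from .regions import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """All per-stage outputs of one end-to-end screen."""

    hits: dict[str, pd.DataFrame]
    peaks: dict[str, list[GenomicInterval]]
    peak_density: dict[str, pd.DataFrame]
    association: dict[str, list]
    assoc_sets: dict[str, set[str]]
    assoc_exclusive: dict[str, set[str]]
    assoc_overlaps: dict[frozenset, int]
    copies: pd.DataFrame
    upregulated: dict[str, set[str]]
    expr_exclusive: dict[str, set[str]]
    candidates: pd.DataFrame
    stat3_flags: dict[str, bool]


def run_screen(
    e4c_signals: pd.DataFrame,
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    expression_intensities: pd.DataFrame,
    spikes: pd.DataFrame,
    config: PipelineConfig | None = None,
    genome=None,
    pwm: PWM | None = None,
) -> ScreenResult:
    """Run the whole screen on in-memory inputs.

    Stages: (1) per-condition replicate-reproducible e4C hit calling and
    peak merging; (2) peak-to-gene mapping within 50 kb; (3) spike-in
    calibration of expression intensities to copies per cell and the
    two-fold/one-copy upregulation filters against NPCs; (4) intersection
    of the LIF+-exclusive association and expression sets, with optional
    STAT3 promoter scanning when a genome and PWM are supplied.
    """
    config = config or PipelineConfig()
    t0 = time.monotonic()

    hits, peaks, density, association, assoc_sets = {}, {}, {}, {}, {}
    for condition in CONDITIONS:
        h, p = call_condition(
            e4c_signals,
            condition,
            window_bp=config.window_bp,
            cutoff=config.ratio_cutoff,
            pseudocount=config.pseudocount,
            max_gap=config.max_gap_bp,
        )
        hits[condition], peaks[condition] = h, p
        density[condition] = peak_density_by_chromosome(p, chrom_sizes)
        records = map_peaks_to_genes(
            p, genes, condition, config.gene_distance_bp
        )
        association[condition] = records
        assoc_sets[condition] = {r.gene.gene_id for r in records}
        logger.info(
            "[e4c] %s: %d hits, %d peaks, %d associated genes",
            condition, len(h), len(p), len(records),
        )
    assoc_exclusive, assoc_overlaps = exclusive_association_sets(assoc_sets)

    calibrations = {}
    for condition in CONDITIONS:
        calibrations[condition] = fit_spike_calibration(
            spikes[spikes["condition"] == condition]
        )
    copies = percellome_normalize(expression_intensities, calibrations)
    upregulated = {
        cond: upregulated_genes(
            copies, cond, "NPC", config.expr_fold, config.expr_floor_copies
        )
        for cond in ("LIF+", "LIF-")
    }
    expr_exclusive = {
        "LIF+": upregulated["LIF+"] - upregulated["LIF-"],
        "LIF-": upregulated["LIF-"] - upregulated["LIF+"],
    }
    logger.info(
        "[expr] upregulated LIF+: %d, LIF-: %d, LIF+-exclusive: %d",
        len(upregulated["LIF+"]), len(upregulated["LIF-"]),
        len(expr_exclusive["LIF+"]),
    )

    candidate_ids = assoc_exclusive["LIF+"] & expr_exclusive["LIF+"]
    stat3_flags: dict[str, bool] = {}
    if genome is not None and pwm is not None:
        by_id = {g.gene_id: g for g in genes}
        for gid in sorted(candidate_ids):
            flag, _ = scan_stat3(
                by_id[gid], genome, pwm,
                config.stat3_window_bp, config.pwm_score_fraction,
            )
            stat3_flags[gid] = flag
    bins = {
        r.gene.gene_id: r.distance_bin for r in association["LIF+"]
    }
    symbols = {g.gene_id: g.symbol for g in genes}
    candidates = integrate_candidates(
        assoc_exclusive["LIF+"],
        expr_exclusive["LIF+"],
        copies,
        distance_bins=bins,
        stat3_flags=stat3_flags,
        symbols=symbols,
    )
    logger.info(
        "[integrate] %d candidate genes in %.1f s",
        len(candidates), time.monotonic() - t0,
    )
    return ScreenResult(
        hits=hits,
        peaks=peaks,
        peak_density=density,
        association=association,
        assoc_sets=assoc_sets,
        assoc_exclusive=assoc_exclusive,
        assoc_overlaps=assoc_overlaps,
        copies=copies,
        upregulated=upregulated,
        expr_exclusive=expr_exclusive,
        candidates=candidates,
        stat3_flags=stat3_flags,
    )


# ------------------------------------------------------------------ manifest

def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config: dict
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__
    started: str = ""
    finished: str = ""

    def add_input(self, name: str, path: str | Path) -> None:
        self.inputs[name] = f"{path}:sha256:{file_digest(path)}"

    def add_output(self, name: str, path: str | Path) -> None:
        self.outputs[name] = str(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


# ---------------------------------------------------------------- validation

def validate_inputs(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Schema-check input files; returns a per-file pass/fail report.

    ``paths`` maps a format name (bed6, gff3, chrom_sizes, probes, fish)
    to a file path. The report carries the first offending line number
    for failures. Never mutates inputs.
    """
    from . import io as gio

    checks = {
        "bed6": _check_bed6,
        "gff3": _check_gff3,
        "chrom_sizes": _check_chrom_sizes,
        "probes": _check_table(gio.PROBE_COLUMNS),
        "fish": _check_table(gio.FISH_COLUMNS),
    }
    rows = []
    for name, path in paths.items():
        kind = name.split(":")[0]
        checker = checks.get(kind)
        if checker is None:
            rows.append((name, str(path), False, "unknown format"))
            continue
        ok, message = checker(Path(path))
        rows.append((name, str(path), ok, message))
    return pd.DataFrame(rows, columns=["input", "path", "ok", "detail"])


def _check_bed6(path: Path) -> tuple[bool, str]:
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            return False, f"line {i}: fewer than 3 fields"
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError:
            return False, f"line {i}: non-integer coordinates"
        if not 0 <= start < end:
            return False, f"line {i}: end <= start"
    return True, "ok"


def _check_gff3(path: Path) -> tuple[bool, str]:
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            return False, f"line {i}: expected 9 fields, got {len(f)}"
        try:
            start, end = int(f[3]), int(f[4])
        except ValueError:
            return False, f"line {i}: non-integer coordinates"
        if not 1 <= start <= end:
            return False, f"line {i}: invalid 1-based span"
    return True, "ok"


def _check_chrom_sizes(path: Path) -> tuple[bool, str]:
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) != 2:
            return False, f"line {i}: expected chrom<TAB>length"
        try:
            if int(f[1]) <= 0:
                return False, f"line {i}: nonpositive length"
        except ValueError:
            return False, f"line {i}: non-integer length"
    return True, "ok"


def _check_table(required: list[str]):
    def check(path: Path) -> tuple[bool, str]:
        try:
            header = path.read_text().splitlines()[0].split("\t")
        except IndexError:
            return False, "empty file"
        missing = set(required) - set(header)
        if missing:
            return False, f"line 1: missing columns {sorted(missing)}"
        return True, "ok"

    return check


def cross_reference_chroms(
    gff3_path: str | Path, sizes_path: str | Path
) -> tuple[bool, str]:
    """Fail when the annotation references a chromosome absent from sizes."""
    from . import io as gio

    sizes = gio.read_chrom_sizes(sizes_path)
    for i, line in enumerate(Path(gff3_path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        chrom = line.split("\t", 1)[0]
        if chrom not in sizes:
            return False, f"line {i}: unknown chromosome {chrom!r}"
    return True, "ok"
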