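"""Synthetic study generator: every input the screen consumes, with truth.

The generator emulates the published study design at desk scale: a bait-
centric 4C-on-array experiment (two replicates per condition on a
BglII→NlaIII fragment array), Percellome-style expression arrays with
dose-graded spike mRNAs, and per-nucleus 3D DNA-FISH coordinates. Planted
ground truth (which genes are bait-associated and/or LIF+-expressed, which
nuclei carry a <500 nm association) is retained so parameter-recovery tests
can score the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    BGLII_SITE,
    CONDITIONS,
    NLAIII_SITE,
    NUCLEAR_DIAMETER_UM,
    SyntheticConfig,
)
from .regions import Fragment, GeneModel, GenomicInterval

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config_seed])


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ------------------------------------------------------------------- genome

def simulate_genome(
    config: SyntheticConfig,
) -> tuple[dict[str, int], list[GeneModel]]:
    """Simulate chromosome sizes and a non-overlapping gene annotation.

    Genes are distributed round-robin over chromosomes and placed by
    partitioning the free space between them, so no two genes on a
    chromosome overlap. Deterministic given ``config.seed``.
    """
    rng = _rng(config.seed, 1)
    sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)
    }
    per_chrom: dict[str, int] = {c: 0 for c in sizes}
    chrom_names = list(sizes)
    for i in range(config.n_genes):
        per_chrom[chrom_names[i % len(chrom_names)]] += 1

    lo, hi = config.gene_length_bp
    min_gap = 1_000
    genes: list[GeneModel] = []
    idx = 0
    for chrom in chrom_names:
        n = per_chrom[chrom]
        if n == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n)
        free = config.chrom_length - int(lengths.sum()) - (n + 1) * min_gap
        if free < 0:
            raise ValueError(
                f"{n} genes of {lo}-{hi} bp do not fit on a "
                f"{config.chrom_length}-bp chromosome"
            )
        # split the free space into n+1 random gaps
        cuts = np.sort(rng.integers(0, free + 1, size=n))
        gaps = np.diff(np.concatenate([[0], cuts, [free]])) + min_gap
        pos = 0
        for k in range(n):
            pos += int(gaps[k])
            start = pos
            end = start + int(lengths[k])
            pos = end
            idx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"G{idx:04d}",
                    symbol=f"Gene{idx:04d}",
                    interval=GenomicInterval(chrom, start, end, strand),
                )
            )
    return sizes, genes


def simulate_sequences(config: SyntheticConfig) -> dict[str, str]:
    """Uniform-random ACGT sequence per chromosome (seeded)."""
    rng = _rng(config.seed, 2)
    return {
        f"chr{i + 1}": _BASES[rng.integers(0, 4, size=config.chrom_length)]
        .tobytes()
        .decode("ascii")
        for i in range(config.n_chromosomes)
    }


# ----------------------------------------------------------------- digestion

def find_sites(sequence: str, site: str) -> list[int]:
    """All (possibly overlapping) occurrence start positions of ``site``."""
    positions = []
    start = sequence.find(site)
    while start != -1:
        positions.append(start)
        start = sequence.find(site, start + 1)
    return positions


def _adjacent_ab_fragments(
    sequence: str, site_a: str, site_b: str
) -> list[tuple[int, int]]:
    """Intervals [pa, pb) where an a-cut is immediately followed by a b-cut."""
    cuts = [(p, "a") for p in find_sites(sequence, site_a)]
    cuts += [(p, "b") for p in find_sites(sequence, site_b)]
    cuts.sort()
    out = []
    for (pa, la), (pb, lb) in zip(cuts, cuts[1:]):
        if la == "a" and lb == "b" and pb > pa:
            out.append((pa, pb))
    return out


def digest_double(
    sequence: str,
    enzyme_a: str = BGLII_SITE,
    enzyme_b: str = NLAIII_SITE,
    min_len: int = 100,
    chrom: str = "chr",
) -> list[Fragment]:
    """Enumerate a→b double-digest fragments on both strands.

    A fragment runs from an ``enzyme_a`` cut (the recognition site's 5'
    coordinate) to the nearest downstream ``enzyme_b`` cut with no
    intervening cut of either enzyme; the same scan is applied to the
    reverse complement and mapped back to forward coordinates. Fragments
    of length <= ``min_len`` are discarded (the array keeps only
    fragments above the size floor).
    """
    for name, site in (("enzyme_a", enzyme_a), ("enzyme_b", enzyme_b)):
        if not site:
            raise ValueError(f"{name} recognition site must be non-empty")
        if set(site.upper()) - set("ACGT"):
            raise ValueError(
                f"{name} site {site!r}: ambiguous IUPAC codes are unsupported"
            )
    if min_len < 0:
        raise ValueError("min_len must be >= 0")

    seq = sequence.upper()
    a, b = enzyme_a.upper(), enzyme_b.upper()
    n = len(seq)
    fragments: list[Fragment] = []
    for pa, pb in _adjacent_ab_fragments(seq, a, b):
        if pb - pa > min_len:
            fragments.append(
                Fragment(GenomicInterval(chrom, pa, pb), "a", "b", "+")
            )
    rc = reverse_complement(seq)
    for pa, pb in _adjacent_ab_fragments(rc, a, b):
        if pb - pa > min_len:
            fragments.append(
                Fragment(GenomicInterval(chrom, n - pb, n - pa), "b", "a", "-")
            )
    fragments.sort(key=lambda f: (f.interval.start, f.interval.end, f.orientation))
    return fragments


def probes_from_fragments(
    fragments_by_chrom: dict[str, list[Fragment]], probe_len: int = 60
) -> pd.DataFrame:
    """One probe per qualifying fragment, anchored at the BglII (enzyme-a) end.

    Forward-orientation fragments carry the a-cut at their left boundary,
    reverse-orientation ones at their right boundary; the probe is the
    ``probe_len`` bp of the fragment adjacent to that boundary.
    """
    rows = []
    i = 0
    for chrom, fragments in fragments_by_chrom.items():
        for frag in fragments:
            iv = frag.interval
            if frag.orientation == "+":
                start, end = iv.start, min(iv.start + probe_len, iv.end)
            else:
                start, end = max(iv.end - probe_len, iv.start), iv.end
            rows.append((f"probe_{i:06d}", chrom, start, end, frag.orientation))
            i += 1
    return pd.DataFrame(
        rows, columns=["probe_id", "chrom", "start", "end", "orientation"]
    )


# ---------------------------------------------------------------- e4C arrays

def simulate_e4c_arrays(
    probes: pd.DataFrame,
    planted: dict[str, list[GenomicInterval]],
    config: SyntheticConfig,
    control_intensity: float = 500.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-replicate two-channel probe tables per condition, plus truth.

    Probes overlapping a planted interval of a condition draw their log2
    ratio around ``interaction_signal_log2``; background probes around 0;
    replicate noise is independent Gaussian on the log2 scale. Intensities
    are reconstructed as ``e4c = control * 2**ratio``.
    """
    rng = _rng(config.seed, 3)
    signal_tables = []
    truth_tables = []
    starts = probes["start"].to_numpy()
    ends = probes["end"].to_numpy()
    chroms = probes["chrom"].to_numpy()
    for condition in CONDITIONS:
        mask = np.zeros(len(probes), dtype=bool)
        for iv in planted.get(condition, []):
            mask |= (chroms == iv.chrom) & (starts < iv.end) & (ends > iv.start)
        mean = np.where(mask, config.interaction_signal_log2, 0.0)
        for replicate in (1, 2):
            ratio = mean + rng.normal(0.0, config.noise_sd, size=len(probes)) \
                if config.noise_sd > 0 else mean.astype(float)
            table = probes[["probe_id", "chrom", "start", "end"]].copy()
            table["e4c"] = control_intensity * np.exp2(ratio)
            table["control"] = control_intensity
            table["replicate"] = replicate
            table["condition"] = condition
            signal_tables.append(table)
        truth = probes[["probe_id"]].copy()
        truth["condition"] = condition
        truth["planted"] = mask
        truth_tables.append(truth)
    return (
        pd.concat(signal_tables, ignore_index=True),
        pd.concat(truth_tables, ignore_index=True),
    )


# --------------------------------------------------------------- expression

def simulate_expression(
    genes: list[GeneModel],
    planted_lifplus: set[str],
    planted_shared: set[str],
    config: SyntheticConfig,
    planted_lifminus: set[str] = frozenset(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Raw intensity tables for NPC / LIF+ / LIF- with dosed spike mRNAs.

    Returns ``(intensities, spike_table, true_copies)``. Intensity is
    ``gain * copies`` with multiplicative log2-Gaussian noise, clipped from
    below at the scanner background floor. Planted LIF+ genes have true
    LIF+/NPC fold = ``expr_fold_planted`` and LIF-/NPC fold 1 (and
    symmetrically for the other planted sets).
    """
    if len(config.spike_copies) == 0:
        raise ValueError("spike set is empty: per-cell calibration impossible")
    if len({c for c in config.spike_copies if c > 0}) < 2:
        raise ValueError("need >= 2 distinct positive spike doses to calibrate")

    rng = _rng(config.seed, 4)
    ids = [g.gene_id for g in genes]
    base = 10.0 ** rng.normal(
        config.base_copies_log10_mean, config.base_copies_log10_sd, size=len(ids)
    )
    planted_any = planted_lifplus | planted_shared | planted_lifminus
    # keep planted effects detectable above the one-copy floor
    base = np.array(
        [max(b, 0.5) if gid in planted_any else b for gid, b in zip(ids, base)]
    )
    copies = pd.DataFrame(
        {c: base.copy() for c in CONDITIONS}, index=pd.Index(ids, name="gene_id")
    )
    for gid in planted_lifplus | planted_shared:
        copies.loc[gid, "LIF+"] *= config.expr_fold_planted
    for gid in planted_lifminus | planted_shared:
        copies.loc[gid, "LIF-"] *= config.expr_fold_planted

    def noisy(values: np.ndarray) -> np.ndarray:
        if config.expr_noise_sd > 0:
            values = values * np.exp2(
                rng.normal(0.0, config.expr_noise_sd, size=len(values))
            )
        return np.maximum(values * 0 + config.background_floor, values)

    intensities = pd.DataFrame(index=copies.index)
    spike_rows = []
    for condition in CONDITIONS:
        intensities[condition] = noisy(config.gain * copies[condition].to_numpy())
        spike_int = noisy(config.gain * np.asarray(config.spike_copies))
        for i, (dose, inten) in enumerate(zip(config.spike_copies, spike_int)):
            spike_rows.append((f"spike_{i:02d}", condition, dose, inten))
    spikes = pd.DataFrame(
        spike_rows,
        columns=["spike_id", "condition", "known_copies_per_cell", "intensity"],
    )
    return intensities.reset_index(), spikes, copies.reset_index()


# --------------------------------------------------------------------- FISH

@dataclass
class FishDataset:
    """Per-nucleus FISH coordinates with geometry and planted-truth tables."""

    signals: pd.DataFrame   # nucleus_id, condition, gene, allele, x_um, y_um, z_um[, active]
    nuclei: pd.DataFrame    # nucleus_id, condition, diameter_um
    truth: pd.DataFrame     # nucleus_id, condition, gene, planted


def _uniform_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * radius * rng.random() ** (1.0 / 3.0)


def _near_point(
    rng: np.random.Generator, anchor: np.ndarray, reach: float, radius: float
) -> np.ndarray:
    """Uniform point within ``reach`` of ``anchor``, inside the nucleus."""
    for _ in range(1000):
        p = anchor + _uniform_in_sphere(rng, reach)
        if np.linalg.norm(p) <= radius:
            return p
    return anchor  # anchor is inside by construction; unreachable in practice


def simulate_fish(
    config: SyntheticConfig,
    pairs: list[tuple[str, str]],
    assoc_fraction: dict[str, float] | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
    activity: bool = False,
    active_assoc_fraction: dict[str, float] | None = None,
) -> FishDataset:
    """Simulate diploid nuclei with two FISH signals per gene.

    Each nucleus is a sphere whose diameter is drawn from the condition's
    published mean +/- sd. The first gene of each pair is the bait; with
    probability ``assoc_fraction[condition]`` one partner allele is placed
    within 500 nm of a bait allele, otherwise uniformly in the sphere.
    With ``activity=True`` bait alleles are labeled active/inactive
    (random monoallelic expression) and the planted partner is anchored on
    the active allele with probability ``active_assoc_fraction`` instead.
    """
    fractions = assoc_fraction or {c: config.assoc_fraction for c in conditions}
    for cond, frac in fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"assoc_fraction[{cond!r}]={frac} outside [0, 1]")
    rng = _rng(config.seed, 5)
    reach = config.fish_threshold_um
    sig_rows, nuc_rows, truth_rows = [], [], []
    for condition in conditions:
        mean, sd = NUCLEAR_DIAMETER_UM.get(
            condition, (config.nucleus_diameter, 0.0)
        )
        for k in range(config.n_nuclei):
            nid = f"{condition}_{k:04d}"
            diameter = max(2.0, rng.normal(mean, sd)) if sd > 0 else mean
            radius = diameter / 2.0
            nuc_rows.append((nid, condition, diameter))
            for bait, partner in pairs:
                b1 = _uniform_in_sphere(rng, radius)
                b2 = _uniform_in_sphere(rng, radius)
                active_first = bool(rng.random() < 0.5)
                baits = [(1, b1, active_first), (2, b2, not active_first)]
                for allele, pos, act in baits:
                    sig_rows.append(
                        (nid, condition, bait, allele, *pos, act if activity else None)
                    )
                if activity and active_assoc_fraction is not None:
                    frac = active_assoc_fraction[condition]
                    anchor = next(p for _, p, act in baits if act)
                else:
                    frac = fractions[condition]
                    anchor = baits[int(rng.random() < 0.5)][1]
                planted = bool(rng.random() < frac)
                p1 = (
                    _near_point(rng, np.asarray(anchor), reach, radius)
                    if planted
                    else _uniform_in_sphere(rng, radius)
                )
                p2 = _uniform_in_sphere(rng, radius)
                sig_rows.append((nid, condition, partner, 1, *p1, None))
                sig_rows.append((nid, condition, partner, 2, *p2, None))
                truth_rows.append((nid, condition, partner, planted))
    signals = pd.DataFrame(
        sig_rows,
        columns=[
            "nucleus_id", "condition", "gene", "allele",
            "x_um", "y_um", "z_um", "active",
        ],
    )
    if not activity:
        signals = signals.drop(columns=["active"])
    nuclei = pd.DataFrame(nuc_rows, columns=["nucleus_id", "condition", "diameter_um"])
    truth = pd.DataFrame(
        truth_rows, columns=["nucleus_id", "condition", "gene", "planted"]
    )
    return FishDataset(signals=signals, nuclei=nuclei, truth=truth)


# ------------------------------------------------------------------- bundle

@dataclass
class SyntheticBundle:
    """Everything the screen consumes, plus planted ground truth."""

    config: SyntheticConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    sequences: dict[str, str]
    probes: pd.DataFrame
    e4c_signals: pd.DataFrame
    e4c_truth: pd.DataFrame
    expression_intensities: pd.DataFrame
    spikes: pd.DataFrame
    true_copies: pd.DataFrame
    planted_assoc: dict[str, set[str]]   # condition -> gene_ids with planted contacts
    planted_expr: dict[str, set[str]]    # condition -> gene_ids upregulated vs NPC
    truth_candidates: set[str]           # associated AND expressed exclusively in LIF+
    bait: GenomicInterval = None


def _planted_interval(gene: GeneModel, pad: int = 20_000) -> GenomicInterval:
    iv = gene.interval
    return GenomicInterval(iv.chrom, max(0, iv.start - pad), iv.end + pad, ".")


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the full synthetic study with planted ground truth.

    The planting plan partitions a random subset of genes into
    condition-exclusive and shared associated/expressed sets; the truth
    candidate set is the ``n_planted_overlap`` genes planted as both
    LIF+-exclusively associated and LIF+-exclusively upregulated. A cis
    cluster of ``n_bait_peaks`` contacts around the bait locus is planted
    in every condition, making the bait chromosome the densest in peaks.
    """
    sizes, genes = simulate_genome(config)
    sequences = simulate_sequences(config)
    fragments = {
        chrom: digest_double(seq, BGLII_SITE, NLAIII_SITE, 100, chrom)
        for chrom, seq in sequences.items()
    }
    probes = probes_from_fragments(fragments)

    rng = _rng(config.seed, 6)
    order = rng.permutation(len(genes))
    cursor = 0
    picked_so_far: list[GeneModel] = []
    # Planted genes must sit outside each other's peak-capture window
    # (planted pad + mapping distance) and outside the bait's cis cluster,
    # otherwise the truth labels would contradict themselves: a gene within
    # capture reach of another condition's planted contact genuinely is
    # associated in that condition.
    bait_chrom = "chr1"
    bait_center = config.chrom_length // 2
    bait_spread = min(1_000_000, config.chrom_length // 10)
    exclusion_bp = 20_000 + 50_000 + 10_000
    bait_reach = bait_spread + config.bait_peak_bp + exclusion_bp

    def eligible(gene: GeneModel) -> bool:
        iv = gene.interval
        if iv.chrom == bait_chrom and (
            iv.end > bait_center - bait_reach
            and iv.start < bait_center + bait_reach
        ):
            return False
        return all(
            g.interval.chrom != iv.chrom
            or g.interval.gap_to(iv) > exclusion_bp
            for g in picked_so_far
        )

    def take(n: int) -> list[GeneModel]:
        nonlocal cursor
        picked: list[GeneModel] = []
        while len(picked) < n:
            if cursor >= len(order):
                raise ValueError(
                    "not enough well-separated genes for the planting plan; "
                    "increase n_genes or chromosome length"
                )
            gene = genes[order[cursor]]
            cursor += 1
            if eligible(gene):
                picked.append(gene)
                picked_so_far.append(gene)
        return picked

    overlap = take(config.n_planted_overlap)
    assoc_only = take(config.n_planted_assoc_genes - config.n_planted_overlap)
    expr_only = take(config.n_planted_expr_genes - config.n_planted_overlap)
    assoc_npc = take(config.n_assoc_other)
    assoc_lifminus = take(config.n_assoc_other)
    assoc_shared = take(config.n_assoc_shared)
    expr_lifminus = take(config.n_expr_lifminus)
    expr_shared = take(config.n_expr_shared)

    assoc_sets = {
        "NPC": assoc_npc + assoc_shared,
        "LIF+": overlap + assoc_only + assoc_shared,
        "LIF-": assoc_lifminus + assoc_shared,
    }
    bait = GenomicInterval(
        bait_chrom, bait_center, bait_center + 2_000
    )
    bait_peaks = []
    width = config.bait_peak_bp
    for i in range(config.n_bait_peaks):
        offset = int(rng.integers(-bait_spread, bait_spread))
        start = min(max(0, bait.start + offset), config.chrom_length - width - 1)
        bait_peaks.append(GenomicInterval(bait_chrom, start, start + width))

    planted_intervals = {
        cond: [_planted_interval(g) for g in gene_list] + bait_peaks
        for cond, gene_list in assoc_sets.items()
    }
    e4c_signals, e4c_truth = simulate_e4c_arrays(probes, planted_intervals, config)

    expr_lifplus_ids = {g.gene_id for g in overlap + expr_only}
    expr_shared_ids = {g.gene_id for g in expr_shared}
    expr_lifminus_ids = {g.gene_id for g in expr_lifminus}
    intensities, spikes, true_copies = simulate_expression(
        genes, expr_lifplus_ids, expr_shared_ids, config, expr_lifminus_ids
    )

    return SyntheticBundle(
        config=config,
        chrom_sizes=sizes,
        genes=genes,
        sequences=sequences,
        probes=probes,
        e4c_signals=e4c_signals,
        e4c_truth=e4c_truth,
        expression_intensities=intensities,
        spikes=spikes,
        true_copies=true_copies,
        planted_assoc={c: {g.gene_id for g in s} for c, s in assoc_sets.items()},
        planted_expr={
            "LIF+": expr_lifplus_ids | expr_shared_ids,
            "LIF-": expr_lifminus_ids | expr_shared_ids,
        },
        truth_candidates={g.gene_id for g in overlap},
        bait=bait,
    )
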