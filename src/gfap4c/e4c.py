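"""e4C hit calling: probe log-ratios, sliding-window smoothing, replicate-
reproducible hits, peak merging and per-chromosome peak densities.

The calling rule follows the published screen: the per-probe
log2(e4C signal / genomic control) is smoothed over a 200-bp sliding window
and probes at or above a cutoff of 2 in both biological replicates are e4C
hits; runs of adjacent hits form peaks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .regions import GenomicInterval


def compute_probe_ratios(probes: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Add a ``log2_ratio`` column: log2((e4c + pc) / (control + pc)).

    Order-preserving with the input. With ``pseudocount=0`` any probe with
    both channels at zero raises, since its ratio is undefined.
    """
    if len(probes) == 0:
        raise ValueError("empty probe table")
    e4c = probes["e4c"].to_numpy(dtype=float)
    control = probes["control"].to_numpy(dtype=float)
    if np.any(e4c < 0) or np.any(control < 0):
        raise ValueError("intensities must be nonnegative")
    if pseudocount == 0 and np.any((e4c == 0) & (control == 0)):
        raise ValueError("both channels zero with pseudocount 0: ratio undefined")
    out = probes.copy()
    out["log2_ratio"] = np.log2((e4c + pseudocount) / (control + pseudocount))
    return out


def smooth_sliding_window(track: pd.DataFrame, window_bp: int = 200) -> pd.DataFrame:
    """Mean log2 ratio over probes within +/- window_bp/2 of each midpoint.

    Windows are probe-centric (no genome grid): each probe's smoothed value
    averages every same-chromosome probe whose midpoint lies within half a
    window of its own. A probe with no neighbours keeps its own ratio.
    """
    out = track.copy()
    smoothed = np.empty(len(track), dtype=float)
    half = window_bp / 2.0
    mids_all = (track["start"].to_numpy() + track["end"].to_numpy()) / 2.0
    ratios_all = track["log2_ratio"].to_numpy(dtype=float)
    for chrom, idx in track.groupby("chrom", sort=False).indices.items():
        mids = mids_all[idx]
        order = np.argsort(mids, kind="stable")
        m = mids[order]
        r = ratios_all[idx][order]
        csum = np.concatenate([[0.0], np.cumsum(r)])
        lo = np.searchsorted(m, m - half, side="left")
        hi = np.searchsorted(m, m + half, side="right")
        vals = (csum[hi] - csum[lo]) / (hi - lo)
        smoothed[idx[order]] = vals
    out["smoothed_ratio"] = smoothed
    return out


def call_positive_probes(track: pd.DataFrame, cutoff: float = 2.0) -> pd.DataFrame:
    """Probes whose smoothed ratio is at or above the cutoff (inclusive)."""
    if "smoothed_ratio" not in track.columns:
        raise ValueError("track lacks smoothed_ratio; smooth before calling")
    return track[track["smoothed_ratio"] >= cutoff].copy()


def reproducible_hits(rep1: pd.DataFrame, rep2: pd.DataFrame) -> pd.DataFrame:
    """Intersection of two replicate hit lists by probe_id.

    Both replicates must come from the same array design; the smoothed
    ratio reported for a reproducible hit is the replicate mean.
    """
    ids1, ids2 = set(rep1["probe_id"]), set(rep2["probe_id"])
    common = ids1 & ids2
    out = rep1[rep1["probe_id"].isin(common)].copy()
    mean2 = rep2.set_index("probe_id")["smoothed_ratio"]
    out["smoothed_ratio"] = (
        out["smoothed_ratio"].to_numpy()
        + mean2.loc[out["probe_id"]].to_numpy()
    ) / 2.0
    out["replicate_support"] = "both"
    return out


def merge_hits_to_peaks(hits: pd.DataFrame, max_gap: int = 0) -> list[GenomicInterval]:
    """Merge hit probes whose gap is <= max_gap into peak intervals.

    Touching or overlapping probes always merge. Output intervals are
    sorted and pairwise non-overlapping.
    """
    if len(hits) == 0:
        return []
    peaks: list[GenomicInterval] = []
    ordered = hits.sort_values(["chrom", "start", "end"])
    cur_chrom, cur_start, cur_end = None, None, None
    for chrom, start, end in zip(ordered["chrom"], ordered["start"], ordered["end"]):
        if chrom == cur_chrom and start - cur_end <= max_gap:
            cur_end = max(cur_end, end)
        else:
            if cur_chrom is not None:
                peaks.append(GenomicInterval(cur_chrom, int(cur_start), int(cur_end)))
            cur_chrom, cur_start, cur_end = chrom, start, end
    peaks.append(GenomicInterval(cur_chrom, int(cur_start), int(cur_end)))
    return peaks


def peak_density_by_chromosome(
    peaks: list[GenomicInterval], chrom_sizes: dict[str, int]
) -> pd.DataFrame:
    """Peaks per chromosome and per Mb, zero-filled over all chromosomes."""
    counts = {chrom: 0 for chrom in chrom_sizes}
    for peak in peaks:
        if peak.chrom not in counts:
            raise KeyError(f"peak chromosome {peak.chrom!r} not in chrom sizes")
        counts[peak.chrom] += 1
    rows = [
        (chrom, counts[chrom], counts[chrom] / (size / 1e6))
        for chrom, size in chrom_sizes.items()
    ]
    return pd.DataFrame(rows, columns=["chrom", "n_peaks", "peaks_per_Mb"])


def call_condition(
    signals: pd.DataFrame,
    condition: str,
    window_bp: int = 200,
    cutoff: float = 2.0,
    pseudocount: float = 1.0,
    max_gap: int = 0,
) -> tuple[pd.DataFrame, list[GenomicInterval]]:
    """Full calling chain for one condition: ratios → smooth → hits in both
    replicates → peaks. Returns (reproducible hits, peaks)."""
    subset = signals[signals["condition"] == condition]
    reps = []
    for replicate in (1, 2):
        rep = subset[subset["replicate"] == replicate]
        track = compute_probe_ratios(rep, pseudocount)
        track = smooth_sliding_window(track, window_bp)
        reps.append(call_positive_probes(track, cutoff))
    hits = reproducible_hits(reps[0], reps[1])
    return hits, merge_hits_to_peaks(hits, max_gap)
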