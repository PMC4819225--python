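"""Spike-in (Percellome-style) expression calibration and set logic.

Array intensities are converted to absolute mRNA copies per cell by fitting
a log-log least-squares line through dose-graded external spike mRNAs and
inverting it. Upregulated genes are those with at least a two-fold copy
increase whose copy number clears the one-copy-per-cell floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

#: denominator guard, far below any observed copy floor
EPSILON_COPIES = 0.01


@dataclass(frozen=True)
class SpikeCalibration:
    """Log-log line log10(intensity) = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    residual_sd: float
    n_spikes: int

    @property
    def gain(self) -> float:
        """Intensity units per copy implied at slope 1."""
        return 10.0 ** self.intercept

    def to_copies(self, intensity: np.ndarray) -> np.ndarray:
        """Invert the calibration; zero intensity maps to zero copies."""
        intensity = np.asarray(intensity, dtype=float)
        if np.any(intensity < 0):
            raise ValueError("negative intensity")
        with np.errstate(divide="ignore"):
            logi = np.log10(intensity)
        copies = 10.0 ** ((logi - self.intercept) / self.slope)
        return np.where(intensity > 0, copies, 0.0)


def fit_spike_calibration(spikes: pd.DataFrame) -> SpikeCalibration:
    """Least-squares fit of log10 intensity against log10 known copies.

    Spikes at zero dose (background controls) are excluded from the fit;
    at least two distinct positive doses are required.
    """
    pos = spikes[spikes["known_copies_per_cell"] > 0]
    doses = pos["known_copies_per_cell"].to_numpy(dtype=float)
    intens = pos["intensity"].to_numpy(dtype=float)
    if len(np.unique(doses)) < 2:
        raise ValueError(
            "calibration needs >= 2 spikes with distinct positive doses"
        )
    if np.any(intens <= 0):
        raise ValueError("positive-dose spike with nonpositive intensity")
    x, y = np.log10(doses), np.log10(intens)
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ np.array([slope, intercept])
    dof = max(len(x) - 2, 1)
    return SpikeCalibration(
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n_spikes=len(x),
    )


def percellome_normalize(
    raw: pd.DataFrame,
    calibrations: dict[str, SpikeCalibration],
    gene_column: str = "gene_id",
) -> pd.DataFrame:
    """Convert per-condition intensity columns to copies per cell.

    ``raw`` has a gene-id column plus one intensity column per condition;
    each condition must have its own fitted calibration.
    """
    out = pd.DataFrame({gene_column: raw[gene_column]})
    for condition, cal in calibrations.items():
        out[condition] = cal.to_copies(raw[condition].to_numpy(dtype=float))
    return out.set_index(gene_column)


def upregulated_genes(
    expr: pd.DataFrame,
    numerator: str,
    denominator: str,
    fold: float = 2.0,
    floor: float = 1.0,
) -> set[str]:
    """Genes upregulated at least ``fold``-fold, above the copy floor.

    The floor applies to the numerator condition: a gene below one copy
    per cell is not considered expressed. Fold comparisons are inclusive
    ("at least two-fold"). The denominator is guarded at EPSILON_COPIES.
    """
    num = expr[numerator].to_numpy(dtype=float)
    den = np.maximum(expr[denominator].to_numpy(dtype=float), EPSILON_COPIES)
    keep = (num >= floor) & (num / den >= fold)
    return set(expr.index[keep])


def venn_partition(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts of 2 or 3 named sets.

    Keys are sorted tuples of set names; a gene is counted in exactly the
    region of every set containing it, so counts sum to the union size.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_partition takes 2 or 3 sets")
    names = sorted(sets)
    regions: dict[tuple[str, ...], int] = {}
    for mask in product([False, True], repeat=len(names)):
        if not any(mask):
            continue
        members = [names[i] for i in range(len(names)) if mask[i]]
        others = [names[i] for i in range(len(names)) if not mask[i]]
        region = set.intersection(*(sets[n] for n in members))
        for n in others:
            region -= sets[n]
        regions[tuple(members)] = len(region)
    return regions
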