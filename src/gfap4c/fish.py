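"""3D DNA-FISH spatial-association scoring and the screen's statistics.

A nucleus counts as associated for a gene pair when the shortest Euclidean
distance over all allele pairs is within 500 nm (inclusive). Association
frequencies across conditions are compared by residual analysis of
chi-squared tests (Haberman adjusted standardized residuals); allele-level
activity contrasts use Fisher's exact test; distance distributions use the
two-sample Kolmogorov-Smirnov test; nuclear diameters use one-way ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------- distances

def min_pair_distance(signals_a: np.ndarray, signals_b: np.ndarray) -> float:
    """Shortest Euclidean distance over all A x B signal pairs (um)."""
    a = np.atleast_2d(np.asarray(signals_a, dtype=float))
    b = np.atleast_2d(np.asarray(signals_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("need at least one signal per gene")
    return float(cdist(a, b).min())


def call_association(distance_um: float, threshold_um: float = 0.5) -> bool:
    """Associated iff the distance is within the threshold (inclusive)."""
    if distance_um < 0:
        raise ValueError("distance must be nonnegative")
    return distance_um <= threshold_um


def pair_distances(
    signals: pd.DataFrame, gene_a: str, gene_b: str
) -> pd.DataFrame:
    """Per-nucleus min distance between two genes' signals.

    Nuclei missing a signal for either gene are skipped and counted in
    the log (hybridization dropout).
    """
    rows = []
    skipped = 0
    coords = ["x_um", "y_um", "z_um"]
    for (nid, condition), group in signals.groupby(
        ["nucleus_id", "condition"], sort=False
    ):
        a = group.loc[group["gene"] == gene_a, coords].to_numpy()
        b = group.loc[group["gene"] == gene_b, coords].to_numpy()
        if len(a) == 0 or len(b) == 0:
            skipped += 1
            continue
        rows.append((nid, condition, min_pair_distance(a, b)))
    if skipped:
        logger.info(
            "pair_distances(%s, %s): skipped %d nuclei missing a signal",
            gene_a, gene_b, skipped,
        )
    return pd.DataFrame(rows, columns=["nucleus_id", "condition", "distance_um"])


def association_frequencies(
    signals: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    conditions: list[str] | None = None,
    threshold_um: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition association counts and the 2 x k contingency table.

    Returns ``(frequencies, table)`` where ``table`` has rows
    associated/not associated and one column per condition.
    """
    dist = pair_distances(signals, gene_a, gene_b)
    if conditions is None:
        conditions = list(dict.fromkeys(dist["condition"]))
    rows = []
    table = {}
    for condition in conditions:
        d = dist.loc[dist["condition"] == condition, "distance_um"]
        if len(d) == 0:
            logger.warning("condition %r has no evaluable nuclei", condition)
            continue
        n_assoc = int((d <= threshold_um).sum())
        rows.append((condition, n_assoc, len(d), n_assoc / len(d)))
        table[condition] = [n_assoc, len(d) - n_assoc]
    freq = pd.DataFrame(
        rows, columns=["condition", "n_assoc", "n_total", "fraction"]
    )
    contingency = pd.DataFrame(table, index=["associated", "not_associated"])
    return freq, contingency


# ---------------------------------------------------------------- statistics

@dataclass(frozen=True)
class ChiSquareResidualResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray
    adjusted_residuals: np.ndarray
    significant_05: np.ndarray   # |z| > 1.96
    significant_01: np.ndarray   # |z| > 2.58


def chisq_residual_test(table) -> ChiSquareResidualResult:
    """Chi-squared independence test with Haberman adjusted residuals.

    The adjusted standardized residual of cell (i, j) is
    (O - E) / sqrt(E (1 - row_i/N) (1 - col_j/N)); it is approximately
    standard normal under independence, so cells are flagged at
    |z| > 1.96 (P < 0.05) and |z| > 2.58 (P < 0.01).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.size == 0:
        raise ValueError("table must be 2-dimensional")
    if np.any(obs < 0):
        raise ValueError("table entries must be nonnegative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if total <= 0 or np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate table: a zero margin")
    expected = np.outer(row, col) / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    denom = np.sqrt(
        expected
        * np.outer(1.0 - row / total, 1.0 - col / total)
    )
    adj = (obs - expected) / denom
    return ChiSquareResidualResult(
        chi2=chi2,
        df=df,
        p=p,
        expected=expected,
        adjusted_residuals=adj,
        significant_05=np.abs(adj) > 1.96,
        significant_01=np.abs(adj) > 2.58,
    )


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test; returns (odds ratio, p).

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one.
    The odds ratio is (ad)/(bc), Haldane 1/2-corrected when any cell is 0.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    _, p = stats.fisher_exact(obs, alternative="two-sided")
    a, b, c, d = obs.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c)), float(p)


def ks_two_sample(
    distances_a, distances_b, exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on distance distributions.

    Uses the exact null distribution when both samples have at most
    ``exact_max_n`` observations, the asymptotic Kolmogorov distribution
    otherwise.
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if max(len(a), len(b)) <= exact_max_n else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def anova_oneway(*groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA; returns (F, df_between, df_within, p)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least two values")
    if all(np.ptp(g) == 0 for g in arrays) and len(
        {float(g[0]) for g in arrays}
    ) == 1:
        raise ValueError("zero variance everywhere: F undefined")
    res = stats.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = sum(len(g) for g in arrays) - len(arrays)
    return float(res.statistic), df1, df2, float(res.pvalue)


# ------------------------------------------------------- allele-level analyses

def allele_activity_association(
    signals: pd.DataFrame,
    bait: str,
    partner: str,
    threshold_um: float = 0.5,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Active/inactive bait alleles vs <=500 nm association with the partner.

    Each bait allele (not each nucleus) is called associated when its
    distance to the nearest partner allele is within the threshold; the
    resulting 2x2 table (rows active/inactive, columns associated/not)
    feeds Fisher's exact test.
    """
    if "active" not in signals.columns:
        raise ValueError("signals carry no allele-activity labels")
    coords = ["x_um", "y_um", "z_um"]
    counts = np.zeros((2, 2), dtype=int)
    for nid, group in signals.groupby("nucleus_id", sort=False):
        baits = group[(group["gene"] == bait) & group["active"].notna()]
        partners = group.loc[group["gene"] == partner, coords].to_numpy()
        if len(baits) == 0 or len(partners) == 0:
            continue
        for _, row in baits.iterrows():
            pos = row[coords].to_numpy(dtype=float)[None, :]
            associated = cdist(pos, partners).min() <= threshold_um
            i = 0 if bool(row["active"]) else 1
            counts[i, 0 if associated else 1] += 1
    if counts.sum() == 0:
        raise ValueError("no labeled bait alleles found")
    table = pd.DataFrame(
        counts,
        index=["active", "inactive"],
        columns=["associated", "not_associated"],
    )
    return table, fisher_exact_2x2(counts)


def triple_colocalization(
    signals: pd.DataFrame,
    genes: tuple[str, str, str],
    threshold_um: float = 0.5,
) -> tuple[float, int]:
    """Fraction of nuclei where all three pairwise min distances are within
    the threshold. Returns (fraction, n evaluable nuclei)."""
    coords = ["x_um", "y_um", "z_um"]
    n_pos = 0
    n_total = 0
    for nid, group in signals.groupby("nucleus_id", sort=False):
        pts = [
            group.loc[group["gene"] == g, coords].to_numpy() for g in genes
        ]
        if any(len(p) == 0 for p in pts):
            continue
        n_total += 1
        d01 = cdist(pts[0], pts[1]).min()
        d02 = cdist(pts[0], pts[2]).min()
        d12 = cdist(pts[1], pts[2]).min()
        if max(d01, d02, d12) <= threshold_um:
            n_pos += 1
    return (n_pos / n_total if n_total else float("nan")), n_total
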