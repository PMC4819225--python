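"""Position-weight-matrix scanning of candidate promoters.

A PWM holds per-position base probabilities; windows score as log2-odds
against a background distribution. A gene is flagged when any window on
either strand of TSS +/- 5 kb reaches a configurable fraction of the
maximal achievable score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import GeneModel

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PWM:
    """Per-position base probabilities (4 x L, rows A/C/G/T) + background."""

    name: str
    probabilities: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[0] != 4:
            raise ValueError("PWM probabilities must be 4 x L")
        if not np.allclose(p.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(np.asarray(self.background).sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(
            self, "background", np.asarray(self.background, dtype=float)
        )

    @property
    def length(self) -> int:
        return self.probabilities.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probabilities) - np.log2(
                self.background[:, None]
            )

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(
            "ACGT"[i] for i in self.probabilities.argmax(axis=0)
        )

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        background: np.ndarray | None = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=0, keepdims=True)
        if background is None:
            background = np.full(4, 0.25)
        return cls(name, probs, np.asarray(background, dtype=float))


def pwm_score(window: str, pwm: PWM) -> float:
    """Log2-odds score of one window; N positions score as background (0)."""
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != PWM length {pwm.length}"
        )
    lo = pwm.log_odds
    score = 0.0
    for i, base in enumerate(window.upper()):
        if base == "N":
            continue
        try:
            score += lo[_BASE_INDEX[base], i]
        except KeyError:
            raise ValueError(f"unsupported base {base!r} in window") from None
    return score


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        code[arr == ord(base)] = i
    if np.any((code == -1) & (arr != ord("N"))):
        raise ValueError("sequence contains bases outside ACGTN")
    return code


def scan_scores(sequence: str, pwm: PWM) -> np.ndarray:
    """Scores of every window of ``sequence`` on the given strand."""
    code = _encode(sequence)
    L = pwm.length
    n = len(code) - L + 1
    if n <= 0:
        return np.zeros(0)
    lo = pwm.log_odds
    scores = np.zeros(n)
    for offset in range(L):
        col = code[offset : offset + n]
        contrib = np.where(col >= 0, lo[np.clip(col, 0, 3), offset], 0.0)
        scores += contrib
    return scores


def scan_stat3(
    gene: GeneModel,
    genome,
    pwm: PWM,
    window_bp: int = 5_000,
    score_fraction: float = 0.8,
) -> tuple[bool, list[int]]:
    """Scan TSS +/- window_bp on both strands for motif hits.

    ``genome`` is any mapping of chromosome name to indexable sequence
    (a dict of strings or a pyfaidx.Fasta). A hit is a window scoring at
    least ``score_fraction`` times the PWM's maximal score; returns the
    flag and the hit start positions in genome coordinates (forward
    strand positions for both orientations).
    """
    chrom_seq = genome[gene.interval.chrom]
    chrom_len = len(chrom_seq)
    lo = max(0, gene.tss - window_bp)
    hi = min(chrom_len, gene.tss + window_bp)
    region = str(chrom_seq[lo:hi])
    if not region:
        raise ValueError(f"no sequence for {gene.gene_id} promoter window")
    threshold = score_fraction * pwm.max_score
    hits: list[int] = []
    fwd = scan_scores(region, pwm)
    for pos in np.nonzero(fwd >= threshold)[0]:
        hits.append(lo + int(pos))
    from .synthetic import reverse_complement

    rev = scan_scores(reverse_complement(region), pwm)
    for pos in np.nonzero(rev >= threshold)[0]:
        # map the reverse-strand window start back to forward coordinates
        hits.append(lo + len(region) - int(pos) - pwm.length)
    return len(hits) > 0, sorted(set(hits))


def stat3_like_pwm(strength: float = 0.94) -> PWM:
    """Synthetic STAT3-like palindromic motif (TTCnnnGAA) for tests.

    This is a stand-in built from the canonical GAS palindrome, not a
    matrix derived from ChIP-seq data; real analyses should load a
    curated PWM (e.g. JASPAR) via :func:`gfap4c.io.read_jaspar`.
    """
    weak = (1.0 - strength) / 3.0
    cols = []
    for base in "TTC" + "NNN" + "GAA":
        if base == "N":
            cols.append([0.25, 0.25, 0.25, 0.25])
        else:
            col = [weak] * 4
            col[_BASE_INDEX[base]] = strength
            cols.append(col)
    return PWM("STAT3_synthetic", np.array(cols).T)
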