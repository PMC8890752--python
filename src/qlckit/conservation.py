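"""Per-column conservation scoring by Jensen-Shannon divergence.

Each alignment column's residue distribution is compared with a background
distribution — by default the marginal amino-acid frequencies of the
BLOSUM62 substitution data — using the base-2 Jensen-Shannon divergence,

    JSD(p, q) = H((p + q) / 2) - (H(p) + H(q)) / 2,

which is symmetric and bounded in [0, 1].  Columns with gaps are penalized
linearly by (1 - gap_fraction).  An optional window average mixes each
column's score with the mean of its neighbors, emphasizing conserved
stretches over isolated conserved columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._alphabet import STANDARD_AA
from .io import Alignment

__all__ = [
    "BLOSUM62_BACKGROUND",
    "background_vector",
    "jsd_column_score",
    "conservation_profile",
    "ConservationProfile",
]

# Marginal amino-acid frequencies associated with the BLOSUM62 substitution
# data (normalized to sum exactly to 1).
BLOSUM62_BACKGROUND: dict[str, float] = {
    "A": 0.078, "R": 0.051, "N": 0.041, "D": 0.052, "C": 0.024,
    "Q": 0.034, "E": 0.059, "G": 0.083, "H": 0.025, "I": 0.062,
    "L": 0.092, "K": 0.056, "M": 0.024, "F": 0.044, "P": 0.043,
    "S": 0.059, "T": 0.055, "W": 0.014, "Y": 0.034, "V": 0.072,
}

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


def background_vector(background: dict[str, float] | np.ndarray | None = None) -> np.ndarray:
    """Background distribution as a length-20 vector indexed by the standard
    alphabet in alphabetical order, normalized to sum to 1."""
    if background is None:
        background = BLOSUM62_BACKGROUND
    if isinstance(background, dict):
        vec = np.array([background[aa] for aa in STANDARD_AA], dtype=float)
    else:
        vec = np.asarray(background, dtype=float)
    if vec.shape != (20,):
        raise ValueError("background must provide one probability per standard residue")
    if (vec <= 0).any():
        raise ValueError("background probabilities must be strictly positive")
    return vec / vec.sum()


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _column_distribution(column: str, pseudocount: float) -> tuple[np.ndarray | None, float]:
    """Pseudocount-smoothed empirical distribution of a column's standard
    residues, plus its gap fraction.  Gaps and ambiguity codes both count as
    uninformative positions.  Returns (None, 1.0) for a fully uninformative
    column."""
    counts = np.zeros(20, dtype=float)
    n_informative = 0
    for ch in column:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
            n_informative += 1
    gap_fraction = 1.0 - n_informative / len(column)
    if n_informative == 0:
        return None, 1.0
    p = counts + pseudocount
    return p / p.sum(), gap_fraction


def jsd_column_score(
    column: str,
    background: dict[str, float] | np.ndarray | None = None,
    pseudocount: float = 1e-7,
) -> float:
    """Gap-penalized Jensen-Shannon divergence of one alignment column
    against the background; in [0, 1], higher = more conserved.  An all-gap
    column scores 0."""
    if len(column) < 2:
        raise ValueError("column must contain at least 2 sequences")
    q = background_vector(background)
    p, gap_fraction = _column_distribution(column, pseudocount)
    if p is None:
        return 0.0
    m = (p + q) / 2
    jsd = _entropy2(m) - (_entropy2(p) + _entropy2(q)) / 2
    return float(np.clip(jsd, 0.0, 1.0)) * (1.0 - gap_fraction)


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation scores and gap fractions for one alignment.
    ``flags`` marks columns whose gap fraction exceeded the reporting cutoff
    (their score is forced to 0)."""

    scores: np.ndarray
    gap_fractions: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.scores) == len(self.gap_fractions) == len(self.flags)):
            raise ValueError("profile arrays must have equal length")

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column_1based": np.arange(1, len(self.scores) + 1),
                "score": self.scores,
                "gap_fraction": self.gap_fractions,
                "flag": np.where(self.flags, "gappy", ""),
            }
        )


def conservation_profile(
    alignment: Alignment,
    background: dict[str, float] | np.ndarray | None = None,
    window: int = 3,
    lambda_window: float = 0.5,
    pseudocount: float = 1e-7,
    max_gap_fraction: float = 0.99,
) -> ConservationProfile:
    """Score every column of an alignment.

    With ``window`` > 0 the final score of column i is
    (1 - lambda_window) * score_i + lambda_window * mean(scores of the up to
    ``window`` neighbors on each side, excluding column i), truncated at the
    alignment ends.  Columns with gap fraction above ``max_gap_fraction``
    are flagged and score 0.
    """
    if not 0 <= lambda_window <= 1:
        raise ValueError("lambda_window must be in [0, 1]")
    n = alignment.n_columns
    raw = np.zeros(n)
    gaps = np.zeros(n)
    flags = np.zeros(n, dtype=bool)
    q = background_vector(background)
    for j in range(n):
        col = alignment.column(j)
        p, gap_fraction = _column_distribution(col, pseudocount)
        gaps[j] = gap_fraction
        if p is None or gap_fraction > max_gap_fraction:
            flags[j] = gap_fraction > max_gap_fraction or p is None
            raw[j] = 0.0
            continue
        m = (p + q) / 2
        jsd = _entropy2(m) - (_entropy2(p) + _entropy2(q)) / 2
        raw[j] = float(np.clip(jsd, 0.0, 1.0)) * (1.0 - gap_fraction)
    if window <= 0:
        return ConservationProfile(scores=raw, gap_fractions=gaps, flags=flags)
    smoothed = np.empty(n)
    for j in range(n):
        lo, hi = max(0, j - window), min(n, j + window + 1)
        neighbors = np.concatenate([raw[lo:j], raw[j + 1 : hi]])
        if neighbors.size:
            smoothed[j] = (1 - lambda_window) * raw[j] + lambda_window * neighbors.mean()
        else:
            smoothed[j] = raw[j]
    smoothed[flags] = 0.0
    return ConservationProfile(scores=smoothed, gap_fractions=gaps, flags=flags)
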