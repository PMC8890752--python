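"""Detection of X-rich low-complexity regions (QLCs when X = Q).

A qualifying region must (i) contain at least ``min_fraction`` target
residues, (ii) have no interruption of more than ``max_gap`` consecutive
non-target residues between any two target residues, and (iii) be at least
``min_length`` residues long.  The defaults (Q, 0.25, 17, 15) define
glutamine-rich low-complexity sequences; any other standard residue can be
targeted to detect generic XLCs.

Candidate spans always begin and end on the target residue — boundaries on
non-target residues would make fraction maximization ill-posed.  The gap
comparison is inclusive: a run of exactly ``max_gap`` non-target residues
between two target residues is allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._alphabet import STANDARD_SET
from .io import Proteome, Region

__all__ = [
    "LCParams",
    "SweepRow",
    "SweepReport",
    "detect_xlc",
    "detect_proteome",
    "sweep_max_gap",
    "rank_regions",
]

RANK_KEYS = ("n_his", "length", "n_target")


@dataclass(frozen=True)
class LCParams:
    """Parameters of the X-rich region detector.

    Defaults reproduce the QLC definition: target residue Q, a minimum
    glutamine fraction of 25%, a maximum interruption of 17 residues between
    any two glutamines, and a minimum overall length of 15 residues.
    """

    target_residue: str = "Q"
    min_fraction: float = 0.25
    max_gap: int = 17
    min_length: int = 15

    def __post_init__(self) -> None:
        if self.target_residue not in STANDARD_SET:
            raise ValueError(
                f"target residue must be one of the 20 standard amino acids, "
                f"got {self.target_residue!r}"
            )
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.max_gap < 0:
            raise ValueError("max_gap must be non-negative")
        if self.min_length < 1:
            raise ValueError("min_length must be positive")


@dataclass(frozen=True)
class SweepRow:
    """One row of the max-gap parameter sweep: how many regions were found
    at this gap and how many residues they cover in total."""

    max_gap: int
    n_regions: int
    n_residues: int


@dataclass(frozen=True)
class SweepReport:
    """Argmax summary of a sweep.  Ties are broken toward the smallest gap;
    the two argmaxes are reported separately so a disagreement between the
    region-count and residue-coverage optima is visible, not hidden."""

    best_gap_by_regions: int
    best_gap_by_residues: int


def _chains(positions: Sequence[int], max_gap: int) -> list[list[int]]:
    """Split target-residue positions into chains in which consecutive
    targets are separated by at most ``max_gap`` non-target residues."""
    chains: list[list[int]] = []
    current: list[int] = []
    for pos in positions:
        if current and pos - current[-1] - 1 > max_gap:
            chains.append(current)
            current = []
        current.append(pos)
    if current:
        chains.append(current)
    return chains


def _prune_contained(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Keep only spans maximal under containment."""
    spans = sorted(spans, key=lambda s: (s[0], -s[1]))
    kept: list[tuple[int, int]] = []
    max_end = -1
    for start, end in spans:
        if end > max_end:
            kept.append((start, end))
            max_end = end
    return kept


def _select_non_overlapping(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Greedy overlap resolution: repeatedly keep the longest remaining span
    (ties toward the leftmost start) and discard everything overlapping it."""
    order = sorted(spans, key=lambda s: (-(s[1] - s[0]), s[0]))
    kept: list[tuple[int, int]] = []
    for start, end in order:
        if all(end <= ks or start >= ke for ks, ke in kept):
            kept.append((start, end))
    return sorted(kept)


def detect_xlc(
    sequence: str, params: LCParams = LCParams(), protein_id: str = ""
) -> list[Region]:
    """Detect target-residue-rich low-complexity regions in one sequence.

    Returns mutually non-overlapping regions sorted by start position.  Every
    region starts and ends on the target residue, satisfies the fraction,
    gap, and length criteria, and is maximal (it cannot be extended to a
    longer qualifying span that contains it).
    """
    target = params.target_residue
    positions = [i for i, ch in enumerate(sequence) if ch == target]
    candidates: list[tuple[int, int]] = []
    for chain in _chains(positions, params.max_gap):
        m = len(chain)
        spans: list[tuple[int, int]] = []
        for i in range(m):
            for j in range(i, m):
                start, end = chain[i], chain[j] + 1
                length = end - start
                if length < params.min_length:
                    continue
                if (j - i + 1) / length >= params.min_fraction:
                    spans.append((start, end))
        candidates.extend(_prune_contained(spans))
    selected = _select_non_overlapping(candidates)
    return [
        Region.from_sequence(protein_id, start, end, sequence, target)
        for start, end in selected
    ]


def detect_proteome(proteome: Proteome, params: LCParams = LCParams()) -> list[Region]:
    """Scan every protein of a proteome; regions keep proteome order and are
    sorted by start within each protein."""
    regions: list[Region] = []
    for rec in proteome:
        regions.extend(detect_xlc(rec.sequence, params, protein_id=rec.id))
    return regions


def sweep_max_gap(
    proteome: Proteome,
    params: LCParams,
    gap_values: Sequence[int],
) -> tuple[list[SweepRow], SweepReport]:
    """Re-run detection across a range of ``max_gap`` values, holding every
    other parameter fixed, and report the gap maximizing the number of
    regions and the gap maximizing the residues covered."""
    if len(gap_values) == 0:
        raise ValueError("gap_values must be non-empty")
    if any(g < 0 for g in gap_values):
        raise ValueError("gap values must be non-negative")
    rows: list[SweepRow] = []
    for gap in gap_values:
        p = LCParams(
            target_residue=params.target_residue,
            min_fraction=params.min_fraction,
            max_gap=int(gap),
            min_length=params.min_length,
        )
        regions = detect_proteome(proteome, p)
        rows.append(
            SweepRow(
                max_gap=int(gap),
                n_regions=len(regions),
                n_residues=sum(r.length for r in regions),
            )
        )
    best_regions = min(rows, key=lambda r: (-r.n_regions, r.max_gap)).max_gap
    best_residues = min(rows, key=lambda r: (-r.n_residues, r.max_gap)).max_gap
    return rows, SweepReport(best_regions, best_residues)


def rank_regions(regions: Sequence[Region], key: str = "n_his") -> list[tuple[int, Region]]:
    """Rank regions in descending order of ``key`` (one of n_his, length,
    n_target).  Tied regions share the better (smaller) rank, competition
    style, and are ordered deterministically by (protein_id, start)."""
    if key not in RANK_KEYS:
        raise ValueError(f"unknown rank key {key!r}; choose from {RANK_KEYS}")
    ordered = sorted(regions, key=lambda r: (-getattr(r, key), r.protein_id, r.start))
    ranked: list[tuple[int, Region]] = []
    for i, reg in enumerate(ordered):
        if i > 0 and getattr(reg, key) == getattr(ordered[i - 1], key):
            rank = ranked[-1][0]
        else:
            rank = i + 1
        ranked.append((rank, reg))
    return ranked
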