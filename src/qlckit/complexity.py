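"""Wootton-Federhen sequence complexity and low-complexity-domain segmentation.

Complexity of a window is the Shannon entropy of its residue composition
normalized by the logarithm of the alphabet size (20), so values fall in
[0, 1]: 0 for a homopolymer, 1 for a window whose length is a multiple of 20
with every residue equally represented.  A protein is profiled with a
sliding window (default 15), each residue classified low/high complexity
against a threshold (default 0.6), short high-complexity gaps closed
(default up to 3 residues), and contiguous low-complexity stretches of at
least ``min_length`` residues (default 30) reported as low-complexity
domains (LCDs).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Proteome, Region

__all__ = [
    "WFParams",
    "ComplexityProfile",
    "window_complexity",
    "complexity_profile",
    "segment_lcds",
    "segment_proteome",
]


@dataclass(frozen=True)
class WFParams:
    window: int = 15
    threshold: float = 0.6
    gap_close: int = 3
    min_length: int = 30
    alphabet_size: int = 20
    # classification of a residue as low complexity uses strict inequality
    # (value < threshold); set strict=False for value <= threshold
    strict: bool = True

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.gap_close < 0:
            raise ValueError("gap_close must be non-negative")
        if self.min_length < 1:
            raise ValueError("min_length must be positive")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be at least 2")


@dataclass(frozen=True)
class ComplexityProfile:
    """Per-residue complexity values for one protein, aligned to its sequence."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("profile values must be a non-empty 1-D array")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("complexity values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def window_complexity(window_sequence: str, alphabet_size: int = 20) -> float:
    """Normalized compositional entropy of one window.

    C = -sum_i (n_i/L) log_B (n_i/L) over residue categories present, with
    B the alphabet size.  Each distinct symbol forms its own category, so
    ambiguity codes conservatively reduce claimed complexity.  Invariant to
    permutation of the window; exactly 0 for homopolymers.
    """
    L = len(window_sequence)
    if L == 0:
        raise ValueError("window must be non-empty")
    log_base = math.log(alphabet_size)
    c = 0.0
    for n in Counter(window_sequence).values():
        f = n / L
        c -= f * math.log(f)
    return min(c / log_base, 1.0)


def complexity_profile(sequence: str, params: WFParams = WFParams()) -> ComplexityProfile:
    """Sliding-window complexity profile of a sequence.

    Each full window's complexity is assigned to its central residue; the
    first and last (window-1)/2 residues inherit the nearest assigned value.
    Raises for sequences shorter than the window.
    """
    return _profile(sequence, params, protein_id="")


def _profile(sequence: str, params: WFParams, protein_id: str) -> ComplexityProfile:
    L = len(sequence)
    w = params.window
    if L < w:
        raise ValueError(f"sequence length {L} is shorter than window {w}")
    half = (w - 1) // 2
    values = np.empty(L, dtype=float)
    # incremental counts: entropy recomputed per window from <= w categories
    counts: Counter[str] = Counter(sequence[:w])
    log_base = math.log(params.alphabet_size)

    def entropy() -> float:
        c = 0.0
        for n in counts.values():
            if n:
                f = n / w
                c -= f * math.log(f)
        return min(c / log_base, 1.0)

    values[half] = entropy()
    for i in range(1, L - w + 1):
        counts[sequence[i - 1]] -= 1
        counts[sequence[i + w - 1]] += 1
        values[half + i] = entropy()
    values[:half] = values[half]
    values[L - half :] = values[L - half - 1]
    return ComplexityProfile(protein_id=protein_id, values=values)


def _low_runs(mask: np.ndarray, gap_close: int) -> list[tuple[int, int]]:
    """Runs of True in a binary mask, after closing gaps of up to
    ``gap_close`` False values between consecutive runs."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, low in enumerate(mask):
        if low and start is None:
            start = i
        elif not low and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe <= gap_close:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def segment_lcds(
    profile: ComplexityProfile,
    sequence: str,
    params: WFParams = WFParams(),
) -> list[Region]:
    """Segment a complexity profile into low-complexity domains.

    Residues with complexity below the threshold are low; runs of low
    residues separated by at most ``gap_close`` high residues are merged;
    merged runs of at least ``min_length`` residues become regions (with
    ``target_residue`` None) whose composition fields come from the
    underlying sequence.
    """
    if len(profile) != len(sequence):
        raise ValueError("profile length must match sequence length")
    if params.strict:
        mask = profile.values < params.threshold
    else:
        mask = profile.values <= params.threshold
    regions = []
    for start, end in _low_runs(mask, params.gap_close):
        if end - start >= params.min_length:
            regions.append(
                Region.from_sequence(profile.protein_id, start, end, sequence, None)
            )
    return regions


def segment_proteome(
    proteome: Proteome, params: WFParams = WFParams()
) -> list[Region]:
    """Profile and segment every protein of a proteome.  Proteins shorter
    than the window are skipped with a warning."""
    regions: list[Region] = []
    for rec in proteome:
        if len(rec.sequence) < params.window:
            warnings.warn(
                f"skipping {rec.id!r}: length {len(rec.sequence)} < window {params.window}"
            )
            continue
        prof = _profile(rec.sequence, params, protein_id=rec.id)
        regions.extend(segment_lcds(prof, rec.sequence, params))
    return regions
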