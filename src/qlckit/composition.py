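"""Residue-frequency distributions and enrichment/depletion statistics.

The central comparison is the per-residue log2 ratio of foreground
frequency (within detected regions) to background frequency (across the
whole proteome).  In the default mode the target residue is removed from
both foreground and background before computing fractions, so enrichment of
the remaining 19 residues is not trivially driven by the target itself; the
20-category mode keeps the target in both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._alphabet import STANDARD_AA
from .io import Proteome, Region, extract_region

__all__ = [
    "FrequencyTable",
    "EnrichmentTable",
    "residue_frequencies",
    "enrichment_log2",
    "compare_region_sets",
]


@dataclass(frozen=True)
class FrequencyTable:
    """Counts and fractions per standard amino-acid category.

    Ambiguity codes are excluded from the categories and from the
    denominator.  With ``excluded`` set, that residue is also removed,
    leaving 19 categories.
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    total_residues: int
    excluded: str | None = None

    def __post_init__(self) -> None:
        if self.total_residues <= 0:
            raise ValueError("frequency table has an empty denominator")
        s = sum(self.fractions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {s}, expected 1")


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-residue foreground/background fractions and log2 ratios.

    Categories with a zero count on either side carry a flag ("zero_fg",
    "zero_bg", or "zero_both") and a NaN ratio rather than +/-infinity, so
    the table stays serializable.
    """

    table: pd.DataFrame  # residue, fg_count, fg_fraction, bg_count, bg_fraction, log2_ratio, flag
    excluded: str | None = None

    def log2_ratio(self, residue: str) -> float:
        row = self.table.loc[self.table["residue"] == residue]
        if row.empty:
            raise KeyError(f"residue {residue!r} not in enrichment table")
        return float(row["log2_ratio"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _category_counts(sequences: Iterable[str], exclude: str | None) -> dict[str, int]:
    cats = [aa for aa in STANDARD_AA if aa != exclude]
    counts = dict.fromkeys(cats, 0)
    for seq in sequences:
        for ch in seq:
            if ch in counts:
                counts[ch] += 1
    return counts


def residue_frequencies(
    sequences: Iterable[str], exclude: str | None = None
) -> FrequencyTable:
    """Frequency distribution over the standard amino acids in a collection
    of sequences, optionally excluding one residue from categories and
    denominator."""
    counts = _category_counts(sequences, exclude)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no countable residues after exclusion")
    fractions = {aa: n / total for aa, n in counts.items()}
    return FrequencyTable(counts=counts, fractions=fractions, total_residues=total, excluded=exclude)


def enrichment_log2(
    foreground_regions: Sequence[Region],
    proteome: Proteome,
    background: Proteome | None = None,
    exclude_target: bool = True,
    target_residue: str | None = None,
) -> EnrichmentTable:
    """Per-residue log2(foreground fraction / background fraction).

    Foreground sequences are the region subsequences extracted from
    ``proteome``; the background is the whole proteome (or a separate one).
    With ``exclude_target`` (the default) the regions' target residue is
    removed from both distributions before fractions are computed.
    """
    if not foreground_regions:
        raise ValueError("foreground region set is empty")
    if background is None:
        background = proteome
    if target_residue is None:
        targets = {r.target_residue for r in foreground_regions}
        targets.discard(None)
        if len(targets) > 1:
            raise ValueError(f"regions carry mixed target residues {sorted(targets)}; pass target_residue explicitly")
        target_residue = targets.pop() if targets else None
    exclude = target_residue if exclude_target else None

    fg_seqs = [extract_region(proteome, r) for r in foreground_regions]
    fg_counts = _category_counts(fg_seqs, exclude)
    bg_counts = _category_counts((rec.sequence for rec in background), exclude)
    fg_total = sum(fg_counts.values())
    bg_total = sum(bg_counts.values())
    if fg_total == 0 or bg_total == 0:
        raise ValueError("empty foreground or background after exclusion")

    rows = []
    for aa in fg_counts:
        fg_f = fg_counts[aa] / fg_total
        bg_f = bg_counts[aa] / bg_total
        if fg_f > 0 and bg_f > 0:
            ratio, flag = math.log2(fg_f / bg_f), ""
        else:
            ratio = float("nan")
            flag = {(True, True): "zero_both", (True, False): "zero_fg", (False, True): "zero_bg"}[
                (fg_f == 0, bg_f == 0)
            ]
        rows.append(
            {
                "residue": aa,
                "fg_count": fg_counts[aa],
                "fg_fraction": fg_f,
                "bg_count": bg_counts[aa],
                "bg_fraction": bg_f,
                "log2_ratio": ratio,
                "flag": flag,
            }
        )
    return EnrichmentTable(table=pd.DataFrame(rows), excluded=exclude)


def _masked_counts(
    regions: Sequence[Region],
    proteome: Proteome,
    residue: str,
    exclude_spans: dict[str, list[tuple[int, int]]] | None,
) -> tuple[int, int]:
    """(count of ``residue``, count of all standard residues) over the
    region set, skipping positions covered by ``exclude_spans``."""
    n_res = 0
    n_all = 0
    standard = set(STANDARD_AA)
    for reg in regions:
        seq = proteome[reg.protein_id].sequence
        spans = (exclude_spans or {}).get(reg.protein_id, [])
        for pos in range(reg.start, reg.end):
            if any(s <= pos < e for s, e in spans):
                continue
            ch = seq[pos]
            if ch in standard:
                n_all += 1
                if ch == residue:
                    n_res += 1
    return n_res, n_all


def compare_region_sets(
    set_a: Sequence[Region],
    set_b: Sequence[Region],
    proteome: Proteome,
    residue: str = "H",
    exclude_overlap: bool = True,
) -> float:
    """Percent excess of ``residue`` in region set A relative to region set B:
    100 * (fraction_in_A / fraction_in_B - 1).

    With ``exclude_overlap`` (the default), positions of B covered by any
    region of A are removed from B's tally first, so B represents "all other"
    regions only.
    """
    if not set_a or not set_b:
        raise ValueError("both region sets must be non-empty")
    a_spans: dict[str, list[tuple[int, int]]] = {}
    if exclude_overlap:
        for reg in set_a:
            a_spans.setdefault(reg.protein_id, []).append((reg.start, reg.end))
    n_res_a, n_all_a = _masked_counts(set_a, proteome, residue, None)
    n_res_b, n_all_b = _masked_counts(set_b, proteome, residue, a_spans if exclude_overlap else None)
    if n_all_a == 0 or n_all_b == 0:
        raise ValueError("a region set covers no standard residues after exclusion")
    frac_a = n_res_a / n_all_a
    frac_b = n_res_b / n_all_b
    if frac_b == 0:
        raise ValueError(f"residue {residue!r} absent from region set B; excess undefined")
    return 100.0 * (frac_a / frac_b - 1.0)
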