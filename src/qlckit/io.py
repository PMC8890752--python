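"""Protein FASTA / aligned FASTA input, region tables, and coordinate conventions.

Internally every region is 0-based half-open ``[start, end)``.  Every file
this package writes uses 1-based inclusive residue numbering, matching the
convention of residue labels like "H106" or "residues 71-120".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from ._alphabet import ALIGNED_SET, ALLOWED_SET, GAP

__all__ = [
    "ProteinRecord",
    "Proteome",
    "Alignment",
    "Region",
    "read_fasta",
    "write_fasta",
    "write_regions",
    "read_regions",
    "extract_region",
]

REGION_TSV_COLUMNS = [
    "protein_id",
    "start_1based",
    "end_1based",
    "length",
    "target_residue",
    "n_target",
    "fraction_target",
    "n_his",
    "sequence",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` is the remainder.  ``sequence`` is uppercase over the 20
    standard residues plus {X, B, Z, U, O} (and '-' inside alignments).
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


class Proteome:
    """Ordered, id-unique collection of :class:`ProteinRecord`."""

    def __init__(self, records: Sequence[ProteinRecord]):
        self._records = list(records)
        self._index: dict[str, ProteinRecord] = {}
        for rec in self._records:
            if rec.id in self._index:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            self._index[rec.id] = rec

    @property
    def records(self) -> list[ProteinRecord]:
        return list(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        try:
            return self._index[protein_id]
        except KeyError:
            raise KeyError(f"unknown protein id {protein_id!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Proteome):
            return NotImplemented
        return self._records == other._records


class Alignment:
    """A multiple sequence alignment: gapped records of equal length."""

    def __init__(self, records: Sequence[ProteinRecord]):
        if len(records) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        lengths = {len(r.sequence) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
        self._records = list(records)
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence id {dup!r}")
        self.n_columns: int = lengths.pop()

    @property
    def records(self) -> list[ProteinRecord]:
        return list(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records)

    def column(self, j: int) -> str:
        """Residues (and gaps) of alignment column ``j`` (0-based)."""
        if not 0 <= j < self.n_columns:
            raise IndexError(f"column {j} out of range [0, {self.n_columns})")
        return "".join(r.sequence[j] for r in self._records)


@dataclass(frozen=True)
class Region:
    """A detected low-complexity span on one protein.

    ``target_residue`` is the enriched residue for X-rich regions and None
    for complexity-defined (Wootton-Federhen) regions, whose ``n_target`` and
    ``fraction_target`` are zero by convention.
    """

    protein_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    target_residue: str | None
    length: int
    n_target: int
    fraction_target: float
    n_his: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.length != self.end - self.start:
            raise ValueError("length must equal end - start")
        if abs(self.fraction_target - self.n_target / self.length) > 1e-9:
            raise ValueError("fraction_target must equal n_target / length")
        if self.n_his > self.length:
            raise ValueError("n_his cannot exceed length")

    @classmethod
    def from_sequence(
        cls,
        protein_id: str,
        start: int,
        end: int,
        sequence: str,
        target_residue: str | None,
    ) -> "Region":
        """Build a region with composition statistics taken from ``sequence``
        (the full protein sequence, not the subsequence)."""
        if not (0 <= start < end <= len(sequence)):
            raise ValueError(
                f"span [{start}, {end}) out of range for protein {protein_id!r} "
                f"of length {len(sequence)}"
            )
        sub = sequence[start:end]
        length = end - start
        n_target = sub.count(target_residue) if target_residue else 0
        return cls(
            protein_id=protein_id,
            start=start,
            end=end,
            target_residue=target_residue,
            length=length,
            n_target=n_target,
            fraction_target=n_target / length,
            n_his=sub.count("H"),
        )

    def jaccard(self, other: "Region") -> float:
        """Interval intersection-over-union with another region (coordinates
        only; protein ids must match for a nonzero result)."""
        if self.protein_id != other.protein_id:
            return 0.0
        inter = max(0, min(self.end, other.end) - max(self.start, other.start))
        union = (self.end - self.start) + (other.end - other.start) - inter
        return inter / union


def _validate_sequence(seq: str, rec_id: str, allow_gaps: bool) -> str:
    allowed = ALIGNED_SET if allow_gaps else ALLOWED_SET
    seq = seq.upper()
    if seq.endswith("*"):
        warnings.warn(f"record {rec_id!r}: stripping terminal stop symbol '*'")
        seq = seq.rstrip("*")
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"record {rec_id!r}: invalid character {ch!r} at position "
                f"{pos + 1} (1-based)"
            )
    return seq


def read_fasta(path: str | Path, allow_gaps: bool = False) -> Proteome | Alignment:
    """Read a protein FASTA file.

    With ``allow_gaps=False`` returns a :class:`Proteome`; with
    ``allow_gaps=True`` the sequences may contain '-' and must be of equal
    length, and an :class:`Alignment` is returned.  Sequences are uppercased;
    a terminal '*' is stripped with a warning; any other character outside
    the allowed alphabet is an error reporting its position.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id = rec.id
        if rec_id in seen:
            raise ValueError(f"duplicate sequence id {rec_id!r} in {path}")
        seen.add(rec_id)
        seq = _validate_sequence(str(rec.seq), rec_id, allow_gaps)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec_id, sequence=seq, description=desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if allow_gaps:
        return Alignment(records)
    return Proteome(records)


def write_fasta(records: Proteome | Alignment | Sequence[ProteinRecord], path: str | Path, width: int = 60) -> int:
    """Write records to FASTA, wrapping sequence lines at ``width``."""
    recs = list(records)
    with open(path, "w") as fh:
        for rec in recs:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
    return len(recs)


def extract_region(proteome: Proteome, region: Region) -> str:
    """Return the exact subsequence ``[start, end)`` of the region's protein."""
    rec = proteome[region.protein_id]
    if region.end > len(rec.sequence):
        raise ValueError(
            f"region [{region.start}, {region.end}) out of range for protein "
            f"{region.protein_id!r} of length {len(rec.sequence)}"
        )
    return rec.sequence[region.start : region.end]


def write_regions(
    regions: Sequence[Region],
    proteome: Proteome,
    tsv_path: str | Path,
    fasta_path: str | Path | None = None,
) -> int:
    """Write a region table (and optionally the region subsequences as FASTA).

    The TSV carries 1-based inclusive coordinates.  FASTA headers are
    ``protein_id/start_1based-end_1based``.  Returns the number of regions
    written.
    """
    rows = []
    fasta_records = []
    for reg in regions:
        sub = extract_region(proteome, reg)  # validates id and range
        rows.append(
            {
                "protein_id": reg.protein_id,
                "start_1based": reg.start + 1,
                "end_1based": reg.end,
                "length": reg.length,
                "target_residue": reg.target_residue or "",
                "n_target": reg.n_target,
                "fraction_target": f"{reg.fraction_target:.6f}",
                "n_his": reg.n_his,
                "sequence": sub,
            }
        )
        if fasta_path is not None:
            fasta_records.append(
                ProteinRecord(id=f"{reg.protein_id}/{reg.start + 1}-{reg.end}", sequence=sub)
            )
    df = pd.DataFrame(rows, columns=REGION_TSV_COLUMNS)
    df.to_csv(tsv_path, sep="\t", index=False)
    if fasta_path is not None:
        write_fasta(fasta_records, fasta_path)
    return len(rows)


def read_regions(tsv_path: str | Path) -> list[Region]:
    """Read a region table written by :func:`write_regions` back into
    internal 0-based half-open coordinates."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"target_residue": str}, keep_default_na=False)
    regions = []
    for row in df.itertuples(index=False):
        start = int(row.start_1based) - 1
        end = int(row.end_1based)
        length = int(row.length)
        n_target = int(row.n_target)
        # the file stores fraction_target rounded to 6 dp; restore it exactly
        fraction = n_target / length
        if abs(fraction - float(row.fraction_target)) > 5e-7:
            raise ValueError(
                f"inconsistent region row for {row.protein_id!r}: "
                f"fraction_target {row.fraction_target} != {n_target}/{length}"
            )
        regions.append(
            Region(
                protein_id=str(row.protein_id),
                start=start,
                end=end,
                target_residue=str(row.target_residue) or None,
                length=length,
                n_target=n_target,
                fraction_target=fraction,
                n_his=int(row.n_his),
            )
        )
    return regions
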