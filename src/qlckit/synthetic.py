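"""Seeded synthetic inputs with known ground truth for every analysis stage.

Three generators cover the package's input types:

* proteomes with planted target-residue-rich tracts (QLC-like) and/or
  generic low-complexity tracts (LCD-like), embedded in high-complexity
  background flanks that are free of the target residue, so planted
  boundaries are unambiguous for recovery scoring;
* alignments with planted perfectly conserved columns over a background
  distribution;
* ideal-polymer conformer ensembles — freely jointed chains (nu ~ 0.5) and
  rigid rods (nu = 1.0) — whose closed-form Rg and scaling exponents anchor
  the ensemble descriptors.

Every generator is a pure function of its parameters and an explicit
integer seed: reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from ._alphabet import STANDARD_AA
from .io import Alignment, Proteome, ProteinRecord
from .ensembles import Ensemble

__all__ = [
    "PlantSpec",
    "generate_proteome",
    "generate_alignment",
    "generate_chain_ensemble",
    "write_ensemble_pdb",
]

TRUTH_COLUMNS = ["protein_id", "start", "end", "kind", "target_residue", "target_fraction", "his_density"]


@dataclass(frozen=True)
class PlantSpec:
    """Specification of a family of planted tracts.

    ``kind`` is "xlc" for target-residue-rich tracts (detectable by the
    X-rich detector) or "lcd" for generic low-complexity tracts built from a
    small residue alphabet (detectable by complexity segmentation).  Tract
    composition is realized with exact residue counts: a tract of length L
    carries round(target_fraction * L) target residues (xlc) and
    round(his_density * L) histidines.  Target residues always occupy the
    first and last tract position and internal non-target runs never exceed
    ``max_gap``.
    """

    kind: str = "xlc"
    n_tracts: int = 10
    tract_length: tuple[int, int] = (40, 80)
    target_residue: str = "Q"
    target_fraction: float = 0.4
    max_gap: int = 10
    gap_mode: str = "random"
    his_density: float = 0.0
    lcd_alphabet: tuple[str, ...] = ("N", "S")

    def __post_init__(self) -> None:
        if self.kind not in ("xlc", "lcd"):
            raise ValueError(f"unknown plant kind {self.kind!r}")
        if self.gap_mode not in ("random", "exact"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")
        if self.n_tracts < 0:
            raise ValueError("n_tracts must be non-negative")
        lo, hi = self.tract_length
        if not 2 <= lo <= hi:
            raise ValueError("tract_length bounds must satisfy 2 <= min <= max")
        if self.kind == "xlc":
            if not 0 < self.target_fraction <= 1:
                raise ValueError("target_fraction must be in (0, 1]")
            if self.max_gap < 1:
                raise ValueError("max_gap must be >= 1 for xlc plants")
            # feasibility at the shortest tract: the non-target residues must
            # fit into the k-1 gaps of size <= max_gap
            k = max(2, round(self.target_fraction * lo))
            if self.gap_mode == "random" and lo - k > (k - 1) * self.max_gap:
                raise ValueError("infeasible plant: too few targets to respect max_gap")
        if not 0 <= self.his_density < 1:
            raise ValueError("his_density must be in [0, 1)")


def _background_alphabet(exclude: set[str]) -> list[str]:
    return [aa for aa in STANDARD_AA if aa not in exclude]


def _draw_background(rng: np.random.Generator, n: int, alphabet: list[str], probs: np.ndarray | None) -> str:
    if n == 0:
        return ""
    return "".join(rng.choice(alphabet, size=n, p=probs))


def _build_exact_gap_tract(rng: np.random.Generator, length: int, spec: PlantSpec) -> str:
    """Tract of target blocks separated by interruptions of exactly
    ``max_gap`` filler residues.  The block size realizes the requested
    target fraction per period, so splitting any interruption (i.e. running
    a detector with a smaller gap allowance) leaves only sub-minimal
    fragments — the construction that pins the sweep optimum at max_gap."""
    g = spec.max_gap
    f = spec.target_fraction
    m = max(1, round(f * g / (1 - f))) if f < 1 else length
    n_blocks = max(2, round((length + g) / (m + g)))
    real_length = n_blocks * m + (n_blocks - 1) * g
    n_filler = (n_blocks - 1) * g
    n_his = min(round(spec.his_density * real_length), n_filler)
    filler_alphabet = _background_alphabet({spec.target_residue, "H"})
    filler = ["H"] * n_his + list(rng.choice(filler_alphabet, size=n_filler - n_his))
    filler = list(rng.permutation(np.array(filler))) if filler else []
    parts = []
    idx = 0
    for b in range(n_blocks):
        parts.append(spec.target_residue * m)
        if b < n_blocks - 1:
            parts.extend(filler[idx : idx + g])
            idx += g
    return "".join(parts)


def _build_xlc_tract(rng: np.random.Generator, length: int, spec: PlantSpec) -> str:
    if spec.gap_mode == "exact":
        return _build_exact_gap_tract(rng, length, spec)
    target = spec.target_residue
    k = max(2, round(spec.target_fraction * length))
    k = min(k, length)
    n_other = length - k
    if n_other > (k - 1) * spec.max_gap:
        raise ValueError(f"infeasible tract: {n_other} non-target residues in {k - 1} gaps of <= {spec.max_gap}")
    # distribute the non-target residues over the k-1 inter-target gaps,
    # unit by unit, among gaps still below max_gap
    gaps = np.zeros(max(k - 1, 1), dtype=int)
    for _ in range(n_other):
        open_gaps = np.flatnonzero(gaps < spec.max_gap)
        gaps[open_gaps[rng.integers(len(open_gaps))]] += 1
    n_his = min(round(spec.his_density * length), n_other)
    filler_alphabet = _background_alphabet({target, "H"})
    filler = ["H"] * n_his + list(rng.choice(filler_alphabet, size=n_other - n_his))
    filler = list(rng.permutation(np.array(filler))) if filler else []
    out = []
    idx = 0
    for g in gaps[: k - 1]:
        out.append(target)
        out.extend(filler[idx : idx + g])
        idx += g
    out.append(target)
    tract = "".join(out)
    assert len(tract) == length
    return tract


def _build_lcd_tract(rng: np.random.Generator, length: int, spec: PlantSpec) -> str:
    n_his = min(round(spec.his_density * length), length)
    n_rest = length - n_his
    alpha = list(spec.lcd_alphabet)
    # fixed 60/40-ish split over the small alphabet keeps windows far below
    # the complexity threshold regardless of draw noise
    base = np.array([0.6, 0.4] + [0.0] * (len(alpha) - 2))[: len(alpha)]
    base = base / base.sum()
    rest = list(rng.choice(alpha, size=n_rest, p=base))
    residues = ["H"] * n_his + rest
    return "".join(rng.permutation(np.array(residues)))


def generate_proteome(
    n_proteins: int,
    protein_length: tuple[int, int] = (200, 400),
    plants: PlantSpec | list[PlantSpec] | None = None,
    flank_length: tuple[int, int] = (30, 80),
    seed: int = 0,
) -> tuple[Proteome, pd.DataFrame]:
    """Generate a proteome with planted tracts and its truth table.

    Each planted tract is placed in its own protein between two background
    flanks; proteins left over after all plants are pure background.  The
    background alphabet excludes every xlc plant's target residue, so no
    qualifying region can arise, or be extended, outside the planted loci.
    Deterministic given ``seed``.
    """
    if n_proteins < 0:
        raise ValueError("n_proteins must be non-negative")
    if plants is None:
        plants = []
    if isinstance(plants, PlantSpec):
        plants = [plants]
    total_tracts = sum(p.n_tracts for p in plants)
    if total_tracts > n_proteins:
        raise ValueError(f"{total_tracts} planted tracts do not fit in {n_proteins} proteins")
    lo_f, hi_f = flank_length
    if not 1 <= lo_f <= hi_f:
        raise ValueError("flank_length bounds must satisfy 1 <= min <= max")
    lo_p, hi_p = protein_length
    if not 1 <= lo_p <= hi_p:
        raise ValueError("protein_length bounds must satisfy 1 <= min <= max")

    rng = np.random.default_rng(seed)
    exclude = {p.target_residue for p in plants if p.kind == "xlc"}
    bg_alphabet = _background_alphabet(exclude)

    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    plant_queue: list[PlantSpec] = []
    for spec in plants:
        plant_queue.extend([spec] * spec.n_tracts)

    for i in range(n_proteins):
        pid = f"synth{i + 1:04d}"
        if i < len(plant_queue):
            spec = plant_queue[i]
            length = int(rng.integers(spec.tract_length[0], spec.tract_length[1] + 1))
            tract = (
                _build_xlc_tract(rng, length, spec)
                if spec.kind == "xlc"
                else _build_lcd_tract(rng, length, spec)
            )
            length = len(tract)  # exact-gap construction may round the length
            left = int(rng.integers(lo_f, hi_f + 1))
            right = int(rng.integers(lo_f, hi_f + 1))
            seq = (
                _draw_background(rng, left, bg_alphabet, None)
                + tract
                + _draw_background(rng, right, bg_alphabet, None)
            )
            records.append(ProteinRecord(id=pid, sequence=seq, description=f"planted {spec.kind} tract"))
            truth_rows.append(
                {
                    "protein_id": pid,
                    "start": left,
                    "end": left + length,
                    "kind": spec.kind,
                    "target_residue": spec.target_residue if spec.kind == "xlc" else "",
                    "target_fraction": spec.target_fraction if spec.kind == "xlc" else 0.0,
                    "his_density": spec.his_density,
                }
            )
        else:
            length = int(rng.integers(lo_p, hi_p + 1))
            seq = _draw_background(rng, length, bg_alphabet, None)
            records.append(ProteinRecord(id=pid, sequence=seq, description="background"))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return Proteome(records), truth


def generate_alignment(
    n_sequences: int,
    n_columns: int,
    conserved_columns: set[int] | list[int] = (),
    background: dict[str, float] | None = None,
    gap_rate: float = 0.0,
    seed: int = 0,
) -> tuple[Alignment, pd.DataFrame]:
    """Generate an alignment with planted perfectly conserved columns.

    ``conserved_columns`` are 0-based indices; each carries one fixed
    residue (drawn once from the background) in every sequence.  All other
    cells are drawn independently from the background distribution (uniform
    over the 20 standard residues by default).  ``gap_rate`` introduces '-'
    at non-conserved cells.  Deterministic given ``seed``.
    """
    if n_sequences < 2:
        raise ValueError("an alignment needs at least 2 sequences")
    if n_columns < 1:
        raise ValueError("n_columns must be positive")
    conserved = sorted(set(int(c) for c in conserved_columns))
    if conserved and (conserved[0] < 0 or conserved[-1] >= n_columns):
        raise ValueError("conserved column indices out of range")
    if not 0 <= gap_rate < 1:
        raise ValueError("gap_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    alphabet = list(STANDARD_AA)
    if background is None:
        probs = np.full(20, 1 / 20)
    else:
        probs = np.array([background.get(aa, 0.0) for aa in alphabet], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("background distribution is empty")
        probs = probs / probs.sum()
    conserved_set = set(conserved)
    conserved_residue = {c: str(rng.choice(alphabet, p=probs)) for c in conserved}
    rows = []
    for s in range(n_sequences):
        chars = []
        for c in range(n_columns):
            if c in conserved_set:
                chars.append(conserved_residue[c])
            elif gap_rate > 0 and rng.random() < gap_rate:
                chars.append("-")
            else:
                chars.append(str(rng.choice(alphabet, p=probs)))
        rows.append(ProteinRecord(id=f"seq{s + 1:03d}", sequence="".join(chars)))
    truth = pd.DataFrame(
        [{"column": c, "residue": conserved_residue[c]} for c in conserved],
        columns=["column", "residue"],
    )
    return Alignment(rows), truth


def generate_chain_ensemble(
    model: str,
    n_sites: int,
    bond_length: float = 3.8,
    n_conformers: int = 1,
    seed: int = 0,
) -> Ensemble:
    """Generate an ideal-polymer conformer ensemble.

    ``model`` "fjc": freely jointed chain, each bond an independent
    uniformly oriented unit vector scaled by ``bond_length`` — the ideal
    chain with <r^2(s)> = s * b^2 and scaling exponent 0.5.  ``model``
    "rod": collinear equally spaced sites (deterministic), the nu = 1.0
    reference.  Coordinates are in Angstrom; deterministic given ``seed``.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    if model == "rod":
        line = np.zeros((n_sites, 3))
        line[:, 0] = bond_length * np.arange(n_sites)
        coords = np.repeat(line[None, :, :], n_conformers, axis=0)
        return Ensemble(coordinates=coords)
    if model == "fjc":
        rng = np.random.default_rng(seed)
        bonds = rng.normal(size=(n_conformers, n_sites - 1, 3))
        bonds /= np.linalg.norm(bonds, axis=2, keepdims=True)
        coords = np.zeros((n_conformers, n_sites, 3))
        coords[:, 1:, :] = np.cumsum(bonds * bond_length, axis=1)
        return Ensemble(coordinates=coords)
    raise ValueError(f"unknown chain model {model!r}; choose 'fjc' or 'rod'")


def write_ensemble_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB of alpha-carbon pseudo-atoms
    (one GLY CA per site), round-trippable through the ensemble reader."""
    n = ensemble.n_sites
    template = struc.AtomArray(n)
    template.coord = ensemble.coordinates[0]
    template.chain_id = np.full(n, "A")
    template.res_id = np.arange(1, n + 1)
    template.res_name = np.full(n, "GLY")
    template.atom_name = np.full(n, "CA")
    template.element = np.full(n, "C")
    template.hetero = np.zeros(n, dtype=bool)
    stack = struc.AtomArrayStack(ensemble.n_conformers, n)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = ensemble.coordinates.copy()
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
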