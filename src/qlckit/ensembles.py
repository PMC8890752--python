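"""Descriptors of conformer ensembles of disordered protein regions.

Two chain-dimension summaries are computed from multi-model coordinate
sets: the radius of gyration Rg (root-mean-square distance of sites from
their centroid, reported per conformer and as an ensemble mean), and the
apparent scaling exponent nu_app, the slope of log RMS inter-site distance
versus log sequence separation |i - j|.  An ideal (theta-state) chain gives
nu ~ 0.5 and a rigid rod gives nu = 1.0 exactly, bracketing the compact-to-
expanded range typical of disordered regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Ensemble",
    "ScalingFit",
    "EnsembleRg",
    "read_ensemble",
    "radius_of_gyration",
    "ensemble_rg",
    "apparent_scaling_exponent",
]


@dataclass(frozen=True)
class Ensemble:
    """Conformer coordinates, shape (n_conformers, n_sites, 3), in Angstrom.
    ``site_labels`` are residue numbers when read from a structure file."""

    coordinates: np.ndarray
    site_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_conformers, n_sites, 3)")
        if coords.shape[0] < 1 or coords.shape[1] < 1:
            raise ValueError("ensemble must contain at least one conformer and one site")
        if not np.isfinite(coords).all():
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_conformers(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class ScalingFit:
    """Least-squares power-law fit RMS(|i-j|=s) ~ prefactor * s**nu_app."""

    nu_app: float
    prefactor: float  # Angstrom
    r_squared: float
    min_separation: int
    n_separations: int

    def __post_init__(self) -> None:
        if self.n_separations < 5:
            raise ValueError("scaling fit needs at least 5 distinct separations")


@dataclass(frozen=True)
class EnsembleRg:
    mean: float
    sd: float
    se: float
    per_conformer: np.ndarray


def read_ensemble(path: str | Path, selection: str = "CA") -> Ensemble:
    """Read a multi-model PDB file into an ensemble of selected atoms
    (default alpha-carbons), one conformer per MODEL, sites ordered by
    residue number."""
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure()  # AtomArrayStack, all models
    except Exception as exc:  # models with differing atom counts
        raise ValueError(f"cannot read {path} as an ensemble: {exc}") from exc
    if not isinstance(stack, struc.AtomArrayStack):
        stack = struc.stack([stack])
    mask = stack.atom_name == selection
    if not mask.any():
        raise ValueError(f"no atoms match selection {selection!r} in {path}")
    sub = stack[..., mask]
    order = np.argsort(sub.res_id, kind="stable")
    sub = sub[..., order]
    return Ensemble(coordinates=np.asarray(sub.coord, dtype=float), site_labels=np.asarray(sub.res_id))


def radius_of_gyration(conformer: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Radius of gyration of one conformer (Angstrom).

    Rg = sqrt( sum_i w_i |r_i - rbar|^2 / sum_i w_i ) with rbar the weighted
    centroid; unit weights by default (geometric Rg).
    """
    pts = np.asarray(conformer, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("conformer must be an (n >= 2, 3) coordinate array")
    if weights is None:
        w = np.ones(pts.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (pts.shape[0],) or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative, one per site, not all zero")
    centroid = (w[:, None] * pts).sum(axis=0) / w.sum()
    sq = ((pts - centroid) ** 2).sum(axis=1)
    return float(np.sqrt((w * sq).sum() / w.sum()))


def ensemble_rg(ensemble: Ensemble, weights: np.ndarray | None = None) -> EnsembleRg:
    """Per-conformer Rg aggregated into mean, standard deviation, and
    standard error of the mean."""
    rgs = np.array([radius_of_gyration(c, weights) for c in ensemble.coordinates])
    sd = float(rgs.std(ddof=1)) if len(rgs) > 1 else 0.0
    return EnsembleRg(
        mean=float(rgs.mean()),
        sd=sd,
        se=sd / np.sqrt(len(rgs)) if len(rgs) > 1 else 0.0,
        per_conformer=rgs,
    )


def internal_distances(ensemble: Ensemble, min_separation: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """RMS inter-site distance per sequence separation.

    For each s >= min_separation, the root of the mean squared distance over
    all site pairs (i, j) with |i - j| = s and over all conformers.  Returns
    (separations, rms_distances).
    """
    coords = ensemble.coordinates
    n_sites = ensemble.n_sites
    seps = np.arange(min_separation, n_sites)
    rms = np.empty(len(seps))
    for k, s in enumerate(seps):
        diffs = coords[:, s:, :] - coords[:, :-s, :]
        rms[k] = np.sqrt((diffs**2).sum(axis=2).mean())
    return seps, rms


def apparent_scaling_exponent(ensemble: Ensemble, min_separation: int = 10) -> ScalingFit:
    """Apparent scaling exponent nu_app from internal-distance scaling.

    Fits log(RMS distance) against log(separation) by ordinary least
    squares over all separations s >= min_separation; the slope is nu_app.
    The default min_separation of 10 skips short separations dominated by
    local chain stiffness.
    """
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    if ensemble.n_sites <= min_separation + 5:
        raise ValueError(
            f"need n_sites > min_separation + 5 "
            f"(got {ensemble.n_sites} sites, min_separation {min_separation})"
        )
    seps, rms = internal_distances(ensemble, min_separation)
    if (rms <= 0).any():
        raise ValueError("zero inter-site distance encountered; cannot fit log-log")
    x = np.log(seps.astype(float))
    y = np.log(rms)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - (resid**2).sum() / ss_tot
    return ScalingFit(
        nu_app=float(slope),
        prefactor=float(np.exp(intercept)),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        min_separation=min_separation,
        n_separations=len(seps),
    )
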