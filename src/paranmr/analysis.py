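"""Superposition, RMSD distributions, KDEs, and restraint-density statistics.

Backbone RMSD is defined over N, CA, C atoms (amide protons excluded —
conventional, and robust to proton placement).  Ensemble comparisons follow
the standard recipe: discard an initial fraction of the trajectory, compute
per-frame least-squares-superposed RMSD to a reference over a stated atom
selection (optionally excluding flexible tail windows), and summarize the
distribution with a Gaussian kernel density estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .io import Structure

__all__ = [
    "RMSDSeries",
    "backbone_selection",
    "kabsch_superpose",
    "rmsd_distribution",
    "kde",
    "restraint_stats",
]

BACKBONE_ATOMS = ("N", "CA", "C")


def backbone_selection(
    structure: Structure,
    exclude: list[tuple[str, int, int]] | None = None,
    chains: list[str] | None = None,
) -> np.ndarray:
    """Atom indices of backbone N/CA/C, optionally excluding residue windows.

    ``exclude`` entries are (chain, first_residue, last_residue) inclusive —
    e.g. flexible terminal tails absent from a reference structure.
    """
    exclude = exclude or []
    out = []
    for i, a in enumerate(structure.atoms):
        if a.atom_name not in BACKBONE_ATOMS:
            continue
        if chains is not None and a.chain_id not in chains:
            continue
        if any(
            a.chain_id == c and lo <= a.residue_index <= hi for c, lo, hi in exclude
        ):
            continue
        out.append(i)
    return np.array(out, dtype=int)


@dataclass(frozen=True)
class RMSDSeries:
    """Per-frame backbone RMSD (Å) with the selection that produced it."""

    values: np.ndarray
    selection: np.ndarray
    discard: float

    def __len__(self) -> int:
        return len(self.values)


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, selection: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD over the
    selected atoms; the rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    x = mobile[sel]
    y = reference[sel]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    cov = x0.T @ y0
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-10 * max(1.0, s[0]):
        raise ValueError("degenerate (collinear) atom set: rotation ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    D = np.diag([1.0, 1.0, d])
    rot = vt.T @ D @ u.T
    trans = yc - rot @ xc
    moved = x @ rot.T + trans
    rmsd = math.sqrt(float(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return rot, trans, rmsd


def rmsd_distribution(
    frames: list[np.ndarray],
    reference: np.ndarray,
    selection: np.ndarray,
    discard: float = 0.0,
) -> RMSDSeries:
    """Per-frame superposed RMSD after discarding an initial fraction."""
    if not 0 <= discard < 1:
        raise ValueError("discard must be in [0, 1)")
    first = int(math.floor(discard * len(frames)))
    kept = frames[first:]
    if not kept:
        raise ValueError("no frames remain after discard")
    values = np.array(
        [kabsch_superpose(f, reference, selection)[2] for f in kept]
    )
    return RMSDSeries(values=values, selection=np.asarray(selection), discard=discard)


def kde(
    series, bandwidth: float | None = None, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate of an RMSD sample.

    Bandwidth defaults to Scott's rule.  Returns (grid, density); the
    density integrates to ~1 over a grid padded by 3 bandwidths.
    """
    values = np.asarray(series.values if isinstance(series, RMSDSeries) else series)
    if values.size < 2:
        raise ValueError("need at least 2 values for a KDE")
    if np.ptp(values) == 0:
        raise ValueError(
            "zero-variance sample: report the exact value instead of a KDE"
        )
    estimator = gaussian_kde(values, bw_method=bandwidth)
    if grid is None:
        bw = math.sqrt(float(estimator.covariance[0, 0]))
        grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, 512)
    return grid, estimator(grid)


def restraint_stats(collections, n_residues: int) -> dict:
    """Per-residue restraint-density statistics.

    Returns total and short-class restraints per residue plus a per-site
    breakdown — the sparse-data bookkeeping used to compare restraint
    networks (e.g. "6.4 total and 0.8 short-distance restraints per
    residue" style counts).
    """
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    total = 0
    short = 0
    per_site: dict[str, dict[str, int]] = {}
    for coll in collections:
        for r in coll.restraints:
            total += 1
            site = per_site.setdefault(r.site_a, {"total": 0, "short": 0})
            site["total"] += 1
            if r.dclass == "short":
                short += 1
                site["short"] += 1
    return {
        "total_per_residue": total / n_residues,
        "short_per_residue": short / n_residues,
        "n_restraints": total,
        "n_short": short,
        "per_site": per_site,
    }
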