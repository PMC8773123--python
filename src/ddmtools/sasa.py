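"""Shrake–Rupley solvent-accessible surface area.

The accessible surface of an atom is the locus traced by the centre of a
probe sphere (radius 1.4 Å, a water molecule) rolling over the van der Waals
surface.  The Shrake–Rupley approximation samples each atom's expanded
sphere (radius r_vdw + r_probe) with a quasi-uniform point set and counts
the fraction of points not occluded by any neighbouring expanded sphere:

    area_i = (n_free / n_points) * 4π (r_i + probe)²

Points are placed by a deterministic golden-section spiral — no randomness
enters the calculation, so areas are bit-reproducible.  Neighbour lookup
uses a k-d tree; only atoms within r_i + r_j + 2·probe can occlude atom i.

Defaults (probe 1.4 Å, 960 points) keep the quadrature error well under a
percent of the area of an isolated atom; a convergence test in the suite
checks that doubling the point count moves totals by <0.3 %.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .radii import RADII_SET_NAME
from .structure_io import ResidueKey, StructureModel

__all__ = ["SASAResult", "sphere_points", "sasa", "sasa_model"]

DEFAULT_PROBE = 1.4  # Å
DEFAULT_N_POINTS = 960
MIN_N_POINTS = 60


@dataclass
class SASAResult:
    """Per-atom accessible areas (Å²) plus per-residue and total sums."""

    per_atom: np.ndarray
    per_residue: dict[ResidueKey, float]
    total: float
    probe: float
    n_points: int
    radii_set: str = RADII_SET_NAME


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-section spiral)."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n, dtype=float)
    # latitude: uniform in z; longitude: golden-angle increments
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    keys: list[ResidueKey] | None = None,
    points: np.ndarray | None = None,
) -> SASAResult:
    """Shrake–Rupley SASA for an atom set.

    Parameters
    ----------
    coords, radii:
        (M, 3) coordinates and (M,) van der Waals radii in Å.
    probe:
        Probe (solvent) radius in Å.
    n_points:
        Sphere sample points per atom; fewer than 60 is refused as too
        coarse a quadrature.
    keys:
        Optional per-atom residue keys for the per-residue sums.
    points:
        Optional explicit (n, 3) unit-sphere sample directions overriding
        the golden-spiral default — e.g. a co-rotated sphere when checking
        rigid-motion invariance, where totals are then identical to within
        floating-point error rather than quadrature error.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    m = coords.shape[0]
    if m == 0:
        raise ValueError("no atoms")
    if points is not None:
        unit = np.asarray(points, dtype=float)
        n_points = unit.shape[0]
    if n_points < MIN_N_POINTS:
        raise ValueError(f"n_points must be >= {MIN_N_POINTS}")
    if coords.shape != (m, 3) or radii.shape != (m,):
        raise ValueError("coords must be (M, 3) and radii (M,)")

    if points is None:
        unit = sphere_points(n_points)
    extended = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * extended.max()
    per_atom = np.empty(m, dtype=float)
    for i in range(m):
        r_i = extended[i]
        pts = coords[i] + r_i * unit
        free = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], r_i + max_reach / 2.0):
            # conservative radius; exact pair criterion below
            if j == i:
                continue
            r_j = extended[j]
            d2 = np.sum((coords[j] - coords[i]) ** 2)
            if d2 >= (r_i + r_j) ** 2:
                continue
            free &= np.sum((pts - coords[j]) ** 2, axis=1) >= r_j * r_j
            if not free.any():
                break
        per_atom[i] = free.sum() / n_points * 4.0 * np.pi * r_i * r_i

    per_residue: dict[ResidueKey, float] = {}
    if keys is not None:
        for k, a in zip(keys, per_atom):
            per_residue[k] = per_residue.get(k, 0.0) + float(a)
    return SASAResult(
        per_atom=per_atom,
        per_residue=per_residue,
        total=float(per_atom.sum()),
        probe=probe,
        n_points=n_points,
    )


def sasa_model(
    model: StructureModel,
    selection: list[ResidueKey] | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SASAResult:
    """SASA of a structure model, optionally restricted to a residue selection.

    Only atoms of the selection participate — atoms outside neither count
    nor occlude (the selection is treated as an isolated molecule).
    """
    coords, radii, atoms = model.atom_records(selection)
    if coords.shape[0] == 0:
        raise ValueError("selection contains no atoms")
    return sasa(coords, radii, probe=probe, n_points=n_points,
                keys=[a.key for a in atoms])
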