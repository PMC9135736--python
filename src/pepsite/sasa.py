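"""Shrake-Rupley solvent-accessible surface area and buried surface area.

Sphere points come from a deterministic golden-spiral (Fibonacci) lattice,
so areas are reproducible bit-for-bit. Radii are standard heavy-atom van der
Waals values; unknown elements fall back to 1.8 Å with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .structure import ProteinStructure

VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.20,
}
DEFAULT_RADIUS = 1.8
PROBE_RADIUS = 1.4


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform unit-sphere points on a golden-spiral lattice."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def element_radii(elements: list[str]) -> np.ndarray:
    radii = np.empty(len(elements))
    for i, el in enumerate(elements):
        key = el.upper()
        if key in VDW_RADII:
            radii[i] = VDW_RADII[key]
        else:
            warnings.warn(f"unknown element {el!r}: using {DEFAULT_RADIUS} Å radius",
                          stacklevel=2)
            radii[i] = DEFAULT_RADIUS
    return radii


def shrake_rupley_sasa(
    coords: np.ndarray,
    elements: list[str],
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in Å².

    Each atom's probe-expanded sphere is sampled with ``n_points`` test
    points; a point counts as accessible when it lies outside every other
    atom's expanded sphere. Area = accessible fraction × 4π(r + probe)².
    """
    coords = np.asarray(coords, dtype=float)
    radii = element_radii(elements) + probe
    n = len(coords)
    unit = _sphere_points(n_points)
    areas = np.empty(n)
    tree = cKDTree(coords)
    rmax = radii.max()
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax) if j != i]
        if neighbors:
            nb = coords[neighbors]
            nr = radii[neighbors]
            d2 = ((pts[:, None, :] - nb[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return areas


def structure_sasa(structure: ProteinStructure, probe: float = PROBE_RADIUS,
                   n_points: int = 960) -> float:
    coords, elements, _ = structure.heavy_atoms()
    return float(shrake_rupley_sasa(coords, elements, probe, n_points).sum())


def buried_surface_area(
    a: ProteinStructure,
    b: ProteinStructure,
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
) -> float:
    """BSA = SASA(A) + SASA(B) - SASA(A ∪ B), in Å² (unhalved two-body form)."""
    ca, ea, _ = a.heavy_atoms()
    cb, eb, _ = b.heavy_atoms()
    sasa_a = shrake_rupley_sasa(ca, ea, probe, n_points).sum()
    sasa_b = shrake_rupley_sasa(cb, eb, probe, n_points).sum()
    both = shrake_rupley_sasa(
        np.concatenate([ca, cb]), ea + eb, probe, n_points
    ).sum()
    return float(sasa_a + sasa_b - both)
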