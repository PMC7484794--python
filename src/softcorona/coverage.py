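"""Protein footprints and nanoparticle monolayer coverage.

A protein of mass M (Da) with partial specific volume 0.73 cm^3 g^-1
occupies V = 1.212e-3 nm^3/Da * M; modelled as a sphere its radius is
R = 0.066 * M^(1/3) nm and its cross-section pi*R^2. Proteins with known
3-D coordinates instead get an orientation-dependent footprint range: the
atom cloud is projected onto planes orthogonal to uniformly sampled
directions (Fibonacci sphere) and the convex-hull area of each projection
is measured, giving (min, max) cross-sections.

The coverage ratio of a nanoparticle of diameter d is the copy-weighted sum
of footprints divided by the particle surface pi*d^2; the (min, max)
orientations bound it. A ratio near 1 indicates a protein monolayer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull

from .errors import DegenerateGeometryError, IncompleteInputError, InvalidMeasurementError
from .quantification import CoronaMatrix

#: Specific volume prefactor, nm^3 per Da (v-bar = 0.73 cm^3/g).
VOLUME_PER_DALTON = 1.212e-3
#: Sphere-radius prefactor, nm per Da^(1/3).
RADIUS_PREFACTOR = 0.066


@dataclass(frozen=True)
class NanoparticleSpec:
    """Nominal nanoparticle geometry; surface area = pi * d^2."""

    diameter: float  # nm
    label: str = "NP"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidMeasurementError("diameter must be > 0")

    @property
    def surface_area(self) -> float:
        return np.pi * self.diameter**2


@dataclass(frozen=True)
class FootprintRange:
    """Minimum and maximum cross-section areas of one protein (nm^2)."""

    a_min: float
    a_max: float
    source: str  # "sphere_model" | "coordinates"

    def __post_init__(self) -> None:
        if not (0 < self.a_min <= self.a_max):
            raise InvalidMeasurementError("need 0 < a_min <= a_max")


def protein_volume(mass_da: float) -> float:
    """Protein volume in nm^3 from its mass in Da."""
    if mass_da <= 0:
        raise InvalidMeasurementError("mass must be > 0")
    return VOLUME_PER_DALTON * mass_da


def protein_radius(mass_da: float) -> float:
    """Equivalent-sphere radius in nm, R = 0.066 * M^(1/3)."""
    if mass_da <= 0:
        raise InvalidMeasurementError("mass must be > 0")
    return RADIUS_PREFACTOR * mass_da ** (1.0 / 3.0)


def sphere_cross_section(mass_da: float) -> float:
    """Cross-section area pi*R^2 of the equivalent sphere (nm^2)."""
    return np.pi * protein_radius(mass_da) ** 2


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _projected_area(coords: np.ndarray, direction: np.ndarray) -> float:
    """Convex-hull area of the point cloud projected along ``direction``."""
    d = direction / np.linalg.norm(direction)
    # orthonormal basis of the projection plane
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    pts2 = np.column_stack([coords @ u, coords @ v])
    return ConvexHull(pts2).volume  # 2-D hull "volume" is its area


def cross_section_range(
    mass_da: Optional[float] = None,
    coordinates: Optional[np.ndarray] = None,
    n_directions: int = 256,
) -> FootprintRange:
    """Orientation-dependent footprint of one protein.

    With ``coordinates`` (N x 3, nm): min/max convex-hull projection areas
    over ``n_directions`` Fibonacci-sphere directions, each extreme then
    polished by a local (Nelder-Mead) search over the direction angles so
    narrow extrema between sampled directions are not missed. Without
    coordinates, the sphere model gives a_min = a_max = pi*(0.066*M^(1/3))^2.
    """
    if coordinates is None:
        if mass_da is None:
            raise IncompleteInputError("need a mass or coordinates")
        a = sphere_cross_section(mass_da)
        return FootprintRange(a_min=a, a_max=a, source="sphere_model")

    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 4:
        raise DegenerateGeometryError("need >= 4 points with 3 coordinates")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 3:
        raise DegenerateGeometryError("points are coplanar or colinear")
    directions = fibonacci_sphere(n_directions)
    areas = np.array([_projected_area(centered, d) for d in directions])

    def polish(start: np.ndarray, sign: float) -> float:
        theta0 = np.arccos(np.clip(start[2], -1, 1))
        phi0 = np.arctan2(start[1], start[0])

        def objective(angles):
            th, ph = angles
            d = np.array(
                [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
            )
            return sign * _projected_area(centered, d)

        res = minimize(objective, [theta0, phi0], method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 0.0, "maxiter": 200})
        return sign * res.fun

    a_min = min(float(areas.min()), polish(directions[np.argmin(areas)], 1.0))
    a_max = max(float(areas.max()), polish(directions[np.argmax(areas)], -1.0))
    return FootprintRange(a_min=a_min, a_max=a_max, source="coordinates")


def coverage_ratio(
    matrix: CoronaMatrix,
    footprints: Mapping[str, FootprintRange],
    np_spec: NanoparticleSpec,
    sample: str,
) -> tuple[float, float]:
    """(lower, upper) monolayer coverage ratio of one sample.

    lower = sum_i copies_i * a_min_i / (pi d^2) and analogously for upper;
    every protein with positive copies must have a footprint.
    """
    if sample not in matrix.samples:
        raise IncompleteInputError(f"sample {sample!r} not in matrix")
    j = matrix.samples.index(sample)
    copies = matrix.copies[:, j]
    lower = upper = 0.0
    for i, acc in enumerate(matrix.proteins):
        if copies[i] <= 0:
            continue
        fp = footprints.get(acc)
        if fp is None:
            raise IncompleteInputError(f"no footprint for {acc!r}")
        lower += copies[i] * fp.a_min
        upper += copies[i] * fp.a_max
    area = np_spec.surface_area
    return lower / area, upper / area


def sphere_footprints(matrix: CoronaMatrix) -> dict[str, FootprintRange]:
    """Sphere-model footprints for every protein in a corona matrix."""
    return {
        acc: cross_section_range(mass_da=mw)
        for acc, mw in zip(matrix.proteins, matrix.mw)
    }


def read_pdb_coordinates(path) -> np.ndarray:
    """Atom coordinates (N x 3, nm) from a PDB-format file.

    Reads ATOM records of the first model, first alternate location only;
    coordinates are converted from Angstrom to nm.
    """
    coords = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("ENDMDL"):
                break
            if not line.startswith("ATOM"):
                continue
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            coords.append(
                (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            )
    if not coords:
        raise DegenerateGeometryError(f"no ATOM records in {path}")
    return np.asarray(coords) * 0.1  # Angstrom -> nm
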