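"""Electrode arrays posed on the cortical surface, and placement constraints.

The default array is a 43-electrode tile at 1 mm pitch (a 7x7 grid with the
four corner sites and the two long-axis mid-edge sites unpopulated), modelled
on intracortical tiles used for cortical visual prostheses.  An
:class:`Implant` is such an array posed at a chosen grayordinate: the planar
electrode offsets are rotated in the local tangent plane (estimated by least
squares from the K nearest grayordinates) and embedded in 3D.

:func:`validate_placement` checks the anatomical and hardware constraints of
a multi-implant plan: rotation within +-45 deg of the coronal plane, implant
centres within 20 mm of the induction-coil centroid, a 3.6 mm minimum
separation between arrays (relaxable for high implant counts, in which case
edge overlaps are quantified instead), placement on gyri, and most electrodes
over V1/V2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .errors import DegenerateSurfaceError, ParameterError
from .surface import RetinotopicSurface


@dataclass(frozen=True)
class ArrayLayout:
    """Planar electrode layout of one array.

    ``electrode_offsets`` are 2D offsets (mm) in the array plane; axis 0 of
    the offsets is the array's long axis.  ``footprint`` is the encapsulated
    tile extent as (long side, short side) in mm.
    """

    electrode_offsets: np.ndarray  # (n, 2) mm
    pitch: float = 1.0
    footprint: tuple[float, float] = (8.0, 7.0)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_offsets)


def gennaris_layout() -> ArrayLayout:
    """Default 43-electrode tile: 7x7 grid at 1 mm pitch, minus the four
    corners and the two mid-edge sites at the ends of the long axis."""
    removed = {(0, 0), (0, 6), (6, 0), (6, 6), (0, 3), (6, 3)}
    offsets = [
        (float(i - 3), float(j - 3))
        for i in range(7)
        for j in range(7)
        if (i, j) not in removed
    ]
    return ArrayLayout(electrode_offsets=np.array(offsets), pitch=1.0)


@dataclass
class Implant:
    """A posed electrode array on the surface."""

    layout: ArrayLayout
    center_vertex: int
    rotation_deg: float
    hemisphere: str
    center_pos: np.ndarray          # (3,) mm
    electrode_positions: np.ndarray  # (n, 3) mm
    normal: np.ndarray              # (3,) unit, outward
    long_axis: np.ndarray           # (3,) unit, in tangent plane
    short_axis: np.ndarray          # (3,) unit, in tangent plane

    def footprint_corners(self) -> np.ndarray:
        """(4, 3) corners of the footprint rectangle in 3D, ordered."""
        L, W = self.layout.footprint
        c = self.center_pos
        u, v = self.long_axis, self.short_axis
        return np.array(
            [
                c + 0.5 * (su * L * u + sv * W * v)
                for su, sv in ((-1, -1), (1, -1), (1, 1), (-1, 1))
            ]
        )


def _tangent_basis(
    positions: np.ndarray, outward_hint: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares plane through ``positions``; returns (e1, e2, normal).

    The in-plane reference axis e1 is the projection of the global
    inferior-superior axis z onto the plane, so that a long axis along e1 lies
    as close to the coronal (x-z) plane as the local geometry allows; the
    rotation parameter is measured from e1.  Falls back to the
    posterior-anterior axis when the plane normal is parallel to z.
    """
    centered = positions - positions.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    if np.dot(normal, outward_hint) < 0:
        normal = -normal
    for ref in (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0])):
        e1 = ref - np.dot(ref, normal) * normal
        nrm = np.linalg.norm(e1)
        if nrm > 1e-6:
            e1 = e1 / nrm
            break
    e2 = np.cross(normal, e1)
    return e1, e2, normal


def place_implant(
    surface: RetinotopicSurface,
    center_vertex: int,
    rotation_deg: float,
    layout: ArrayLayout | None = None,
    k_neighbours: int = 20,
    neighbourhood_mm: float = 20.0,
) -> Implant:
    """Pose an array with its centre at a grayordinate, parallel to the
    local cortical surface.

    The tangent plane is fitted by least squares over the ``k_neighbours``
    nearest grayordinates (which must lie within ``neighbourhood_mm``);
    electrode offsets are rotated by ``rotation_deg`` about the plane normal
    and embedded from the centre vertex.
    """
    if layout is None:
        layout = gennaris_layout()
    if not np.isfinite(rotation_deg):
        raise ParameterError("rotation_deg must be finite")
    n = len(surface)
    if not (0 <= center_vertex < n):
        raise ParameterError(f"center_vertex {center_vertex} out of range")
    if k_neighbours > n:
        raise DegenerateSurfaceError("surface smaller than k_neighbours")

    center = surface.positions[center_vertex]
    dist, idx = surface.kdtree.query(center, k=k_neighbours)
    dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
    if np.any(dist > neighbourhood_mm):
        raise DegenerateSurfaceError(
            f"fewer than {k_neighbours} grayordinates within "
            f"{neighbourhood_mm} mm of vertex {center_vertex}"
        )

    hemi = str(surface.hemisphere[center_vertex])
    outward = np.array([-1.0, 0.0, 0.0]) if hemi == "left" else np.array([1.0, 0.0, 0.0])
    e1, e2, normal = _tangent_basis(surface.positions[idx], outward)

    phi = np.deg2rad(rotation_deg)
    long_axis = np.cos(phi) * e1 + np.sin(phi) * e2
    short_axis = -np.sin(phi) * e1 + np.cos(phi) * e2
    offs = layout.electrode_offsets
    positions = center + np.outer(offs[:, 0], long_axis) + np.outer(offs[:, 1], short_axis)

    return Implant(
        layout=layout,
        center_vertex=int(center_vertex),
        rotation_deg=float(rotation_deg),
        hemisphere=hemi,
        center_pos=center.copy(),
        electrode_positions=positions,
        normal=normal,
        long_axis=long_axis,
        short_axis=short_axis,
    )


def _project_to_plane(
    points: np.ndarray, origin: np.ndarray, e1: np.ndarray, e2: np.ndarray
) -> np.ndarray:
    rel = points - origin
    return np.column_stack([rel @ e1, rel @ e2])


def overlap_distance(a: Implant, b: Implant) -> float:
    """Maximum overlap distance between the footprints of two implants.

    Both footprint rectangles are projected into the tangent plane halfway
    between the implants (normal = mean of the two array normals).  The
    overlap distance is the extent of the footprint intersection measured
    across the long edges, i.e. along the short axis of either implant
    (the larger of the two extents); 0 when the footprints are disjoint.
    Symmetric in its arguments.
    """
    normal = a.normal + b.normal
    nrm = np.linalg.norm(normal)
    normal = a.normal if nrm < 1e-9 else normal / nrm
    origin = 0.5 * (a.center_pos + b.center_pos)
    for ref in (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0])):
        e1 = ref - np.dot(ref, normal) * normal
        if np.linalg.norm(e1) > 1e-6:
            e1 = e1 / np.linalg.norm(e1)
            break
    e2 = np.cross(normal, e1)

    poly_a = Polygon(_project_to_plane(a.footprint_corners(), origin, e1, e2))
    poly_b = Polygon(_project_to_plane(b.footprint_corners(), origin, e1, e2))
    inter = poly_a.intersection(poly_b)
    if inter.is_empty or inter.area < 1e-12:
        return 0.0

    coords = np.asarray(inter.convex_hull.exterior.coords)
    depth = 0.0
    for imp in (a, b):
        axis2d = np.array([imp.short_axis @ e1, imp.short_axis @ e2])
        nrm = np.linalg.norm(axis2d)
        if nrm < 1e-9:
            continue
        proj = coords @ (axis2d / nrm)
        depth = max(depth, float(proj.max() - proj.min()))
    return depth


@dataclass
class PlacementConstraints:
    """Hardware and anatomical constraint thresholds."""

    max_rotation_deg: float = 45.0
    max_coil_distance_mm: float = 20.0
    min_separation_mm: float = 3.6
    coil_centroid: np.ndarray | None = None  # per-hemisphere centroid if None
    allow_overlap: bool = False
    v1v2_min_fraction: float = 0.9


@dataclass
class ConstraintReport:
    """Outcome of checking a multi-implant plan against all constraints."""

    rotation_ok: bool
    coil_ok: bool
    separation_ok: bool
    region_ok: bool
    gyrus_ok: bool
    separation_mm: np.ndarray          # (n, n) min electrode-pair distances
    overlaps_mm: list[float]           # positive footprint overlaps only
    v1v2_fraction: float
    coil_distances_mm: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def all_ok(self) -> bool:
        return (self.rotation_ok and self.coil_ok and self.separation_ok
                and self.region_ok and self.gyrus_ok)

    def to_dict(self) -> dict:
        return {
            "rotation_ok": self.rotation_ok,
            "coil_ok": self.coil_ok,
            "separation_ok": self.separation_ok,
            "region_ok": self.region_ok,
            "gyrus_ok": self.gyrus_ok,
            "separation_mm": self.separation_mm.tolist(),
            "overlaps_mm": list(self.overlaps_mm),
            "v1v2_fraction": self.v1v2_fraction,
            "coil_distances_mm": self.coil_distances_mm.tolist(),
            "warnings": list(self.warnings),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def validate_placement(
    implants: list[Implant],
    surface: RetinotopicSurface,
    constraints: PlacementConstraints | None = None,
) -> ConstraintReport:
    """Check every placement constraint and quantify array overlaps.

    Boundary semantics are inclusive: a rotation of exactly 45 deg, a coil
    distance of exactly 20 mm and a separation of exactly 3.6 mm all pass.
    With ``allow_overlap`` (the high-implant-count regime) separation
    violations are reported as warnings rather than failures, but the
    pairwise footprint overlaps are still quantified.
    """
    if not implants:
        raise ParameterError("at least one implant required")
    c = constraints or PlacementConstraints()
    warnings: list[str] = []

    rotation_ok = all(abs(im.rotation_deg) <= c.max_rotation_deg for im in implants)

    centers = np.array([im.center_pos for im in implants])
    if c.coil_centroid is not None:
        coil_dist = np.linalg.norm(centers - np.asarray(c.coil_centroid), axis=1)
    else:
        coil_dist = np.empty(len(implants))
        hemis = np.array([im.hemisphere for im in implants])
        for h in np.unique(hemis):
            sel = hemis == h
            centroid = centers[sel].mean(axis=0)
            coil_dist[sel] = np.linalg.norm(centers[sel] - centroid, axis=1)
    coil_ok = bool(np.all(coil_dist <= c.max_coil_distance_mm))

    n = len(implants)
    sep = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(
                implants[i].electrode_positions[:, None, :]
                - implants[j].electrode_positions[None, :, :],
                axis=2,
            ).min()
            sep[i, j] = sep[j, i] = d
    off_diag = sep[np.triu_indices(n, k=1)]
    # inclusive boundary: exactly the minimum separation passes
    sep_violated = bool(
        off_diag.size and off_diag.min() < c.min_separation_mm - 1e-9
    )
    if sep_violated and c.allow_overlap:
        warnings.append(
            f"minimum separation {off_diag.min():.2f} mm below "
            f"{c.min_separation_mm} mm (allowed for this implant count)"
        )
        separation_ok = True
    else:
        separation_ok = not sep_violated

    overlaps = []
    for i in range(n):
        for j in range(i + 1, n):
            d = overlap_distance(implants[i], implants[j])
            if d > 1e-9:
                overlaps.append(d)

    electrodes = np.vstack([im.electrode_positions for im in implants])
    _, nearest = surface.kdtree.query(electrodes, k=1)
    in_v1v2 = np.isin(surface.roi[nearest], ("V1", "V2"))
    v1v2_fraction = float(in_v1v2.mean())
    region_ok = v1v2_fraction >= c.v1v2_min_fraction

    gyrus_ok = all(bool(surface.is_gyrus[im.center_vertex]) for im in implants)

    return ConstraintReport(
        rotation_ok=rotation_ok,
        coil_ok=coil_ok,
        separation_ok=separation_ok,
        region_ok=region_ok,
        gyrus_ok=gyrus_ok,
        separation_mm=sep,
        overlaps_mm=overlaps,
        v1v2_fraction=v1v2_fraction,
        coil_distances_mm=coil_dist,
        warnings=warnings,
    )
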