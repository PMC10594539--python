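"""Predictive quality metrics of phosphene maps.

Three map-level quantities correlate with the acuity and recognition
performance a map can support:

* **Complexity** — a point-set adaptation of a shape-complexity measure,
  combining the entropy of distances to the map centroid (global structure),
  the entropy of local angles (local structure) and a perceptual smoothness
  term.  Regular arrangements (a circle) score low; random scatters score
  high.
* **Mutual information** between a stimulus image and the map rendering,
  from the joint histogram of co-located pixels.
* **Area** — the area of a compact concave boundary around the phosphene
  centres (the tightest single-component alpha-shape that still contains all
  points), which measures visual-field coverage without bridging across
  empty field the way a convex hull would.

Entropies and mutual information are reported in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from .errors import ParameterError

DEFAULT_HIST_BINS = 16
DEFAULT_MI_BINS = 64
MI_FLOOR = 1e-12


@dataclass
class ComplexityScore:
    distance_entropy: float   # bits
    angle_entropy: float      # bits
    smoothness: float         # [0, 1]; 0 = locally flat, 1 = spiky
    combined: float           # [0, 1]


@dataclass
class MIResult:
    mi: float                 # bits
    n_bins: int
    excluded_mass: float      # probability mass dropped by the 1e-12 floor


@dataclass
class AreaResult:
    area: float               # deg^2
    boundary: np.ndarray      # (M, 2) ordered polygon vertices
    shrink: float = 1.0
    degenerate: bool = False


def _as_points(obj) -> np.ndarray:
    if hasattr(obj, "x") and hasattr(obj, "y"):
        return np.column_stack([np.asarray(obj.x, float), np.asarray(obj.y, float)])
    pts = np.asarray(obj, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("expected an (N, 2) point array or a phosphene map")
    return pts


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p = p / p.sum()
    return float(-(p * np.log2(p)).sum())


def global_distance_entropy(points, n_bins: int = DEFAULT_HIST_BINS) -> float:
    """Entropy (bits) of the histogram of distances to the point centroid.

    Bins are equal-width over [0, max distance].  Coincident points (zero
    spread) give zero entropy by convention.
    """
    pts = _as_points(points)
    if len(pts) < 2:
        raise ParameterError("need at least 2 points")
    d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    dmax = d.max()
    if dmax <= 0:
        return 0.0
    counts, _ = np.histogram(d, bins=n_bins, range=(0.0, dmax))
    return _entropy_bits(counts)


def _local_angles(pts: np.ndarray) -> np.ndarray:
    """Angle (rad, in [0, pi]) at each point subtended by its two nearest
    neighbours.  Ties and duplicates resolve to the lowest index; a
    zero-length neighbour vector contributes angle 0."""
    n = len(pts)
    if n < 3:
        raise ParameterError("need at least 3 points")
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")  # stable: lowest index on ties
    n1, n2 = order[:, 0], order[:, 1]
    v1 = pts[n1] - pts
    v2 = pts[n2] - pts
    nrm = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    cosang = np.ones(n)
    ok = nrm > 0
    cosang[ok] = np.einsum("ij,ij->i", v1[ok], v2[ok]) / nrm[ok]
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def local_angle_entropy(points, n_bins: int = DEFAULT_HIST_BINS) -> float:
    """Entropy (bits) of the histogram of local neighbour angles over
    [0, pi]."""
    angles = _local_angles(_as_points(points))
    counts, _ = np.histogram(angles, bins=n_bins, range=(0.0, np.pi))
    return _entropy_bits(counts)


def perceptual_smoothness(points) -> float:
    """Mean per-point smoothness s = 1 - angle/pi.

    0 when every local angle is pi (collinear/flat neighbourhoods), 1 when
    every angle is 0 (degenerate spikes).
    """
    angles = _local_angles(_as_points(points))
    return float(np.mean(1.0 - angles / np.pi))


def map_complexity(points, n_bins: int = DEFAULT_HIST_BINS) -> ComplexityScore:
    """Combined complexity: unweighted mean of the two normalised entropies
    and the smoothness term.

    Smoothness enters directly (not inverted): near-pi local angles mean the
    point set is locally flat and regular, which is the low-complexity end,
    and they already score s ~= 0.
    """
    de = global_distance_entropy(points, n_bins)
    ae = local_angle_entropy(points, n_bins)
    sm = perceptual_smoothness(points)
    norm = np.log2(n_bins)
    combined = float(np.mean([de / norm, ae / norm, sm]))
    return ComplexityScore(distance_entropy=de, angle_entropy=ae,
                           smoothness=sm, combined=combined)


# --------------------------------------------------------------------------
# mutual information
# --------------------------------------------------------------------------

def _pad_centred(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape)
    h, w = img.shape
    r0 = (shape[0] - h) // 2
    c0 = (shape[1] - w) // 2
    out[r0:r0 + h, c0:c0 + w] = img
    return out


def mutual_information(
    img_a: np.ndarray, img_b: np.ndarray, n_bins: int = DEFAULT_MI_BINS
) -> MIResult:
    """Mutual information (bits) between two grayscale images in [0, 1].

    Images are zero-padded (centred) to a common size; the joint PMF is the
    2D histogram of co-located pixel pairs over ``n_bins`` equal-width bins.
    Joint cells below 1e-12 are excluded from the sum (their mass is
    reported), which speeds up the log-ratio accumulation on sparse joints.
    """
    a, b = np.asarray(img_a, float), np.asarray(img_b, float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("images must be non-empty")
    shape = (max(a.shape[0], b.shape[0]), max(a.shape[1], b.shape[1]))
    a, b = _pad_centred(a, shape), _pad_centred(b, shape)

    joint, _, _ = np.histogram2d(
        a.ravel(), b.ravel(), bins=n_bins, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    keep = pxy >= MI_FLOOR
    excluded = float(pxy[~keep].sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(keep, pxy / (px * py), 1.0)
        terms = np.where(keep, pxy * np.log2(ratio), 0.0)
    return MIResult(mi=float(max(terms.sum(), 0.0)), n_bins=n_bins,
                    excluded_mass=excluded)


# --------------------------------------------------------------------------
# concave boundary area
# --------------------------------------------------------------------------

def _triangle_circumradius(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    ab, ac = b - a, c - a
    area2 = np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])  # twice the area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 < 1e-12] = np.inf
    return r


def map_area(points) -> AreaResult:
    """Area (deg^2) under a compact concave boundary of the point set.

    The boundary is the tightest single-piece alpha-shape that still
    contains every point: Delaunay triangles are admitted in order of
    circumradius, and the smallest radius threshold whose triangle union is
    a single polygon covering all points wins (found by bisection, since the
    property is monotone in the threshold).  Collinear input yields zero
    area with the degenerate flag set.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise ParameterError("need at least 3 points")
    try:
        tri = Delaunay(pts)
    except Exception:
        return AreaResult(area=0.0, boundary=pts[:0], degenerate=True)
    if len(tri.simplices) == 0:
        return AreaResult(area=0.0, boundary=pts[:0], degenerate=True)

    radii = _triangle_circumradius(pts, tri.simplices)
    finite = np.isfinite(radii)
    if not finite.any():
        return AreaResult(area=0.0, boundary=pts[:0], degenerate=True)
    thresholds = np.unique(radii[finite])
    all_points = MultiPoint(pts)

    def union_at(threshold: float):
        keep = radii <= threshold
        polys = [Polygon(pts[s]) for s in tri.simplices[keep]]
        return unary_union(polys) if polys else None

    def acceptable(threshold: float) -> bool:
        u = union_at(threshold)
        return (
            u is not None
            and isinstance(u, Polygon)
            and not list(u.interiors)
            and u.buffer(1e-9).covers(all_points)
        )

    lo, hi = 0, len(thresholds) - 1
    if not acceptable(thresholds[hi]):
        # fall back to the convex hull (can happen with slivers at the rim)
        hull = MultiPoint(pts).convex_hull
        return AreaResult(area=float(hull.area),
                          boundary=np.asarray(hull.exterior.coords))
    while lo < hi:
        mid = (lo + hi) // 2
        if acceptable(thresholds[mid]):
            hi = mid
        else:
            lo = mid + 1
    poly = union_at(thresholds[lo])
    return AreaResult(area=float(poly.area),
                      boundary=np.asarray(poly.exterior.coords))
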