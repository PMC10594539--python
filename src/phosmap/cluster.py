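"""Density-based relocation of stimuli onto phosphene-dense regions.

Brain-derived phosphene maps concentrate phosphenes in patches of the visual
field, so a stimulus centred at fixation may fall on empty field.  DBSCAN
with an epsilon of 200 px (~5 deg at 40 px/deg) and a 100-point minimum
separates the dominant phosphene cluster from outliers; the stimulus centre
is then translated to the target cluster's centroid.

Conventions (DBSCAN implementations differ): the eps-neighbourhood is closed
(distance <= eps) and a point counts itself towards the minimum, matching
scikit-learn's semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import DBSCAN

from .derive import PhospheneMap
from .errors import ParameterError
from .stimuli import Stimulus

DEFAULT_EPS_PX = 200.0
DEFAULT_MIN_PTS = 100


@dataclass
class ClusterLabels:
    """Per-point DBSCAN labels: -1 marks noise, >= 0 a cluster id."""

    labels: np.ndarray
    eps_px: float
    min_pts: int

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels.tolist()) - {-1}))


def dbscan(
    points: np.ndarray,
    eps_px: float = DEFAULT_EPS_PX,
    min_pts: int = DEFAULT_MIN_PTS,
) -> ClusterLabels:
    """Cluster 2D pixel positions with DBSCAN.

    A point is core when at least ``min_pts`` points (itself included) lie
    within ``eps_px``; clusters are the connected components of core points
    plus any border points.  ``eps_px <= 0`` degenerates to all-noise.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) < 1:
        raise ParameterError("at least one point required")
    if min_pts < 1:
        raise ParameterError("min_pts must be >= 1")
    if eps_px <= 0:
        labels = np.full(len(points), -1)
    else:
        labels = DBSCAN(eps=eps_px, min_samples=min_pts).fit(points).labels_
    return ClusterLabels(labels=labels, eps_px=float(eps_px), min_pts=int(min_pts))


def _shift_image(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer translation with zero fill."""
    out = np.zeros_like(img)
    h, w = img.shape
    r_src = slice(max(0, -dr), min(h, h - dr))
    c_src = slice(max(0, -dc), min(w, w - dc))
    r_dst = slice(max(0, dr), min(h, h + dr))
    c_dst = slice(max(0, dc), min(w, w + dc))
    out[r_dst, c_dst] = img[r_src, c_src]
    return out


def target_cluster_centroid(
    pmap: PhospheneMap,
    eps_px: float = DEFAULT_EPS_PX,
    min_pts: int = DEFAULT_MIN_PTS,
) -> tuple[np.ndarray | None, ClusterLabels]:
    """Centroid (row, col) of the target cluster, or None if no cluster forms.

    The target is the largest cluster; ties go to the cluster whose centroid
    is nearest the canvas centre.
    """
    px = pmap.pixel_positions()
    cl = dbscan(px, eps_px, min_pts)
    ids = sorted(set(cl.labels.tolist()) - {-1})
    if not ids:
        return None, cl
    h, w = pmap.canvas
    centre = np.array([h / 2.0, w / 2.0])
    best = None
    for cid in ids:
        members = px[cl.labels == cid]
        centroid = members.mean(axis=0)
        key = (-len(members), float(np.linalg.norm(centroid - centre)))
        if best is None or key < best[0]:
            best = (key, centroid)
    return best[1], cl


def relocate_stimulus(
    pmap: PhospheneMap,
    stim: Stimulus,
    eps_px: float = DEFAULT_EPS_PX,
    min_pts: int = DEFAULT_MIN_PTS,
) -> Stimulus:
    """Translate a stimulus so its centre sits on the densest phosphene
    cluster.

    The translation is rounded to whole pixels and clamped so the stimulus
    foreground stays on the canvas.  If no cluster forms the stimulus is
    returned unchanged with ``meta['relocated'] = False``.
    """
    centroid, cl = target_cluster_centroid(pmap, eps_px, min_pts)
    meta = dict(stim.meta)
    if centroid is None:
        meta.update(relocated=False, warning="no cluster formed")
        return replace(stim, meta=meta)

    target = np.rint(centroid).astype(int)
    dr = int(target[0] - stim.centre_px[0])
    dc = int(target[1] - stim.centre_px[1])

    clamped = False
    fg = np.nonzero(stim.image > 0)
    if len(fg[0]):
        h, w = stim.image.shape
        dr_lo, dr_hi = -fg[0].min(), (h - 1) - fg[0].max()
        dc_lo, dc_hi = -fg[1].min(), (w - 1) - fg[1].max()
        dr_c = int(np.clip(dr, dr_lo, dr_hi))
        dc_c = int(np.clip(dc, dc_lo, dc_hi))
        clamped = (dr_c, dc_c) != (dr, dc)
        dr, dc = dr_c, dc_c

    meta.update(relocated=True, clamped=clamped,
                n_clusters=cl.n_clusters, shift_px=(dr, dc))
    return replace(
        stim,
        image=_shift_image(stim.image, dr, dc),
        centre_px=(stim.centre_px[0] + dr, stim.centre_px[1] + dc),
        meta=meta,
    )
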