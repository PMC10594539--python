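"""Projection of electrodes into the visual field and the phosphene-size model.

Each electrode is assumed to elicit one phosphene at the visual-field
location encoded by the cortex beneath it.  The location and raw pRF size are
interpolated from the 50 nearest grayordinates by inverse-distance weighting.

Phosphene radius follows a two-factor scaling of the pRF size:

1. *Subdural relation.*  The diameter of cortex activated by a current I is
   sigmoidal, ``AC = MD / (1 + exp(-slope * (I - I50)))``, and cortical
   magnification falls with eccentricity as ``1/M = (ecc + e2) / A``.  At the
   half-saturation current the activated radius is ``MD/4`` (1.325 mm with the
   default constants), giving a linear phosphene-radius/eccentricity relation
   ``PS = (MD/4)/A * ecc + (MD/4)*e2/A`` = ``0.044*ecc + 0.163`` deg.  A
   subject's own pRF-size slope ``a`` is rescaled onto this relation by the
   factor ``0.044/a``.
2. *Intracortical correction.*  Intracortical stimulation activates a smaller
   patch than subdural stimulation; the ratio of activated radii
   (0.34 mm / 1.325 mm ~= 0.256) shrinks the phosphenes accordingly.

The combined pRF-size-to-phosphene-radius factor is therefore ~0.011/a.

Control maps place the same number of phosphenes uniformly at random in a
disc of the visual field and assign sizes from the average linear fit, so the
cortical magnification effect is preserved while the spatial clustering of
the brain-derived map is removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError, ParameterError
from .implants import Implant
from .surface import RetinotopicSurface

#: Pixels per degree of visual angle of the rendering canvas.
DEFAULT_PX_PER_DEG = 40.0
DEFAULT_CANVAS = (1080, 1080)  # (height, width) px


@dataclass(frozen=True)
class SizeModelParams:
    """Constants of the activated-cortex / magnification size model.

    max_diameter_mm
        Saturating diameter of activated cortex for subdural stimulation.
    half_saturation_current_ma
        Current at which the activated diameter is half its maximum.
    slope_mm_per_ma
        Maximum slope of the diameter-vs-current sigmoid.
    e2_deg
        Eccentricity at which cortical magnification halves from its foveal
        value.
    cortical_scale
        Dimensionless scaling factor A of the magnification relation
        1/M = (ecc + e2) / A.
    intracortical_radius_mm
        Activated-cortex radius assumed for intracortical stimulation at
        80 uA (taken as a given constant).
    intracortical_current_ma
        The intracortical stimulation current the radius above refers to.
    """

    max_diameter_mm: float = 5.3
    half_saturation_current_ma: float = 0.89
    slope_mm_per_ma: float = 5.85
    e2_deg: float = 3.67
    cortical_scale: float = 29.8
    intracortical_radius_mm: float = 0.34
    intracortical_current_ma: float = 0.08

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class LinearFit:
    """Slope/intercept of a pRF-size (deg) vs eccentricity (deg) relation."""

    a: float
    b: float
    n_replaced: int = 0


@dataclass(frozen=True)
class Phosphene:
    x: float       # deg, positive right
    y: float       # deg, positive up
    radius: float  # deg
    source_electrode: tuple[int, int] = (-1, -1)  # (implant, electrode)


@dataclass
class PhospheneMap:
    """Visual-field phosphenes with rendering geometry.

    Positions and radii are stored as arrays; ``kind`` records whether the
    map was derived from a cortical surface (``retinotopic``) or generated as
    a spatially even control (``control``).
    """

    x: np.ndarray          # (N,) deg
    y: np.ndarray          # (N,) deg
    radius: np.ndarray     # (N,) deg
    source: np.ndarray     # (N, 2) int (implant, electrode); -1 for control
    kind: str = "retinotopic"
    px_per_deg: float = DEFAULT_PX_PER_DEG
    canvas: tuple[int, int] = DEFAULT_CANVAS
    meta: dict | None = None

    def __post_init__(self):
        if np.any(self.radius <= 0):
            raise ParameterError("phosphene radius must be > 0")
        if self.kind not in ("retinotopic", "control"):
            raise ParameterError(f"unknown map kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.x)

    def phosphene(self, i: int) -> Phosphene:
        return Phosphene(
            x=float(self.x[i]), y=float(self.y[i]), radius=float(self.radius[i]),
            source_electrode=tuple(int(v) for v in self.source[i]),
        )

    @property
    def eccentricity(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    def pixel_positions(self) -> np.ndarray:
        """(N, 2) positions as (row, col) pixels on the canvas.

        The canvas centre is the fixation point; columns grow with visual x
        (rightward), rows grow downward (against visual y).
        """
        h, w = self.canvas
        col = w / 2.0 + self.x * self.px_per_deg
        row = h / 2.0 - self.y * self.px_per_deg
        return np.column_stack([row, col])

    def n_offcanvas(self) -> int:
        """Phosphenes whose centre pixel falls outside the canvas."""
        h, w = self.canvas
        rc = np.rint(self.pixel_positions()).astype(int)
        return int(np.sum(
            (rc[:, 0] < 0) | (rc[:, 0] >= h) | (rc[:, 1] < 0) | (rc[:, 1] >= w)
        ))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "x_deg": self.x,
                "y_deg": self.y,
                "radius_deg": self.radius,
                "implant": self.source[:, 0],
                "electrode": self.source[:, 1],
                "kind": self.kind,
            }
        ).to_csv(path, index=False, float_format="%.17g")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "px_per_deg": self.px_per_deg,
            "canvas": list(self.canvas),
            "meta": self.meta or {},
            "phosphenes": [
                {
                    "x_deg": float(xx), "y_deg": float(yy),
                    "radius_deg": float(rr),
                    "implant": int(si), "electrode": int(se),
                }
                for xx, yy, rr, (si, se) in zip(
                    self.x, self.y, self.radius, self.source
                )
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        px_per_deg: float = DEFAULT_PX_PER_DEG,
        canvas: tuple[int, int] = DEFAULT_CANVAS,
    ) -> "PhospheneMap":
        df = pd.read_csv(path, float_precision="round_trip")
        kind = str(df["kind"].iloc[0]) if "kind" in df and len(df) else "retinotopic"
        return cls(
            x=df["x_deg"].to_numpy(float),
            y=df["y_deg"].to_numpy(float),
            radius=df["radius_deg"].to_numpy(float),
            source=df[["implant", "electrode"]].to_numpy(int)
            if "implant" in df
            else np.full((len(df), 2), -1),
            kind=kind,
            px_per_deg=px_per_deg,
            canvas=canvas,
        )


# --------------------------------------------------------------------------
# size model
# --------------------------------------------------------------------------

def activated_cortex_diameter(
    current_ma: float, params: SizeModelParams | None = None
) -> float:
    """Diameter (mm) of cortex activated by subdural stimulation at a given
    current: a sigmoid saturating at ``max_diameter_mm``."""
    p = params or SizeModelParams()
    if np.any(np.asarray(current_ma) < 0):
        raise ParameterError("current must be >= 0")
    return p.max_diameter_mm / (
        1.0 + np.exp(-p.slope_mm_per_ma * (current_ma - p.half_saturation_current_ma))
    )


def inverse_magnification(
    eccentricity_deg: float, params: SizeModelParams | None = None
) -> float:
    """Inverse cortical magnification 1/M = (ecc + e2) / A, deg/mm."""
    p = params or SizeModelParams()
    if np.any(np.asarray(eccentricity_deg) < 0):
        raise ParameterError("eccentricity must be >= 0")
    return (eccentricity_deg + p.e2_deg) / p.cortical_scale


def subdural_size_relation(params: SizeModelParams | None = None) -> LinearFit:
    """Phosphene radius vs eccentricity for subdural stimulation at the
    half-saturation current.

    The activated radius there is ``AC(I50)/2 = MD/4``; multiplying by the
    inverse magnification gives radius = (MD/4)/A * ecc + (MD/4)*e2/A,
    i.e. 0.044*ecc + 0.163 deg with the default constants.
    """
    p = params or SizeModelParams()
    r = activated_cortex_diameter(p.half_saturation_current_ma, p) / 2.0
    return LinearFit(a=r / p.cortical_scale, b=r * p.e2_deg / p.cortical_scale)


def prf_to_phosphene_scale(
    subject_fit: LinearFit, params: SizeModelParams | None = None
) -> float:
    """Combined scaling factor from pRF size to phosphene radius.

    The subject's size/eccentricity slope ``a`` is matched to the subdural
    relation (factor ``0.044/a``), then shrunk by the intracortical-to-
    subdural activated-radius ratio (~0.256), i.e. ~``0.011/a`` overall.
    """
    p = params or SizeModelParams()
    if subject_fit.a <= 0:
        raise ParameterError("subject fit slope must be > 0")
    subdural = subdural_size_relation(p)
    r_subdural = activated_cortex_diameter(p.half_saturation_current_ma, p) / 2.0
    return (subdural.a / subject_fit.a) * (p.intracortical_radius_mm / r_subdural)


def fit_ecc_size(
    surface: RetinotopicSurface, alpha: float = 0.05
) -> LinearFit:
    """Robustified linear fit of pRF size against eccentricity over V1+V2.

    An ordinary least-squares fit yields per-observation 95% prediction
    intervals; responses outside their interval are replaced by the fitted
    value and the model is refit once on the clamped data.  The number of
    replaced observations is reported so outlier handling can be audited.
    """
    sel = np.isin(surface.roi, ("V1", "V2"))
    ecc = surface.eccentricity[sel]
    size = surface.prf_size[sel]
    if len(ecc) < 3:
        raise FitError("need at least 3 V1/V2 grayordinates")
    if np.ptp(ecc) < 1e-12:
        raise FitError("eccentricities are collinear (no spread)")

    X = sm.add_constant(ecc)
    res = sm.OLS(size, X).fit()
    pred = res.get_prediction(X)
    bounds = pred.conf_int(obs=True, alpha=alpha)
    out = (size < bounds[:, 0]) | (size > bounds[:, 1])
    n_replaced = int(out.sum())
    if n_replaced:
        clamped = np.where(out, res.fittedvalues, size)
        res = sm.OLS(clamped, X).fit()
    return LinearFit(a=float(res.params[1]), b=float(res.params[0]),
                     n_replaced=n_replaced)


# --------------------------------------------------------------------------
# electrode projection
# --------------------------------------------------------------------------

def electrode_to_visual_field(
    surface: RetinotopicSurface,
    electrode_pos: np.ndarray,
    k: int = 50,
) -> tuple[float, float, float]:
    """Visual-field position (deg) and raw pRF size under one electrode.

    The ``k`` nearest grayordinates (3D Euclidean distance) are averaged with
    inverse-distance weights 1/d.  An electrode within 1e-9 mm of a
    grayordinate takes that grayordinate's values exactly.
    """
    x, y, s = _electrodes_to_visual_field(surface, np.atleast_2d(electrode_pos), k)
    return float(x[0]), float(y[0]), float(s[0])


def _electrodes_to_visual_field(
    surface: RetinotopicSurface, electrode_pos: np.ndarray, k: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if k > len(surface):
        raise ParameterError(f"k={k} exceeds surface size {len(surface)}")
    dist, idx = surface.kdtree.query(electrode_pos, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    vis = surface.visual_xy

    zero = dist[:, 0] < 1e-9
    with np.errstate(divide="ignore"):
        w = 1.0 / dist
    w[zero] = 0.0
    w[zero, 0] = 1.0  # exact hit: that grayordinate's values verbatim
    w = w / w.sum(axis=1, keepdims=True)

    x = np.sum(w * vis[idx, 0], axis=1)
    y = np.sum(w * vis[idx, 1], axis=1)
    s = np.sum(w * surface.prf_size[idx], axis=1)
    return x, y, s


def derive_phosphene_map(
    surface: RetinotopicSurface,
    implants: list[Implant],
    params: SizeModelParams | None = None,
    k: int = 50,
    px_per_deg: float = DEFAULT_PX_PER_DEG,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
) -> PhospheneMap:
    """Derive the retinotopic phosphene map of a multi-implant plan.

    One phosphene per electrode: position and raw pRF size by KNN(k) +
    inverse-distance weighting, radius by the two-factor size scaling with
    the subject's own eccentricity/pRF-size fit.
    """
    p = params or SizeModelParams()
    fit = fit_ecc_size(surface)
    scale = prf_to_phosphene_scale(fit, p)

    electrodes = np.vstack([im.electrode_positions for im in implants])
    x, y, s = _electrodes_to_visual_field(surface, electrodes, k)
    source = np.array(
        [
            (i, j)
            for i, im in enumerate(implants)
            for j in range(im.layout.n_electrodes)
        ]
    )
    return PhospheneMap(
        x=x, y=y, radius=s * scale, source=source, kind="retinotopic",
        px_per_deg=px_per_deg, canvas=canvas,
        meta={"subject_fit_a": fit.a, "subject_fit_b": fit.b,
              "n_replaced": fit.n_replaced, "prf_scale": scale, "knn": k},
    )


def generate_control_map(
    n: int,
    avg_fit: LinearFit,
    field_radius_deg: float,
    seed: int = 0,
    params: SizeModelParams | None = None,
    px_per_deg: float = DEFAULT_PX_PER_DEG,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
) -> PhospheneMap:
    """Spatially even control map with the same phosphene count.

    Positions are uniform over the disc of radius ``field_radius_deg`` about
    fixation; sizes come from the averaged linear fit, so the magnification
    effect matches the paired retinotopic map.  Deterministic for a fixed
    seed.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if field_radius_deg <= 0:
        raise ParameterError("field_radius_deg must be > 0")
    p = params or SizeModelParams()
    rng = np.random.default_rng(seed)
    ecc = field_radius_deg * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    scale = prf_to_phosphene_scale(avg_fit, p)
    radius = (avg_fit.a * ecc + avg_fit.b) * scale
    return PhospheneMap(
        x=ecc * np.cos(theta),
        y=ecc * np.sin(theta),
        radius=radius,
        source=np.full((n, 2), -1),
        kind="control",
        px_per_deg=px_per_deg,
        canvas=canvas,
        meta={"seed": seed, "field_radius_deg": field_radius_deg},
    )


def control_field_radius(pmap: PhospheneMap, q: float = 0.95) -> float:
    """Default control-map field extent: the q-quantile eccentricity of the
    paired retinotopic map."""
    return float(np.quantile(pmap.eccentricity, q))
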