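"""Stimulus generation, phosphene selection and Gaussian rendering.

Optotypes follow the standard 5x5 construction: a letter at acuity level
``logmar`` has a minimum angle of resolution MAR = 10**logmar arc-minutes,
letter height 5*MAR and stroke width MAR.  Gratings are square waves with bar
width MAR inside a circular patch.  Object stimuli are parameterised
silhouettes of five everyday-clothing classes drawn at 540x540 px.

Two selection rules map a stimulus to active phosphenes: *skeleton sampling*
(thin the stroke to one pixel and light the nearest phosphene of every
skeleton pixel) for letter optotypes, and *direct masking* (light every
phosphene whose centre lies under a bright region) for gratings and objects.

Rendering draws each active phosphene as a 2D Gaussian with sigma equal to
one third of its radius; overlapping luminance is summed and capped at 1.

The acuity ladder combines the single tumbling-E test (0.8-2.6 LogMAR, pass
at >= 4/8 correct) with the grating test (2.3-2.9 LogMAR, pass at >= 7/8);
performance worse than 2.9 LogMAR scores 3.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.morphology import skeletonize

from .derive import DEFAULT_CANVAS, DEFAULT_PX_PER_DEG, PhospheneMap
from .errors import ParameterError, ResolutionError, ValidationError

#: Tumbling-E ladder levels (LogMAR) and grating ladder levels.
E_LEVELS = tuple(np.round(np.arange(0.8, 2.601, 0.2), 1))
GRATING_LEVELS = (2.3, 2.5, 2.7, 2.9)
#: Score assigned when even the coarsest grating is failed.
LADDER_FLOOR = 3.0

E_ORIENTATIONS = ("up", "down", "left", "right")
GRATING_ORIENTATIONS = ("horizontal", "vertical")


@dataclass
class Stimulus:
    """A physical-scale grayscale stimulus image."""

    image: np.ndarray                 # 2D float in [0, 1]
    px_per_deg: float
    kind: str                         # tumbling_E | grating | object
    logmar: float | None = None
    orientation: str | None = None
    centre_px: tuple[int, int] = (0, 0)  # (row, col)
    meta: dict = dc_field(default_factory=dict)


@dataclass
class RenderedFrame:
    """A stimulus as seen through a phosphene map."""

    image: np.ndarray
    active_phosphenes: frozenset[int]


@dataclass
class LadderResult:
    va_logmar: float
    trials: list[tuple[float, int, int]]


def mar_arcmin(logmar: float) -> float:
    """Minimum angle of resolution in arc-minutes at a LogMAR level."""
    return 10.0 ** logmar


def _blank_canvas(canvas: tuple[int, int] | None, tight: np.ndarray):
    """Centre a tight binary patch on a canvas (or return it as-is)."""
    if canvas is None:
        h, w = tight.shape
        return tight, (h // 2, w // 2)
    H, W = canvas
    h, w = tight.shape
    if h > H or w > W:
        raise ResolutionError(
            f"stimulus ({h}x{w} px) larger than canvas ({H}x{W} px)"
        )
    out = np.zeros((H, W))
    r0, c0 = (H - h) // 2, (W - w) // 2
    out[r0:r0 + h, c0:c0 + w] = tight
    return out, (H // 2, W // 2)


def make_tumbling_E(
    logmar: float,
    orientation: str = "right",
    px_per_deg: float = DEFAULT_PX_PER_DEG,
    canvas: tuple[int, int] | None = DEFAULT_CANVAS,
) -> Stimulus:
    """A binary tumbling-E optotype.

    The letter is 5 strokes tall (height = 5 * MAR arc-minutes) with stroke
    width one fifth of the height; ``orientation`` is the direction the three
    arms point.
    """
    if orientation not in E_ORIENTATIONS:
        raise ParameterError(f"orientation must be one of {E_ORIENTATIONS}")
    height = int(round(5.0 * mar_arcmin(logmar) / 60.0 * px_per_deg))
    if height < 5:
        raise ResolutionError(
            f"letter height {height} px < 5 px; increase px_per_deg"
        )
    bands = np.round(np.linspace(0, height, 6)).astype(int)
    letter = np.zeros((height, height))
    letter[:, bands[0]:bands[1]] = 1.0          # spine on the left
    for k in (0, 2, 4):                          # three arms pointing right
        letter[bands[k]:bands[k + 1], :] = 1.0
    rot = {"right": 0, "up": 1, "left": 2, "down": 3}[orientation]
    letter = np.rot90(letter, rot)

    image, centre = _blank_canvas(canvas, letter)
    return Stimulus(
        image=image, px_per_deg=px_per_deg, kind="tumbling_E",
        logmar=float(logmar), orientation=orientation, centre_px=centre,
        meta={"letter_height_px": height},
    )


def make_grating(
    logmar: float,
    orientation: str = "vertical",
    px_per_deg: float = DEFAULT_PX_PER_DEG,
    patch_diameter_deg: float = 20.0,
    canvas: tuple[int, int] | None = DEFAULT_CANVAS,
) -> Stimulus:
    """A binary square-wave grating in a circular patch.

    Bar width is MAR arc-minutes; duty cycle 50%; the phase is anchored at
    the patch centre.  ``vertical`` bars alternate along the horizontal axis.
    """
    if orientation not in GRATING_ORIENTATIONS:
        raise ParameterError(f"orientation must be one of {GRATING_ORIENTATIONS}")
    bar_px = mar_arcmin(logmar) / 60.0 * px_per_deg
    if bar_px < 1:
        raise ResolutionError("bar width below 1 px; increase px_per_deg")
    d = int(round(patch_diameter_deg * px_per_deg))
    rr, cc = np.mgrid[0:d, 0:d]
    centre = (d - 1) / 2.0
    coord = cc if orientation == "vertical" else rr
    bars = (np.floor((coord - centre) / bar_px) % 2 == 0).astype(float)
    mask = (rr - centre) ** 2 + (cc - centre) ** 2 <= (d / 2.0) ** 2
    patch = bars * mask

    image, centre_px = _blank_canvas(canvas, patch)
    return Stimulus(
        image=image, px_per_deg=px_per_deg, kind="grating",
        logmar=float(logmar), orientation=orientation, centre_px=centre_px,
        meta={"bar_px": bar_px, "patch_diameter_deg": patch_diameter_deg},
    )


# --------------------------------------------------------------------------
# object silhouettes (stand-ins for a clothing-image benchmark)
# --------------------------------------------------------------------------

OBJECT_CLASSES = ("top", "trousers", "dress", "sneaker", "bag")


def make_object_silhouette(
    category: str,
    size_px: int = 540,
    px_per_deg: float = DEFAULT_PX_PER_DEG,
    seed: int | None = None,
) -> Stimulus:
    """Synthetic binary silhouette of one of five clothing classes.

    These parameterised shapes emulate the coarse outlines of a clothing
    image benchmark at 540x540 px; an optional seed jitters vertex positions
    by a few percent for variety.
    """
    if category not in OBJECT_CLASSES:
        raise ParameterError(f"category must be one of {OBJECT_CLASSES}")
    s = size_px
    img = np.zeros((s, s))
    rng = np.random.default_rng(seed)
    jit = (lambda: 1.0 + 0.04 * rng.standard_normal()) if seed is not None else (lambda: 1.0)

    def poly(points):
        pts = np.array([(r * jit(), c * jit()) for r, c in points]) * s
        rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=img.shape)
        img[rr, cc] = 1.0

    if category == "top":                      # T-shirt: body + sleeves
        poly([(0.25, 0.35), (0.25, 0.65), (0.8, 0.65), (0.8, 0.35)])
        poly([(0.25, 0.12), (0.25, 0.88), (0.45, 0.88), (0.45, 0.12)])
    elif category == "trousers":               # two legs joined at the waist
        poly([(0.15, 0.3), (0.15, 0.7), (0.35, 0.7), (0.35, 0.3)])
        poly([(0.3, 0.3), (0.9, 0.3), (0.9, 0.45), (0.3, 0.45)])
        poly([(0.3, 0.55), (0.9, 0.55), (0.9, 0.7), (0.3, 0.7)])
    elif category == "dress":                  # bodice + flared skirt
        poly([(0.12, 0.42), (0.12, 0.58), (0.45, 0.58), (0.45, 0.42)])
        poly([(0.4, 0.5), (0.9, 0.2), (0.9, 0.8)])
    elif category == "sneaker":                # sole + toe box
        poly([(0.6, 0.1), (0.6, 0.9), (0.75, 0.9), (0.75, 0.1)])
        poly([(0.35, 0.45), (0.35, 0.9), (0.65, 0.9), (0.65, 0.45)])
    else:                                      # bag: body + handle arch
        poly([(0.4, 0.2), (0.4, 0.8), (0.85, 0.8), (0.85, 0.2)])
        rr, cc = draw_disk((0.4 * s, 0.5 * s), 0.18 * s, shape=img.shape)
        handle = np.zeros_like(img)
        handle[rr, cc] = 1.0
        rr, cc = draw_disk((0.4 * s, 0.5 * s), 0.12 * s, shape=img.shape)
        handle[rr, cc] = 0.0
        handle[int(0.4 * s):, :] = 0.0
        img = np.maximum(img, handle)

    return Stimulus(
        image=img, px_per_deg=px_per_deg, kind="object",
        orientation=None, centre_px=(s // 2, s // 2),
        meta={"category": category, "seed": seed},
    )


# --------------------------------------------------------------------------
# phosphene selection
# --------------------------------------------------------------------------

def skeleton_sample(stim: Stimulus, pmap: PhospheneMap) -> set[int]:
    """Active phosphenes under the one-pixel skeleton of the stimulus.

    The foreground (> 0.5) is thinned to a 1 px medial axis; for every
    skeleton pixel the nearest phosphene centre (Euclidean distance in
    pixels, ties to the lowest index) joins the active set.
    """
    if len(pmap) == 0:
        raise ParameterError("empty phosphene map")
    fg = stim.image > 0.5
    if not fg.any():
        return set()
    skel = skeletonize(fg)
    pixels = np.column_stack(np.nonzero(skel)).astype(float)
    centres = pmap.pixel_positions()
    active: set[int] = set()
    for chunk in np.array_split(pixels, max(1, len(pixels) // 2048)):
        d = cdist(chunk, centres)
        active.update(np.argmin(d, axis=1).tolist())  # argmin = lowest index on ties
    return active


def direct_mask(
    stim: Stimulus, pmap: PhospheneMap, threshold: float = 0.5
) -> set[int]:
    """Active phosphenes whose centre pixel lies on a bright stimulus region.

    Phosphene centres outside the stimulus canvas are simply inactive; their
    count is available as ``pmap.n_offcanvas()``.
    """
    if len(pmap) == 0:
        raise ParameterError("empty phosphene map")
    h, w = stim.image.shape
    rc = np.rint(pmap.pixel_positions()).astype(int)
    on = (rc[:, 0] >= 0) & (rc[:, 0] < h) & (rc[:, 1] >= 0) & (rc[:, 1] < w)
    idx = np.nonzero(on)[0]
    lit = stim.image[rc[idx, 0], rc[idx, 1]] > threshold
    return set(idx[lit].tolist())


def render_phosphenes(
    pmap: PhospheneMap,
    active: set[int] | None = None,
    intensities: np.ndarray | None = None,
) -> RenderedFrame:
    """Render active phosphenes as Gaussian blobs.

    Each phosphene contributes a 2D Gaussian with peak equal to its intensity
    (default 1) and sigma = radius/3 (in pixels); contributions are summed
    pixel-wise and capped at 1.
    """
    h, w = pmap.canvas
    img = np.zeros((h, w))
    if active is None:
        active = set(range(len(pmap)))
    if not active <= set(range(len(pmap))):
        raise ParameterError("active set contains out-of-range indices")
    centres = pmap.pixel_positions()
    for i in sorted(active):
        peak = 1.0 if intensities is None else float(intensities[i])
        sigma = pmap.radius[i] * pmap.px_per_deg / 3.0
        r0, c0 = centres[i]
        half = int(np.ceil(4.0 * sigma))
        rlo, rhi = int(np.floor(r0)) - half, int(np.floor(r0)) + half + 1
        clo, chi = int(np.floor(c0)) - half, int(np.floor(c0)) + half + 1
        rlo_c, rhi_c = max(rlo, 0), min(rhi, h)
        clo_c, chi_c = max(clo, 0), min(chi, w)
        if rlo_c >= rhi_c or clo_c >= chi_c:
            continue
        rr = np.arange(rlo_c, rhi_c)[:, None]
        cc = np.arange(clo_c, chi_c)[None, :]
        g = peak * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma ** 2))
        img[rlo_c:rhi_c, clo_c:chi_c] += g
    return RenderedFrame(image=np.minimum(img, 1.0),
                         active_phosphenes=frozenset(active))


# --------------------------------------------------------------------------
# acuity ladder
# --------------------------------------------------------------------------

def _is_grating_level(level: float) -> bool:
    return any(abs(level - g) < 1e-9 for g in GRATING_LEVELS)


def brvt_score(trials: list[tuple[float, int, int]]) -> LadderResult:
    """Score an acuity ladder of (level, n_correct, n_total) trial blocks.

    Tumbling-E levels pass at >= half correct (4/8); grating levels pass at
    >= 7/8 correct.  The visual acuity is the best (lowest) level passed; if
    nothing passes the score is the 3.0 LogMAR floor.
    """
    if not trials:
        raise ValidationError("no trial blocks supplied")
    passed = []
    for level, n_correct, n_total in trials:
        if n_total <= 0 or not (0 <= n_correct <= n_total):
            raise ValidationError(
                f"malformed trial block at level {level}: {n_correct}/{n_total}"
            )
        frac = n_correct / n_total
        ok = frac >= (7.0 / 8.0) if _is_grating_level(level) else frac >= 0.5
        if ok:
            passed.append(level)
    va = min(passed) if passed else LADDER_FLOOR
    return LadderResult(va_logmar=float(va), trials=list(trials))


def validation_block(va_logmar: float) -> list[tuple[float, int]]:
    """Post-test validation levels: 12 trials at VA-0.2, VA and VA+0.2.

    Levels that fall below the tumbling-E ladder floor (0.8 LogMAR) are
    still returned but flagged with a warning.
    """
    if not np.isfinite(va_logmar):
        raise ParameterError("va must be finite")
    levels = [round(va_logmar - 0.2, 10), float(va_logmar), round(va_logmar + 0.2, 10)]
    if levels[0] < E_LEVELS[0] - 1e-9:
        warnings.warn(
            f"validation level {levels[0]:.1f} LogMAR is below the ladder floor",
            stacklevel=2,
        )
    return [(lv, 12) for lv in levels]
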