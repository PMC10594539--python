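"""Retinotopically mapped cortical surfaces.

A :class:`RetinotopicSurface` is a cloud of grayordinates (cortical surface
vertices), each carrying a 3D position in millimetres together with its
population receptive field (pRF): visual-field polar angle, eccentricity and
pRF size in degrees, plus an ROI label (V1/V2/other), hemisphere and a
gyrus/sulcus flag.

The synthetic generator emulates the structure of 7 T retinotopy data of the
human early visual cortex: grayordinates spaced on average 2 mm apart, a
log-polar (complex-logarithm-like) V1 retinotopy with a mirrored V2 band
adjacent to it, a sinusoidal gyral folding pattern, and pRF size increasing
linearly with eccentricity.  Left-hemisphere grayordinates represent the right
visual hemifield and vice versa.

Polar angle convention (declared, not universal): 0 deg is the upper vertical
meridian, positive angles run clockwise, so the right visual field has
positive horizontal coordinate ``x = ecc * sin(angle)`` and
``y = ecc * cos(angle)``.

Anatomical coordinate frame: x = left-right (the coronal plane is the x-z
plane), y = posterior-anterior, z = inferior-superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ParameterError, SchemaError, ValidationError

#: Documented column schema of the delimited retinotopy table.
TABLE_COLUMNS = [
    "id",
    "x_mm",
    "y_mm",
    "z_mm",
    "polar_angle_deg",
    "eccentricity_deg",
    "prf_size_deg",
    "roi",
    "hemisphere",
    "is_gyrus",
]

ROI_LABELS = ("V1", "V2", "other")
HEMISPHERES = ("left", "right")

#: Mean grayordinate spacing of the emulated dataset, mm.
GRAYORDINATE_SPACING_MM = 2.0

#: Eccentricity offset of the log-polar template, deg.  Shared with the
#: cortical magnification model (the eccentricity at which magnification
#: halves), so synthetic magnification is consistent with the size model.
_TEMPLATE_A0 = 3.67


@dataclass(frozen=True)
class Grayordinate:
    """One cortical sample point with its population receptive field."""

    id: int
    pos: np.ndarray            # (3,) mm
    polar_angle: float         # deg, 0 = upper vertical meridian, cw positive
    eccentricity: float        # deg
    prf_size: float            # deg (radius)
    roi: str                   # V1 | V2 | other
    hemisphere: str            # left | right
    is_gyrus: bool


@dataclass
class SyntheticCortexParams:
    """Parameters of the synthetic cortical patch generator.

    Defaults give two hemispheres of 2000 grayordinates each, covering
    0.5-40 deg of eccentricity with moderate folding and a pRF-size/
    eccentricity relation typical of early visual cortex
    (size = 0.05 * ecc + 0.5 deg, s.d. 0.1 deg).
    """

    n_per_hemi: int = 2000
    ecc_range: tuple[float, float] = (0.5, 40.0)
    fold_amplitude_mm: float = 2.0
    fold_wavelength_mm: float = 12.0
    size_slope: float = 0.05
    size_intercept: float = 0.5
    size_noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_hemi < 100:
            raise ParameterError("n_per_hemi must be >= 100")
        lo, hi = self.ecc_range
        if not (0.0 < lo < hi < 90.0):
            raise ParameterError("ecc_range must satisfy 0 < lo < hi < 90 deg")
        if self.size_slope <= 0:
            raise ParameterError("size_slope must be > 0")
        if self.size_intercept <= 0:
            raise ParameterError("size_intercept must be > 0")
        if self.size_noise_sd < 0:
            raise ParameterError("size_noise_sd must be >= 0")
        if self.fold_wavelength_mm <= 0:
            raise ParameterError("fold_wavelength_mm must be > 0")


@dataclass
class RetinotopicSurface:
    """A grayordinate cloud with per-grayordinate pRF data.

    Fields are stored as parallel arrays for vectorised downstream use;
    :meth:`grayordinate` gives the per-point record view.
    """

    positions: np.ndarray        # (N, 3) mm
    polar_angle: np.ndarray      # (N,) deg
    eccentricity: np.ndarray     # (N,) deg
    prf_size: np.ndarray         # (N,) deg
    roi: np.ndarray              # (N,) str
    hemisphere: np.ndarray       # (N,) str
    is_gyrus: np.ndarray         # (N,) bool
    subject_id: str = "synthetic"
    rng_seed: int | None = None
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.positions)
        for name in ("polar_angle", "eccentricity", "prf_size", "roi",
                     "hemisphere", "is_gyrus"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"field '{name}' length mismatch")
        if np.any(self.eccentricity < 0):
            raise ValidationError("eccentricity must be >= 0")
        if np.any(self.prf_size <= 0):
            raise ValidationError("prf_size must be > 0")
        bad_roi = set(np.unique(self.roi)) - set(ROI_LABELS)
        if bad_roi:
            raise ValidationError(f"unknown ROI labels: {sorted(bad_roi)}")
        bad_hemi = set(np.unique(self.hemisphere)) - set(HEMISPHERES)
        if bad_hemi:
            raise ValidationError(f"unknown hemispheres: {sorted(bad_hemi)}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def kdtree(self) -> cKDTree:
        if self._tree is None:
            object.__setattr__(self, "_tree", cKDTree(self.positions))
        return self._tree

    @property
    def mean_spacing(self) -> float:
        """Mean 3D nearest-neighbour distance, mm."""
        d, _ = self.kdtree.query(self.positions, k=2)
        return float(d[:, 1].mean())

    @property
    def visual_xy(self) -> np.ndarray:
        """(N, 2) visual-field coordinates in degrees."""
        ang = np.deg2rad(self.polar_angle)
        return np.column_stack(
            [self.eccentricity * np.sin(ang), self.eccentricity * np.cos(ang)]
        )

    def grayordinate(self, i: int) -> Grayordinate:
        return Grayordinate(
            id=int(i),
            pos=self.positions[i].copy(),
            polar_angle=float(self.polar_angle[i]),
            eccentricity=float(self.eccentricity[i]),
            prf_size=float(self.prf_size[i]),
            roi=str(self.roi[i]),
            hemisphere=str(self.hemisphere[i]),
            is_gyrus=bool(self.is_gyrus[i]),
        )

    def equals(self, other: "RetinotopicSurface") -> bool:
        """Field-by-field exact equality (positions, pRF data, labels)."""
        return (
            np.array_equal(self.positions, other.positions)
            and np.array_equal(self.polar_angle, other.polar_angle)
            and np.array_equal(self.eccentricity, other.eccentricity)
            and np.array_equal(self.prf_size, other.prf_size)
            and np.array_equal(self.roi, other.roi)
            and np.array_equal(self.hemisphere, other.hemisphere)
            and np.array_equal(self.is_gyrus, other.is_gyrus)
        )


def _hemisphere_patch(
    params: SyntheticCortexParams, hemisphere: str, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Build one hemisphere as adjacent V1 and V2 bands of a folded sheet.

    The sheet's u axis (anterior-posterior, embedded along -y) carries
    log-spaced eccentricity; the v axis (inferior-superior, embedded along z)
    carries polar angle linearly over the contralateral hemifield.  V2 is a
    band adjacent to V1 in v with the polar-angle mapping mirrored, emulating
    the reversal of the visual-field map at the V1/V2 border.  Folding is a
    sinusoid along u displacing the sheet along +-x; outward (positive)
    displacement marks gyral crowns.
    """
    n = params.n_per_hemi
    n_v1 = n - n // 2
    n_v2 = n // 2
    spacing = GRAYORDINATE_SPACING_MM
    lo, hi = params.ecc_range

    n_u = max(3, int(round(np.sqrt(n_v1))))
    n_rows_v1 = -(-n_v1 // n_u)  # ceil
    n_rows_v2 = -(-n_v2 // n_u)

    # log-polar radial scale: u spans the eccentricity range exactly
    k = (n_u - 1) * spacing / np.log((hi + _TEMPLATE_A0) / (lo + _TEMPLATE_A0))

    sign = -1.0 if hemisphere == "left" else 1.0     # x side of the midline
    hemifield = 1.0 if hemisphere == "left" else -1.0  # contralateral field

    rows = []
    for roi, n_roi, n_rows, row0, mirrored in (
        ("V1", n_v1, n_rows_v1, 0, False),
        ("V2", n_v2, n_rows_v2, n_rows_v1, True),
    ):
        jj, ii = np.divmod(np.arange(n_roi), n_u)
        u = ii * spacing
        v = (row0 + jj) * spacing
        ecc = (lo + _TEMPLATE_A0) * np.exp(u / k) - _TEMPLATE_A0
        frac = (jj + 0.5) / n_rows
        if mirrored:
            frac = 1.0 - frac
        angle = hemifield * 180.0 * frac
        fold = params.fold_amplitude_mm * np.sin(
            2.0 * np.pi * u / params.fold_wavelength_mm
        )
        x = sign * (15.0 + fold)
        y = -u
        z = v
        rows.append(
            dict(
                pos=np.column_stack([x, y, z]),
                angle=angle,
                ecc=ecc,
                roi=np.full(n_roi, roi, dtype=object),
                gyrus=fold > 0,
            )
        )

    pos = np.vstack([r["pos"] for r in rows])
    ecc = np.concatenate([r["ecc"] for r in rows])
    angle = np.concatenate([r["angle"] for r in rows])
    roi = np.concatenate([r["roi"] for r in rows])
    gyrus = np.concatenate([r["gyrus"] for r in rows])
    size = params.size_slope * ecc + params.size_intercept
    if params.size_noise_sd > 0:
        size = size + rng.normal(0.0, params.size_noise_sd, size=len(size))
    size = np.maximum(size, 1e-3)
    return dict(pos=pos, ecc=ecc, angle=angle, roi=roi, gyrus=gyrus, size=size)


def generate_synthetic_surface(
    params: SyntheticCortexParams | None = None, **overrides
) -> RetinotopicSurface:
    """Generate a deterministic synthetic retinotopically mapped surface.

    Parameters may be given as a :class:`SyntheticCortexParams` or as keyword
    overrides of its defaults.  The same parameters and seed always produce a
    bit-identical surface.
    """
    if params is None:
        params = SyntheticCortexParams(**overrides)
    elif overrides:
        raise ParameterError("pass either params or keyword overrides, not both")
    params.validate()
    rng = np.random.default_rng(params.seed)

    parts = [_hemisphere_patch(params, h, rng) for h in ("left", "right")]
    n = params.n_per_hemi
    return RetinotopicSurface(
        positions=np.vstack([p["pos"] for p in parts]),
        polar_angle=np.concatenate([p["angle"] for p in parts]),
        eccentricity=np.concatenate([p["ecc"] for p in parts]),
        prf_size=np.concatenate([p["size"] for p in parts]),
        roi=np.concatenate([p["roi"] for p in parts]),
        hemisphere=np.concatenate(
            [np.full(n, h, dtype=object) for h in ("left", "right")]
        ),
        is_gyrus=np.concatenate([p["gyrus"] for p in parts]),
        subject_id=f"synthetic-{params.seed}",
        rng_seed=params.seed,
    )


def write_retinotopy_table(surface: RetinotopicSurface, path: str | Path) -> None:
    """Write a surface as a delimited table with the documented schema.

    Floats are written with 17 significant digits so that a write/read cycle
    round-trips bit-exactly for finite values.  Files ending in ``.tsv`` are
    tab-separated, otherwise comma-separated.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "id": np.arange(len(surface)),
            "x_mm": surface.positions[:, 0],
            "y_mm": surface.positions[:, 1],
            "z_mm": surface.positions[:, 2],
            "polar_angle_deg": surface.polar_angle,
            "eccentricity_deg": surface.eccentricity,
            "prf_size_deg": surface.prf_size,
            "roi": surface.roi,
            "hemisphere": surface.hemisphere,
            "is_gyrus": surface.is_gyrus.astype(int),
        }
    )
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_retinotopy_table(
    path: str | Path, subject_id: str | None = None
) -> RetinotopicSurface:
    """Read a retinotopy table (CSV or TSV) into a surface.

    Raises
    ------
    SchemaError
        if a required column is missing.
    ValidationError
        if any pRF field is non-finite (the offending row ids are listed)
        or labels fall outside the documented enums.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    numeric = df[["x_mm", "y_mm", "z_mm", "polar_angle_deg",
                  "eccentricity_deg", "prf_size_deg"]].to_numpy(float)
    bad = ~np.isfinite(numeric).all(axis=1)
    if bad.any():
        ids = df["id"].to_numpy()[bad].tolist()
        raise ValidationError(f"non-finite pRF values in rows: {ids}")

    is_gyrus = df["is_gyrus"].map(
        {True: True, False: False, 1: True, 0: False, "True": True,
         "False": False, "true": True, "false": False}
    )
    if is_gyrus.isna().any():
        raise ValidationError("is_gyrus must be boolean (0/1/True/False)")

    return RetinotopicSurface(
        positions=numeric[:, :3].copy(),
        polar_angle=numeric[:, 3].copy(),
        eccentricity=numeric[:, 4].copy(),
        prf_size=numeric[:, 5].copy(),
        roi=df["roi"].to_numpy(object),
        hemisphere=df["hemisphere"].to_numpy(object),
        is_gyrus=is_gyrus.to_numpy(bool),
        subject_id=subject_id or path.stem,
    )
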