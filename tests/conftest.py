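import numpy as np
import pytest

import phosmap as pm
from phosmap.pipeline import plan_placements
from phosmap.surface import RetinotopicSurface


@pytest.fixture(scope="session")
def surface():
    """Default-sized synthetic surface shared by the heavier tests."""
    return pm.generate_synthetic_surface(seed=1)


@pytest.fixture(scope="session")
def flat_surface():
    """Unfolded surface: each hemisphere lies in a plane of constant x."""
    return pm.generate_synthetic_surface(
        n_per_hemi=500, seed=2, fold_amplitude_mm=0.0, size_noise_sd=0.0
    )


@pytest.fixture(scope="session")
def implants12(surface):
    plan = plan_placements(surface, 12)
    return [pm.place_implant(surface, v, rot) for v, rot in plan]


@pytest.fixture(scope="session")
def derived_map(surface, implants12):
    return pm.derive_phosphene_map(surface, implants12)


def toy_surface(positions, ecc=None, angle=None, prf=None, roi="V1",
                hemisphere="left"):
    """Hand-constructed surface for analytic fixtures."""
    positions = np.asarray(positions, float)
    n = len(positions)
    return RetinotopicSurface(
        positions=positions,
        polar_angle=np.zeros(n) if angle is None else np.asarray(angle, float),
        eccentricity=np.ones(n) if ecc is None else np.asarray(ecc, float),
        prf_size=np.ones(n) if prf is None else np.asarray(prf, float),
        roi=np.full(n, roi, dtype=object),
        hemisphere=np.full(n, hemisphere, dtype=object),
        is_gyrus=np.zeros(n, dtype=bool),
        subject_id="toy",
    )
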