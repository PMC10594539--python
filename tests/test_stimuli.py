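"""Optotype/grating generation, phosphene selection, rendering, scoring."""

import itertools

import numpy as np
import pytest

import phosmap as pm
from phosmap.derive import PhospheneMap
from phosmap.errors import ParameterError, ResolutionError, ValidationError
from phosmap.stimuli import E_LEVELS, GRATING_LEVELS, LADDER_FLOOR


def grid_map(rows, cols, canvas=(1080, 1080), px_per_deg=40.0, radius=0.5):
    """Phosphene map on a regular pixel grid (for selection fixtures)."""
    rows = np.asarray(rows, float)
    cols = np.asarray(cols, float)
    h, w = canvas
    x = (cols - w / 2.0) / px_per_deg
    y = (h / 2.0 - rows) / px_per_deg
    return PhospheneMap(
        x=x, y=y, radius=np.full(len(x), radius),
        source=np.full((len(x), 2), -1), kind="control",
        px_per_deg=px_per_deg, canvas=canvas,
    )


# --------------------------------------------------------------------------
# optotypes
# --------------------------------------------------------------------------

def test_tumbling_e_letter_height_arithmetic():
    # MAR = 100 arcmin at 2.0 LogMAR: height = 5 * (100/60) * 40 px
    stim = pm.make_tumbling_E(2.0, "right", px_per_deg=40.0)
    assert stim.meta["letter_height_px"] == 333
    assert set(np.unique(stim.image)) <= {0.0, 1.0}


def test_tumbling_e_opposite_orientations_are_180_rotations():
    up = pm.make_tumbling_E(2.0, "up", canvas=None)
    down = pm.make_tumbling_E(2.0, "down", canvas=None)
    assert np.array_equal(np.rot90(up.image, 2), down.image)
    left = pm.make_tumbling_E(2.0, "left", canvas=None)
    right = pm.make_tumbling_E(2.0, "right", canvas=None)
    assert np.array_equal(np.rot90(right.image, 2), left.image)


def test_tumbling_e_stroke_is_fifth_of_height():
    stim = pm.make_tumbling_E(2.0, "right", canvas=None)
    h = stim.image.shape[0]
    # middle arm occupies one fifth of the rows at the right edge
    col = stim.image[:, -1]
    assert col.sum() == pytest.approx(3 * h / 5, abs=3)
    # spine fills the full height on the left edge
    assert stim.image[:, 0].sum() == h


def test_tumbling_e_too_small_raises():
    with pytest.raises(ResolutionError):
        pm.make_tumbling_E(0.8, "up", px_per_deg=1.0)


def test_grating_bar_width_and_duty_cycle():
    stim = pm.make_grating(2.9, "vertical", px_per_deg=40.0,
                           patch_diameter_deg=25.0)
    assert stim.meta["bar_px"] == pytest.approx(10 ** 2.9 / 60 * 40)
    patch = stim.image[stim.image > -1]
    # ~50% duty cycle inside the circular patch
    rr, cc = np.nonzero(stim.image)
    mean = stim.image.sum() / (np.pi * (25.0 * 40 / 2) ** 2)
    assert mean == pytest.approx(0.5, abs=0.1)


def test_grating_orientations_transpose_equal():
    h = pm.make_grating(2.5, "horizontal", canvas=(1080, 1080))
    v = pm.make_grating(2.5, "vertical", canvas=(1080, 1080))
    assert np.array_equal(h.image, v.image.T)


def test_unknown_orientation_rejected():
    with pytest.raises(ParameterError):
        pm.make_tumbling_E(2.0, "diagonal")
    with pytest.raises(ParameterError):
        pm.make_grating(2.5, "up")


def test_object_silhouettes_cover_all_classes():
    for cat in pm.stimuli.OBJECT_CLASSES:
        stim = pm.make_object_silhouette(cat, size_px=540)
        assert stim.image.shape == (540, 540)
        assert 0.02 < stim.image.mean() < 0.8  # non-trivial foreground
    a = pm.make_object_silhouette("top", seed=1)
    b = pm.make_object_silhouette("top", seed=1)
    assert np.array_equal(a.image, b.image)


# --------------------------------------------------------------------------
# selection rules
# --------------------------------------------------------------------------

def test_skeleton_sample_blank_stimulus_is_empty(derived_map):
    blank = pm.Stimulus(image=np.zeros((1080, 1080)), px_per_deg=40.0,
                        kind="object")
    assert pm.skeleton_sample(blank, derived_map) == set()


def test_skeleton_sample_single_pixel_selects_nearest():
    pmap = grid_map([500, 540, 580], [540, 540, 540])
    img = np.zeros((1080, 1080))
    img[502, 540] = 1.0
    assert pm.skeleton_sample(
        pm.Stimulus(image=img, px_per_deg=40.0, kind="object"), pmap
    ) == {0}


def test_skeleton_sample_plus_sign_over_grid():
    """A plus-shaped stroke over a 3x3 grid activates the 5 axis phosphenes."""
    rows, cols = np.mgrid[0:3, 0:3]
    pmap = grid_map(440 + rows.ravel() * 100, 440 + cols.ravel() * 100)
    img = np.zeros((1080, 1080))
    img[538:543, 420:661] = 1.0  # horizontal stroke through the centre row
    img[420:661, 538:543] = 1.0  # vertical stroke
    stim = pm.Stimulus(image=img, px_per_deg=40.0, kind="object")
    active = pm.skeleton_sample(stim, pmap)
    assert active == {1, 3, 4, 5, 7}  # centre + the four edge midpoints

    # brute-force nearest-neighbour oracle over the skeleton pixels
    from skimage.morphology import skeletonize

    skel = np.column_stack(np.nonzero(skeletonize(img > 0.5)))
    centres = pmap.pixel_positions()
    oracle = {
        int(np.argmin(((centres - p) ** 2).sum(axis=1))) for p in skel
    }
    assert active == oracle


def test_skeleton_sample_translation_equivariance():
    rows = [400, 500, 600, 700]
    pmap_a = grid_map(rows, rows)
    pmap_b = grid_map([r + 60 for r in rows], [r - 40 for r in rows])
    img = np.zeros((1080, 1080))
    img[480:560, 450:530] = 1.0
    a = pm.skeleton_sample(pm.Stimulus(image=img, px_per_deg=40, kind="object"), pmap_a)
    shifted = np.zeros((1080, 1080))
    shifted[540:620, 410:490] = 1.0
    b = pm.skeleton_sample(pm.Stimulus(image=shifted, px_per_deg=40, kind="object"), pmap_b)
    assert a == b


def test_direct_mask_saturation_and_empty(derived_map):
    white = pm.Stimulus(image=np.ones(derived_map.canvas), px_per_deg=40.0,
                        kind="object")
    active = pm.direct_mask(white, derived_map)
    assert len(active) == len(derived_map) - derived_map.n_offcanvas()
    black = pm.Stimulus(image=np.zeros(derived_map.canvas), px_per_deg=40.0,
                        kind="object")
    assert pm.direct_mask(black, derived_map) == set()


def test_direct_mask_half_white_selects_exact_subset():
    # 10 phosphenes, 4 in the white (left) half of the canvas
    cols = [100, 200, 300, 400, 600, 700, 800, 900, 950, 1000]
    pmap = grid_map([500] * 10, cols)
    img = np.zeros((1080, 1080))
    img[:, :540] = 1.0
    stim = pm.Stimulus(image=img, px_per_deg=40.0, kind="object")
    assert pm.direct_mask(stim, pmap) == {0, 1, 2, 3}


def test_direct_mask_monotone_in_threshold():
    rng = np.random.default_rng(0)
    img = rng.uniform(size=(1080, 1080))
    pmap = grid_map(rng.uniform(0, 1080, 60), rng.uniform(0, 1080, 60))
    stim = pm.Stimulus(image=img, px_per_deg=40.0, kind="object")
    sizes = [len(pm.direct_mask(stim, pmap, threshold=t))
             for t in (0.8, 0.5, 0.2)]
    assert sizes[0] <= sizes[1] <= sizes[2]


def test_offcanvas_phosphenes_are_inactive_not_errors():
    pmap = grid_map([500, -50], [500, 2000])
    assert pmap.n_offcanvas() == 1
    white = pm.Stimulus(image=np.ones((1080, 1080)), px_per_deg=40.0,
                        kind="object")
    assert pm.direct_mask(white, pmap) == {0}


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def test_render_single_gaussian_peak_and_decay():
    pmap = grid_map([540], [540], radius=0.75)  # sigma = 10 px
    frame = pm.render_phosphenes(pmap, {0})
    assert frame.image[540, 540] == pytest.approx(1.0)
    row = frame.image[540, 540:572]
    assert np.all(np.diff(row) < 0)  # radially monotone decay
    # value at 3 sigma is exp(-4.5) of the peak
    assert frame.image[540, 570] == pytest.approx(np.exp(-4.5), rel=1e-9)


def test_render_cap_with_coincident_phosphenes():
    one = grid_map([540], [540], radius=0.75)
    two = grid_map([540, 540], [540, 540], radius=0.75)
    f1 = pm.render_phosphenes(one, {0})
    f2 = pm.render_phosphenes(two, {0, 1})
    assert f2.image.max() <= 1.0
    assert np.allclose(
        f2.image[f2.image >= 1.0 - 1e-12], 1.0
    )
    # the capped centre is identical; the flanks saturate differently
    assert f2.image[540, 540] == f1.image[540, 540] == pytest.approx(1.0)


def test_render_respects_intensities_and_bounds(derived_map):
    intens = np.linspace(0.1, 1.0, len(derived_map))
    frame = pm.render_phosphenes(derived_map, set(range(len(derived_map))),
                                 intensities=intens)
    assert frame.image.min() >= 0.0 and frame.image.max() <= 1.0


def test_render_rejects_out_of_range_active():
    pmap = grid_map([540], [540])
    with pytest.raises(ParameterError):
        pm.render_phosphenes(pmap, {5})


# --------------------------------------------------------------------------
# acuity ladder
# --------------------------------------------------------------------------

def test_ladder_simple_rule_application():
    result = pm.brvt_score([(2.0, 5, 8), (1.8, 3, 8)])
    assert result.va_logmar == 2.0


def test_ladder_grating_needs_seven_of_eight():
    trials = [(lv, 0, 8) for lv in E_LEVELS] + [(2.9, 7, 8)]
    assert pm.brvt_score(trials).va_logmar == 2.9
    trials = [(lv, 0, 8) for lv in E_LEVELS] + [(2.9, 6, 8)]
    assert pm.brvt_score(trials).va_logmar == LADDER_FLOOR


def test_ladder_floor_when_everything_fails():
    trials = [(lv, 0, 8) for lv in E_LEVELS] + [(lv, 0, 8) for lv in GRATING_LEVELS]
    assert pm.brvt_score(trials).va_logmar == 3.0


def test_ladder_against_exhaustive_brute_force():
    """Agreement with direct rule evaluation over all pass/fail patterns."""
    levels = [1.8, 2.0, 2.3, 2.9]  # two letter, two grating levels
    for pattern in itertools.product([0, 1], repeat=len(levels)):
        trials = []
        for lv, passed in zip(levels, pattern):
            if lv in (2.3, 2.9):
                trials.append((lv, 7 if passed else 6, 8))
            else:
                trials.append((lv, 4 if passed else 3, 8))
        passed_levels = [lv for lv, p in zip(levels, pattern) if p]
        expected = min(passed_levels) if passed_levels else 3.0
        assert pm.brvt_score(trials).va_logmar == expected


def test_ladder_malformed_trials_rejected():
    with pytest.raises(ValidationError):
        pm.brvt_score([(2.0, 9, 8)])
    with pytest.raises(ValidationError):
        pm.brvt_score([])


def test_validation_block_levels_and_trials():
    block = pm.validation_block(2.0)
    assert block == [(1.8, 12), (2.0, 12), (2.2, 12)]
    assert sum(n for _, n in block) == 36


def test_validation_block_below_floor_flagged():
    with pytest.warns(UserWarning, match="below the ladder floor"):
        block = pm.validation_block(0.8)
    assert block[0][0] == pytest.approx(0.6)
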