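"""Cost function: trapezoid restriction, histograms, NMI, Dice, total cost."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ebusreg import (CostConfig, DegenerateEntropyError, EBUSFrame,
                     EmptyROIError, FanImageGeometry, FanSpec,
                     TrapezoidRegion, bounding_trapezoid, dice_index,
                     joint_histogram, nmi_cost, total_cost)

GEOM = FanImageGeometry.from_fan_spec(FanSpec())
SHAPE = (300, 300)


def _frame(roi, image=None):
    if image is None:
        image = np.zeros(SHAPE, dtype=np.uint8)
    return EBUSFrame(image=image, roi_mask=roi, fan_geometry=GEOM)


def _full_region(shape):
    return TrapezoidRegion(r_lo=0.0, r_hi=1e6, theta_lo=-180.0,
                           theta_hi=180.0, mask=np.ones(shape, dtype=bool))


# -- bounding trapezoid ----------------------------------------------------

def test_trapezoid_of_full_fan_is_full_fan():
    fan = GEOM.fan_mask(SHAPE)
    region = bounding_trapezoid(_frame(fan))
    assert np.array_equal(region.mask, fan)


def test_single_pixel_roi_expands_to_minimum_region():
    roi = np.zeros(SHAPE, dtype=bool)
    roi[150, 150] = True
    region = bounding_trapezoid(_frame(roi))
    assert region.r_hi - region.r_lo >= 8.0
    assert region.n_pixels >= 8 * 8 / 2  # clipped to the fan at worst
    assert region.mask[150, 150]


def test_disc_roi_bounds_match_exhaustive_polar_scan():
    """r/theta bounds of a raster disc equal its per-pixel polar extremes."""
    rr, cc = np.mgrid[0:300, 0:300]
    disc = (rr - 180) ** 2 + (cc - 120) ** 2 <= 30 ** 2
    region = bounding_trapezoid(_frame(disc))
    radius, theta = GEOM.polar(SHAPE)
    assert region.r_lo == pytest.approx(radius[disc].min())
    assert region.r_hi == pytest.approx(radius[disc].max())
    assert region.theta_lo == pytest.approx(theta[disc].min())
    assert region.theta_hi == pytest.approx(theta[disc].max())
    assert np.all(region.mask[disc])  # every ROI pixel inside the region


def test_empty_roi_rejected():
    with pytest.raises(EmptyROIError):
        bounding_trapezoid(_frame(np.zeros(SHAPE, dtype=bool)))


# -- joint histogram -------------------------------------------------------

def test_constant_pair_puts_all_mass_in_one_bin():
    a = np.full((4, 4), 7, dtype=np.uint8)
    region = _full_region(a.shape)
    joint, pa, pb = joint_histogram(a, a, region)
    assert joint[7, 7] == pytest.approx(1.0)
    assert joint.sum() == pytest.approx(1.0, abs=1e-9)


def test_histogram_mass_conservation_and_marginals(rng):
    a = rng.integers(0, 256, size=(20, 20)).astype(np.uint8)
    b = rng.integers(0, 256, size=(20, 20)).astype(np.uint8)
    mask = rng.random((20, 20)) > 0.4
    region = TrapezoidRegion(r_lo=0, r_hi=1e6, theta_lo=-180, theta_hi=180,
                             mask=mask)
    joint, pa, pb = joint_histogram(a, b, region)
    assert joint.sum() == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(pa, joint.sum(axis=1))
    np.testing.assert_allclose(pb, joint.sum(axis=0))
    # unnormalized count equals the region size
    av, bv = a[mask], b[mask]
    assert joint[av[0], bv[0]] * mask.sum() == pytest.approx(
        np.sum((av == av[0]) & (bv == bv[0])))


def test_joint_histogram_matches_hand_enumeration():
    a = np.array([[0, 0, 1], [1, 2, 2], [0, 1, 2]], dtype=np.uint8)
    b = np.array([[0, 1, 1], [1, 2, 0], [0, 1, 2]], dtype=np.uint8)
    joint, _, _ = joint_histogram(a, b, _full_region(a.shape),
                                  CostConfig(gray_levels=3))
    hand = np.zeros((3, 3))
    for x, y in zip(a.ravel(), b.ravel()):
        hand[x, y] += 1
    np.testing.assert_allclose(joint, hand / 9.0)


# -- NMI -------------------------------------------------------------------

def test_identical_nonconstant_images_give_minus_one(rng):
    a = rng.integers(0, 256, size=(30, 30)).astype(np.uint8)
    assert nmi_cost(a, a, _full_region(a.shape)) == pytest.approx(-1.0)


def test_nmi_hand_computed_toy_value():
    """a = (0,0,1,1), b = (0,0,1,2): CN = 1 - (ln2 + 1.5 ln2)/(1.5 ln2)
    = -2/3 exactly."""
    a = np.array([[0, 0], [1, 1]], dtype=np.uint8)
    b = np.array([[0, 0], [1, 2]], dtype=np.uint8)
    assert nmi_cost(a, b, _full_region(a.shape)) == pytest.approx(
        -2.0 / 3.0, abs=1e-9)


def test_independent_images_approach_zero_from_below(rng):
    """In the independence limit h(a,b) -> h(a) + h(b), so CN -> 0; the gap
    shrinks as the region grows."""
    gaps = []
    for n in (64, 512):
        a = rng.integers(0, 256, size=(n, n)).astype(np.uint8)
        b = rng.integers(0, 256, size=(n, n)).astype(np.uint8)
        cn = nmi_cost(a, b, _full_region(a.shape))
        assert -1.0 <= cn <= 0.0
        gaps.append(-cn)
    assert gaps[1] < gaps[0]
    assert gaps[1] < 0.35


def test_degenerate_entropy_raises_unless_opted_in():
    a = np.full((5, 5), 9, dtype=np.uint8)
    region = _full_region(a.shape)
    with pytest.raises(DegenerateEntropyError):
        nmi_cost(a, a, region)
    assert nmi_cost(a, a, region, allow_degenerate=True) == -1.0


# -- Dice ------------------------------------------------------------------

@pytest.mark.parametrize("r1,r2,expect", [
    (np.ones((4, 4), bool), np.ones((4, 4), bool), 1.0),
    (np.eye(4, dtype=bool), ~np.eye(4, dtype=bool), 0.0),
    (np.zeros((4, 4), bool), np.zeros((4, 4), bool), 0.0),
])
def test_dice_limits(r1, r2, expect):
    assert dice_index(r1, r2) == expect


def test_dice_hand_count():
    r1 = np.zeros((4, 4), bool)
    r2 = np.zeros((4, 4), bool)
    r1[0, :4] = True          # |r1| = 4
    r2[0, 2:] = r2[1, :2] = True  # |r2| = 4, overlap 2
    assert dice_index(r1, r2) == pytest.approx(0.5)
    assert dice_index(r2, r1) == pytest.approx(0.5)


# -- total cost ------------------------------------------------------------

class _View:
    def __init__(self, image, roi_mask):
        self.image = image
        self.roi_mask = roi_mask


def _gradient_image():
    rr, cc = np.mgrid[0:300, 0:300]
    return ((rr + cc) % 256).astype(np.uint8)


def test_perfect_match_reaches_lower_bound():
    img = _gradient_image()
    roi = GEOM.fan_mask(SHAPE) & (np.mgrid[0:300, 0:300][0] > 100)
    frame = _frame(roi, image=img)
    out = total_cost(_View(img, roi), frame)
    assert out["C"] == pytest.approx(-2.0)
    assert out["CN"] == pytest.approx(-1.0)
    assert out["CD"] == pytest.approx(1.0)


def test_identical_images_disjoint_masks():
    img = _gradient_image()
    rr = np.mgrid[0:300, 0:300][0]
    fan = GEOM.fan_mask(SHAPE)
    roi_frame = fan & (rr > 100) & (rr <= 160)
    roi_view = fan & (rr > 160)
    out = total_cost(_View(img, roi_view), _frame(roi_frame, image=img))
    assert out["C"] == pytest.approx(-1.0)
    assert out["CD"] == 0.0


def test_total_cost_is_component_difference(rng):
    a = rng.integers(0, 256, size=SHAPE).astype(np.uint8)
    b = rng.integers(0, 256, size=SHAPE).astype(np.uint8)
    fan = GEOM.fan_mask(SHAPE)
    rr, cc = np.mgrid[0:300, 0:300]
    roi_f = fan & ((rr - 170) ** 2 + (cc - 150) ** 2 <= 40 ** 2)
    roi_v = fan & ((rr - 150) ** 2 + (cc - 170) ** 2 <= 40 ** 2)
    frame = _frame(roi_f, image=b)
    region = bounding_trapezoid(frame)
    out = total_cost(_View(a, roi_v), frame)
    assert out["C"] == pytest.approx(
        nmi_cost(a, b, region) - dice_index(roi_v, roi_f), abs=1e-12)


# -- invariants (hypothesis) ----------------------------------------------

small_img = hnp.arrays(np.uint8, (12, 12),
                       elements=st.integers(0, 255))
small_mask = hnp.arrays(np.bool_, (12, 12), elements=st.booleans())


@settings(max_examples=60, derandomize=True)
@given(a=small_img, b=small_img, r1=small_mask, r2=small_mask)
def test_cost_range_and_symmetry(a, b, r1, r2):
    """-2 <= C <= 1 for any input; CN and CD are symmetric."""
    region = _full_region(a.shape)
    cn = nmi_cost(a, b, region, allow_degenerate=True)
    cd = dice_index(r1, r2)
    assert -1.0 - 1e-12 <= cn <= 1.0 + 1e-12
    assert 0.0 <= cd <= 1.0
    assert -2.0 - 1e-12 <= cn - cd <= 1.0 + 1e-12
    assert nmi_cost(b, a, region, allow_degenerate=True) == pytest.approx(cn)
    assert dice_index(r2, r1) == pytest.approx(cd)


@settings(max_examples=40, derandomize=True)
@given(a=small_img, b=small_img, perm_seed=st.integers(0, 2 ** 31 - 1))
def test_nmi_invariant_to_shared_gray_relabeling(a, b, perm_seed):
    """Applying one gray-level permutation to both images preserves CN."""
    region = _full_region(a.shape)
    perm = np.random.default_rng(perm_seed).permutation(256).astype(np.uint8)
    cn = nmi_cost(a, b, region, allow_degenerate=True)
    cn_p = nmi_cost(perm[a], perm[b], region, allow_degenerate=True)
    assert cn_p == pytest.approx(cn, abs=1e-12)


def test_dice_monotone_under_mask_growth():
    """Growing the virtual mask from disjoint to identical never decreases
    the Dice term."""
    rr = np.mgrid[0:100, 0:100][0]
    frame_mask = rr < 30
    prev = -1.0
    for overlap in range(0, 31, 5):
        mask = (rr >= 30 - overlap) & (rr < 60 - overlap)
        cd = dice_index(mask, frame_mask)
        assert cd >= prev - 1e-12
        prev = cd
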