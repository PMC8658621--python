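import numpy as np
import pytest

from ustiff.massmetrics import (
    MassROI,
    circle_roi,
    classify_size,
    equivalent_diameter_mm,
    glcm_homogeneity,
    rasterize_roi,
    roi_component_percentages,
    stiffness_index,
)

SPACING = (0.75, 0.75)


def test_axis_aligned_square_rasterizes_to_analytic_pixel_count():
    roi = MassROI(((0.0, 0.0), (7.5, 0.0), (7.5, 7.5), (0.0, 7.5)), 0, "cyst")
    mask = rasterize_roi(roi, (20, 20), SPACING)
    assert mask.sum() == 100  # 7.5 mm / 0.75 mm = 10 pixel centers per axis
    assert mask.sum() * 0.75**2 == pytest.approx(56.25)


def test_translation_by_pixel_multiples_preserves_count():
    base = ((1.1, 0.9), (6.3, 1.4), (4.8, 6.9))
    roi1 = MassROI(base, 0, "cancer")
    shift = (4 * 0.75, 7 * 0.75)
    roi2 = MassROI(tuple((x + shift[0], y + shift[1]) for x, y in base), 0, "cancer")
    m1 = rasterize_roi(roi1, (30, 30), SPACING)
    m2 = rasterize_roi(roi2, (30, 30), SPACING)
    assert m1.sum() == m2.sum()
    np.testing.assert_array_equal(np.roll(np.roll(m1, 4, 0), 7, 1), m2)


def test_subpixel_triangle_covers_at_most_one_pixel():
    tri = ((1.0, 1.0), (1.2, 1.0), (1.1, 1.2))
    mask = rasterize_roi(MassROI(tri, 0, "cyst"), (10, 10), SPACING)
    assert mask.sum() <= 1


def test_degenerate_and_self_intersecting_polygons_rejected():
    with pytest.raises(ValueError):
        MassROI(((0, 0), (1, 1)), 0, "cyst")
    with pytest.raises(ValueError):
        MassROI(((0, 0), (2, 2), (2, 0), (0, 2)), 0, "cyst")  # bow-tie
    with pytest.raises(ValueError):
        MassROI(((0, 0), (1, 0), (2, 0)), 0, "cyst")  # zero area


def test_stiffness_index_is_the_roi_mean(rng):
    S = rng.random((20, 20))
    mask = rng.random((20, 20)) > 0.5
    assert stiffness_index(S, mask) == pytest.approx(S[mask].sum() / mask.sum())
    uniform = np.full((5, 5), 0.5)
    assert stiffness_index(uniform, np.ones((5, 5), bool)) == 0.5
    half = np.zeros((4, 4))
    half[:2] = 1.0
    assert stiffness_index(half, np.ones((4, 4), bool)) == 0.5
    with pytest.raises(ValueError):
        stiffness_index(S, np.zeros((20, 20), bool))


def test_component_percentages_partition_and_pure_region():
    labels = np.full((10, 10), 6)  # hard fibroglandular everywhere
    stiff, comp = roi_component_percentages(labels, np.ones((10, 10), bool))
    assert (stiff["soft"], stiff["intermediate"], stiff["hard"]) == (0.0, 0.0, 100.0)
    assert comp["hard_fibroglandular"] == 100.0
    mixed = np.array([[1, 2], [5, 6]])
    stiff, comp = roi_component_percentages(mixed, np.ones((2, 2), bool))
    assert sum(stiff.values()) == pytest.approx(100.0)
    assert sum(comp.values()) == pytest.approx(100.0)
    with pytest.raises(ValueError, match="outside"):
        roi_component_percentages(np.zeros((2, 2), int), np.ones((2, 2), bool))


def test_constant_region_has_unit_homogeneity():
    assert glcm_homogeneity(np.full((6, 6), 0.42), np.ones((6, 6), bool)) == pytest.approx(1.0)


def test_checkerboard_homogeneity_closed_form():
    # strict two-level checkerboard in the extreme bins: every horizontal
    # pair has |i - j| = 7, so homogeneity = 1/8
    cb = (np.indices((8, 8)).sum(axis=0) % 2) * 0.95
    hom = glcm_homogeneity(cb, np.ones((8, 8), bool), offsets=((0, 1),))
    assert hom == pytest.approx(1.0 / 8.0)


def test_matches_bruteforce_pair_enumeration(rng):
    S = rng.random((4, 4))
    mask = rng.random((4, 4)) > 0.25
    if mask.sum() < 2:
        mask[:2, 0] = True
    levels = 8
    bins = np.clip((S * levels).astype(int), 0, levels - 1)
    offsets = ((0, 1), (1, 0), (1, 1), (1, -1))
    homs = []
    for dr, dc in offsets:
        pairs = []
        for i in range(4):
            for j in range(4):
                r, c = i + dr, j + dc
                if 0 <= r < 4 and 0 <= c < 4 and mask[i, j] and mask[r, c]:
                    pairs.append((bins[i, j], bins[r, c]))
        if not pairs:
            continue
        P = np.zeros((levels, levels))
        for a, b in pairs:
            P[a, b] += 1
            P[b, a] += 1
        P /= P.sum()
        homs.append(sum(P[a, b] / (1 + abs(a - b)) for a in range(levels) for b in range(levels)))
    expected = float(np.mean(homs))
    assert glcm_homogeneity(S, mask) == pytest.approx(expected, abs=1e-12)


def test_matches_skimage_on_full_rectangle(rng):
    # independent cross-check against the reference GLCM implementation,
    # valid where the ROI is the full rectangle
    from skimage.feature import graycomatrix

    S = rng.random((12, 12))
    levels = 8
    bins = np.clip((S * levels).astype(int), 0, levels - 1).astype(np.uint8)
    weight = 1.0 / (1.0 + np.abs(np.subtract.outer(np.arange(levels), np.arange(levels))))
    homs = []
    # the four symmetric unit offsets expressed as skimage angles
    for dist, ang in [(1, 0.0), (1, np.pi / 2), (1, np.pi / 4), (1, 3 * np.pi / 4)]:
        glcm = graycomatrix(bins, [dist], [ang], levels=levels, symmetric=True, normed=True)
        homs.append(float((glcm[:, :, 0, 0] * weight).sum()))
    ours = glcm_homogeneity(S, np.ones((12, 12), bool))
    assert ours == pytest.approx(float(np.mean(homs)), abs=1e-9)


def test_homogeneity_invariant_to_shift_within_bins():
    base = np.array([[0.01, 0.14], [0.30, 0.52]])
    mask = np.ones((2, 2), bool)
    shifted = base + 0.04  # stays within the same 1/8-wide bins
    assert glcm_homogeneity(base, mask) == glcm_homogeneity(shifted, mask)


@pytest.mark.parametrize(
    "diameter_mm,expected",
    [(10.0, "small"), (20.0, "large")],
)
def test_size_classification_from_equivalent_diameter(diameter_mm, expected):
    roi = circle_roi((15.0, 15.0), diameter_mm, 0, "cancer", n_vertices=256)
    mask = rasterize_roi(roi, (40, 40), SPACING)
    d = equivalent_diameter_mm(mask, SPACING)
    assert d == pytest.approx(diameter_mm, abs=0.5)
    assert classify_size(mask, SPACING) == expected


def test_exact_cutoff_diameter_counts_as_small():
    # build a mask whose equivalent diameter is exactly 15.0 mm
    n_px = int(round(np.pi * 7.5**2 / 0.75**2))
    mask = np.zeros((60, 60), bool)
    mask.flat[:n_px] = True
    d = equivalent_diameter_mm(mask, SPACING)
    assert d <= 15.0 + 1e-6
    assert classify_size(mask, SPACING) == "small"
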