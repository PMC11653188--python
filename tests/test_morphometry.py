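import math

import numpy as np
import pytest

from micromorph.morphometry import (
    FEATURE_NAMES,
    MorphometryConfig,
    convex_hull_mask,
    detect_soma,
    extract_features,
    fractal_dimension,
    shape_metrics,
    skeleton_metrics,
    skeletonize_cell,
    sholl_metrics,
)

from conftest import as_cell, disk_mask


def rect_mask(h, w, pad=5):
    m = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    m[pad:pad + h, pad:pad + w] = True
    return m


def sierpinski(depth):
    m = np.array([[1]], dtype=bool)
    for _ in range(depth):
        z = np.zeros_like(m)
        m = np.block([[m, m], [m, z]])
    return m


class TestShapeMetrics:
    def test_disk_is_nearly_circular(self):
        s = shape_metrics(disk_mask(50))
        assert 0.95 <= s.circularity <= 1.02
        assert s.area == pytest.approx(math.pi * 50**2, rel=0.02)
        assert s.feret_diameter == pytest.approx(100, rel=0.03)

    def test_rectangle_closed_form(self):
        # 20 wide x 10 tall: A=200, P=60 -> circularity 4*pi*200/3600
        s = shape_metrics(rect_mask(10, 20))
        assert s.aspect_ratio == 2.0
        assert s.orientation == pytest.approx(0.0, abs=1e-6)
        assert s.circularity == pytest.approx(4 * math.pi * 200 / 60**2, abs=0.05)
        assert s.area == 200

    def test_square_symmetry_forces_unit_eccentricity(self):
        s = shape_metrics(rect_mask(20, 20))
        assert 1.0 <= s.eccentricity <= 1.05

    def test_vertical_rectangle_orientation(self):
        s = shape_metrics(rect_mask(20, 10))
        assert s.orientation == pytest.approx(90.0, abs=1e-6)
        assert s.eccentricity == pytest.approx(2.0, rel=0.05)

    def test_single_pixel_defined(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        s = shape_metrics(m)
        assert s.area == 1
        assert np.isfinite(s.perimeter) and s.perimeter > 0
        assert s.eccentricity == pytest.approx(1.0)

    def test_empty_mask_is_domain_error(self):
        with pytest.raises(ValueError):
            shape_metrics(np.zeros((5, 5), dtype=bool))

    def test_circularity_rotation_and_area_flip_invariance(self):
        blob = disk_mask(12)
        c = blob.shape[0] // 2
        blob[c - 2:c + 2, c:] = True  # disk with one rectangular arm
        s0 = shape_metrics(blob)
        assert shape_metrics(np.rot90(blob)).circularity == pytest.approx(
            s0.circularity, rel=0.01)
        assert shape_metrics(blob[::-1]).area == s0.area
        assert shape_metrics(blob[:, ::-1]).area == s0.area


class TestSoma:
    def test_opening_preserves_a_disk(self):
        m = disk_mask(20)
        soma = detect_soma(m, opening_radius=5)
        assert soma.sum() >= 0.95 * m.sum()

    def test_processes_excluded_from_soma(self):
        m = disk_mask(10, pad=45)
        c = m.shape[0] // 2
        m[c, :] = True  # two horizontal 1-px processes through the disk
        m[:, c] = True
        soma = detect_soma(m, opening_radius=5)
        # soma stays within the disk (plus 2 px rasterization slack) and
        # excludes the length-40 process tails entirely
        rr, cc = np.indices(m.shape)
        dist = np.hypot(rr - c, cc - c)
        assert dist[soma].max() <= 12
        assert soma.sum() >= 0.8 * math.pi * 10**2

    def test_thin_mask_fallback_nonempty(self):
        m = np.zeros((30, 30), dtype=bool)
        m[15, 5:25] = True  # 1-px line, thinner than the element everywhere
        soma = detect_soma(m, opening_radius=6)
        assert soma.any()
        assert (soma & ~m).sum() == 0


class TestSkeleton:
    def test_bar_skeleton_is_a_line(self):
        m = rect_mask(3, 50)
        sk = skeletonize_cell(m)
        assert (sk & ~m).sum() == 0
        res = skeleton_metrics(sk)
        assert res.n_endpoints == 2
        assert res.n_junctions == 0
        assert 40 <= sk.sum() <= 52

    def test_disk_collapses(self):
        sk = skeletonize_cell(disk_mask(15))
        assert sk.sum() <= 10

    def test_plus_sign_topology(self):
        m = np.zeros((41, 41), dtype=bool)
        m[19:22, :] = True
        m[:, 19:22] = True
        sk = skeletonize_cell(m)
        res = skeleton_metrics(sk)
        assert res.n_endpoints == 4
        assert res.n_junctions == 1

    def test_straight_line_endpoints(self):
        sk = np.zeros((10, 30), dtype=bool)
        sk[5, 2:28] = True
        res = skeleton_metrics(sk)
        assert (res.n_endpoints, res.n_junctions) == (2, 0)
        assert res.branch_length == 26

    def test_one_px_plus_junction(self):
        sk = np.zeros((11, 11), dtype=bool)
        sk[5, :] = True
        sk[:, 5] = True
        res = skeleton_metrics(sk)
        assert (res.n_endpoints, res.n_junctions) == (4, 1)

    def test_t_shape_initial_points(self):
        # soma disk centred on the T junction; three arms leave it
        sk = np.zeros((41, 41), dtype=bool)
        sk[20, :] = True
        sk[20:, 20] = True
        rr, cc = np.indices((41, 41))
        soma_mask = (rr - 20) ** 2 + (cc - 20) ** 2 <= 5**2
        res = skeleton_metrics(sk, soma_mask)
        assert res.n_initial_points == 3

    def test_empty_skeleton_all_zero(self):
        res = skeleton_metrics(np.zeros((5, 5), dtype=bool))
        assert (res.branch_length, res.n_initial_points, res.n_junctions,
                res.n_endpoints) == (0, 0, 0, 0)

    def test_diagonal_weighting_flag(self):
        sk = np.eye(10, dtype=bool)
        plain = skeleton_metrics(sk, diagonal_weight=1.0)
        weighted = skeleton_metrics(sk, diagonal_weight=math.sqrt(2))
        assert plain.branch_length == 10
        assert weighted.branch_length > plain.branch_length


def oracle_skeleton_metrics(skel, soma):
    """Independent double-loop reimplementation of the neighbor-count rules."""
    h, w = skel.shape
    nbrs = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            if not skel[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                        nbrs[r, c] += 1
    endpoints = sum(1 for r in range(h) for c in range(w)
                    if skel[r, c] and nbrs[r, c] == 1)
    # merge adjacent junction pixels via DFS flood fill
    junction = [(r, c) for r in range(h) for c in range(w)
                if skel[r, c] and nbrs[r, c] >= 3]
    unseen = set(junction)
    n_junctions = 0
    while unseen:
        n_junctions += 1
        stack = [unseen.pop()]
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (r + dr, c + dc) in unseen:
                        unseen.remove((r + dr, c + dc))
                        stack.append((r + dr, c + dc))
    initial = 0
    branch_length = 0
    for r in range(h):
        for c in range(w):
            if not (skel[r, c] and not soma[r, c]):
                continue
            branch_length += 1
            touches = any(
                0 <= r + dr < h and 0 <= c + dc < w and soma[r + dr, c + dc]
                for dr in (-1, 0, 1) for dc in (-1, 0, 1)
            )
            if touches:
                initial += 1
    return branch_length, initial, n_junctions, endpoints


@pytest.mark.parametrize("seed", range(25))
def test_skeleton_metrics_match_bruteforce_oracle(seed):
    """Neighbor-count rules agree with an independent enumeration."""
    rng = np.random.default_rng(seed)
    skel = rng.random((32, 32)) < 0.2
    rr, cc = np.indices((32, 32))
    soma = (rr - rng.integers(8, 24)) ** 2 + (cc - rng.integers(8, 24)) ** 2 \
        <= rng.integers(3, 8) ** 2
    res = skeleton_metrics(skel, soma)
    assert (res.branch_length, res.n_initial_points, res.n_junctions,
            res.n_endpoints) == oracle_skeleton_metrics(skel, soma)


class TestFractal:
    def test_filled_square_plane_filling(self):
        assert 1.9 <= fractal_dimension(np.ones((256, 256), dtype=bool)) <= 2.0

    def test_line_is_one_dimensional(self):
        m = np.zeros((256, 256), dtype=bool)
        m[128, :] = True
        assert 0.95 <= fractal_dimension(m) <= 1.1

    def test_sierpinski_triangle(self):
        d = fractal_dimension(sierpinski(6))
        assert abs(d - math.log(3) / math.log(2)) <= 0.12

    def test_degenerate_fit_is_error(self):
        m = np.zeros((64, 64), dtype=bool)
        m[32, 32] = True  # one box occupied at every size
        with pytest.raises(ValueError):
            fractal_dimension(m)

    def test_too_few_box_sizes_is_error(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.ones((64, 64), dtype=bool), box_sizes=[4])


class TestConvexHull:
    def test_disk_is_nearly_convex(self):
        m = disk_mask(20)
        hull = convex_hull_mask(m)
        assert 1.0 <= hull.sum() / m.sum() <= 1.05
        assert (m & ~hull).sum() == 0

    def test_two_points_hull_contains_both(self):
        m = np.zeros((30, 30), dtype=bool)
        m[5, 5] = m[25, 20] = True
        hull = convex_hull_mask(m)
        assert hull[5, 5] and hull[25, 20]

    def test_c_shape_hull_strictly_larger(self):
        m = disk_mask(15)
        m[:, m.shape[1] // 2:] = False  # half-moon
        hull = convex_hull_mask(m)
        assert hull.sum() > m.sum()
        # near-idempotence: re-hulling adds at most rasterization slack
        hull2 = convex_hull_mask(hull)
        assert (hull & ~hull2).sum() == 0
        assert hull2.sum() - hull.sum() <= 0.02 * hull.sum()


class TestSholl:
    def test_single_straight_process(self):
        sk = np.zeros((200, 200), dtype=bool)
        sk[100, 100:196] = True  # distances 0..95 from the centroid
        res = sholl_metrics(sk, (100, 100), (200, 200), step=10)
        assert res.n_circles == 9
        assert res.n_crossings == 9

    def test_empty_skeleton_keeps_max_distance(self):
        res = sholl_metrics(np.zeros((200, 200), dtype=bool), (100, 100),
                            (200, 200), step=10)
        assert res.n_circles == 0 and res.n_crossings == 0
        assert res.max_distance == pytest.approx(math.sqrt(2) * 100, rel=1e-6)

    def test_four_arms_cross_each_circle_four_times(self):
        sk = np.zeros((101, 101), dtype=bool)
        sk[50, :] = True
        sk[:, 50] = True
        res = sholl_metrics(sk, (50, 50), (101, 101), step=10)
        assert res.n_circles == 5
        assert res.n_crossings == 20

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            sholl_metrics(np.zeros((5, 5), dtype=bool), (2, 2), (5, 5), step=0)


class TestExtractFeatures:
    def test_exactly_32_named_features(self, small_scene):
        from micromorph.mask_io import segment_cells

        img, _ = small_scene
        cells = segment_cells(img)
        feats = extract_features(cells[0])
        assert tuple(feats) == FEATURE_NAMES
        assert len(feats) == 32
        assert all(np.isfinite(v) for v in feats.values())

    def test_translation_invariance_on_matched_canvas(self):
        base = np.zeros((300, 300), dtype=bool)
        blob = disk_mask(8, pad=40) | (np.hypot(
            *(np.indices((96, 96)) - 48)) < 1)
        base[30:126, 30:126] = blob
        shifted = np.zeros((300, 300), dtype=bool)
        shifted[37:133, 43:139] = blob  # translated by (7, 13)
        f0 = extract_features(as_cell(base))
        # matched canvas: same shape, centroid offset matched by shifting
        # the canvas the same way, so corner distances change
        f1 = extract_features(as_cell(shifted))
        for name in FEATURE_NAMES:
            if name == "Sh_max_distance":
                continue
            assert f0[name] == pytest.approx(f1[name], rel=1e-9), name

    def test_disk_only_cell_joint_sanity(self):
        feats = extract_features(as_cell(disk_mask(30)))
        assert feats["Sk_endpoints"] <= 2
        assert feats["C_circularity"] >= 0.9
        assert feats["F_fractal_dimension"] >= 1.75

    def test_hull_metrics_dominate_cell_metrics(self, small_scene):
        from micromorph.mask_io import segment_cells

        img, _ = small_scene
        for cell in segment_cells(img):
            feats = extract_features(cell)
            assert feats["F_area"] >= feats["C_area"]
            assert feats["C_area"] / feats["F_area"] <= 1.0 + 1e-9

    def test_adding_a_process_never_decreases_endpoints(self):
        m = disk_mask(10, pad=60)
        c = m.shape[0] // 2
        counts = []
        # grow processes one at a time in the four cardinal directions
        for arm in range(1, 5):
            if arm == 1:
                m[c, c:c + 50] = True
            elif arm == 2:
                m[c, c - 50:c] = True
            elif arm == 3:
                m[c:c + 50, c] = True
            else:
                m[c - 50:c, c] = True
            feats = extract_features(as_cell(m.copy()))
            counts.append(feats["Sk_endpoints"])
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_features_table_shape_and_failures(self, small_scene):
        from micromorph.mask_io import segment_cells
        from micromorph.morphometry import features_table, META_COLUMNS

        img, truth = small_scene
        cells = segment_cells(img)
        table, failures = features_table(cells)
        assert list(table.columns) == list(META_COLUMNS) + list(FEATURE_NAMES)
        assert len(table) + len(failures) == len(cells)
        assert not table[list(FEATURE_NAMES)].isna().any().any()
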