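"""GPA, symmetrization, Procrustes distances and outlier screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from craniomorph import (GroupSpec, SimulationSpec, centroid_size, gpa,
                         optimal_rotation, procrustes_distance,
                         screen_outliers, simulate, symmetrize)
from craniomorph.superimpose import AlignmentError, _center_scale

from conftest import build_dataset


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def euler_zyz(a, b, c):
    ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
    rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz1 @ ry @ rz2


def grid_search_rotation(x, y, final_step_deg=0.1):
    """Brute-force rotation fit: coarse ZYZ Euler grid refined to 0.1 deg.

    Minimises ||x R - y||^2 over proper rotations; independent of the SVD
    solution it checks.
    """
    best = (np.inf, None)
    centers = (np.pi, np.pi / 2, np.pi)
    spans = (np.pi, np.pi / 2, np.pi)
    step = np.radians(10.0)
    while True:
        aa = [np.arange(c - s, c + s + 1e-12, step) for c, s in zip(centers, spans)]
        for a in aa[0]:
            for b in aa[1]:
                for c in aa[2]:
                    r = euler_zyz(a, b, c)
                    obj = ((x @ r - y) ** 2).sum()
                    if obj < best[0]:
                        best = (obj, (a, b, c))
        if step <= np.radians(final_step_deg):
            return best[0]
        centers = best[1]
        spans = (2 * step,) * 3
        step /= 5.0


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        assert centroid_size(sq) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_homogeneity(self, rng):
        x = rng.normal(size=(12, 3))
        assert centroid_size(3.7 * x) == pytest.approx(3.7 * centroid_size(x),
                                                       rel=1e-12)

    def test_matches_term_by_term_sum(self, rng):
        x = rng.normal(size=(10, 3))
        c = x.mean(axis=0)
        direct = np.sqrt(sum((p - c) @ (p - c) for p in x))
        assert abs(centroid_size(x) - direct) < 1e-12

    def test_coincident_points_error(self):
        with pytest.raises(AlignmentError, match="coincident"):
            centroid_size(np.ones((5, 3)))


class TestGPA:
    def test_rigid_copies_align_exactly(self, rng):
        base = rng.normal(size=(20, 3))
        arr = np.stack([(2 + i) * base @ random_rotation(rng) + rng.normal(size=3) * 9
                        for i in range(6)])
        al = gpa(arr, tangent=False)
        for i in range(1, 6):
            assert np.abs(al.shapes[i] - al.shapes[0]).max() < 1e-9

    def test_unit_size_centered_and_consensus_is_mean(self, rng):
        arr = rng.normal(size=(7, 15, 3)) + 5.0
        al = gpa(arr, tangent=False)
        for s in al.shapes:
            assert np.abs(s.mean(axis=0)).max() < 1e-9
            assert abs(np.sqrt((s ** 2).sum()) - 1.0) < 1e-9
        assert np.abs(al.consensus - al.shapes.mean(axis=0)).max() < 1e-12

    def test_invariant_to_input_rigid_motion(self, rng):
        arr = rng.normal(size=(6, 18, 3))
        al0 = gpa(arr)
        moved = arr.copy()
        for i in (0, 3):  # includes the consensus-initialising specimen
            moved[i] = 4.2 * moved[i] @ random_rotation(rng) + [80, -5, 12]
        al1 = gpa(moved)
        assert np.abs(al0.shapes - al1.shapes).max() < 1e-9

    def test_objective_nonincreasing(self, rng):
        arr = rng.normal(size=(9, 12, 3))
        shapes = np.stack([_center_scale(a)[0] for a in arr])
        consensus = shapes[0].copy()
        objs = []
        for _ in range(8):
            for i in range(len(shapes)):
                shapes[i] = shapes[i] @ optimal_rotation(shapes[i], consensus)
            consensus = shapes.mean(axis=0)
            objs.append(((shapes - consensus) ** 2).sum())
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_degenerate_configuration_rejected(self, rng):
        arr = rng.normal(size=(3, 10, 3))
        arr[1] = np.outer(np.arange(10), [1.0, 2.0, 3.0])  # collinear
        with pytest.raises(AlignmentError, match="spec1"):
            gpa(arr)


class TestProcrustesDistance:
    def test_identity_and_symmetry(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        assert procrustes_distance(a, a) == pytest.approx(0.0, abs=1e-12)
        assert procrustes_distance(a, b) == pytest.approx(
            procrustes_distance(b, a), abs=1e-12)

    def test_matches_rotation_grid_brute_force(self, rng):
        for _ in range(3):
            a = rng.normal(size=(3, 3))  # triangles in 3D
            b = rng.normal(size=(3, 3))
            xa, _ = _center_scale(a)
            xb, _ = _center_scale(b)
            obj_grid = grid_search_rotation(xb, xa)
            d = procrustes_distance(a, b)
            assert d ** 2 <= obj_grid + 1e-12  # never worse than the grid
            assert d ** 2 == pytest.approx(obj_grid, abs=5e-5)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_triangle_inequality_small_shape_regime(self, seed):
        r = np.random.default_rng(seed)
        base = r.normal(size=(15, 3))
        a = base + 0.02 * r.normal(size=base.shape)
        b = base + 0.02 * r.normal(size=base.shape)
        c = base + 0.02 * r.normal(size=base.shape)
        dab = procrustes_distance(a, b)
        dbc = procrustes_distance(b, c)
        dac = procrustes_distance(a, c)
        assert dac <= dab + dbc + 1e-9


def reflect_relabel_average_oracle(coords, scheme):
    """Independent symmetrization: reflect about x=0, swap pair labels,
    rigid-fit back with an explicitly assembled Kabsch solution, average."""
    cen = coords.mean(axis=0)
    x = coords - cen
    y = (x * np.array([-1.0, 1.0, 1.0]))[scheme.antimere]
    h = y.T @ x
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (x + y @ r.T) / 2.0 + cen


class TestSymmetrize:
    def test_symmetric_configuration_is_fixed_point(self, scheme, template):
        out = symmetrize(700 * template, scheme)
        assert np.abs(out - 700 * template).max() < 1e-9

    def test_idempotent(self, scheme, template, rng):
        x = 700 * (template + rng.normal(scale=0.01, size=template.shape))
        once = symmetrize(x, scheme)
        twice = symmetrize(once, scheme)
        assert np.abs(twice - once).max() < 1e-9

    def test_result_has_exact_object_symmetry(self, scheme, template, rng):
        x = 700 * (template + rng.normal(scale=0.02, size=template.shape))
        out = symmetrize(x, scheme)
        c = out - out.mean(axis=0)
        refl = (c * np.array([-1.0, 1.0, 1.0]))[scheme.antimere]
        r = optimal_rotation(refl, c)
        assert np.abs(refl @ r - c).max() < 1e-9

    def test_planted_displacement_split_half_half(self, scheme, template):
        left = next(e.landmark_id for e in scheme.entries
                    if e.laterality == "left")
        right = int(scheme.antimere[left])
        v = np.array([0.001, -0.002, 0.0015])
        x = template.copy()
        x[left] += v
        out = symmetrize(x, scheme)
        moved_left = out[left] - x[left]
        moved_right = out[right] - x[right]
        assert np.linalg.norm(moved_left + v / 2) < 1e-4
        # the antimere absorbs the mirrored half of the displacement
        assert np.linalg.norm(moved_right) == pytest.approx(
            np.linalg.norm(v) / 2, rel=0.05)

    def test_matches_independent_oracle(self, scheme, template, rng):
        x = 700 * (template + rng.normal(scale=0.02, size=template.shape))
        out = symmetrize(x, scheme)
        oracle = reflect_relabel_average_oracle(x, scheme)
        assert np.abs(out - oracle).max() < 1e-9


class TestOutlierScreen:
    def test_planted_extreme_specimen_flagged(self):
        spec = SimulationSpec(
            groups=[GroupSpec("EuS", 12, sigma=0.02)],
            outliers={"EuS_3": 5.0}, seed=11)
        ds, _ = simulate(spec)
        aligned = gpa(ds)
        table = screen_outliers(aligned, "whole-sample")
        flagged = table[table.is_outlier].specimen_id.tolist()
        assert flagged == ["EuS_3"]

    def test_identical_specimens_none_flagged(self, scheme, template):
        ds = build_dataset(scheme, [300 * template] * 5)
        table = screen_outliers(gpa(ds), "whole-sample")
        assert not table.is_outlier.any()

    def test_small_scope_refused(self, scheme, template, rng):
        coords = [300 * template + rng.normal(size=template.shape)
                  for _ in range(2)]
        ds = build_dataset(scheme, coords)
        with pytest.raises(ValueError, match="fewer than 3"):
            screen_outliers(gpa(ds), "whole-sample")
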