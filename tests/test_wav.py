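"""Accessible volumes, Gaussian weighting and inter-dye distance statistics."""

import numpy as np
import pytest

from fretwav.structure_builder import AttachmentSite, PseudoAtomStructure, attachment_sites
from fretwav.wav import (
    ACCEPTOR_ALEXA647,
    DONOR_ALEXA488,
    AccessibleVolume,
    DyeGeometry,
    accessible_volume,
    build_obstacle_grid,
    calibrate_beff,
    compute_av,
    interdye_distribution,
    sigma_av,
    weight_av,
)


def _structure(positions, radii):
    n = len(radii)
    return PseudoAtomStructure(
        positions=np.asarray(positions, dtype=float),
        radii=np.asarray(radii, dtype=float),
        residue_index=np.arange(1, n + 1),
        strand=np.zeros(n, dtype=int),
        role=np.full(n, 2),
    )


def _site(position, atom_index=-1):
    return AttachmentSite(position=np.asarray(position, dtype=float), residue=1,
                         strand=0, atom_index=atom_index)


FAR_AWAY = _structure([[500.0, 500.0, 500.0]], [1.0])
SMALL_GEOM = DyeGeometry(l_link=8.0, w_link=4.5, r_dye=(2.25, 2.25, 2.25))


class TestObstacleGrid:
    def test_no_atoms_nearby_means_no_blocking(self):
        grid = build_obstacle_grid(FAR_AWAY, SMALL_GEOM, _site([0, 0, 0]), spacing=0.8)
        assert not grid.blocked.any()

    def test_single_atom_blocking_radius(self):
        s = _structure([[6.0, 0.0, 0.0]], [2.0])
        grid = build_obstacle_grid(s, SMALL_GEOM, _site([0, 0, 0]), spacing=0.5,
                                   clear_radius=0.01)
        centers = grid.cell_centers(grid.blocked)
        d = np.linalg.norm(centers - np.array([6.0, 0.0, 0.0]), axis=1)
        assert np.all(d < 2.0 + 4.5 / 2 + 1e-9)
        free_centers = grid.cell_centers(~grid.blocked)
        d_free = np.linalg.norm(free_centers - np.array([6.0, 0.0, 0.0]), axis=1)
        assert d_free.min() > 2.0 + 4.5 / 2 - 1e-9

    def test_blocked_count_monotone_in_linker_width(self):
        s = _structure([[5.0, 0.0, 0.0]], [2.0])
        counts = []
        for w in (2.0, 4.0, 6.0):
            geom = DyeGeometry(l_link=8.0, w_link=w, r_dye=(1.0, 1.0, 1.0))
            grid = build_obstacle_grid(s, geom, _site([0, 0, 0]), spacing=0.5,
                                       clear_radius=0.01)
            counts.append(int(grid.blocked.sum()))
        assert counts[0] < counts[1] < counts[2]

    def test_buried_attachment_rejected(self):
        s = _structure([[0.0, 0.0, 0.0]], [6.0])
        with pytest.raises(ValueError, match="blocked"):
            build_obstacle_grid(s, SMALL_GEOM, _site([0, 0, 0]), spacing=0.5,
                                clear_radius=0.01)


class TestComputeAV:
    def test_free_space_gives_sphere_volume(self):
        av = accessible_volume(FAR_AWAY, DONOR_ALEXA488, _site([0, 0, 0]), spacing=0.8)
        exact = 4.0 / 3.0 * np.pi * DONOR_ALEXA488.l_link**3
        assert abs(av.volume - exact) / exact < 0.05

    def test_plane_wall_halves_the_volume(self):
        # dense atom plane: blocked slab just below z = 0
        xs = np.arange(-14, 14.5, 1.0)
        pts = [[x, y, -3.25] for x in xs for y in xs]
        wall = _structure(pts, [1.0] * len(pts))
        site = _site([0.0, 0.0, 0.0])
        av_wall = compute_av(
            build_obstacle_grid(wall, SMALL_GEOM, site, spacing=0.5, clear_radius=0.01),
            SMALL_GEOM,
        )
        av_free = compute_av(
            build_obstacle_grid(FAR_AWAY, SMALL_GEOM, site, spacing=0.5, clear_radius=0.01),
            SMALL_GEOM,
        )
        assert av_wall.volume / av_free.volume == pytest.approx(0.5, abs=0.05)

    def test_points_behind_wall_need_path_not_euclidean_distance(self):
        # a wide wall 2 A above the attachment: points just behind it are
        # within Euclidean reach but the free-space path around the wall
        # exceeds the linker length
        xs = np.arange(-20, 20.5, 1.0)
        pts = [[x, y, 4.5] for x in xs for y in xs]
        wall = _structure(pts, [1.0] * len(pts))
        geom = DyeGeometry(l_link=6.0, w_link=2.0, r_dye=(0.5, 0.5, 0.5))
        av = compute_av(
            build_obstacle_grid(wall, geom, _site([0, 0, 0]), spacing=0.5,
                                clear_radius=0.01),
            geom,
        )
        assert not np.any(av.points[:, 2] > 6.0)  # nothing beyond the wall
        assert np.any(av.points[:, 2] < 0.0)  # but the open side is filled


class TestWeighting:
    @pytest.fixture()
    def small_av(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-5, 5, size=(400, 3))
        return AccessibleVolume(
            points=pts, weights=np.full(400, 1 / 400),
            attachment=np.zeros(3), spacing=1.0,
        )

    def test_weights_sum_to_one(self, small_av):
        w = weight_av(small_av, 2.0)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_flat_limit_recovers_uniform(self, small_av):
        w = weight_av(small_av, 1e6)
        np.testing.assert_allclose(w.weights, small_av.weights, atol=1e-6)

    def test_gaussian_ratio_at_one_sigma(self):
        av = AccessibleVolume(
            points=np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]),
            weights=np.array([0.5, 0.5]),
            attachment=np.zeros(3), spacing=1.0,
        )
        w = weight_av(av, 2.0)
        assert w.weights[1] / w.weights[0] == pytest.approx(np.exp(-0.5))

    def test_weighting_never_increases_spread(self, small_av):
        other = AccessibleVolume(
            points=small_av.points + np.array([30.0, 0, 0]),
            weights=small_av.weights.copy(),
            attachment=np.array([30.0, 0, 0]), spacing=1.0,
        )
        base = interdye_distribution(small_av, other).sigma
        for s in (1.0, 2.0, 5.0, 20.0):
            weighted = interdye_distribution(
                weight_av(small_av, s), weight_av(other, s)
            ).sigma
            assert weighted <= base + 1e-9


class TestSigmaAV:
    def test_closed_forms(self):
        assert sigma_av(3.0, 3.0) == pytest.approx(np.sqrt(3.0))
        assert sigma_av(3.6, 19.3) == pytest.approx(4.81, abs=0.01)

    def test_monotone_in_both_arguments(self):
        assert sigma_av(2.0, 10.0) < sigma_av(3.0, 10.0) < sigma_av(3.0, 15.0)

    def test_alternative_scaling(self):
        assert sigma_av(3.6, 19.3, mode="rigid") == pytest.approx(
            3.6 * np.sqrt(19.3 / 3.0)
        )


class TestInterdyeDistribution:
    def test_single_point_clouds(self):
        a = AccessibleVolume(np.array([[0.0, 0, 0]]), np.array([1.0]), np.zeros(3), 1.0)
        b = AccessibleVolume(np.array([[50.0, 0, 0]]), np.array([1.0]),
                             np.array([50.0, 0, 0]), 1.0)
        res = interdye_distribution(a, b)
        assert res.mean == pytest.approx(50.0)
        assert res.sigma == pytest.approx(0.0, abs=1e-9)

    def test_sampled_matches_brute_force(self, rng):
        pts_d = rng.normal(0, 3, (50, 3))
        pts_a = rng.normal(0, 3, (50, 3)) + np.array([20.0, 0, 0])
        w_d = rng.random(50)
        w_a = rng.random(50)
        av_d = AccessibleVolume(pts_d, w_d, np.zeros(3), 1.0)
        av_a = AccessibleVolume(pts_a, w_a, np.array([20.0, 0, 0]), 1.0)
        exact = interdye_distribution(av_d, av_a)  # 2500 pairs: full double sum
        assert exact.exact
        sampled = interdye_distribution(av_d, av_a, n_pairs=200_000, seed=3,
                                        exact_limit=0)
        assert not sampled.exact
        assert abs(sampled.mean - exact.mean) < 3 * sampled.se_mean
        assert sampled.sigma == pytest.approx(exact.sigma, rel=0.02)


@pytest.fixture(scope="module")
def small_system():
    # short 12-mer-like stack of base pseudo-atoms with two labels
    z = np.arange(12) * 3.4
    pts = np.stack([2.5 * np.cos(np.deg2rad(36 * np.arange(12))),
                    2.5 * np.sin(np.deg2rad(36 * np.arange(12))), z], axis=1)
    s = _structure(pts, [3.5] * 12)
    sites = attachment_sites(s, [(0, 3), (0, 10)])
    geom = DyeGeometry(l_link=10.0, w_link=4.5, r_dye=(3.0, 2.0, 1.5))
    av1 = accessible_volume(s, geom, sites[0], spacing=0.8)
    av2 = accessible_volume(s, geom, sites[1], spacing=0.8)
    return s, geom, av1, av2


class TestFrameIndependenceAndCalibration:
    def test_frame_independence(self, small_system):
        s, geom, av1, av2 = small_system
        base = interdye_distribution(av1, av2, seed=5)
        # random rigid transform
        rng = np.random.default_rng(11)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = s.transformed(q, np.array([13.0, -7.0, 29.0]))
        sites = attachment_sites(moved, [(0, 3), (0, 10)])
        av1m = accessible_volume(moved, geom, sites[0], spacing=0.8)
        av2m = accessible_volume(moved, geom, sites[1], spacing=0.8)
        res = interdye_distribution(av1m, av2m, seed=5)
        assert abs(res.mean - base.mean) < 0.8  # within one grid spacing
        assert abs(res.sigma - base.sigma) < 0.8

    def test_sigma_monotone_in_beff_and_calibration(self, small_system):
        _, geom, av1, av2 = small_system
        widths = []
        for b in (0.5, 1.5, 3.0, 6.0, 10.0):
            w1 = weight_av(av1, sigma_av(b, geom.l_link))
            w2 = weight_av(av2, sigma_av(b, geom.l_link))
            widths.append(interdye_distribution(w1, w2, seed=7).sigma)
        assert all(b - a > -1e-6 for a, b in zip(widths, widths[1:]))
        target = 0.5 * (widths[1] + widths[2])
        b = calibrate_beff(av1, av2, geom, geom, target, search_range=(0.5, 10.0),
                           seed=7)
        assert 1.5 <= b <= 3.0

    def test_unreachable_target_raises(self, small_system):
        _, geom, av1, av2 = small_system
        with pytest.raises(ValueError, match="outside attainable"):
            calibrate_beff(av1, av2, geom, geom, 0.01, search_range=(0.5, 10.0))

    def test_refinement_keeps_the_mean(self, small_system):
        s, geom, av1, av2 = small_system
        sites = attachment_sites(s, [(0, 3), (0, 10)])
        av1f = accessible_volume(s, geom, sites[0], spacing=0.4)
        av2f = accessible_volume(s, geom, sites[1], spacing=0.4)
        coarse = interdye_distribution(av1, av2, seed=5)
        fine = interdye_distribution(av1f, av2f, seed=5)
        assert abs(fine.mean - coarse.mean) / coarse.mean < 0.01
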