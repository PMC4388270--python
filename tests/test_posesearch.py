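"""Six-dimensional grid search and pose clustering."""

import numpy as np
import pytest

from deerdock import synthdata
from deerdock.posesearch import (GridSpec, Pose, PoseScore, axis_points,
                                 center_moving, cluster_poses,
                                 default_translation_bounds,
                                 exhaustive_search, orientation_grid,
                                 pose_backbone_rmsd_matrix, rotation_zyz,
                                 score_pose, translation_grid)
from deerdock.structio import rmsd_direct


def test_default_orientation_grid_counts():
    spec = GridSpec()
    pts = axis_points(spec)
    assert len(pts) == 326            # round(4 pi / 0.0385)
    rots = orientation_grid(spec)
    assert len(rots) == 326 * 36      # 10 degree gamma sweep


def test_whole_sphere_single_orientation():
    spec = GridSpec(solid_angle=4 * np.pi, gamma_step=360.0)
    assert len(orientation_grid(spec)) == 1


def test_axis_points_uniformity():
    """Nearest-neighbour great-circle spacing of the spherical lattice has
    coefficient of variation < 0.25."""
    pts = axis_points(GridSpec())
    dots = np.clip(pts @ pts.T, -1, 1)
    np.fill_diagonal(dots, -1)
    nn = np.arccos(dots.max(axis=1))
    assert nn.std() / nn.mean() < 0.25


def test_rotation_matrices_orthonormal():
    for a, b, g in orientation_grid(GridSpec(solid_angle=1.0, gamma_step=90)):
        r = rotation_zyz(a, b, g)
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)


def test_translation_grid_counts():
    spec = GridSpec(t_bounds=((0, 4), (0, 4), (0, 4)), t_step=2.0)
    assert len(translation_grid(spec)) == 27
    spec1 = GridSpec(t_bounds=((1, 1), (2, 2), (3, 3)))
    np.testing.assert_allclose(translation_grid(spec1), [[1, 2, 3]])


def test_grid_spec_validation():
    with pytest.raises(ValueError):
        GridSpec(solid_angle=20.0)
    with pytest.raises(ValueError):
        GridSpec(gamma_step=7.0)
    with pytest.raises(ValueError):
        GridSpec(t_step=-1.0)


def test_default_bounds_contain_truth(system, noiseless_restraints):
    bounds = default_translation_bounds(system.fixed_sites,
                                        noiseless_restraints)
    for (lo, hi), t in zip(bounds, system.pose.t):
        assert lo <= t <= hi


def _search_spec(centre, half=12.0):
    return GridSpec(t_step=2.0,
                    t_bounds=tuple((c - half, c + half) for c in centre),
                    solid_angle=0.3, gamma_step=30.0)


def test_exact_recovery_of_grid_commensurate_truth(system, noiseless_restraints):
    """Noiseless restraints generated at a pose on the grid: the search
    returns that pose at rank 1 with sigma = 0."""
    spec = _search_spec(system.pose.t)
    hits = exhaustive_search(system.fixed_sites, system.moving_sites_body,
                             noiseless_restraints, spec, sigma_max=3.0)
    assert hits, "no accepted poses"
    best = hits[0]
    assert best.sigma == pytest.approx(0.0, abs=1e-6)
    np.testing.assert_allclose(best.pose.t, system.pose.t, atol=1e-9)
    np.testing.assert_allclose(best.pose.rotation, system.pose.rotation,
                               atol=1e-6)
    # exhaustiveness: no other accepted pose scores better
    assert all(h.sigma >= best.sigma - 1e-12 for h in hits)


def test_inconsistent_restraints_are_infeasible(system, noiseless_restraints):
    """Perturbing the experimental distances by alternating +-10 A makes
    them geometrically unrealizable by any rigid arrangement: nothing is
    accepted at the 3 A threshold.  (A *uniform* +10 A inflation is not a
    valid infeasibility probe: sliding the moving domain radially outward
    realizes it to within ~1 A for this site geometry.)"""
    import copy
    shifted = copy.deepcopy(noiseless_restraints)
    for k, r in enumerate(shifted.interdomain):
        r.delta_exp += 10.0 if k % 2 == 0 else -10.0
    spec = _search_spec(system.pose.t)
    hits = exhaustive_search(system.fixed_sites, system.moving_sites_body,
                             shifted, spec, sigma_max=3.0)
    assert hits == []


def test_search_determinism(system, noiseless_restraints):
    spec = _search_spec(system.pose.t, half=6.0)
    a = exhaustive_search(system.fixed_sites, system.moving_sites_body,
                          noiseless_restraints, spec)
    b = exhaustive_search(system.fixed_sites, system.moving_sites_body,
                          noiseless_restraints, spec)
    assert [(p.pose, p.sigma) for p in a] == [(p.pose, p.sigma) for p in b]


def test_search_invariant_under_global_translation_of_fixed_frame(
        system, noiseless_restraints):
    """Translating the fixed body (and its label positions) shifts the
    accepted translations rigidly and leaves the sigma spectrum unchanged
    (the translation lattice is congruent under lattice shifts)."""
    shift = np.array([8.0, -4.0, 12.0])  # multiple of the 2 A step
    moved_sites = {k: v + shift for k, v in system.fixed_sites.items()}
    spec0 = _search_spec(system.pose.t, half=6.0)
    centre = np.asarray(system.pose.t) + shift
    spec1 = GridSpec(t_step=2.0,
                     t_bounds=tuple((c - 6.0, c + 6.0) for c in centre),
                     solid_angle=0.3, gamma_step=30.0)
    s0 = exhaustive_search(system.fixed_sites, system.moving_sites_body,
                           noiseless_restraints, spec0)
    s1 = exhaustive_search(moved_sites, system.moving_sites_body,
                           noiseless_restraints, spec1)
    assert len(s0) == len(s1)
    for a, b in zip(s0, s1):
        assert b.sigma == pytest.approx(a.sigma, abs=1e-9)
        np.testing.assert_allclose(np.asarray(b.pose.t) - shift, a.pose.t,
                                   atol=1e-9)


def test_score_pose_under_determination_warning(system, noiseless_restraints):
    import copy
    few = copy.deepcopy(noiseless_restraints)
    few.restraints = few.restraints[:4]
    spec = GridSpec(t_bounds=tuple((c - 2, c + 2) for c in system.pose.t),
                    solid_angle=2.0, gamma_step=120.0)
    with pytest.warns(UserWarning):
        exhaustive_search(system.fixed_sites, system.moving_sites_body, few,
                          spec)


# ---------------------------------------------------------------------------
# clustering

def _fake_scores(poses, sigmas):
    return [PoseScore(p, s, True) for p, s in zip(poses, sigmas)]


def test_identical_poses_single_cluster(system):
    backbone = system.moving_body.coords(atom_names=("N", "CA", "C", "O"))
    p = Pose(0.1, 0.2, 0.3, (1.0, 2.0, 3.0))
    clusters = cluster_poses(_fake_scores([p, p, p], [1.0, 0.5, 2.0]), backbone)
    assert len(clusters) == 1
    assert clusters[0].representative.sigma == 0.5


def test_distant_poses_two_clusters(system):
    backbone = system.moving_body.coords(atom_names=("N", "CA", "C", "O"))
    p1 = Pose(0.0, 0.0, 0.0, (0.0, 0.0, 0.0))
    p2 = Pose(0.0, 0.0, 0.0, (8.0, 0.0, 0.0))  # induced RMSD exactly 8 A
    clusters = cluster_poses(_fake_scores([p1, p2], [1.0, 2.0]), backbone,
                             rmsd_max=4.0)
    assert len(clusters) == 2


def test_cluster_oracle_all_pairs(system, rng):
    """Complete linkage guarantee checked against a brute-force all-pairs
    scan on a random accepted set."""
    backbone = system.moving_body.coords(atom_names=("N", "CA", "C", "O"))
    poses = [Pose(rng.uniform(0, 2 * np.pi), rng.uniform(0, np.pi),
                  rng.uniform(0, 2 * np.pi), tuple(rng.uniform(-6, 6, 3)))
             for _ in range(40)]
    scores = _fake_scores(poses, rng.uniform(0, 3, 40))
    clusters = cluster_poses(scores, backbone, rmsd_max=4.0)
    assert sum(c.size for c in clusters) == 40
    for c in clusters:
        for i, a in enumerate(c.members):
            for b in c.members[i + 1:]:
                r = rmsd_direct(a.pose.apply(backbone), b.pose.apply(backbone))
                assert r <= 4.0 + 1e-9
        assert c.representative.sigma == min(m.sigma for m in c.members)
    # condensed matrix matches the direct metric
    condensed = pose_backbone_rmsd_matrix([p.pose for p in scores[:8]],
                                          backbone)
    k = 0
    for i in range(8):
        for j in range(i + 1, 8):
            r = rmsd_direct(scores[i].pose.apply(backbone),
                            scores[j].pose.apply(backbone))
            assert condensed[k] == pytest.approx(r, abs=1e-8)
            k += 1


def test_empty_cluster_input():
    assert cluster_poses([], np.zeros((4, 3))) == []
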