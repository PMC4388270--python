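"""Exhaustive six-dimensional rigid-body search under sigma_DEER.

One domain ("fixed") stays put; the other ("moving") is swept over a
six-dimensional grid of relative arrangements: a 3-D translation lattice of
2 A step combined with a rotational grid of (alpha, beta) axis directions
uniformly distributed over the sphere (one orientation per 0.0385 sr by
default) times a spin angle gamma sampled every 10 degrees.  Every pose is
scored by sigma_DEER over the interdomain restraints; poses under the
acceptance threshold (3 A) are kept and clustered by the backbone RMSD they
induce on the moving domain.

Conventions
-----------
* Rotation: intrinsic ZYZ Euler angles Rz(alpha) Ry(beta) Rz(gamma);
  (alpha, beta) are the spherical coordinates of the rotated z-axis and
  gamma the spin about it.
* The moving body is expressed in a body frame centred on the centroid of
  its mean label positions (see ``center_moving``); the pose translation is
  then the global position of that centroid, which keeps the translation
  grid compact and restraint-relevant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from deerdock.restraints import RestraintSet, sigma_deer

__all__ = [
    "Pose",
    "GridSpec",
    "PoseScore",
    "PoseCluster",
    "orientation_grid",
    "translation_grid",
    "exhaustive_search",
    "cluster_poses",
    "center_moving",
    "default_translation_bounds",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def rotation_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Intrinsic ZYZ rotation matrix."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    rz_a = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry_b = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz_g = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return rz_a @ ry_b @ rz_g


@dataclass(frozen=True)
class Pose:
    """SE(3) arrangement of the moving body: x_global = R x_body + t."""

    alpha: float  # radians, [0, 2 pi)
    beta: float   # radians, [0, pi]
    gamma: float  # radians, [0, 2 pi)
    t: tuple[float, float, float]  # Angstrom

    @property
    def rotation(self) -> np.ndarray:
        return rotation_zyz(self.alpha, self.beta, self.gamma)

    @property
    def translation(self) -> np.ndarray:
        return np.asarray(self.t, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Pose":
        return cls(0.0, 0.0, 0.0, (0.0, 0.0, 0.0))


@dataclass
class GridSpec:
    """Six-dimensional search grid parameters."""

    t_step: float = 2.0                      # A
    t_bounds: tuple[tuple[float, float], ...] = ((-20.0, 20.0),) * 3
    solid_angle: float = 0.0385              # sr per (alpha, beta) orientation
    gamma_step: float = 10.0                 # degrees

    def __post_init__(self) -> None:
        if self.t_step <= 0:
            raise ValueError("t_step must be positive")
        if not (0 < self.solid_angle <= 4 * np.pi):
            raise ValueError("solid_angle must lie in (0, 4 pi]")
        if abs(360.0 / self.gamma_step - round(360.0 / self.gamma_step)) > 1e-9:
            raise ValueError("gamma_step must divide 360")


@dataclass(frozen=True)
class PoseScore:
    pose: Pose
    sigma: float  # sigma_DEER, Angstrom
    accepted: bool


@dataclass
class PoseCluster:
    members: list[PoseScore]
    representative: PoseScore  # lowest-sigma member

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# grids

def orientation_grid(spec: GridSpec) -> np.ndarray:
    """(n_rot, 3) array of (alpha, beta, gamma) triples.

    The (alpha, beta) axis directions come from a deterministic
    generalized-spiral (Fibonacci) lattice with round(4 pi / solid_angle)
    points; gamma is swept every ``gamma_step`` degrees.
    """
    n_axis = max(1, round(4.0 * np.pi / spec.solid_angle))
    i = np.arange(n_axis)
    z = 1.0 - (2.0 * i + 1.0) / n_axis
    beta = np.arccos(np.clip(z, -1.0, 1.0))
    alpha = np.mod(i * _GOLDEN_ANGLE, 2.0 * np.pi)
    gammas = np.deg2rad(np.arange(0.0, 360.0, spec.gamma_step))
    ab = np.column_stack([alpha, beta])
    out = np.empty((n_axis * len(gammas), 3))
    out[:, :2] = np.repeat(ab, len(gammas), axis=0)
    out[:, 2] = np.tile(gammas, n_axis)
    return out


def axis_points(spec: GridSpec) -> np.ndarray:
    """Unit vectors of the (alpha, beta) lattice (one per orientation)."""
    angles = orientation_grid(GridSpec(spec.t_step, spec.t_bounds,
                                       spec.solid_angle, 360.0))
    a, b = angles[:, 0], angles[:, 1]
    return np.column_stack([np.sin(b) * np.cos(a), np.sin(b) * np.sin(a),
                            np.cos(b)])


def translation_grid(spec: GridSpec) -> np.ndarray:
    """(n_t, 3) lattice of step ``t_step`` covering ``t_bounds`` inclusively."""
    axes = []
    for lo, hi in spec.t_bounds:
        if hi < lo:
            raise ValueError("degenerate translation bounds")
        n = int(np.floor((hi - lo) / spec.t_step + 1e-9)) + 1
        axes.append(lo + spec.t_step * np.arange(n))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def default_translation_bounds(fixed_label_positions: dict[int, np.ndarray],
                               restraint_set: RestraintSet,
                               tether_allowance: float = 10.0
                               ) -> tuple[tuple[float, float], ...]:
    """Cube centred on the fixed-body label centroid with half-side
    max(delta_exp) + tether allowance; guaranteed to contain the feasible
    region of the moving-label centroid."""
    centroid = np.mean(list(fixed_label_positions.values()), axis=0)
    half = float(restraint_set.deltas().max()) + tether_allowance
    return tuple((float(c - half), float(c + half)) for c in centroid)


def center_moving(moving_label_positions: dict[int, np.ndarray]
                  ) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Express moving-body label positions in the search body frame
    (centred on their centroid); returns (centred dict, centroid)."""
    centroid = np.mean(list(moving_label_positions.values()), axis=0)
    return {k: np.asarray(v) - centroid
            for k, v in moving_label_positions.items()}, centroid


# ---------------------------------------------------------------------------
# search

def _restraint_arrays(fixed_label_positions, moving_label_positions,
                      restraint_set: RestraintSet):
    f, m, d = [], [], []
    for r in restraint_set.interdomain:
        pair = {r.site_i.domain_id: r.site_i, r.site_j.domain_id: r.site_j}
        if set(pair) != {"fixed", "moving"}:
            raise ValueError("interdomain restraint must join fixed and moving bodies")
        f.append(np.asarray(fixed_label_positions[pair["fixed"].residue_number]))
        m.append(np.asarray(moving_label_positions[pair["moving"].residue_number]))
        d.append(r.delta_exp)
    return np.asarray(f), np.asarray(m), np.asarray(d)


def exhaustive_search(fixed_label_positions: dict[int, np.ndarray],
                      moving_positions_bodyframe: dict[int, np.ndarray],
                      restraint_set: RestraintSet,
                      spec: GridSpec,
                      sigma_max: float = 3.0) -> list[PoseScore]:
    """Score every grid pose by sigma_DEER; return accepted poses sorted
    ascending by sigma (ties broken by grid order, deterministic).

    Moving-body label positions must already be in the body frame
    (``center_moving``).  Scoring is vectorized over the translation grid
    for each rotation.
    """
    import warnings as _warnings

    fpos, mpos, delta = _restraint_arrays(
        fixed_label_positions, moving_positions_bodyframe, restraint_set)
    if len(delta) == 0:
        raise ValueError("no interdomain restraints to score")
    if len(delta) < 6:
        _warnings.warn("fewer than 6 interdomain restraints: pose under-determined",
                       stacklevel=2)
    angles = orientation_grid(spec)
    tgrid = translation_grid(spec)
    if len(angles) == 0 or len(tgrid) == 0:
        raise ValueError("empty search grid")
    n = float(len(delta))
    accepted: list[tuple[float, int, int]] = []  # (sigma, rot idx, t idx)
    for ri, (a, b, g) in enumerate(angles):
        rot = rotation_zyz(a, b, g)
        anchor = fpos - mpos @ rot.T          # (K, 3)
        diff = anchor[None, :, :] - tgrid[:, None, :]
        dist = np.sqrt(np.einsum("tkj,tkj->tk", diff, diff))
        sig = np.sqrt(np.mean((dist - delta) ** 2, axis=1))
        hits = np.nonzero(sig <= sigma_max)[0]
        accepted.extend((float(sig[ti]), ri, int(ti)) for ti in hits)
    accepted.sort(key=lambda x: (x[0], x[1], x[2]))
    out = []
    for sig, ri, ti in accepted:
        a, b, g = angles[ri]
        out.append(PoseScore(Pose(float(a), float(b), float(g),
                                  tuple(tgrid[ti])), sig, True))
    return out


def score_pose(fixed_label_positions, moving_positions_bodyframe,
               restraint_set: RestraintSet, pose: Pose,
               sigma_max: float = 3.0) -> PoseScore:
    """sigma_DEER of a single (possibly off-grid) pose."""
    fpos, mpos, delta = _restraint_arrays(
        fixed_label_positions, moving_positions_bodyframe, restraint_set)
    dist = np.linalg.norm(fpos - pose.apply(mpos), axis=1)
    sig = sigma_deer(delta, dist)
    return PoseScore(pose, sig, sig <= sigma_max)


# ---------------------------------------------------------------------------
# clustering

def pose_backbone_rmsd_matrix(poses: Sequence[Pose],
                              moving_backbone: np.ndarray) -> np.ndarray:
    """Condensed pairwise RMSD of the moving backbone under each pose
    (no re-superposition: the shared fixed-domain frame is meaningful)."""
    x = np.asarray(moving_backbone, dtype=float)
    n = x.shape[0]
    y = np.stack([p.apply(x).ravel() for p in poses])  # (P, 3n)
    sq = np.sum(y * y, axis=1)
    g = y @ y.T
    d2 = (sq[:, None] + sq[None, :] - 2.0 * g) / n
    np.fill_diagonal(d2, 0.0)
    d2 = np.clip(d2, 0.0, None)
    dm = np.sqrt(d2)
    iu = np.triu_indices(len(poses), k=1)
    return dm[iu]


def cluster_poses(accepted: Sequence[PoseScore], moving_backbone: np.ndarray,
                  rmsd_max: float = 4.0) -> list[PoseCluster]:
    """Complete-linkage clustering of accepted poses under the induced
    backbone RMSD metric; every intra-cluster pairwise RMSD <= rmsd_max.
    Representative = lowest-sigma member; clusters sorted by it."""
    if len(accepted) == 0:
        return []
    if len(accepted) == 1:
        return [PoseCluster(list(accepted), accepted[0])]
    condensed = pose_backbone_rmsd_matrix([p.pose for p in accepted],
                                          moving_backbone)
    z = linkage(condensed, method="complete")
    ids = fcluster(z, t=rmsd_max, criterion="distance")
    clusters: dict[int, list[PoseScore]] = {}
    for cid, ps in zip(ids, accepted):
        clusters.setdefault(int(cid), []).append(ps)
    out = []
    for members in clusters.values():
        rep = min(members, key=lambda ps: ps.sigma)
        out.append(PoseCluster(members, rep))
    out.sort(key=lambda c: c.representative.sigma)
    return out
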