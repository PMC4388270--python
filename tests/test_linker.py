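"""Linker backbone construction, the clash rule and Monte Carlo sampling."""

import numpy as np
import pytest
from scipy.stats import chisquare

from deerdock.geometry import dihedral
from deerdock.labelmodel import LabelModel
from deerdock.linker import (STANDARD_GEOMETRY, BuilderParams,
                             build_backbone_from_dihedrals, default_rama,
                             has_clash, initial_frame_from_anchor,
                             linker_label_position, measure_dihedrals,
                             sample_linker)

ANCHOR = (np.array([0.0, 0.0, 0.0]),
          np.array([1.458, 0.0, 0.0]),
          np.array([2.009, 1.420, 0.0]))


def test_zero_residues_returns_empty():
    conf = build_backbone_from_dihedrals(np.zeros((0, 3)), ANCHOR)
    assert conf.n_residues == 0


def test_extended_chain_ca_ca_spacing():
    """Fully extended trans chain: consecutive CA-CA distances ~3.80 A."""
    dih = np.tile([180.0, 180.0, 180.0], (12, 1))
    conf = build_backbone_from_dihedrals(dih, ANCHOR, anchor_psi=180.0)
    d = np.linalg.norm(np.diff(conf.ca, axis=0), axis=1)
    np.testing.assert_allclose(d, 3.80, atol=0.03)


def test_standard_internal_geometry():
    rng = np.random.default_rng(0)
    dih = np.column_stack([rng.uniform(-150, -50, 8),
                           rng.uniform(-60, 150, 8),
                           np.full(8, 180.0)])
    conf = build_backbone_from_dihedrals(dih, ANCHOR)
    g = STANDARD_GEOMETRY
    for i in range(8):
        assert np.linalg.norm(conf.ca[i] - conf.n[i]) == \
            pytest.approx(g["N-CA"], abs=0.02)
        assert np.linalg.norm(conf.c[i] - conf.ca[i]) == \
            pytest.approx(g["CA-C"], abs=0.02)
        assert np.linalg.norm(conf.o[i] - conf.c[i]) == \
            pytest.approx(g["C=O"], abs=0.02)
        if i:
            assert np.linalg.norm(conf.n[i] - conf.c[i - 1]) == \
                pytest.approx(g["C-N"], abs=0.02)


def test_carbonyl_o_in_peptide_plane():
    dih = np.tile([-120.0, 130.0, 180.0], (5, 1))
    conf = build_backbone_from_dihedrals(dih, ANCHOR)
    for i in range(4):
        # O of residue i is anti to N of residue i+1 across the C atom:
        # dihedral(N_{i+1}, CA_i, C_i, O_i) = 180 within numerical tolerance
        ang = dihedral(conf.n[i + 1], conf.ca[i], conf.c[i], conf.o[i])
        assert abs(abs(np.rad2deg(ang)) - 180.0) < 1e-3


def test_dihedral_round_trip():
    rng = np.random.default_rng(1)
    dih = np.column_stack([rng.uniform(-170, 170, 10),
                           rng.uniform(-170, 170, 10),
                           np.full(10, 180.0)])
    conf = build_backbone_from_dihedrals(dih, ANCHOR)
    meas = measure_dihedrals(conf, ANCHOR)
    wrapped = (meas - dih + 180.0) % 360.0 - 180.0
    np.testing.assert_allclose(wrapped, 0.0, atol=1e-6)


def test_initial_frame_properties():
    f = initial_frame_from_anchor(*ANCHOR)
    np.testing.assert_allclose(f.T @ f, np.eye(3), atol=1e-12)
    assert np.linalg.det(f) == pytest.approx(1.0, abs=1e-12)
    # equivariance under rigid motion
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=2).as_matrix()
    shift = np.array([4.0, 5.0, 6.0])
    f2 = initial_frame_from_anchor(*(rot @ a + shift for a in ANCHOR))
    np.testing.assert_allclose(f2, rot @ f, atol=1e-9)
    with pytest.raises(ValueError):
        initial_frame_from_anchor(np.zeros(3), np.array([1.0, 0, 0]),
                                  np.array([2.0, 0, 0]))


def test_junction_peptide_bond_standard_length():
    """Continuing from an anchor residue yields a standard C-N bond across
    the junction."""
    conf = build_backbone_from_dihedrals(np.array([[180.0, 180.0, 180.0]]),
                                         ANCHOR)
    assert np.linalg.norm(conf.n[0] - ANCHOR[2]) == \
        pytest.approx(STANDARD_GEOMETRY["C-N"], abs=1e-9)


# ---------------------------------------------------------------------------
# clash rule

def _pair(dist, sep):
    coords = np.array([[0.0, 0, 0], [dist, 0, 0]])
    return coords, np.array([10, 10 + sep])


@pytest.mark.parametrize("dist,sep,expect", [
    (2.4, 5, True),    # closer than 2.5 A, nonconsecutive -> clash
    (2.6, 5, False),   # beyond the cutoff
    (2.0, 1, False),   # consecutive residues exempt
    (2.499, 2, True),  # boundary: strictly 'closer than'
    (2.5, 2, False),
])
def test_clash_rule_boundaries(dist, sep, expect):
    coords, idx = _pair(dist, sep)
    got, pair = has_clash(coords, idx, cutoff=2.5)
    assert got is expect
    if expect:
        assert set(pair) == {10, 10 + sep}


def test_clash_against_context():
    coords = np.array([[0.0, 0, 0]])
    ctx = np.array([[2.0, 0, 0], [10.0, 0, 0]])
    got, pair = has_clash(coords, np.array([5]), 2.5, ctx, np.array([20, 21]))
    assert got and pair == (5, 20)


# ---------------------------------------------------------------------------
# Ramachandran sampling

def test_rama_tables_normalized_with_zero_forbidden_band():
    rama = default_rama()
    for cls in ("general", "gly", "pro", "prepro"):
        g = rama.probability_grid(cls)
        assert g.sum() == pytest.approx(1.0)
        assert np.all(g >= 0)
    # steric band around phi = 0 empty for non-Gly
    g = rama.probability_grid("general")
    centre_rows = np.abs(rama.centers) < 25.0
    assert g[centre_rows].sum() == 0.0


def test_rama_sampling_matches_bin_frequencies(rng):
    """10^4 draws reproduce the tabulated bin probabilities (chi-square)."""
    rama = default_rama()
    g = rama.probability_grid("general")
    n = 10_000
    counts = np.zeros_like(g)
    for _ in range(n):
        phi, psi = rama.sample(rng, "general")
        i, j = rama.bin_index(phi, psi)
        counts[i, j] += 1
    mask = g * n >= 5  # chi-square validity
    stat, p = chisquare(counts[mask], g[mask] / g[mask].sum() * counts[mask].sum())
    assert p > 0.01


# ---------------------------------------------------------------------------
# Monte Carlo sampling

@pytest.fixture(scope="module")
def linker_setup(system):
    ctx_coords, ctx_idx = system.clash_context()
    return system.anchor_atoms(), system.target_ca(), ctx_coords, ctx_idx


def test_sampling_deterministic_under_seed(linker_setup):
    anchor, target, ctx_c, ctx_i = linker_setup
    p = BuilderParams(seed=5, max_model_attempts=200)
    a = sample_linker(anchor, target, None, p, n_residues=23,
                      context_coords=ctx_c, context_res_idx=ctx_i)
    b = sample_linker(anchor, target, None, p, n_residues=23,
                      context_coords=ctx_c, context_res_idx=ctx_i)
    assert a.success and b.success
    np.testing.assert_array_equal(a.backbone_atoms(), b.backbone_atoms())


def test_successful_build_contract(linker_setup):
    anchor, target, ctx_c, ctx_i = linker_setup
    conf = sample_linker(anchor, target, None,
                         BuilderParams(seed=0, max_model_attempts=300),
                         n_residues=23, context_coords=ctx_c,
                         context_res_idx=ctx_i)
    assert conf.success
    assert conf.closure_error <= 5.0
    # corrected terminus exactly on target
    assert np.linalg.norm(conf.ca[-1] - target) < 1e-6
    # corrected chain still near-standard geometry
    for i in range(1, conf.n_residues):
        assert np.linalg.norm(conf.n[i] - conf.c[i - 1]) == \
            pytest.approx(STANDARD_GEOMETRY["C-N"], abs=0.1)
    # clash-free including the flanking domains (independent full scan)
    atoms = np.vstack([conf.backbone_atoms(), conf.cb_virtual()])
    idx = np.concatenate([np.repeat(np.arange(1, 24), 4), np.arange(1, 24)])
    clash, _ = has_clash(atoms, idx, 2.5, ctx_c, ctx_i)
    assert not clash


def test_zero_residual_correction_moves_nothing(linker_setup):
    """Target placed exactly at the endpoint of a pre-sampled chain: the
    correction displaces no atom beyond numerical noise."""
    anchor, _, ctx_c, ctx_i = linker_setup
    free = sample_linker(anchor, None, None, BuilderParams(seed=11),
                         n_residues=23, context_coords=ctx_c,
                         context_res_idx=ctx_i)
    assert free.success
    target = free.ca[-1].copy()
    again = sample_linker(anchor, target, None,
                          BuilderParams(seed=11,
                                        unrestricted_prefix_length=23),
                          n_residues=23, context_coords=ctx_c,
                          context_res_idx=ctx_i)
    assert again.success
    assert again.closure_error < 1e-9
    np.testing.assert_allclose(again.backbone_atoms(), free.backbone_atoms(),
                               atol=1e-6)


def test_failure_returns_statistics_not_exception(linker_setup):
    anchor, _, ctx_c, ctx_i = linker_setup
    unreachable = np.array([500.0, 500.0, 500.0])
    conf = sample_linker(anchor, unreachable, None,
                         BuilderParams(seed=0, max_model_attempts=3),
                         n_residues=23, context_coords=ctx_c,
                         context_res_idx=ctx_i)
    assert not conf.success
    assert conf.attempts > 0
    assert not np.isfinite(conf.closure_error)


def test_linker_label_position_frame_identity():
    """Residue with attachment frame aligned to the global axes: label at
    CA + in-frame mean offset."""
    model = LabelModel(np.array([[6.0, 1.0, 0.5]]), np.array([1.0]))
    dih = np.tile([-120.0, 130.0, 180.0], (3, 1))
    conf = build_backbone_from_dihedrals(dih, ANCHOR)
    pos = linker_label_position(conf, 2, model)
    from deerdock.geometry import virtual_cb
    n, ca, c = conf.n[1], conf.ca[1], conf.c[1]
    cb = virtual_cb(n, ca, c)
    e1 = (cb - ca) / np.linalg.norm(cb - ca)
    v = n - ca
    e2 = v - v @ e1 * e1
    e2 /= np.linalg.norm(e2)
    f = np.column_stack([e1, e2, np.cross(e1, e2)])
    np.testing.assert_allclose(pos, ca + f @ model.mean_offset(), atol=1e-9)


def test_linker_label_position_equivariant():
    from scipy.spatial.transform import Rotation
    model = LabelModel.default_mtsl()
    dih = np.tile([-70.0, -40.0, 180.0], (4, 1))
    conf = build_backbone_from_dihedrals(dih, ANCHOR)
    p0 = linker_label_position(conf, 3, model)
    rot = Rotation.random(random_state=4).as_matrix()
    shift = np.array([3.0, 1.0, -2.0])
    moved = build_backbone_from_dihedrals(
        dih, tuple(rot @ a + shift for a in ANCHOR))
    p1 = linker_label_position(moved, 3, model)
    np.testing.assert_allclose(p1, rot @ p0 + shift, atol=1e-6)


def test_anchor_filter_hook(linker_setup):
    """The mid-linker label anchoring hook: a rejecting filter yields no
    model, an accepting one returns a model that satisfied it."""
    anchor, target, ctx_c, ctx_i = linker_setup
    p = BuilderParams(seed=2, max_model_attempts=30)
    rejected = sample_linker(anchor, target, None, p, n_residues=23,
                             context_coords=ctx_c, context_res_idx=ctx_i,
                             anchor_filter=lambda conf: False)
    assert not rejected.success
    seen = []
    accepted = sample_linker(anchor, target, None,
                             BuilderParams(seed=2, max_model_attempts=200),
                             n_residues=23, context_coords=ctx_c,
                             context_res_idx=ctx_i,
                             anchor_filter=lambda conf: seen.append(1) or True)
    assert accepted.success and seen
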