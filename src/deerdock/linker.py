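"""Monte Carlo construction of interdomain linker backbones.

The linker connecting the two rigid domains is grown residue by residue
from the C-terminal residue of the fixed domain, with standard peptide
bond lengths and angles, trans peptide bonds, and backbone (phi, psi)
dihedrals drawn from residue-class-specific Ramachandran densities.
Coordinates are propagated by the classical recursive internal-coordinate
construction (Sugeta-Miyazawa style chain propagation); carbonyl O atoms
are added in the peptide plane.

The first ``unrestricted_prefix_length`` residues (up to the mid-linker
labelled cysteine) are sampled freely; the remaining residues are grown
under a Metropolis-style geometric acceptance rule: a proposed residue
placement is accepted only if it advances the chain towards the target
C-alpha (the N-terminal residue of the moving domain) by at least
``min_advance`` (default 1.325 A).  A build succeeds when the final
C-alpha lands within ``success_radius`` (5 A) of the target; the residual
closure error is then removed by a linear ramp distributed over the
backbone atoms so that the final C-alpha coincides with the target.

Models with self-clashes or clashes against either domain (heavy atoms of
nonconsecutive residues closer than 2.5 A) are rejected.  The clash scan
for the linker uses backbone atoms plus a virtual C-beta per residue; side
chains are not built.

The packaged Ramachandran densities are synthetic: coarse 10-degree-binned
Gaussian-mixture stand-ins for the PDB-derived coil statistics, per residue
class (general / Gly / Pro / pre-Pro), adequate for sampling validity but
not a redistribution of any published table.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import dist as _dist

import numpy as np

from deerdock.geometry import dihedral, place_atom, virtual_cb
from deerdock.labelmodel import LabelModel

__all__ = [
    "STANDARD_GEOMETRY",
    "RamachandranTable",
    "LinkerConformation",
    "BuilderParams",
    "build_backbone_from_dihedrals",
    "initial_frame_from_anchor",
    "has_clash",
    "sample_linker",
    "linker_label_position",
    "measure_dihedrals",
]

#: standard peptide internal geometry (lengths in A, angles in degrees)
STANDARD_GEOMETRY = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C=O": 1.231,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "N-CA-C": 111.2,
    "CA-C-O": 120.8,
}


# ---------------------------------------------------------------------------
# Ramachandran densities (synthetic Gaussian-mixture stand-ins)

def _wrapped_gauss(grid: np.ndarray, mu: float, sd: float) -> np.ndarray:
    out = np.zeros_like(grid)
    for shift in (-360.0, 0.0, 360.0):
        out += np.exp(-0.5 * ((grid - mu + shift) / sd) ** 2)
    return out


#: (weight, phi0, psi0, sd_phi, sd_psi) per basin
_BASINS = {
    "general": [(0.35, -120.0, 130.0, 25.0, 25.0),   # beta
                (0.25, -65.0, 145.0, 15.0, 20.0),    # polyproline II
                (0.35, -63.0, -43.0, 12.0, 12.0),    # alpha R
                (0.05, 55.0, 45.0, 12.0, 12.0)],     # alpha L
    "gly": [(0.25, -90.0, 150.0, 30.0, 30.0),
            (0.25, 90.0, -150.0, 30.0, 30.0),
            (0.20, -63.0, -40.0, 15.0, 15.0),
            (0.20, 63.0, 40.0, 15.0, 15.0),
            (0.10, 180.0, 180.0, 30.0, 30.0)],
    "pro": [(0.55, -63.0, 150.0, 10.0, 20.0),
            (0.45, -63.0, -35.0, 10.0, 15.0)],
    "prepro": [(0.55, -120.0, 130.0, 25.0, 25.0),
               (0.35, -65.0, 145.0, 15.0, 20.0),
               (0.10, -63.0, -43.0, 12.0, 12.0)],
    # helix-biased mixture for growing compact globules (synthetic domains);
    # not a coil distribution and not used for linker sampling
    "compact": [(0.62, -63.0, -43.0, 14.0, 14.0),
                (0.14, -120.0, 130.0, 25.0, 25.0),
                (0.12, -65.0, 145.0, 15.0, 20.0),
                (0.12, 55.0, 45.0, 14.0, 14.0)],
}


class RamachandranTable:
    """Discretized (phi, psi) probability grids, 10-degree bins per class.

    Bins with negligible density and the sterically forbidden band around
    phi = 0 (non-Gly classes) carry exactly zero probability.
    """

    BIN = 10.0  # degrees

    def __init__(self) -> None:
        edges = np.arange(-180.0, 180.0 + self.BIN, self.BIN)
        self.centers = 0.5 * (edges[:-1] + edges[1:])  # 36 values
        self.grids: dict[str, np.ndarray] = {}
        pc, sc = np.meshgrid(self.centers, self.centers, indexing="ij")
        for cls, basins in _BASINS.items():
            g = np.zeros_like(pc)
            for w, p0, s0, sp, ss in basins:
                g += w * _wrapped_gauss(pc, p0, sp) * _wrapped_gauss(sc, s0, ss)
            g[g < 1e-6 * g.max()] = 0.0
            if cls != "gly":
                g[np.abs(pc) < 25.0] = 0.0  # steric clash of side chain with O
            self.grids[cls] = g / g.sum()
        # cached cumulative distributions for fast inverse-cdf sampling
        self._cdf = {c: np.cumsum(g.ravel()) for c, g in self.grids.items()}
        self._cond_cdf = {}
        for c, g in self.grids.items():
            rows = np.where(g.sum(axis=1, keepdims=True) > 0,
                            g / np.maximum(g.sum(axis=1, keepdims=True), 1e-300),
                            (g.sum(axis=0) / g.sum())[None, :])
            self._cond_cdf[c] = np.cumsum(rows, axis=1)

    def probability_grid(self, residue_class: str = "general") -> np.ndarray:
        return self.grids[residue_class]

    def sample(self, rng: np.random.Generator,
               residue_class: str = "general") -> tuple[float, float]:
        """Draw one (phi, psi) pair in degrees: multinomial over bins, then
        uniform jitter within the chosen bin."""
        g = self.grids[residue_class]
        idx = int(np.searchsorted(self._cdf[residue_class], rng.random()))
        i, j = divmod(min(idx, g.size - 1), g.shape[1])
        phi = self.centers[i] + rng.uniform(-self.BIN / 2, self.BIN / 2)
        psi = self.centers[j] + rng.uniform(-self.BIN / 2, self.BIN / 2)
        return float(phi), float(psi)

    def bin_index(self, phi: float, psi: float) -> tuple[int, int]:
        i = int((phi + 180.0) // self.BIN)
        j = int((psi + 180.0) // self.BIN)
        return min(max(i, 0), 35), min(max(j, 0), 35)

    def sample_psi_given_phi(self, rng: np.random.Generator, phi: float,
                             residue_class: str = "general") -> float:
        """Redraw psi from the conditional distribution given the (binned)
        committed phi; used by the chain growers, whose moves reposition the
        next residue by revising the current residue's psi."""
        i, _ = self.bin_index(phi, 0.0)
        cdf = self._cond_cdf[residue_class][i]
        j = min(int(np.searchsorted(cdf, rng.random() * cdf[-1])), len(cdf) - 1)
        return float(self.centers[j] + rng.uniform(-self.BIN / 2, self.BIN / 2))


@lru_cache(maxsize=1)
def default_rama() -> RamachandranTable:
    return RamachandranTable()


# ---------------------------------------------------------------------------
# containers

@dataclass
class LinkerConformation:
    """Backbone of one linker model: per-residue N, CA, C, O arrays."""

    n: np.ndarray   # (n_res, 3)
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    phi: np.ndarray  # degrees
    psi: np.ndarray
    omega: np.ndarray
    success: bool = True
    closure_error: float = 0.0  # pre-correction final-CA-to-target, A
    attempts: int = 0

    @property
    def n_residues(self) -> int:
        return len(self.ca)

    def backbone_atoms(self) -> np.ndarray:
        """(4 n_res, 3) in chain order N, CA, C, O per residue."""
        return np.stack([self.n, self.ca, self.c, self.o], axis=1).reshape(-1, 3)

    def cb_virtual(self) -> np.ndarray:
        return np.stack([virtual_cb(n, ca, c)
                         for n, ca, c in zip(self.n, self.ca, self.c)])


@dataclass
class BuilderParams:
    min_advance: float = 1.325        # A per accepted restricted-phase move
    success_radius: float = 5.0       # A, closure acceptance
    clash_cutoff: float = 2.5         # A, heavy-atom rule
    unrestricted_prefix_length: int = 11  # residues up to the labelled Cys
    seed: int = 0
    max_attempts_per_residue: int = 100
    max_model_attempts: int = 1000
    correction: str = "ramp"          # "ramp" | "uniform"

    def __post_init__(self) -> None:
        for name in ("min_advance", "success_radius", "clash_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


_D2R = np.pi / 180.0
_RAD = {k: v * _D2R for k, v in STANDARD_GEOMETRY.items()
        if k in ("CA-C-N", "C-N-CA", "N-CA-C", "CA-C-O")}


# ---------------------------------------------------------------------------
# deterministic backbone construction

def initial_frame_from_anchor(n: np.ndarray, ca: np.ndarray,
                              c: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame of the anchor residue (columns:
    CA->C direction, in-plane normal component of CA->N, their cross
    product).  Chain propagation itself uses the anchor atoms directly,
    which guarantees standard junction geometry."""
    e1 = c - ca
    nrm = np.linalg.norm(e1)
    if nrm < 1e-9:
        raise ValueError("degenerate anchor: CA and C coincide")
    e1 = e1 / nrm
    v = n - ca
    e2 = v - np.dot(v, e1) * e1
    nrm2 = np.linalg.norm(e2)
    if nrm2 < 1e-9:
        raise ValueError("degenerate anchor: collinear N, CA, C")
    e2 = e2 / nrm2
    return np.column_stack([e1, e2, np.cross(e1, e2)])


def _extend_residue(prev_n, prev_ca, prev_c, psi_prev, phi, omega):
    """Place N, CA, C of the next residue (angles in degrees)."""
    g = STANDARD_GEOMETRY
    n = place_atom(prev_n, prev_ca, prev_c, g["C-N"],
                   np.deg2rad(g["CA-C-N"]), np.deg2rad(psi_prev))
    ca = place_atom(prev_ca, prev_c, n, g["N-CA"],
                    np.deg2rad(g["C-N-CA"]), np.deg2rad(omega))
    c = place_atom(prev_c, n, ca, g["CA-C"],
                   np.deg2rad(g["N-CA-C"]), np.deg2rad(phi))
    return n, ca, c


def _carbonyl_o(ca, c, next_n):
    """O in the peptide plane, anti to the next backbone N."""
    g = STANDARD_GEOMETRY
    return place_atom(next_n, ca, c, g["C=O"],
                      np.deg2rad(g["CA-C-O"]), np.deg2rad(180.0))


def build_backbone_from_dihedrals(dihedrals: np.ndarray,
                                  anchor: tuple[np.ndarray, np.ndarray, np.ndarray],
                                  anchor_psi: float = 180.0) -> LinkerConformation:
    """Grow a backbone from an anchor residue's (N, CA, C) atoms.

    ``dihedrals``: (n, 3) array of (phi, psi, omega) in degrees, one row per
    new residue.  ``anchor_psi`` is the psi dihedral of the anchor residue,
    which orients the first peptide unit.  Deterministic.
    """
    dih = np.atleast_2d(np.asarray(dihedrals, dtype=float))
    n_res = dih.shape[0]
    an, aca, ac = (np.asarray(x, dtype=float) for x in anchor)
    if n_res == 0:
        return LinkerConformation(*(np.zeros((0, 3)),) * 4,
                                  phi=np.zeros(0), psi=np.zeros(0),
                                  omega=np.zeros(0))
    ns, cas, cs = [], [], []
    prev = (an, aca, ac)
    psi_prev = anchor_psi
    for phi, psi, omega in dih:
        n, ca, c = _extend_residue(*prev, psi_prev, phi, omega)
        ns.append(n)
        cas.append(ca)
        cs.append(c)
        prev = (n, ca, c)
        psi_prev = psi
    # carbonyl O: anti to the next residue's N; last residue uses a virtual
    # next N placed from its own psi
    os_ = []
    for i in range(n_res):
        if i + 1 < n_res:
            nxt = ns[i + 1]
        else:
            g = STANDARD_GEOMETRY
            nxt = place_atom(ns[i], cas[i], cs[i], g["C-N"],
                             np.deg2rad(g["CA-C-N"]), np.deg2rad(dih[i, 1]))
        os_.append(_carbonyl_o(cas[i], cs[i], nxt))
    return LinkerConformation(np.asarray(ns), np.asarray(cas), np.asarray(cs),
                              np.asarray(os_), phi=dih[:, 0].copy(),
                              psi=dih[:, 1].copy(), omega=dih[:, 2].copy())


def measure_dihedrals(conf: LinkerConformation,
                      anchor: tuple[np.ndarray, np.ndarray, np.ndarray]
                      ) -> np.ndarray:
    """Recompute (phi, psi, omega) in degrees from built coordinates
    (independent of the construction path; psi of the last residue is read
    off the carbonyl O, which is anti to the virtual next N)."""
    an, aca, ac = (np.asarray(x) for x in anchor)
    out = np.empty((conf.n_residues, 3))
    for i in range(conf.n_residues):
        prev_c = ac if i == 0 else conf.c[i - 1]
        prev_ca = aca if i == 0 else conf.ca[i - 1]
        out[i, 0] = np.rad2deg(dihedral(prev_c, conf.n[i], conf.ca[i], conf.c[i]))
        if i + 1 < conf.n_residues:
            psi = np.rad2deg(dihedral(conf.n[i], conf.ca[i], conf.c[i],
                                      conf.n[i + 1]))
        else:
            psi = np.rad2deg(dihedral(conf.n[i], conf.ca[i], conf.c[i],
                                      conf.o[i])) + 180.0
            psi = (psi + 180.0) % 360.0 - 180.0
        out[i, 1] = psi
        out[i, 2] = np.rad2deg(dihedral(prev_ca, prev_c, conf.n[i], conf.ca[i]))
    return out


# ---------------------------------------------------------------------------
# clash rule

def has_clash(coords: np.ndarray, res_idx: np.ndarray,
              cutoff: float = 2.5,
              context_coords: np.ndarray | None = None,
              context_res_idx: np.ndarray | None = None
              ) -> tuple[bool, tuple[int, int] | None]:
    """Heavy-atom clash rule: two atoms of *nonconsecutive* residues closer
    than ``cutoff``.  Residue indices live on one global sequence axis, so
    junction residues of the flanking domains count as consecutive to the
    first/last linker residue.  Returns (clash?, offending residue pair).
    """
    coords = np.asarray(coords, dtype=float)
    res_idx = np.asarray(res_idx)
    n = len(coords)
    if n > 1:
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        sep = np.abs(res_idx[:, None] - res_idx[None, :])
        bad = (d < cutoff) & (sep >= 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            return True, (int(res_idx[i]), int(res_idx[j]))
    if context_coords is not None and len(context_coords):
        cc = np.asarray(context_coords, dtype=float)
        ci = np.asarray(context_res_idx)
        d = np.linalg.norm(coords[:, None, :] - cc[None, :, :], axis=2)
        sep = np.abs(res_idx[:, None] - ci[None, :])
        bad = (d < cutoff) & (sep >= 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            return True, (int(res_idx[i]), int(ci[j]))
    return False, None


def _clash_new_vs_placed(new: np.ndarray, new_idx: np.ndarray,
                         placed: np.ndarray, placed_idx: np.ndarray,
                         cutoff: float,
                         context_coords: np.ndarray | None = None,
                         context_res_idx: np.ndarray | None = None) -> bool:
    """Incremental form of the clash rule used during chain growth: only
    the newly placed atoms are tested (against each other, the atoms placed
    so far, and the context)."""
    ok, _ = has_clash(new, new_idx, cutoff)
    if ok:
        return True
    for other, oidx in ((placed, placed_idx), (context_coords, context_res_idx)):
        if other is None or len(other) == 0:
            continue
        d = np.linalg.norm(new[:, None, :] - np.asarray(other)[None, :, :], axis=2)
        sep = np.abs(new_idx[:, None] - np.asarray(oidx)[None, :])
        if np.any((d < cutoff) & (sep >= 2)):
            return True
    return False


# ---------------------------------------------------------------------------
# Monte Carlo sampling

def sample_linker(anchor: tuple[np.ndarray, np.ndarray, np.ndarray],
                  target_ca: np.ndarray | None,
                  rama: RamachandranTable | None,
                  params: BuilderParams,
                  n_residues: int = 23,
                  residue_classes: list[str] | None = None,
                  context_coords: np.ndarray | None = None,
                  context_res_idx: np.ndarray | None = None,
                  rng: np.random.Generator | None = None,
                  anchor_filter=None,
                  ) -> LinkerConformation:
    """Sample one clash-free linker conformation steered to ``target_ca``.

    With ``target_ca=None`` the whole chain is grown by the unrestricted
    Monte Carlo (no steering, no closure test, no correction) - useful for
    free-chain sampling and for constructing reachable targets.

    ``anchor_filter``, if given, is a predicate evaluated on each
    otherwise-successful conformation; models failing it are rejected and
    sampling continues.  This is the hook for DEER anchoring of the
    mid-linker label: pass a closure comparing
    ``linker_label_position(conf, ...)`` against the label's distance
    restraints at a chosen tolerance.

    The anchor is the fixed-domain C-terminal residue (N, CA, C); linker
    residues occupy global sequence indices 1..n following the anchor at 0;
    context residue indices must share this axis (moving-domain N-terminal
    residue at n+1).  Returns an unsuccessful conformation (``success
    False``) with attempt statistics if no model closes within the budget.
    """
    rama = rama or default_rama()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    steered = target_ca is not None
    target = np.asarray(target_ca, dtype=float) if steered else None
    classes = residue_classes or ["general"] * n_residues
    if len(classes) != n_residues:
        raise ValueError("residue_classes length mismatch")
    prefix = params.unrestricted_prefix_length if steered else n_residues
    if n_residues < prefix and steered:
        raise ValueError("linker shorter than the unrestricted prefix")
    total_attempts = 0
    for _model in range(params.max_model_attempts):
        # A move places the next residue.  Because the next residue's
        # position is set by the *current* residue's psi, each proposal
        # redraws that psi from its Ramachandran conditional (given the
        # committed phi) together with a fresh (phi, psi) for the new
        # residue; the joint dihedral statistics are preserved.
        dihedrals: list[list[float]] = []  # per residue [phi, psi, omega]
        anchor_psi = 180.0
        placed = np.empty((5 * n_residues, 3))   # accepted heavy atoms so far
        placed_idx = np.empty(5 * n_residues, dtype=int)
        n_placed = 0
        prev = tuple(np.asarray(x, dtype=float) for x in anchor)
        frames = [prev]
        ok = True
        backtracks = 0
        i = 0
        while i < n_residues:
            accepted = False
            for _ in range(params.max_attempts_per_residue):
                total_attempts += 1
                if i == 0:
                    psi_prev = rama.sample(rng, "general")[1]
                else:
                    psi_prev = rama.sample_psi_given_phi(
                        rng, dihedrals[i - 1][0], classes[i - 1])
                phi, psi = rama.sample(rng, classes[i])
                g = STANDARD_GEOMETRY
                n_at = place_atom(prev[0], prev[1], prev[2], g["C-N"],
                                  _RAD["CA-C-N"], psi_prev * _D2R)
                ca_at = place_atom(prev[1], prev[2], n_at, g["N-CA"],
                                   _RAD["C-N-CA"], np.pi)
                if i >= prefix:
                    # CA position is fully determined before C is placed:
                    # test the advance rule first and skip dead proposals
                    advance = _dist(prev[1], target) - _dist(ca_at, target)
                    if advance < params.min_advance:
                        continue
                c_at = place_atom(prev[2], n_at, ca_at, g["CA-C"],
                                  _RAD["N-CA-C"], phi * _D2R)
                cb = virtual_cb(n_at, ca_at, c_at)
                if i > 0:
                    # previous linker residue's carbonyl O is now determined
                    o_prev = _carbonyl_o(prev[1], prev[2], n_at)
                    new = np.stack([n_at, ca_at, c_at, cb, o_prev])
                    new_idx = np.array([i + 1] * 4 + [i])
                else:
                    new = np.stack([n_at, ca_at, c_at, cb])
                    new_idx = np.full(4, i + 1)
                if _clash_new_vs_placed(
                        new, new_idx, placed[:n_placed], placed_idx[:n_placed],
                        params.clash_cutoff, context_coords, context_res_idx):
                    continue
                accepted = True
                break
            if not accepted:
                # dead end: back off a few residues before giving up on
                # the whole model
                backtracks += 1
                if backtracks > 20 or len(dihedrals) < 3:
                    ok = False
                    break
                drop = min(3, len(dihedrals) - 1)
                for _ in range(drop):
                    dihedrals.pop()
                    frames.pop()
                    n_placed -= 5
                i -= drop
                prev = frames[-1]
                continue
            if i == 0:
                anchor_psi = psi_prev
            else:
                dihedrals[i - 1][1] = psi_prev
            dihedrals.append([phi, psi, 180.0])
            placed[n_placed:n_placed + len(new)] = new
            placed_idx[n_placed:n_placed + len(new)] = new_idx
            n_placed += len(new)
            prev = (n_at, ca_at, c_at)
            frames.append(prev)
            i += 1
        if not ok:
            continue
        conf = build_backbone_from_dihedrals(np.asarray(dihedrals), anchor,
                                             anchor_psi=anchor_psi)
        closure = (float(np.linalg.norm(conf.ca[-1] - target))
                   if steered else 0.0)
        if steered and closure > params.success_radius:
            continue
        # last residue's carbonyl O only known now: final clash scan
        clash, _pair = has_clash(
            np.concatenate([placed[:n_placed], conf.o[-1].reshape(1, 3)]),
            np.concatenate([placed_idx[:n_placed], [n_residues]]),
            params.clash_cutoff, context_coords, context_res_idx)
        if clash:
            continue
        conf.closure_error = closure
        conf.attempts = total_attempts
        if steered:
            _apply_closure_correction(conf, target, mode=params.correction)
            # the correction moves atoms by up to the closure residual, so
            # the clash rule must be re-verified on the corrected model
            atoms = np.vstack([conf.backbone_atoms(), conf.cb_virtual()])
            aidx = np.concatenate([
                np.repeat(np.arange(1, n_residues + 1), 4),
                np.arange(1, n_residues + 1)])
            clash, _pair = has_clash(atoms, aidx, params.clash_cutoff,
                                     context_coords, context_res_idx)
            if clash:
                continue
        if anchor_filter is not None and not anchor_filter(conf):
            continue
        return conf
    return LinkerConformation(*(np.zeros((0, 3)),) * 4, phi=np.zeros(0),
                              psi=np.zeros(0), omega=np.zeros(0),
                              success=False, closure_error=np.inf,
                              attempts=total_attempts)


def _apply_closure_correction(conf: LinkerConformation, target: np.ndarray,
                              mode: str = "ramp") -> None:
    """Remove the residual closure error.

    ``ramp``: atom k (chain order) is shifted by (k / k_final_CA) * residual
    so the junction stays immobile and the final CA lands exactly on the
    target; per-atom shift increments are residual / (4 n) and therefore
    perturb bonds far less than 0.1 A for residuals within the 5 A success
    radius.  ``uniform``: every atom shifted by the full residual (the final
    CA lands on target but the junction moves too).
    """
    atoms = conf.backbone_atoms()  # view-order N, CA, C, O per residue
    n_atoms = len(atoms)
    residual = target - conf.ca[-1]
    if mode == "ramp":
        # bonded-order ramp coordinate: N -> 3j, CA -> 3j+1, C -> 3j+2 for
        # residue j, with O riding on its C so no bond spans two ramp steps;
        # normalized so the final CA moves exactly onto the target
        j = np.repeat(np.arange(conf.n_residues), 4)
        off = np.tile([0.0, 1.0, 2.0, 2.0], conf.n_residues)
        coord = 3.0 * j + off + 1.0
        w = coord / (3.0 * (conf.n_residues - 1) + 1.0 + 1.0)
    elif mode == "uniform":
        w = np.ones(n_atoms)
    else:
        raise ValueError(f"unknown correction mode {mode!r}")
    shifted = atoms + w[:, None] * residual
    shaped = shifted.reshape(conf.n_residues, 4, 3)
    conf.n, conf.ca, conf.c, conf.o = (shaped[:, 0], shaped[:, 1],
                                       shaped[:, 2], shaped[:, 3])


def linker_label_position(conf: LinkerConformation, label_residue: int,
                          model: LabelModel) -> np.ndarray:
    """Mean N-O midpoint of a label on linker residue ``label_residue``
    (1-based along the linker), using the *unrestricted* (clash-unfiltered)
    mean offset of the label model."""
    i = label_residue - 1
    n, ca, c = conf.n[i], conf.ca[i], conf.c[i]
    cb = virtual_cb(n, ca, c)
    e1 = (cb - ca) / np.linalg.norm(cb - ca)
    v = n - ca
    e2 = v - np.dot(v, e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    f = np.column_stack([e1, e2, np.cross(e1, e2)])
    return ca + f @ model.mean_offset()
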