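"""Ground-truth synthetic two-domain systems with simulated DEER and SAXS
observations.

Every stage of the pipeline is verifiable by parameter recovery on systems
generated here: two compact toy domains (self-avoiding backbones built with
the same internal-coordinate machinery as the linker), a known SE(3) pose
joining them, surface-exposed label sites with true mean nitroxide
positions, Gaussian observation noise on DEER mean distances, and a Debye
SAXS curve with multiplicative Gaussian noise.

The restraint design mirrors the experimental labelling strategy: several
sites on the fixed domain measured against a shared anchor site on the
moving domain, plus extra moving-domain sites pairing with a subset of the
fixed sites, for 13 interdomain restraints, and a mid-linker label with one
restraint to each domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from deerdock import linker as linkermod
from deerdock.geometry import virtual_cb
from deerdock.labelmodel import LabelModel, LabelSite, mean_label_position
from deerdock.linker import BuilderParams, LinkerConformation, default_rama, sample_linker
from deerdock.posesearch import Pose
from deerdock.restraints import DEER_WINDOW, RestraintSet, load_restraint_table
from deerdock.saxs import ScatteringCurve, debye_intensity
from deerdock.structio import AtomRecord, DomainStructure

__all__ = [
    "SyntheticSystem",
    "make_toy_domain",
    "make_two_domain_system",
    "simulate_deer_means",
    "simulate_saxs",
    "table3_fixture",
    "build_true_linker",
]

#: Table 3 style pairing pattern: (fixed site index, moving site index).
#: Moving index 0 is the shared anchor (all five fixed sites pair with it).
DESIGN_PAIRS = [(0, 0), (1, 0), (2, 0), (3, 0), (4, 0),
                (3, 2), (4, 2),
                (1, 1),
                (1, 3), (3, 3), (4, 3),
                (1, 4), (4, 4)]


# ---------------------------------------------------------------------------
# toy domains

def make_toy_domain(n_residues: int, seed: int, label: str = "toy",
                    chain_id: str = "A") -> DomainStructure:
    """Compact self-avoiding backbone (N, CA, C, O, CB per residue).

    Residues are grown with Ramachandran-sampled dihedrals and rejected if
    any heavy atom leaves a confinement sphere sized for collapsed-globule
    scaling (Rg ~ 1.9 n^0.36 A) or clashes (< 2.5 A, nonconsecutive).
    Deterministic per seed; centred on the CA centroid.
    """
    if n_residues < 20:
        raise ValueError("toy domains need at least 20 residues")
    rng = np.random.default_rng(seed)
    rama = default_rama()
    radius = 1.85 * 1.9 * n_residues ** 0.36
    # both chain termini stay in an outer shell so that they are
    # surface-exposed (they anchor the interdomain linker downstream)
    shell = 0.55 * radius
    start = np.array([0.82 * radius, 0.0, 0.0])
    for _restart in range(400):
        anchor_n = start + np.array([0.0, 0.0, 0.0])
        anchor_ca = start + np.array([1.458, 0.0, 0.0])
        ang = np.deg2rad(linkermod.STANDARD_GEOMETRY["N-CA-C"])
        anchor_c = anchor_ca + 1.525 * np.array([np.cos(np.pi - ang),
                                                 np.sin(np.pi - ang), 0.0])
        # proposals redraw the previous residue's psi conditionally (it is
        # what positions the new residue) plus a fresh (phi, psi) pair
        dihedrals: list[list[float]] = []
        anchor_psi = 180.0
        frames = [(anchor_n, anchor_ca, anchor_c)]
        placed = np.empty((3 + 5 * n_residues, 3))
        placed[:3] = [anchor_n, anchor_ca, anchor_c]
        placed_idx = np.empty(3 + 5 * n_residues, dtype=int)
        placed_idx[:3] = 0
        n_placed = 3
        backtracks = 0
        i = 1
        failed = False
        while i < n_residues:
            good = False
            for _ in range(150):
                if i == 1:
                    psi_prev = rama.sample(rng, "compact")[1]
                else:
                    psi_prev = rama.sample_psi_given_phi(
                        rng, dihedrals[i - 2][0], "compact")
                phi, psi = rama.sample(rng, "compact")
                n_at, ca_at, c_at = linkermod._extend_residue(
                    *frames[-1], psi_prev, phi, 180.0)
                if np.linalg.norm(ca_at) > radius:
                    continue
                if i >= n_residues - 3:
                    # the C-terminal tail protrudes radially so that the
                    # interdomain linker can escape the fold
                    rmin = shell + 0.1 * radius * (i - (n_residues - 4))
                    if np.linalg.norm(ca_at) < rmin:
                        continue
                cb = virtual_cb(n_at, ca_at, c_at)
                # carbonyl O of the previous residue is now determined
                o_prev = linkermod._carbonyl_o(frames[-1][1], frames[-1][2], n_at)
                new = np.stack([n_at, ca_at, c_at, cb, o_prev])
                new_idx = np.array([i, i, i, i, i - 1])
                if linkermod._clash_new_vs_placed(
                        new, new_idx, placed[:n_placed],
                        placed_idx[:n_placed], 2.5):
                    continue
                good = True
                break
            if not good:
                # back off a few residues and retry from there
                backtracks += 1
                if backtracks > 80 or len(dihedrals) < 3:
                    failed = True
                    break
                drop = min(3, len(dihedrals))
                for _ in range(drop):
                    dihedrals.pop()
                    frames.pop()
                    n_placed -= 5
                i -= drop
                continue
            if i == 1:
                anchor_psi = psi_prev
            else:
                dihedrals[i - 2][1] = psi_prev
            dihedrals.append([phi, psi, 180.0])
            placed[n_placed:n_placed + 5] = new
            placed_idx[n_placed:n_placed + 5] = new_idx
            n_placed += 5
            frames.append((n_at, ca_at, c_at))
            i += 1
        if not failed:
            # final residue's carbonyl O is only known now: full clash scan
            conf = linkermod.build_backbone_from_dihedrals(
                np.asarray(dihedrals), (anchor_n, anchor_ca, anchor_c),
                anchor_psi=anchor_psi)
            all_coords = np.concatenate([placed[:n_placed],
                                         conf.o[-1].reshape(1, 3)])
            all_idx = np.concatenate([placed_idx[:n_placed], [n_residues - 1]])
            clash, _ = linkermod.has_clash(all_coords, all_idx, 2.5)
            if not clash:
                break
    else:
        raise RuntimeError("could not build a self-avoiding toy domain")
    # assemble residue 1 (anchor) + residues 2..n
    ns = np.vstack([anchor_n, conf.n])
    cas = np.vstack([anchor_ca, conf.ca])
    cs = np.vstack([anchor_c, conf.c])
    o1 = linkermod._carbonyl_o(anchor_ca, anchor_c, conf.n[0])
    os_ = np.vstack([o1, conf.o])
    centroid = cas.mean(axis=0)
    atoms = []
    for i in range(n_residues):
        cb = virtual_cb(ns[i], cas[i], cs[i])
        for name, el, xyz in (("N", "N", ns[i]), ("CA", "C", cas[i]),
                              ("C", "C", cs[i]), ("O", "O", os_[i]),
                              ("CB", "C", cb)):
            atoms.append(AtomRecord(name, el, np.asarray(xyz) - centroid,
                                    i + 1, "ALA", chain_id))
    return DomainStructure(atoms, label=label)


def _surface_sites(structure: DomainStructure, n_sites: int,
                   min_separation: int = 5) -> list[int]:
    """Residues with CA farthest from the centroid, spaced along the
    sequence; interior residues of the termini are avoided so label frames
    stay well defined."""
    cas = {num: structure.residue_atom(num, "CA").coord
           for _, num in structure.residue_keys}
    centroid = np.mean(list(cas.values()), axis=0)
    ranked = sorted(cas, key=lambda k: -np.linalg.norm(cas[k] - centroid))
    for sep in range(min_separation, 1, -1):  # relax spacing if greedy fails
        chosen: list[int] = []
        for resnum in ranked:
            if len(chosen) == n_sites:
                break
            if resnum in (1, structure.n_residues):
                continue
            if all(abs(resnum - c) >= sep for c in chosen):
                chosen.append(resnum)
        if len(chosen) == n_sites:
            return sorted(chosen)
    raise RuntimeError("could not place the requested number of label sites")


# ---------------------------------------------------------------------------
# system assembly

@dataclass
class SyntheticSystem:
    """Ground-truth two-domain system in the search convention: the moving
    domain (and its label positions) are in a body frame centred on the
    moving-label centroid; ``pose`` transports body-frame points to the
    global (fixed-domain) frame."""

    fixed: DomainStructure
    moving_body: DomainStructure
    pose: Pose
    fixed_sites: dict[int, np.ndarray]        # residue -> global mean label pos
    moving_sites_body: dict[int, np.ndarray]  # residue -> body-frame label pos
    design_pairs: list[tuple[int, int]]       # (fixed residue, moving residue)
    linker_length: int
    seed: int
    label_model: LabelModel
    true_linker: LinkerConformation | None = None

    @property
    def moving_placed(self) -> DomainStructure:
        from deerdock.structio import Transform
        return self.moving_body.transformed(
            Transform(self.pose.rotation, self.pose.translation))

    def true_distances(self) -> np.ndarray:
        out = []
        for fres, mres in self.design_pairs:
            pf = self.fixed_sites[fres]
            pm = self.pose.apply(self.moving_sites_body[mres])
            out.append(np.linalg.norm(pf - pm))
        return np.asarray(out)

    def anchor_atoms(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """N, CA, C of the fixed domain's C-terminal residue (linker anchor)."""
        last = self.fixed.n_residues
        return tuple(self.fixed.residue_atom(last, nm).coord
                     for nm in ("N", "CA", "C"))

    def target_ca(self) -> np.ndarray:
        """CA of the moving domain's N-terminal residue, global frame."""
        return self.pose.apply(self.moving_body.residue_atom(1, "CA").coord)

    def clash_context(self, pose: Pose | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Heavy atoms of both placed domains on the linker's global
        sequence axis: fixed C-terminal residue = 0, linker residues 1..L.
        The last linker residue *is* the moving domain's N-terminal residue
        (its CA is the steering target), so moving residue r maps to index
        L + r - 1."""
        return linker_context(self.fixed, self.moving_body,
                              pose or self.pose, self.linker_length)


def linker_context(fixed: DomainStructure, moving_body: DomainStructure,
                   pose: Pose, linker_length: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Clash context for linker building: heavy atoms of the fixed domain
    and the pose-placed moving domain with global sequence indices on the
    linker axis (fixed C-term = 0; moving residue r -> linker_length + r - 1,
    because the final linker residue coincides with moving residue 1)."""
    from deerdock.structio import Transform

    nf = fixed.n_residues
    # the anchor residue's carbonyl O is re-determined by the first linker
    # residue, so the stale O of the free C-terminus is dropped
    fatoms = [a for a in fixed.atoms
              if not (a.residue_number == nf and a.name == "O")]
    fixed_coords = np.array([a.coord for a in fatoms])
    fixed_idx = np.array([a.residue_number - nf for a in fatoms])
    placed = moving_body.transformed(Transform(pose.rotation, pose.translation))
    mov_coords = np.array([a.coord for a in placed.atoms])
    mov_idx = np.array([a.residue_number + linker_length - 1
                        for a in placed.atoms])
    return (np.vstack([fixed_coords, mov_coords]),
            np.concatenate([fixed_idx, mov_idx]))


def make_two_domain_system(pose: Pose, n_sites_per_domain: int = 5,
                           seed: int = 0, n_residues: int = 60,
                           linker_length: int = 23) -> SyntheticSystem:
    """Assemble a ground-truth system at the given pose.

    Raises if the pose makes the domains clash (< 2.5 A between heavy atoms)
    and warns if any true inter-label distance leaves the DEER window.
    """
    import warnings

    model = LabelModel.default_mtsl()
    fixed = make_toy_domain(n_residues, seed, label="fixed", chain_id="A")
    moving = make_toy_domain(n_residues, seed + 1, label="moving", chain_id="B")
    fixed_res = _surface_sites(fixed, n_sites_per_domain)
    moving_res = _surface_sites(moving, n_sites_per_domain)
    fixed_sites = {r: mean_label_position(fixed, LabelSite(r, "fixed"), model)
                   for r in fixed_res}
    moving_sites = {r: mean_label_position(moving, LabelSite(r, "moving"), model)
                    for r in moving_res}
    # re-centre the moving body on its label centroid (search convention)
    centroid = np.mean(list(moving_sites.values()), axis=0)
    moved_atoms = [AtomRecord(a.name, a.element, a.coord - centroid,
                              a.residue_number, a.residue_name, a.chain_id)
                   for a in moving.atoms]
    moving_body = DomainStructure(moved_atoms, label="moving")
    moving_sites_body = {r: p - centroid for r, p in moving_sites.items()}

    pairs = [(fixed_res[i], moving_res[j]) for i, j in DESIGN_PAIRS
             if i < len(fixed_res) and j < len(moving_res)]
    system = SyntheticSystem(fixed, moving_body, pose, fixed_sites,
                             moving_sites_body, pairs, linker_length, seed, model)
    # pose validity
    fixed_coords = np.array([a.coord for a in fixed.atoms])
    mov_coords = np.array([a.coord for a in system.moving_placed.atoms])
    dmin = np.min(np.linalg.norm(
        fixed_coords[:, None, :] - mov_coords[None, :, :], axis=2))
    if dmin < 2.5:
        raise ValueError(f"clashing pose: minimum interdomain distance {dmin:.2f} A")
    d = system.true_distances()
    if np.any(d < DEER_WINDOW[0]) or np.any(d > DEER_WINDOW[1]):
        warnings.warn("some true inter-label distances fall outside the "
                      "measurable DEER window", stacklevel=2)
    return system


# ---------------------------------------------------------------------------
# simulated observations

def simulate_deer_means(system: SyntheticSystem, noise_sd: float = 0.5,
                        seed: int = 0, path: str | Path | None = None
                        ) -> RestraintSet:
    """Noisy interdomain restraint table: delta_exp = true distance +
    N(0, noise_sd^2), truncated to the measurable window (flagged)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    truths = system.true_distances()
    noisy = truths + rng.normal(0.0, noise_sd, size=len(truths)) \
        if noise_sd > 0 else truths.copy()
    rows = []
    for (fres, mres), delta in zip(system.design_pairs, noisy):
        rows.append((fres, "fixed", mres, "moving", delta, ".", "interdomain"))
    if system.true_linker is not None:
        label_pos = linkermod.linker_label_position(
            system.true_linker, (system.linker_length + 1) // 2,
            system.label_model)
        fres = system.design_pairs[2][0]
        mres = system.design_pairs[0][1]
        d1 = float(np.linalg.norm(system.fixed_sites[fres] - label_pos))
        d2 = float(np.linalg.norm(
            system.pose.apply(system.moving_sites_body[mres]) - label_pos))
        if noise_sd > 0:
            d1 += float(rng.normal(0.0, noise_sd))
            d2 += float(rng.normal(0.0, noise_sd))
        mid = 1000 + (system.linker_length + 1) // 2  # linker numbering offset
        rows.append((fres, "fixed", mid, "linker", d1, ".", "linker"))
        rows.append((mid, "linker", mres, "moving", d2, ".", "linker"))
    lines = ["site_i_res\tsite_i_body\tsite_j_res\tsite_j_body\tmean_A\tpeaks_A\tcategory"]
    for r in rows:
        lines.append(f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3]}\t{r[4]:.12f}\t{r[5]}\t{r[6]}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
        return load_restraint_table(path)
    import io
    return load_restraint_table(io.StringIO(text))


def build_true_linker(system: SyntheticSystem,
                      params: BuilderParams | None = None
                      ) -> LinkerConformation:
    """Sample the ground-truth linker conformation joining the two domains
    at the true pose; stored on the system for linker-restraint and SAXS
    simulation."""
    params = params or BuilderParams(seed=system.seed + 17)
    ctx_coords, ctx_idx = system.clash_context()
    conf = sample_linker(system.anchor_atoms(), system.target_ca(),
                         None, params, n_residues=system.linker_length,
                         context_coords=ctx_coords, context_res_idx=ctx_idx)
    if not conf.success:
        raise RuntimeError("could not build a ground-truth linker for this pose")
    system.true_linker = conf
    return conf


def composite_scatterers(system: SyntheticSystem,
                         conf: LinkerConformation | None = None) -> list:
    """Model pieces entering the Debye calculation: fixed domain, placed
    moving domain, and linker backbone coordinates."""
    parts: list = [system.fixed, system.moving_placed]
    conf = conf if conf is not None else system.true_linker
    if conf is not None and conf.success:
        parts.append(conf.ca)  # one dummy scatterer per linker residue
    return parts


def simulate_saxs(system: SyntheticSystem, q_grid: np.ndarray | None = None,
                  relative_noise: float = 0.05, seed: int = 0
                  ) -> ScatteringCurve:
    """Debye curve of the true composite model with multiplicative Gaussian
    noise; the sigma column matches the generating noise level."""
    q = np.asarray(q_grid) if q_grid is not None \
        else np.linspace(0.01, 0.30, 120)
    truth = debye_intensity(composite_scatterers(system), q)
    rng = np.random.default_rng(seed)
    sigma = np.maximum(relative_noise * truth.i, 1e-12)
    noisy = truth.i + rng.normal(0.0, 1.0, size=len(q)) * sigma \
        if relative_noise > 0 else truth.i.copy()
    return ScatteringCurve(q, noisy, sigma)


def table3_fixture() -> Path:
    """Path of the packaged experimental restraint transcription
    (13 interdomain + 2 linker + intradomain calibration rows)."""
    return Path(__file__).parent / "data" / "table3.tsv"
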