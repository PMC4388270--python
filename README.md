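# deerdock

Hybrid structure determination of two-domain proteins from DEER distance
restraints and SAXS curves.

When a multidomain protein resists crystallization as a whole but its
individual domains are known at high resolution, the relative domain
arrangement can still be determined in solution: DEER (double
electron-electron resonance) spectroscopy on pairs of nitroxide spin
labels yields mean inter-label distances in the 10-80 Å range, and
small-angle X-ray scattering yields the overall size and shape.
`deerdock` implements the complete pipeline for the two-domain case,
developed around the membrane-proximal FnIII-3,4 tandem of the integrin
β4 subunit (two fibronectin type III domains joined by a 23-residue
linker) and equally applicable to any pair of rigid bodies.

The method, in brief:

1. **Label model** — each spin-labelled site is reduced to the mean
   N-O midpoint of a discrete MTSL conformer set, clash-filtered against
   the host domain.
2. **Rigid-body search** — one domain is fixed; the other is swept over
   an exhaustive six-dimensional grid (2 Å translation lattice x
   uniform-sphere rotational grid, one orientation per 0.0385 sr, spin
   angle every 10°).  Each pose is scored by

       σ_DEER = sqrt( (1/N) Σ_i (δ_i,EXP − δ_i,MODEL)² )

   over the N interdomain restraints; poses with σ_DEER ≤ 3 Å are kept
   and clustered at 4 Å backbone RMSD.
3. **Linker construction** — clash-free linker backbones are grown by
   Monte Carlo from Ramachandran-distributed dihedrals with standard
   peptide geometry, steered onto the moving domain's N-terminal Cα
   (accept a residue only if it advances ≥ 1.325 Å; success within 5 Å;
   residual closed by a small ramp correction).
4. **Joint selection** — composite models are scored by σ_DEER over all
   restraints (now including the two involving the mid-linker label) and
   by χ_SAXS of their Debye scattering curve against the experimental
   curve (q ≤ 0.3 Å⁻¹); models with σ_DEER ≤ 3 Å and χ_SAXS ≤ 1.5 are
   selected.

A synthetic-data module generates ground-truth two-domain systems with
simulated DEER and SAXS observations, so every stage is verifiable by
parameter recovery without downloading anything.  The experimentally
measured FnIII-3,4 restraint table (13 interdomain + 2 linker mean
distances, with multimodal entries reduced to their peak average) ships
with the package.

## Layout

```
src/deerdock/        library: structio, labelmodel, restraints,
                     posesearch, linker, saxs, selection, synthdata
analysis/01-05_*.py  numbered analysis drivers (simulate, search, link,
                     SAXS analytics, select); outputs under results/
scripts/acceptance.py  recomputes the headline desk-scale quantity
tests/               pytest suite incl. end-to-end acceptance checks
docs/methods.md      model, parameters, numerical choices, limitations
```

## Worked example

Run the numbered analyses from the repository root:

```
python analysis/01_simulate.py
python analysis/02_search_poses.py
python analysis/04_saxs_analysis.py
python analysis/05_select_models.py
```

`01_simulate.py` builds the packaged ground-truth system (two 40-residue
globular domains at a known pose, 13 interdomain + 2 linker restraints
with 0.5 Å Gaussian noise, a Debye SAXS curve with 5% multiplicative
noise) and prints:

```
system: 2 x 40 residues, 13 interdomain restraints (19.1-55.1 A), 2 linker restraints
DEER noise sd 0.5 A; SAXS relative noise 0.05
```

`02_search_poses.py` sweeps the reduced six-dimensional grid and reports
exact recovery of the generating pose:

```
accepted 487 of 1107288 grid poses (sigma <= 3.0 A)
best pose: sigma = 0.48 A, translation error vs truth = 0.00 A
127 clusters at 4 A backbone RMSD; sizes [7, 4, 4, 4, 4, 3, 4, 4]
```

The best pose's σ_DEER of ~0.5 Å reflects the 0.5 Å observation noise —
with noiseless restraints it is exactly zero — and the zero translation
error means the true arrangement was identified on the grid.

`04_saxs_analysis.py` runs the standard 1-D analytics on the simulated
curve:

```
Guinier: Rg = 20.35 A (true composite model: 20.36 A)
P(r):    Rg = 19.67 A, D_max = 46.6 A
Kratky:  max 1.53 at qRg = 2.98 (compact globule reference: 1.10 at 1.73)
```

The Guinier Rg matches the true composite model's Rg to 0.1%; the
Kratky transform rises above the compact-globule reference because the
two-domain particle is elongated (and the coarse per-residue scatterer
model flattens the high-q tail).  Finally `05_select_models.py` runs the
full pipeline end to end:

```
487 grid poses accepted, 5 clusters, 18 composite candidates, 5 selected (sigma_DEER <= 3 A and chi_SAXS <= 1.5)
best pose translation error vs truth: 0.00 A
```

The selected models all share the true relative arrangement and differ
only in their linker conformations, with χ_SAXS near 1 (the level
expected when the only model-data discrepancy is the generating noise).

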