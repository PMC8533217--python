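# scdtraj

Trajectory statistics for the substrate-binding tunnel of stearoyl-CoA
desaturase-1 (SCD1), the ER membrane enzyme that inserts a cis double bond at
the Δ9 position of stearoyl-CoA.

SCD1's binding tunnel is kinked, and the kink is attributed to hydrogen
bonding among three residues that line it — Gln147, Trp153, and Thr261.  For
desaturation at the C9–C10 bond, the substrate's C8-C9-C10-C11 torsion χ must
adopt a negative gauche ("actionable") conformation near −60°.  `scdtraj`
implements the trajectory analyses that connect these two observations:

- **Paired-distance free-energy landscapes.**  The per-frame distances
  d(Gln147 Oε1 – Trp153 Hε1) and d(Gln147 Hε22 – Thr261 Oγ1) are binned on a
  0.1 Å grid and Boltzmann-inverted,

  ΔG_i = −kT ln(ρ_i / ρ_max),

  with ρ_i the population of bin i and ρ_max that of the most populated bin;
  empty bins carry a 10 kT sentinel.  Utilities report the ΔG minimum, the
  percent of observations per integer-kT level, and secondary basins
  (subpopulations behind a free-energy barrier, found by a minimax-path
  search on the bin grid).
- **Dihedral conformer statistics.**  The distribution ρ(χ) of the
  C8-C9-C10-C11 torsion, its free-energy profile ϕ = −0.6 ln ρ(χ) (kcal/mol,
  0.6 ≈ RT at 300 K), gauche−/gauche+/trans classification, and the fraction
  of actionable dihedrals (within ±5° of −60°) conditioned on whether both
  hydrogen-bond distances are simultaneously ≤ 2.5 Å.
- **Pocket volumetrics.**  Grid-occupancy volume of a 6 Å sphere centered on
  the ligand's 5th tail carbon: grid points free of any occluding atom
  (within vdW + 1.4 Å probe) times the cell volume.
- **Synthetic two-state trajectories.**  A Markov-chain generator (kinked ⇄
  open) with state-dependent Gaussian distances and von Mises torsion
  mixtures, embedded into real coordinates, so the whole pipeline is testable
  against known ground truth.  Presets emulate the Substrate, Product,
  Apoprotein, CoA, and ligand-in-water systems.

Standard formats are supported throughout: multi-model PDB and DCD in/out,
CSV reports, YAML run configs.

## Worked example

Generate three synthetic substrate-like replicates and analyze them:

```bash
scdtraj generate substrate --n-frames 5000 --seed 1 --outdir rep1
scdtraj generate substrate --n-frames 5000 --seed 2 --outdir rep2
scdtraj generate substrate --n-frames 5000 --seed 3 --outdir rep3
scdtraj analyze config.yaml     # see tests/test_cli.py for the config layout
scdtraj report out
```

prints

```
Landscape minimum: Gln147-Trp153 = 2.05 A, Gln147-Thr261 = 2.15 A (5.68% of observations)
kT-level populations (percent of observations):
  level 1 kT: 60.4%
  level 2 kT: 20.1%
  level 3 kT: 11.5%
  ...
Basins (center x, center y, dG kT, % obs, barrier kT):
  (2.05, 2.15)  dG=0.00  5.68%  barrier=0.00
  (4.15, 5.55)  dG=2.19  0.63%  barrier=7.81
Actionable (within tolerance of -60 deg): 18.1% when hydrogen-bonded (n=13159), 6.6% otherwise (n=1841)
```

Reading the output: the pooled landscape minimum sits in the bin at
Gln147-Trp153 ≈ 2.0 Å / Gln147-Thr261 ≈ 2.2 Å — the kinked, hydrogen-bonded
geometry — holding 5.7% of all observations, with a secondary open-state
basin near 4.1/5.6 Å behind a high barrier.  The actionable-dihedral
fraction is several-fold higher in frames where both hydrogen bonds are
formed than where they are not, the correlation the substrate preset encodes
(state-wise actionable probabilities 0.18 vs 0.035).  All numbers come from
synthetic trajectories with known ground truth, so they can be checked
against the generator's parameters.

The same `analyze` command runs unchanged on real MD output (PDB topology +
DCD frames per replicate).

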