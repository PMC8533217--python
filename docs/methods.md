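# Methods

## Observables

All coordinates are Cartesian angstroms; atoms are addressed by residue
number + PDB v3 atom name (Oε1 → `OE1`, Hε1 → `HE1`, Hε22 → `HE22`,
Oγ1 → `OG1`).  Two hydrogen-bond distances define the tunnel-kink state:

- d1 = d(Gln147 `OE1`, Trp153 `HE1`)
- d2 = d(Gln147 `HE22`, Thr261 `OG1`)

and the substrate torsion χ is the proper dihedral over the ligand's
C8-C9-C10-C11 carbons, IUPAC sign convention (cis = 0°, positive clockwise
sighting down the central bond), reported on (−180°, +180°] with −180°
mapped to +180°.  No minimum-image correction is applied: both distance
pairs and the torsion are intramolecular, so inputs are assumed whole.
Distances are measured to the hydrogens the definitions name, so topologies
must carry those hydrogens explicitly.

## Free-energy landscapes from populations

Frame-aligned (d1, d2) pairs are binned on a square grid (default width
0.1 Å) whose edges sit at exact multiples of the width, anchored at zero.
Absolute edges make pooling trivial: replicate histograms align by edge, and
pooling by concatenation equals bin-wise addition (the "combined" landscape
is pooled counts with a pooled ρ_max; per-replicate normalization is also
available).  Binning is half-open, [edge, edge + w); a value within 1e-6 of
an edge is snapped onto it, so that a printed boundary value like 2.10 lands
in the bin labeled 2.1 despite binary rounding.

Free energy per bin is ΔG_i = −ln(ρ_i/ρ_max) in kT.  The argmax bin has
ΔG = 0 exactly; empty bins carry a sentinel (default 10 kT) that is excluded
from all statistics and only sets the plot ceiling.  Level populations
report the percent of *observations* (not bins) in each integer band,
level n ≡ (n−1, n] kT with ΔG = 0 included in level 1; bands extend past the
default 10 when populated bins require it, so percentages always total 100.
Reported coordinates are emitted both as bin centers (in-memory results) and
bin starts (CSV label columns), since a coordinate like "2.0 Å" is
convention-dependent.

Ties for the most-populated bin break toward the smallest (x, then y)
center and are logged.

### Basins

Secondary subpopulations are located as populated bins that are local ΔG
minima over their 8-neighborhood and whose minimax-path barrier to the
global minimum (Dijkstra-style search over the grid, empty bins at the
sentinel) is at least 1 kT.  Bins holding < 0.02% of observations are not
counted as basins: with tens of thousands of frames an isolated
single-count outlier bin would otherwise qualify.  Both thresholds are
parameters.

## Dihedral distribution, PMF, conformer classes

ρ(χ) uses 5° bins tiling (−180, 180] (width configurable; it must divide
360).  Bins are half-open on the left, (edge, edge + w], so +180° — the
representative of the trans boundary — lands in the last bin.  The profile
is ϕ = −0.6 ln ρ(χ) in kcal/mol (0.6 ≈ RT near 300 K), reported unshifted;
empty bins are NaN (undefined), never zero.

Conformer classes partition the circle: gauche− for |χ+60°| ≤ 30°, gauche+
for |χ−60°| ≤ 30°, trans for |χ| ≥ 150°, other elsewhere.  "Actionable"
flags |χ+60°| ≤ tol, with tol = 5° for the conditional statistic and 10° for
the looser descriptive use; both are parameters.

## Hydrogen-bond conditioning

A frame is "hydrogen-bonded" when both d1 ≤ c and d2 ≤ c simultaneously,
boundary inclusive, with c = 2.5 Å by default.  The cutoff is an
interpretation: 2.5 Å is the standard geometric criterion for
hydrogen–acceptor distances and brackets the observed kinked-minimum
distances (2.0–2.3 Å); it is exposed as config rather than hard-coded,
because the source description of the threshold is internally inconsistent.
Conditioning on both pairs (rather than either) reflects that the kink
involves all three residues.  Conditional actionable fractions report
numerators and denominators, and an empty conditioning class yields an
undefined marker, not zero.

## Pocket volume

A cubic grid (default 1.0 Å; 0.5 Å in validation) is anchored at the
per-frame position of the center atom (the ligand's 5th tail carbon) and
clipped to a 6 Å sphere.  A point is occluded if it lies within
vdW + probe (1.4 Å) of any occluding atom; occluders default to all
amino-acid atoms (ligand/water excluded), configurable.  vdW radii are the
Bondi set (H 1.20, C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, Fe 1.40 Å);
unknown elements fall back to 1.70 Å with a logged warning.  Anchoring the
grid to the center atom makes the measurement translation invariant; the
test surface is the analytic sphere (and sphere-minus-sphere) volume, not
parity with any particular volumetrics program.

## Synthetic two-state generator

The generator emulates the joint statistics of (d1, d2, χ) with a hidden
two-state Markov chain (kinked/open), per-frame transition matrix, initial
state drawn from the stationary distribution (no burn-in parameter).
Emissions given the state are independent: Gaussians for d1 and d2
(clipped below at 0.1 Å, which is > 9σ from every preset mean) and a
von Mises mixture over the −60° and 180° modes for χ (κ = 30 gauche,
κ = 10 trans).  Mixture weights are solved analytically so the per-state
probability of |χ+60°| ≤ 5° equals the preset target — 0.18 (kinked) / 0.035
(open) for the substrate preset, mirroring the reported contrast.

Coordinates are a geometric embedding, not physics: each distance pair lies
along a fixed axis in a spatial block 50 Å from the others, and the torsion
quad is built by natural-extension (NeRF) internal-coordinate placement
(C–C 1.53 Å, angles 111°).  Measuring d1, d2, χ back from the coordinates
reproduces the sampled values to ~1e-6 (1e-3/1e-4 after a PDB/DCD round
trip, the formats' storage precision).

Preset anchors: basin means follow the published landscape coordinates
(substrate kinked (2.0, 2.2) Å; product minimum (2.0, 2.3) Å with secondary
(4.1, 5.6) Å; apoprotein (1.9, 2.2) / (2.0, 4.3) Å; CoA (2.0, 2.3) /
(1.9, 4.9) Å).  Kinked spreads are σ = 0.15 Å; open spreads 0.15–0.2 Å and
transition rates (λ = 0.2 second eigenvalue; kinked occupancies 0.9 / 0.4 /
0.45 / 0.4) were fixed by a design-time power analysis so that a pooled
5 × 10,000-frame run resolves both basins' modal bins reliably — the real
trajectories' kinetics are unknown, so rates are chosen for test power, not
realism.  The waterbox preset is trans-dominated with no distance
emissions.  What passing tests show, therefore, is that the estimators
recover known generative structure of this toy; they say nothing about
force-field accuracy, membrane effects, or sampling convergence of real MD.

Two statistical details matter when validating against ground truth:

- The empirical occupancy of a Markov chain is autocorrelated; its standard
  error is the binomial one inflated by sqrt((1+λ)/(1−λ)).  The model
  exposes this corrected SE.
- The hydrogen-bond indicator is not the hidden state: each state leaks
  tail mass across the 2.5 Å cutoff (e.g. the kinked d2 Gaussian at
  2.2 ± 0.15 Å leaves ~2% past 2.5 Å).  The model therefore exposes the
  exact conditional truths P(actionable | bonded) and P(actionable | not)
  via Bayes over the stationary weights, and validation compares the
  estimator to those, not to the state-wise targets.

## Crystal-fragment stand-in

`synthetic_data.crystal_fragment_standin` builds, by direct coordinate
construction, a minimal fragment with the published active-site geometry:
two iron ions 6.8 Å apart and a C8–C11 stearoyl fragment at a −111.1°
torsion.  It is a synthetic object for exercising the PDB-I/O + measurement
path, clearly labeled as such; the same code paths run unchanged on the real
crystal-structure file when one is supplied.

## Problem sizes and numerical choices

Validation runs use 5 replicates × 10,000 frames per preset (50,000 pooled
frames), the package's chosen test scale; estimator exactness checks
(ΔG = 0 at the argmax, sentinel in empty bins, ln 2 at a half-max bin, PMF
round trip exp(−ϕ/0.6) = ρ) are asserted to 1e-12, geometric round trips
(place-chain → dihedral) to 1e-6°, and grid volumes to 5% of the analytic
values at 0.5 Å spacing.  Dihedral sign and magnitude are cross-checked
against MDAnalysis' torsion routine as an independent oracle, and the
landscape/level statistics against a per-observation enumeration in exact
rational arithmetic.

## Known limitations

- The generator's conditional independence of d1, d2, χ given the state is
  a simplification; real trajectories correlate the observables within a
  state.
- Landscape basin finding operates on raw binned counts; no smoothing or
  reweighting (WHAM/MBAR) is provided, matching the population-inversion
  definition, so sparse regions are noisy and the min-percent filter is a
  blunt instrument.
- The pocket module measures a sphere region only — no tunnel-axis tracing,
  surface meshing, or ligand-shaped carving — and hydrogen-bond detection is
  distance-only (no angle criterion), by design.
- PDB altloc handling keeps the first-occurring conformer and logs the
  dropped count; occupancies are not compared.
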