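# Methods

## The question and the quantities

A retro-D peptide reverses its parent's sequence and inverts every
residue's Cα configuration. Whether it *mimics* the parent is asked
here in three independent languages:

1. **Geometry.** For conformer ensembles A (parent) and B (retro-D), the
   cross-RMSD matrix has entries `M[i, j] = rmsd(A_i, B_j)` computed over
   an explicit atom correspondence in which parent residue `i` maps to
   retro residue `N+1-i`. The matrix is non-symmetric (different
   ensembles on the two axes); its minimum and histogram summarize how
   close the two molecules can come to the same 3D arrangement.
2. **Sampled subspaces.** After re-ordering B's coordinates by the same
   correspondence, each ensemble's positional covariance is
   diagonalized; RMSIP over the leading k modes and the
   eigenvalue-weighted covariance overlap quantify whether the two
   ensembles fluctuate along the same collective directions.
3. **Observables.** NMR chemical-shift deviations aligned by amino-acid
   type compare local conformational preferences residue by residue;
   ELISA titrations with per-dilution exact tests compare humoral
   responses; serum-stability fits contrast protease-sensitive decay
   with D-peptide flatness.

## Atom correspondence

Within a residue pair, Cα always maps to Cα and side-chain heavy atoms
map by identical PDB atom name (side chains are chemically identical
between a residue and its type-aligned partner). The default policy is
`ca-sidechain`. The `all-heavy-swap` policy additionally maps backbone
N(i) ↔ C′(N+1−i) and C′(i) ↔ N(N+1−i): reversing the chain direction
swaps the roles of the two backbone neighbors of Cα. The carbonyl O and
amide H are never mapped — the amide direction reverses in a retro
peptide, so these atoms have no analog under the correspondence. Which
atom set the original trajectory analyses used is generally not
recoverable from published figures, so the policy is an explicit option,
not a guess presented as fact.

## Superposition

Weighted Kabsch superposition restricted to proper rotations
(det R = +1). This restriction is load-bearing: an L-peptide ensemble
and a D-peptide ensemble are related by reflection in the coarse
backbone sense, and an unconstrained orthogonal fit would silently
absorb exactly the chirality difference the analysis is about. A
mirrored comparison exists as a separately named diagnostic
(`mirror_cross_rmsd_matrix`) and is never used in any verdict.
Single-pair fits compute the RMSD from the explicit residual (accurate
near zero); the all-against-all matrix path uses the batched
singular-value form, accurate to ~1e-7 Å at zero, which is far below
any decision threshold. Collinear or coincident point sets leave the
optimal rotation non-unique; the result is flagged, not silently
returned.

## Essential dynamics

Frames are iteratively superposed onto the running mean until the mean
moves < 1e-6 Å RMS (max 100 iterations, non-convergence flagged).
Using the converged mean rather than an arbitrary reference frame
removes reference bias from the covariance. RMSIP defaults to k = 10
modes; k is reported alongside the eigenvalue spectrum so sensitivity to
the cutoff is visible. The covariance overlap is computed with the
cancellation-free identity
`Σ_ij (v_i·v_j)² (√λ_i − √λ_j)²` for the numerator whenever both mode
sets are complete orthonormal bases (always true for modes produced
here), which keeps `overlap(A, A) = 1` to machine precision.

## Cluster counting

The published practice of visually counting clusters in a 2D RMSD plot
is replaced by a deterministic rule: single-linkage components of the
mass-weighted self-RMSD matrix at a cutoff (default 2.0 Å, exposed as an
option). Cluster ids are ordered by first frame, making labels
reproducible.

## Exact Mann-Whitney tests

Each dilution point of an ELISA titration is tested on its own at
α = 0.05 with **no multiplicity correction** — this mirrors the
per-dilution testing convention of the assay literature and is stated
prominently because it inflates the family-wise rate by design. The
test is exact: the null is the set of all C(m+n, m) labelings of the
pooled readings, enumerated in full (bounded to m+n ≤ 25; no asymptotic
fallback); ties are handled with mid-ranks, conditioning on the observed
tie pattern. Two-sided p-values take the probability of a U at least as
far from m·n/2 as observed. With 4 animals per group the smallest
attainable two-sided p is 2/70 ≈ 0.0286 — reported with every
comparison so borderline calls at α = 0.05 are interpretable. The
"initial consecutive significance run" starts at the lowest dilution
factor (highest serum concentration) and stops at the first
non-significant point.

## Stability fits

L-peptide time courses are fitted with
`y = plateau + span·exp(−k·t)` (scipy least squares, k ≥ 0, half-life
ln 2 / k); D-peptide curves with the zero-slope model `y = mean(y)`.
A decay fit whose rate collapses onto the k = 0 boundary (k·Δt < 1e-3
over the observation window) is flagged as better served by the
constant model. Both fits report residual sums of squares so the nested
models can be contrasted directly.

## NMR stage

CSD = δ_obs − δ_RC per residue and nucleus (HA, CA, CB, HN). The
random-coil reference table ships as an editable TSV populated from the
standard peptide random-coil compilations (provenance in the file
header); D-residues use their L-counterparts' values, since enantiomers
are spectroscopically identical in an achiral solvent. No neighbor or
temperature corrections are applied by default (a replacement table is
the correction hook). Amide temperature coefficients are OLS slopes of
shift vs temperature in ppb/K; the −4.6 ppb/K shielding flag threshold
is a literature convention, not a result of this package, and is
configurable. Cis/trans populations are intensity shares; the 1D-amide
and proline-Cδ-HSQC "methods" differ only in where the integrals come
from, so they agree identically on identical integrals.

## Synthetic data: what it emulates and what it cannot show

Real inputs to this kind of study are cluster-scale replica-exchange MD
simulations and animal sera. The generators replace them with
structurally plausible stand-ins whose ground truth is exact:

- **Coarse peptide model.** Backbone N, Cα, C′ at canonical internal
  coordinates (ω fixed trans) plus one side-chain centroid ("CB") per
  non-glycine residue, placed so the N-Cα-C′-CB improper dihedral is
  negative for L and positive for D residues (matching the real L
  convention). Virtual flanking atoms realize φ₁ and ψ_N, so torsions
  round-trip exactly.
- **Toy replica exchange.** Metropolis sampling in (φ, ψ) space under a
  soft-min mixture of basins (α-helical, polyproline-II, extended; mirrored
  for D residues; both halves for glycine) plus a Cα soft-sphere clash
  term. Geometric 300–500 K ladder, 8 replicas, swap attempts every 50
  steps with `min(1, exp[(β_i−β_j)(E_i−E_j)])`; analytic acceptance
  probabilities are accumulated alongside the empirical counts so the
  bookkeeping is checkable against its own trajectory. The energy scale
  is arbitrary: this sampler supplies realistically heterogeneous
  multi-basin ensembles, not physics.
- **Mimic pairs.** `mimic` mode retro-constructs each parent frame
  geometrically — the same point set read in the reversed chain
  direction is a genuine retro-D conformer, superposable by construction
  — plus isotropic Gaussian noise (default σ = 0.5 Å, a deliberately
  imperfect mimic). `independent` mode samples the retro-D molecule from
  its own mirrored basin preferences with a fresh seed. Frames are drawn
  directly from per-residue basin mixtures whose weights are drawn once
  per ensemble (Dirichlet α = 0.5), so different seeds genuinely occupy
  different regions; the full replica-exchange sampler is kept separate
  for the physics checks. Pair generation uses 60-frame ensembles in the
  tests and the acceptance script — large enough for stable covariance
  spectra over 14 mapped atoms, small enough for quick runs.
- **Shift tables and plates.** Shifts = random coil + imposed CSD +
  noise, with HN series linear in temperature; titrations follow
  `OD(d) = background + A/(1 + (d/EC50)^hill)` on a two-fold grid from
  1:100 with log-normal per-animal amplitudes (σ = 0.2) and 0.02 OD read
  noise, four animals per group — the shape of a small mouse study.

Passing tests on these generators demonstrates that the *analysis*
recovers known ground truth and separates mimicry from its absence
under realistic heterogeneity. It does not validate any force field,
solvent model, NMR assignment, or immunological mechanism, and says
nothing about how a particular real peptide behaves — those questions
require the real experiments.

## Numerical and design choices

- Histogram bins are right-open `[k·w, (k+1)·w)` from zero, default
  width 0.25 Å; counts always sum to the matrix size.
- Best cross-RMSD pairings break ties by lowest (frame_A, frame_B);
  ranked pairings are available since a single displayed pairing is a
  choice, not a unique object.
- Cross-RMSD weighting defaults to uniform; self-RMSD defaults to
  mass-weighted (the convention for trajectory 2D-RMSD plots).
- Frame selection keeps the final 2/3 of a run as equilibrated by
  default and thins to n equally spaced frames with indices
  `round(i·(M−1)/(n−1))`, first and last tail frames always included.
- Titration grids must be two-fold from the start dilution (default
  1:100; other start dilutions are a parameter, e.g. 1:500 for serum
  protocols that begin there).
- All generators are bit-reproducible given a seed; the CLI persists
  every resolved configuration and input hash in its run directory.

## Known limitations

- Side chains are single centroids in the synthetic ensembles; all-atom
  name matching is exercised against residue-template inventories, not
  simulated all-atom coordinates.
- The exact-test enumeration is bounded at m+n ≤ 25 pooled readings and
  offers no asymptotic fallback by design.
- Non-canonical residues, β-amino acids and cyclic peptides are out of
  scope; the sequence layer accepts only the 20 canonical amino acids.
- The CSD stage applies no sequence-neighbor corrections; for real data
  with strong neighbor effects, supply a corrected reference table.
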