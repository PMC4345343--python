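# Methods

## The model

A conformational ensemble of a homodimeric receptor domain is represented
by the Cα coordinates of its helix residues (internal units are nm
everywhere; conversion from the PDB's ångströms happens only at file
I/O). For the Tar periplasmic domain the default selection covers the
four helices of each monomer — residues 44–75, 89–113, 118–144 and
146–175 (α1…α4), 228 sites for a complete A/B dimer — on the view that
loop regions fluctuate too much to carry the collective-mode signal;
selection ranges are fully configurable per chain.

Three mode descriptions are combined:

1. **Essential dynamics.** Frames are superposed by alternating
   Kabsch fits to the running average until the mean structure converges
   (tolerance 1e-6 nm, ≤100 iterations; the returned mean is the exact
   arithmetic mean of the final fitted frames, so projections of the
   fitted ensemble have exactly zero mean per mode). The population
   covariance `C = (1/M) Σ (x−x̄)(x−x̄)ᵀ` (unit masses — all sites are
   Cα, so mass weighting is a global scalar that leaves eigenvectors
   unchanged; divisor 1/M by convention, eigenvectors unaffected) is
   diagonalized; eigenvalues descend, and each eigenvector's sign is
   fixed by making its largest-magnitude component positive. Projections
   `pe_k = (x_fitted − x̄)·v_k` are reported in nm.
2. **Anisotropic network model.** Sites closer than `R_c = 1.5 nm` in
   the input structure are joined by springs of uniform stiffness
   `γ = 100 kcal·mol⁻¹·nm⁻²` (both configurable). The Hessian block for
   a connected pair is `H_ij = −γ r̂ᵢⱼ r̂ᵢⱼᵀ`, diagonal blocks close each
   block row to zero. Eigenvalues below `1e-8 × λ_max` (a relative
   threshold, so the split is invariant under rescaling γ) are removed
   as rigid-body modes; more than six removable modes on a non-collinear
   structure means floating fragments and is an error. Collinear inputs
   legitimately carry more null directions, so the check is suppressed
   when supplied coordinates are collinear.
3. **Piston vector.** Given apo and holo structures with identical site
   labels, the holo structure is superposed on the non-α4 "static core"
   (when the α4 mask covers under half the sites; configurable to
   all-site fitting), the displacement is masked to the α4 sites of both
   monomers and normalized. Core fitting is chosen because an all-site
   fit absorbs part of the α4 motion itself into the superposition; the
   both-monomer mask reflects that both α4 helices slide. The PV sign is
   oriented so the mean masked z-displacement is negative ("downward"
   slide ⇒ negative pe₂ by convention); the raw apo→holo orientation can
   be kept instead.

Mode similarity is the absolute normalized dot product; signed
projections are kept where sign is meaningful (the PV spectrum). Rows of
an overlap matrix against a complete orthonormal basis satisfy Parseval
(sum of squares 1), which the tests assert to 1e-8.

## Structural metrics and clustering

Pairwise RMSD fits every frame pair independently (Kabsch, proper
rotations only; rank-deficient configurations produce a valid but
flagged non-unique minimizer). DRMS is the RMS difference of all
N(N−1)/2 intramolecular site distances — mean over pairs, then square
root — and needs no superposition, making it exactly rigid-invariant;
conformational families are extracted from the DRMS matrix by
gromos-style leader clustering at a 0.2 nm cutoff with lowest-index
tie-breaking (deterministic partitions).

The 2D (pe₁, pe₂) landscape is clustered by density peaks: local density
ρ (Gaussian kernel by default — smoother on continuous landscapes; the
cutoff kernel is kept for oracle tests) and δ, the distance to the
nearest point of higher density, with density ties broken by point index
and the global maximum assigned δ = max pairwise distance. The kernel
scale dc defaults to the distance quantile at which the mean neighbor
count is 2% of M. Centers are chosen either as the top-k points by
γ = ρ·δ or by explicit (ρ_min, δ_min) thresholds read off the emitted
decision-graph TSV; remaining points inherit the label of their nearest
higher-density neighbor in decreasing density order. Halo demotion is
off by default so occupancy probabilities sum to 1 over all frames.

## The synthetic generator

`synthetic_data` builds an idealized C2-symmetric dimer: two chains of
four straight ideal helices (rise 0.15 nm/residue, radius 0.23 nm, twist
100°/residue — consecutive Cα spacing 0.383 nm), antiparallel on the
corners of a 1 nm square, chain centers 0.9 nm from the dimer axis,
chain B the exact 180° image of chain A. Residue numbering follows the
Tar ranges so the selection machinery is exercised end to end. Two
fields are planted: the anti-symmetric rotation (chain A displaced by an
infinitesimal +θ rotation about the dimer axis, chain B by −θ) and the
α4 axial slide (−z on α4 sites of both chains). Frames are
`template + a₁v₁ + a₂v₂ + ε` with amplitudes drawn from a (possibly
multi-basin) correlated Gaussian — defaults: variances 0.04/0.01 nm²,
correlation 0.6, one basin at the origin — isotropic site noise
σ = 0.01 nm, and a uniform random rigid pose per frame (on by default so
superposition code paths are always exercised). Everything is
reproducible from a single seed.

Two deliberate modeling choices:

- **Linearized fields.** The rotation field is the infinitesimal
  generator, not a finite rotation: PCA is a linear decomposition and
  the planted truth must live in its model class.
- **Rigid-orthogonal planting.** Superposition removes rigid-body
  motion, so any rigid component of a planted field is unrecoverable by
  construction; the planted mode vectors are therefore projected onto
  the orthogonal complement of the six rigid-body generators before
  orthonormalization (the raw fields are retained in
  `GroundTruth.raw_fields`). This matters quantitatively: the raw α4
  slide has overlap `sqrt(N_α4/N) ≈ 0.51` with a pure z-translation, so
  no mode of a superposed ensemble can overlap the PV by more than the
  PV's non-rigid fraction (≈0.86 for the Tar ranges). This ceiling — not
  imperfect recovery — is why observed PV↔mode-2 projections sit well
  below 1, and the piston tests assert recovery relative to it.

With amplitude correlation 0.6 the PCA eigenvectors are *mixtures* of
the planted modes (the eigenbasis diagonalizes the amplitude
covariance, whose eigenvalues — 0.0442 and 0.0058 nm² at the defaults —
are what eigenvalue recovery is checked against), and projections onto
the recovered eigenvectors are uncorrelated by construction; correlation
recovery is therefore measured by projecting onto the planted basis.

The generator emulates the statistical structure of a fluctuating dimer
only: no force field, solvent, thermostat, or realistic loop geometry,
and site noise is isotropic and uncorrelated, unlike real anisotropic,
sequence-dependent fluctuations. Passing tests demonstrate that the
pipeline's estimators recover known ground truth through superposition,
projection and clustering — not that any particular receptor moves this
way.

The `weak_alpha4_spec` template variant widens the bundle to 1.2 nm and
pushes α4 a further 0.8 nm radially outward, leaving α4 far fewer
within-cutoff contacts than the core (while the network stays connected
with exactly six zero modes). Its softest ANM mode is then an α4 axial
slide (overlap ≈0.94 with the planted field) — the coarse-grained
analogue of a loosely packed signaling helix whose cheapest motion is
the piston. The geometry was fixed by scanning spacing/offset during
fixture design, before the assertions were frozen.

The two-basin landscape fixture places basins at (0.15, 0.75) and
(1.53, −1.83) nm in (pe₁, pe₂) with weights 0.7/0.3 and isotropic
within-basin spread 0.15 nm — small against the ≈3 nm basin separation,
so the planted partition is unambiguous; these centers are generator
inputs chosen to make the fixture visually comparable to published
chemoreceptor landscapes, not reproduction claims.

## Problem sizes and numerical tolerances

The test suite and the acceptance script use M = 5000 frames for mode
recovery (subspace overlap > 0.98 asserted, ≈0.999 observed; eigenvalues
within 10%, ≈1% observed; amplitude correlation within ±0.05), M = 3000
for basin-weight recovery (±0.03 asserted, ≈0.006 observed), 500 points
for the brute-force density oracle, and 20-site random structures for
the finite-difference Hessian oracle (central differences, step 1e-4 nm,
agreement < 1e-4 asserted, ≈5e-5 observed). Exact identities (DRMS
rigid invariance, chain-swap involution and projection anti-symmetry,
Parseval) are asserted at 1e-8…1e-12. The chain-swap projection test
uses noise-free frames because site noise is not chain-symmetric. The
end-to-end CLI run is checked for byte-identical artifacts across
reruns; artifacts carry config/input hashes but deliberately no
timestamps.

## Known limitations

- DRMS uses all site pairs (no cutoff); for very large N the M×P
  distance matrix dominates memory.
- Pairwise RMSD matrices are O(M²) Kabsch fits; the CLI subsamples
  frames (default 150) for the DRMS/RMSD matrix stage.
- Density-peak clustering is O(M²) in memory and time; intended for
  landscape-sized point sets (≤ a few 10⁴).
- The pocket analysis measures Cα geometry only; side-chain rotamer
  effects (e.g. aromatic gating of the pocket) are out of scope.
- Structure mapping between different receptors requires identical
  label sets; no sequence alignment is performed.
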