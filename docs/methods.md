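# Methods

This note documents the model implemented by `flexcmp`, the conventions
and defaults it commits to, and what its synthetic test world does and
does not establish.

## Elastic network and normal modes

The protein is reduced to one bead per residue at the Cα position, with
coordinates in nm (converted once, at the PDB boundary) and the average
residue mass (amino acid minus water, Da) as the bead mass; unknown
residues get the table mean. Beads interact through the pair potential
`U_ij = k(r⁰ij)(rij − r⁰ij)²` with the distance-dependent force constant

- `k(r) = a·r − b` for `r < d` — the stiff pseudo-bond regime of
  sequence neighbours, which cluster just below 0.4 nm;
- `k(r) = c·r⁻⁶` for `r ≥ d` — a smooth decay that localises the
  network without a hard cutoff (an optional numerical cutoff exists
  for large systems and is off by default);
- `a = 8.6×10⁵ kJ mol⁻¹ nm⁻³`, `b = 2.39×10⁵ kJ mol⁻¹ nm⁻²`,
  `c = 128 kJ mol⁻¹ nm⁴`, `d = 0.4 nm`. These constants were fitted
  once against an all-atom model and are treated as transferable; the
  CLI deliberately does not re-fit them per protein.

`k(r)` crosses zero at `r = b/a ≈ 0.278 nm`: a closer Cα pair would
make the input a saddle rather than a minimum of the energy, so
validation rejects any pair strictly below 0.278 nm (2.78 Å), naming
the first offending pair. A pair at exactly 0.278 nm passes.

The Hessian at the reference configuration has off-diagonal 3×3 blocks
`−2k(r⁰)û ûᵀ` and diagonal blocks that accumulate the opposite sign, so
row-block sums vanish (translation invariance) and the matrix is
positive semidefinite. Modes are computed by a full dense symmetric
eigendecomposition of `M^(−1/2) H M^(−1/2)` — exact and affordable at
the sizes this package targets; no reduced-basis approximation is used.
Trivial modes are detected as eigenvalues below `1e-9 × λ_max` rather
than assumed to be six: a connected three-dimensional network has
exactly six, but degenerate geometries have more (a collinear chain
leaves every transverse displacement free at harmonic order — 5 zero
modes for a dimer, 7 for a 3-bead chain), and a count above six
triggers a warning, escalated to an error when the spring graph is
actually disconnected. Single-structure analyses keep the 200
lowest-frequency non-trivial modes by default.

Eigenvalue units (kJ mol⁻¹ nm⁻² Da⁻¹) are internal bookkeeping; only
relative quantities are reported and no conversion to physical
frequencies is attempted.

## Single-structure analyses

**Fluctuations.** `f_i ∝ Σ_m (1/λ_m) ‖d_m,i‖²` over retained modes,
with `d_m = M^(−1/2)X_m` the Cartesian displacement pattern. Profiles
are normalised to sum 1 (a `max_to_one` option exists for visual
comparison); the constant is a convention, so only relative shapes are
meaningful.

**Deformation energies.** Each pair's second-order energy
`k(r⁰ij)(ûij·(d_m,i − d_m,j))²` is split half/half between its
partners, weighted by 1/λ_m and summed over modes, then normalised to
sum 1. Note a consequence of this definition: per unit-normalised mode
the pair energies total λ_m/2, which the 1/λ weight cancels — every
mode contributes the same total (the harmonic-ensemble equipartition),
and an average over *all* modes is therefore nearly flat. Hinge
detection should look at the soft modes: on a two-domain dumbbell the
linker carries 2.5–5× the mean deformation energy of the domains over
the 10 lowest modes, and that is how the tests exercise the hinge
signature.

**Correlations.** `C_ij` is the 1/λ-weighted inner product of residue
displacement vectors normalised by the per-residue amplitudes — the
expected inner product of displacements, in [−1, 1] with unit diagonal,
identical to normalising the 3N×3N covariance `Σ (1/λ) d dᵀ` by its
block diagonal. The PyMOL export draws pairs whose |C_ij| exceeds a
percentile threshold computed over pairs at least 0.8 nm apart
(sequence-local contacts are dominated by backbone springs and would
drown the long-range couplings). The percentile is 95 below 200
residues and 99.9 above 2000, interpolated linearly in N between those
endpoints — the pair count grows quadratically, so larger structures
need a stricter cut. The chosen percentile and resulting threshold are
written as header comments; an empty selection still yields a valid
script.

**Overlap analysis.** The second conformation is superposed onto the
first by least squares (Kabsch) on all matched Cα before differencing —
the rigid-body part of the difference is not representable by
non-trivial modes and would otherwise contaminate every projection.
`O_m = (d_m·ΔR)²/(‖d_m‖²‖ΔR‖²)` and `CO_k = √(Σ_{m≤k} O_m)`. Identical
conformations (after superposition) are a degenerate input and raise an
error rather than returning noise.

## Comparative analysis

Structures are matched to alignment records by order; the ungapped
record sequence must equal the structure sequence ('X' is a wildcard).
A column is *conserved* when no record has a gap there — conservation
here means presence, not sequence identity, because the reduction needs
coordinates in every structure.

**Aligned profiles** are computed per structure from its full
(unreduced) mode set over all non-trivial modes and tabulated on
alignment columns, blank at gaps, so rows are directly comparable.

**Effective Hessian.** For RMSIP/BC each network is reduced to the
conserved residues by the Schur complement
`Ḧ = H_aa − H_ab H_bb⁻¹ H_abᵀ` — the exact curvature after minimising
the energy over the non-conserved coordinates, preserving the full
network's flexibility and its rigid-body null space. `H_bb` is solved
symmetrically, with a pseudo-inverse fallback (and warning) if
singular.

**Frames.** Mode-vector inner products are frame-dependent, so every
pairwise comparison first superposes the second structure's conserved
coordinates onto the first's and rotates its vectors accordingly. This
makes RMSIP and BC invariant to the arbitrary orientations in which
structures are deposited.

**RMSIP** uses the 10 lowest-frequency non-trivial modes of each
reduced system (all available, with a warning, if fewer), as
unit-normalised Cartesian displacement vectors (mass weighting cancels
in direction comparisons; a flag switches to mass-weighted vectors).
It measures subspace overlap only and ignores the eigenvalue spectrum.

**Bhattacharyya coefficient.** Covariances `Σ (1/λ) d dᵀ` are built
from the fewest lowest-frequency modes retaining 95% of the 1/λ
variance, normalised to unit trace, and both are projected onto the `s`
leading eigenvectors of their average retaining 75% of its variance;
`BC = exp(−(1/2s) ln[|½(Ã+B̃)| / √(|Ã||B̃|)])`, evaluated via
eigenvalue log-determinants to avoid underflow. Because the projection
rank `s` may not exceed either covariance's rank, the per-protein mode
counts are floored at `s` (recomputed until consistent) — retention
stays ≥ 95% and the projected matrices are guaranteed positive
definite; without this the determinants degenerate to roundoff noise on
small systems. BC weighs directions by their variance, which is why it
can separate ensembles whose subspaces coincide but whose spectra
differ — a case RMSIP merges by construction.

**Clustering.** All-pairs similarity matrices keep input order with
self-comparisons (=1) on the diagonal; a complete-linkage dendrogram is
built on the dissimilarity 1 − value and can be cut into k flat
clusters. Heat maps with the dendrogram attached are optional
(matplotlib is imported lazily).

## Input conventions

First PDB MODEL only; alternate locations resolved to the highest
occupancy (ties: first in file); MSE read as methionine; other HETATM
records skipped with a per-structure warning, as are non-standard
residues (mapped to 'X', table-mean mass). All chains by default, a
subset selectable. '-' and '.' both parse as alignment gaps. These are
conventional defaults, not behaviours the method itself prescribes.

## Synthetic data

The generator produces poly-alanine geometries that are valid elastic
networks, not realistic decoys: ideal helices (rise 0.15 nm, radius
0.23 nm, 100°/residue — consecutive beads 0.38 nm apart), compact
self-avoiding walks (0.38 nm steps, 0.30 nm clash floor, centroid-
biased for compactness), and two-domain dumbbells whose 4-bead extended
linker zig-zags like an ideal strand — a perfectly straight linker
would be a zero-energy mechanism for central-force springs, an artifact
of collinearity rather than a feature of proteins. Families are seeded
Gaussian perturbations (default experiments use σ = 0.02 nm, 5 copies
per fold) of a base fold, re-sampled until clash-free, optionally with
short indels to exercise gap handling; open/closed pairs rotate one
dumbbell domain 30° about the linker hinge. All generation is seeded
and reproducible.

A green comparative test on this world establishes that the pipeline
separates genuinely different folds and groups noisy copies — it does
not establish discrimination power on real families or superfamilies,
where differences are far subtler than independent random folds.
Sequence effects are likewise untested by poly-alanine fixtures (the
mass table is exercised separately).

## Numerical choices and limitations

- Trivial-mode threshold `1e-9 × λ_max` (relative, not absolute);
  orthonormality and reconstruction are verified to 1e-8.
- All-pairs Hessian assembly is O(N²) memory in 3×3 blocks; fine to a
  few thousand residues, the intended scale.
- The 95%/75% variance fractions and the 10-mode RMSIP convention are
  exposed as parameters but defaults follow the established practice.
- No solvent, no ligands, no all-atom detail: the model sees shape and
  packing density only. Effects not mediated by geometry are invisible
  to it, and eigenvalues are not calibrated to physical frequencies.
- B-factor comparison is deliberately out of scope: B-factors are a
  disputed proxy for thermal fluctuations.
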