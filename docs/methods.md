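# Methods

This note documents the models implemented in flexkit, the numerical
choices behind them, what the synthetic structure generator does and
does not emulate, and the known limitations.

## Elastic network models

All ENMs place a node per selected atom (conventionally Cα) and connect
node pairs within a distance cutoff by harmonic springs.

**ANM.** The Hessian is assembled from pairwise super-elements
`H_ij = −γ_ij Δ Δᵀ/|Δ|²` with `Δ = x_j − x_i`, diagonal super-elements
the negated row sums, so super-rows sum to zero exactly. Eigenvectors
of `H` are the normal modes; eigenvalues are spring-energy curvatures
in units of `γ` (force constant, set to 1 unless a spring function is
given). The default Cα cutoff is 15 Å; 15–18 Å for Cα and 5–7 Å for
all-atom networks are the conventional ranges, and both the cutoff and
the spring function are exposed. Spring functions: `uniform` (γ = 1),
`ed` (the essential-dynamics-refined constant `2.9·ln N − 2.9`, a
single value applied to all pairs), and `structure_based` (base
constant ×6 within one helix/strand element, ×3 for sequence
neighbours i, i±3/4, ×1 otherwise; all three factors configurable,
since published variants differ in the exact constants).

**GNM.** The Kirchhoff matrix `Γ_ij = −γ_ij` for contacts,
`Γ_ii = −Σ_j Γ_ij`, default cutoff 10 Å for Cα. GNM modes are scalar
shapes (no directions); the covariance is the Kirchhoff pseudoinverse,
and the orientational cross-correlation is the covariance normalised to
unit diagonal. For ANM the per-atom 3×3 covariance blocks are traced
before normalising.

**Mode solving.** Dense symmetric eigendecomposition below ~2000
degrees of freedom, shift-invert Lanczos (`σ` slightly negative, so the
softest modes come out first) above. Eigenvalues below `zero_tol`
(default 1e-6) times the spectral scale are counted as rigid-body
modes and skipped: exactly 6 for a connected ANM, 1 for a connected
GNM, 6 per connected component otherwise. In the RTB path the
threshold is scaled by the full Hessian's diagonal, not the reduced
spectrum, so the single-block limit (an all-zero reduced spectrum) is
classified correctly. Eigenvector sign is fixed by making each mode's
largest-magnitude component positive.

**RTB.** Each block contributes an orthonormalised basis of 3 rigid
translations and (for blocks of ≥3 atoms) 3 rotations about the block
centroid; 1–2-atom blocks get translations only because their rotations
are undefined or degenerate. The Hessian is projected into this basis,
solved, and back-projected; because the basis is orthonormal the
back-projected modes are orthonormal, and by Rayleigh–Ritz every RTB
eigenvalue upper-bounds its full-ANM counterpart. Block optimisation
splits oversize blocks along their principal axis at the median
projection and merges undersize blocks into the nearest block by
centroid distance, iterating until the size bounds hold.

**Mode statistics.** Collectivity `κ = (1/N)·exp(−Σ p_i ln p_i)` with
`p_i ∝ |u_i|²`; 1 for a fully collective mode, 1/N for a single-atom
mode. Mean square fluctuations are `Σ_k u_{k,i}²/λ_k` over the modes
present. The per-atom maximum distance at a traversal amplitude `R` is
`R·|u_i|·√N` per mode; the reported profile is the maximum over modes
(the full per-mode array is also returned). The mode score averages
each mode's ascending rank by eigenvalue and by `1 − κ` (scaled by the
mode count, lower = softer and more collective); the score's exact
published form is not available, so this documented ranking stands in
for it.

## Ensembles, superposition and PCA

**Kabsch.** Weighted SVD superposition with the determinant correction
that excludes reflections; collinear point sets are solved but flagged
as degenerate. Zero-weight (dummy) atoms never contribute to the
rotation, the mean, fluctuations, or PCA.

**Chain matching.** `same_id`, `same_position` (file order), `custom`
(a dictionary of per-structure chain-order strings paired
position-wise), and `auto`, which enumerates candidate pairings and
scores each by the mean per-chain (sequence identity × coverage) among
pairs passing the cutoffs (defaults 0.5/0.5), breaking ties by lowest
whole-structure RMSD and then lexicographically. Scores and RMSDs are
rounded (1e-9 / 1e-6) before comparison so that exactly symmetric
assemblies resolve ties deterministically rather than by float noise.
Residue mapping tries residue numbers first and falls back to global
sequence alignment (match 1, mismatch −1, gap open −10, extend −0.5 —
fixed for cross-platform determinism); precomputed mappings from
external structural aligners can be supplied.

**Ensemble building.** Each member is matched to the reference
chain-by-chain; reference Cα positions missing from a member become
dummy atoms when the column's occupancy stays at or above the cutoff
(default 0.9) and are trimmed away otherwise, optionally intersected
with a trim selection. Members are then iteratively superposed onto the
occupancy-weighted running mean until it moves less than `tol`
(default 1e-4 Å, max 100 iterations) — each round is a weighted
least-squares fit, so the total weighted RMSD to the mean is
non-increasing.

**PCA.** The covariance is the average (divisor M) of the outer
products of deviations from the converged mean. When 3N > M and all
weights are 1 the spectrum is computed through the M×M Gram matrix
(identical non-zero eigenvalues at a fraction of the memory); with
dummy atoms a dense pairwise-available covariance with per-entry
effective counts is used instead — unbiased entry-wise, though such
matrices are not guaranteed positive semidefinite for extreme
missingness. Components are truncated at the numerical rank (variance
above 1e-9 of the leading one, with a 1e-20 Å² absolute floor) with a
warning when fewer than requested survive.

## Mode editing, comparison and projection

Slicing restricts mode rows to a selection (renormalising columns by
default); extension copies each residue's Cα vector to every atom of
that residue, matching residues by (chain, number, insertion code).
Vibrational subsystem analysis computes the Schur complement
`H_eff = H_ss − H_se H_ee⁻¹ H_es` with a pseudoinverse for singular
environments; `H_eff ⪯ H_ss`, i.e. the environment can only soften the
subsystem. Thin-plate-spline interpolation fits each displacement
component with the 3D biharmonic kernel `U(r) = r` plus an affine term
(exact at the nodes, optional ridge for near-degenerate node sets) and
requires ≥4 non-coplanar sources.

Comparisons report absolute cosine overlaps by default (eigenvector
sign is arbitrary), signed raw products behind a flag. RWSIP and the
covariance overlap weight modes by variance contribution — λ for PCA,
1/λ for ENMs — and both equal 1 on self-comparison. Cumulative overlap
is the square root of the running sum of squared overlaps across a row,
capped at 1; against a complete basis it is exactly 1 (Parseval). Mode
matching maximises the summed squared overlap by Hungarian assignment.
Projections are dot products of member deviations with unit mode
vectors, divided by √N when RMSD scaling is requested; projecting an
ensemble onto its own components gives per-axis variances equal to the
component variances.

## Clustering, domains and hybrid sampling

**UPGMA.** Average-linkage agglomeration (heights are monotone);
deterministic tie-breaking. Trees are cut at a height (Å) or to at most
k clusters; each cluster's representative is its medoid (lowest mean
RMSD to co-members) — the "most distinct representative" criterion is
not formalised in the literature this follows, so the medoid is used
and the distance matrix is kept available for other rankings.

**Dynamical domains.** Atoms are embedded in the row space of the
first n GNM mode shapes, rows normalised to the unit sphere, and
clustered by Lloyd k-means with deterministic farthest-point seeding
(first centre farthest from the data mean) — fully reproducible and
label-permutation invariant for well-separated domains. Including the
zero mode (solve with `skip_zeros=False`) makes disconnected components
separate exactly; with one non-zero mode and two domains the boundary
falls at the mode's sign change. Contiguity is not enforced.

**Hybrid sampling.** Generation 0 relaxes the start structure; each
generation re-solves the ANM on every current parent, draws conformers
as standard-normal combinations of the first n modes rescaled so each
conformer sits exactly at the target RMSD from its parent (an
average-RMSD behaviour is available as `rmsd_mode="sampled"`, uniform
on 0.5–1.5× the target, since exact scaling is the more testable
convention), pools them, clusters the pool by UPGMA to that
generation's max-cluster bound, and relaxes the medoids. Mode
displacements contain no rigid-body component, so the pool shares a
common frame and generation clustering uses a vectorised
superposition-free RMSD; a superposing variant exists for unaligned
pools. The relaxer is a pluggable pure function of coordinates and
seed: bundled are the identity and a short steepest descent on the
conformer's own ENM energy; all-atom minimisation/MD belongs to
external engines and is intentionally out of scope. One seeded
generator drives the whole run, so reruns are bit-identical, and a
run can never contain more than 1 + Σ max-clusters structures.

## Structures, selections and formats

Parsing goes through gemmi, so PDB and PDBx/mmCIF yield identical
records; assembly operators (REMARK 350 / mmCIF assembly categories)
are applied per assembly with copy k of chain X renamed X, X2, X3, …
Alternate locations keep the first-listed conformer by default for
deterministic atom counts. Writers emit fixed-column PDB (hybrid-36
serials beyond 99999; chain ids wider than one character are redirected
to mmCIF) and a minimal `atom_site` loop, both at 3-decimal precision,
so write→parse round-trips agree to ≤5e-4 Å.

The selection mini-language supports `protein`, `nucleic`, `hetero`,
`ca`, `name`/`chain`/`resname`/`element` with value lists,
`resnum` with values and inclusive `A to B` ranges, and
`and`/`or`/`not` with parentheses. Insertion codes participate in
residue identity but `resnum` compares the numeric part only. The
conventional default selection string is accepted verbatim, including
its bare `C2` token (kept alongside `C2'`, as the intended spelling is
not decidable). Selections on selections intersect.

NMD files store title, atom names, residue names/ids, chain ids,
B-factors, coordinates and one `mode index scale vector` line per mode,
with the scale as √variance (√λ for PCA, √(1/λ) for ENMs; a flag stores
raw eigenvalues). Per-mode directories hold one `vec.<k>` text file per
mode (one `x y z` line per atom at 12 significant digits) with a CSV
metadata table (eigenvalue, collectivity, score, enabled flag, path)
and an optional SQLite mirror; CSV is canonical to keep the artifact
dependency-light. Ensembles serialise to compressed named-array
archives (coords, weights, labels, mean, per-member alignment rows)
plus a FASTA of the alignment; trajectories to multi-model PDB.

## Synthetic structures

All fixtures are Cα-only poly-alanine chains from seeded, fully
deterministic constructions, with consecutive residues 3.8 Å apart and
non-bonded atoms kept ≥3 Å apart. The coil is a confined self-avoiding
walk (compact and therefore elastically well-connected); the dumbbell
is two such lobes 36 Å apart whose connecting walk forms a thin neck,
giving exactly six ANM zero modes and a genuine inter-lobe hinge as the
softest mode; the pseudo-spike is three helical-coil protomers around a
common axis (helix pitch ~12 Å, below the 15 Å cutoff, so each protomer
is a stiff tube) whose terminal quarter rotates rigidly about a hinge
atom by a per-chain opening angle — 3-down/1-up/2-up-like states — with
optional per-chain missing residues. A 24-member study set draws from
seven such states (≥30° apart, several Å of backbone RMSD) with 0.3 Å
per-coordinate noise and cycles three chain-labelling conventions, so
custom chain matching is exercised and the state partition is ground
truth by construction.

The mode-driven ensemble generator displaces a base structure along
planted orthonormal vectors with normal amplitudes plus isotropic
noise. Planted directions should be orthogonal to the rigid-body
subspace (`rigid_orthogonal_vectors` provides these): superposition
removes rigid components, so a random 3N vector loses about √(6/3N) of
its norm and subspace recovery saturates below 1 otherwise.

What the generator does **not** emulate: real secondary structure,
side chains, sequence variation, physically realistic spike geometry,
crystallographic disorder, or experimental coordinate error models.
Passing tests therefore demonstrate the correctness of the algorithms
and pipelines — selection counts, spectral properties, recovery of
planted structure, clustering of well-separated states — not the
biological accuracy of any specific prediction on deposited data.

## Problem sizes and defaults

The bundled analyses run at desk scale by choice: full-size trimers
(3366 Cα) for selection counts and three-state PCA, 150 residues per
chain wherever an ANM is solved, 60 per chain for the five-generation
hybrid run (schedule 10/20/30/40/50 with 50 conformers per parent at
2 Å), M = 200 for planted-subspace recovery. Defaults in one place:
ANM cutoff 15 Å, GNM 10 Å, γ = 1; `zero_tol` 1e-6; chain-matching
cutoffs 0.5/0.5; occupancy cutoff 0.9; superposition tol 1e-4 Å, max
100 iterations; TPS ridge 0; traversal 2 Å over 11 frames.

## Known limitations

- The automated chain-matching score is a reasonable composite, not a
  published formula; alternatives (e.g. RMSD-first) may order
  borderline pairings differently.
- Pairwise-available covariance under heavy missingness can be
  indefinite; eigenvalues are clipped at zero.
- CE-style structural alignment is not implemented; residue mappings
  beyond sequence alignment must be supplied precomputed.
- GNM domain k-means does not enforce sequence or spatial contiguity.
- The bundled ENM relaxer smooths local strain only; it is not an
  all-atom minimiser.
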