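# Methods

## Model

The package ranks candidate ligand-binding pockets of a protein structure by
how strongly their occupation would constrain the protein's global dynamics —
the working definition of allosteric propensity used here — combined with how
hydrophobic the pocket lining is.

Dynamics are described by the Gaussian network model (GNM).  The structure is
coarse-grained to its Cα atoms; every residue pair within a cutoff distance
r_c is connected by an identical harmonic spring of constant γ.  The network
topology is the Kirchhoff (connectivity) matrix Γ, a weighted graph
Laplacian:

    Γ_ij = −1            if i ≠ j and R_ij ≤ r_c
    Γ_ij = 0             if i ≠ j and R_ij > r_c
    Γ_ii = −Σ_{j≠i} Γ_ij

Eigenvectors of Γ are vibrational modes, eigenvalues their squared
frequencies in units of γ.  The uniform-displacement (rigid-body) zero mode
is removed — one per connected component.  The low-eigenvalue "global" modes
describe the collective motions that mediate allosteric transitions.

Ligand binding at a pocket p is emulated by stiffening the network there:
the spring constant between **every** pair of residues lining the pocket is
set to γ_p, regardless of whether the pair is within the cutoff.  For each
pocket the perturbed spectrum is recomputed and each of the slowest n_g
reference modes is re-identified among the first n_s perturbed modes by
largest absolute eigenvector overlap |v_m · v_n^p| (eigenvector sign is
arbitrary, so the absolute value is used), assigning greedily with
uniqueness: the largest overlap in the n_g × n_s block is fixed first, its
row and column removed, and so on.  The pocket's dynamics score is the mean
percentage eigenvalue shift over the matched global modes,

    Δλ_k = (λ_k^p − λ_k) / λ_k × 100,     Δλ̄_p = mean over k ≤ n_g.

Over the pocket population of one protein, Δλ̄_p and the pocket's local
hydrophobic density H_p (a per-pocket descriptor reported by the Fpocket
cavity detector, measuring clustering of apolar residues in the lining) are
each standardized to z-scores, and the final allostery score gives the two
terms equal weight:

    z_p = (Δλ̄_p − μ)/σ,   z_h,p = (H_p − μ_h)/σ_h,   s_p = (z_p + z_h,p)/2.

Pockets are ranked by descending s_p.  A prediction counts as a success when
a known allosteric pocket appears within the top 3; when several pockets
overlap the known site, the best-ranked occurrence governs.

## Parameters

| parameter        | default | units              | role |
|------------------|---------|--------------------|------|
| cutoff r_c       | 10.0    | Å                  | GNM contact distance (inclusive comparison); the standard optimal GNM cutoff |
| γ                | 1.0     | kcal mol⁻¹ Å⁻²     | base spring constant; only the ratio γ_p/γ affects percentage shifts, z-scores and ranks |
| γ_p              | 10.0    | kcal mol⁻¹ Å⁻²     | pocket spring constant, *set* (not added) for all pocket pairs |
| n_global (n_g)   | 5       | —                  | slowest reference modes averaged into Δλ̄_p |
| n_perturbed (n_s)| 15      | —                  | perturbed modes searched during re-identification; clamped to the retained mode count on small networks |

z-scores use the population (divide-by-P) standard deviation over scored
pockets; pockets resolving to fewer than two Cα nodes are reported but
excluded from μ/σ, so one unresolvable pocket cannot distort the others.
Score ties are broken by larger z_p, then smaller pocket id.

## Numerical choices

- **Eigensolver.** Full dense symmetric eigendecomposition
  (`numpy.linalg.eigh`); for the symmetric PSD Kirchhoff matrix this
  coincides with an SVD up to sign.  Deterministic for fixed input; a fixed
  sign convention (largest-magnitude component positive) removes the
  remaining eigenvector sign freedom.
- **Zero-mode removal.** Eigenvalues ≤ 1e-8 × λ_max are treated as rigid.  A
  disconnected contact graph yields one zero mode per component; all are
  removed with a warning rather than a hard failure, because assemblages
  with a stray peptide are common.
- **Degenerate eigenvalues.** Within a numerically degenerate perturbed
  eigenvalue (gap ≤ 1e-8 relative), any orthonormal basis of the eigenspace
  is equally valid, so raw eigenvector overlaps are basis noise.  Matching
  therefore treats each degenerate cluster as a subspace: a reference mode's
  overlap with the cluster is the norm of its projection, orthogonalized
  against projections already consumed.  Exactly-degenerate spectra (e.g.
  symmetric homo-oligomer fixtures) then give unit overlaps, and a uniform
  rescale of the whole network reproduces its analytic shift exactly.
  Matches that touched a degenerate cluster are flagged.
- **Mode crossings.** Stiffening adds a positive-semidefinite term, so the
  *sorted* perturbed spectrum always dominates the unperturbed one (Weyl).
  Matched-mode shifts are *usually* nonnegative too, but when the
  perturbation mixes two slow modes strongly (matched overlap dropping
  toward ~0.4), best-overlap matching can pair a reference mode with a
  lower perturbed mode and produce a modestly negative shift (observed:
  −0.5% to −6% in roughly 0.5–2% of random instances, at every network size
  tried).  This is intrinsic to overlap-based mode tracking under strong
  perturbation, not a solver artifact.  `PerturbationResult.min_overlap`
  reports the weakest overlap used, flagging exactly these cases.
- **Greedy vs optimal matching.** The product path is greedy-by-largest
  overlap; the Hungarian optimal assignment over the same block serves as a
  test oracle.  For spatially contiguous pockets — the method's operating
  regime, since a pocket is a cavity lining — the two agree in ≥95% of
  random trials and never move the mean shift appreciably.  For *scattered*
  random residue subsets (not a pocket in any physical sense) the 10×
  springs act like long-range cross-links, mode identity degrades, and the
  two assignments can differ substantially; this regime is outside the
  method's assumptions.

## Synthetic data

The fixture generator produces deterministic Cα geometries (path, ring,
cubic lattice, multimer ring) with explicit pocket definitions, written both
in a neutral pocket format and in a miniature Fpocket-style directory so
both ingestion paths are exercised on identical ground truth.  Randomness is
confined to seeded coordinate jitter; topology is always explicit.

The `multimer-ring` fixture emulates the situation in which central cavities
of multimeric assemblages rank at the top: four chains, each a compact body
plus a two-residue linker reaching the symmetry axis, with all inter-chain
coupling mediated by the central hub.  The slow modes are relative motions
of whole subunits, so stiffening the central cavity (which touches every
chain) raises the slow eigenvalues far more than stiffening any
single-chain pocket.  The demo's hydrophobic densities are fixed so the
central pocket is *not* the most hydrophobic — its top rank is
dynamics-driven.  Test structures elsewhere are uniform random clouds (for
matrix/spectral oracles), self-avoiding 3.8 Å-step chains, and jittered
lattice globules (for perturbation statistics); random-instance tests use
chains of 100 residues with pockets of 4–10 spatially nearest residues,
representative pocket-to-protein ratios.

What passing these tests does **not** show: synthetic geometries have no
side chains, sequence, or physical pocket shapes, so the hydrophobic-density
term is exercised only as an input column, and absolute shift magnitudes on
fixtures say nothing about real proteins.  Benchmarking prediction success
on real allosteric datasets requires structures plus a cavity detector and
is out of scope here.

## Limitations

- Pocket detection is delegated entirely to Fpocket (or user-supplied
  definitions); a site Fpocket misses can never be ranked.
- Isotropic GNM only: no directional (anisotropic) information, no
  mass-weighting, no distance-weighted springs.
- The mean shift always averages over n_global matched modes even when some
  overlaps are weak; the minimum matched overlap is reported as a quality
  flag rather than used to reweight.
- Multimeric biological assemblies must be provided as assembled PDB files;
  the reader takes the file as given (first MODEL, standard amino acids plus
  MSE, altloc by highest occupancy).
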