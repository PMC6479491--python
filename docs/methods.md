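# Methods

This note documents the models, conventions and numerical choices behind
`rinflow`, and what the synthetic fixtures do and do not establish about
real trajectory data.

## Coordinates, units, containers

Coordinates are Angstrom internally; SASA and covariance eigenvalues are
reported in nm² because that is how MD analysis tools print them; frame
times are ps. A `TrajectoryEnsemble` is a fixed topology plus an
(n_frames × n_atoms × 3) array with strictly increasing times. Multi-model
PDB is the mandatory on-disk ensemble format (read/written through
biotite); per-frame times ride in `REMARK   6 TIME_PS MODEL <i> <t>`
header lines and default to a uniform stride (100 ps, the sampling
cadence typical of production runs) when absent. Alternate locations
resolve to the highest occupancy (first listed on ties); waters are
dropped on read by default; missing element symbols are inferred from the
first alphabetic character of the atom name.

Selections use a small grammar (`backbone`, `calpha`, `heavy`,
`sidechain`, `protein`, `ligand`, `water`, `resid a-b`, `chain`, `name`,
with `and/or/not` and parentheses). "Backbone" means N, CA, C, O — the
carbonyl O belongs to the standard PDB backbone — and is configurable.
`resid` uses author numbering, and all user-facing reports print
author-numbered one-letter labels (Y314 style). "Sidechain" is defined as
protein heavy atoms outside the backbone set; side-chain hydrogens are
deliberately not chased through connectivity.

## Superposition, RMSD, RMSF

Rigid-body fits use the SVD solution of the orthogonal Procrustes problem
with a determinant guard so only proper rotations are returned. Fits
require ≥ 3 non-collinear atoms. RMSD series superpose each frame onto the
chosen reference (frame 0 by default, standing in for the equilibrated
structure when that is not supplied separately). RMSF uses an iterative
mean reference: frames are fitted to frame 0, then three fit → recompute
mean → refit cycles; per-atom fluctuations about the converged mean are
reported per residue through its Cα. Because the fit itself absorbs a
small share of any localized motion (of order 1/M for M fitted atoms),
tests of exact variance identities fit on a disjoint static selection
(`fit_selection`), which is also the practical recommendation when one
atom's motion is of interest.

## SASA

Shrake–Rupley sphere sampling with a deterministic golden-spiral point
set (default 960 points; floor 100), probe radius 0.14 nm, and a built-in
vdW table (C 0.17, N 0.155, O 0.152, S 0.18, H 0.12, P 0.18 nm). Only the
selected atoms participate, as both surface and occluders — the default
pipeline selection is the backbone, and whole-protein SASA is one flag
away. Two boundary rules make degenerate fixtures exact: sample points
lying exactly on a neighbour's sphere count as accessible (a 1e-9
relative shrink of the burial test), and an atom exactly coincident with
an equal-radius earlier atom contributes zero area, so a fully
overlapping pair has the area of a single sphere.

## Hydrogen bonds

A donor is an N/O/S with an explicit covalently attached hydrogen (same
residue, D–H < 1.25 Å); acceptors are N/O/S. The default criterion is
donor–acceptor distance ≤ 3.5 Å and the angle at the donor between D→H
and D→A ≤ 30° — the convention under which those two numbers are the
standard MD cutoffs. Both cutoffs are inclusive; ties count as bonds,
which keeps designed-occupancy recovery exact rather than approximate.
An alternative `dha` convention (deviation of the D–H…A angle from
linearity) is available. Occupancy is per residue ("at least one bond
with the partner group in this frame"), matching how per-residue
occupancy bars are usually reported; intra-residue bonds are excluded.
Donors lacking hydrogens are skipped with a warning count; a structure
with no hydrogens at all is an error instructing protonation, except in
RIN edge weighting where it degrades to zero weights with a warning
(contact networks of unprotonated crystal structures are still useful).

## Essential dynamics and the free-energy landscape

The covariance of the 3M-dimensional selected-coordinate vector is
accumulated after superposition onto the iterative mean, removing rigid
translation/rotation, and normalized by 1/N (population convention), so
the projection variance along eigenvector i equals eigenvalue i exactly
and a designed ±0.1 nm oscillation appears as exactly 0.01 nm². Negative
round-off eigenvalues are clipped to zero. Mass weighting is not applied
(a flagged alternative would be the natural extension); eigenvalues are
in nm².

Cosine content is evaluated by trapezoidal quadrature of the projection
against cos(iπt/T) on the actual frame time grid. The landscape is built
over a PC pair only when both cosine contents are ≤ 0.2 (override with
`force`): near-cosine projections indicate random-diffusion-like
sampling, on which a "landscape" would be an artifact. The 2-D histogram
uses 32 × 32 bins by default over [min, max] per axis extended by half a
bin; ΔG(bin) = −k_B T ln(n/n_max) with k_B = 0.0083145 kJ mol⁻¹ K⁻¹ and
T = 300 K by default, so the most populated bin sits at exactly 0. Empty
bins are masked (NaN), not assigned a ceiling. Raw counts are used (no
kernel smoothing). Minimum-energy frames are the frames in the most
populated bin; ties between equally populated bins resolve to the first
bin in scan order, and frames are returned in time order.

## Representative selection

The total conformational energy is an input series aligned to the frames
— reimplementing a forcefield is out of scope, and whether "total
conformational energy" means potential or total energy is left to the
producer of the series; reports label the column as supplied. The k = 20
lowest-energy frames (stable sort, so energy ties resolve to the earliest
frame) are clustered by pairwise superposed RMSD with single linkage cut
at 2.0 Å — chosen for determinism and because single linkage is
refinement-monotone in the cutoff. The representative is the
lowest-energy member of the largest cluster; size ties go to the cluster
holding the global minimum, then to the cluster with the lowest-energy
member.

## Residue interaction network and centralities

Each amino-acid residue contributes two coarse centers: its Cα and the
side-chain heavy atom farthest from Cα in the given structure (glycine
has no side-chain center; alanine's is Cβ). An edge exists when any of
the ≤ 4 center-pair distances is strictly below 7 Å, recording which
center classes touched (backbone–backbone, backbone–sidechain,
sidechain–sidechain) and the number of distinct hydrogen bonds between
the two residues as the weight. Sequence-adjacent residues are connected
like any others by default (`exclude_neighbors` prunes them when a
contact map without trivial chain edges is wanted). Ligands are excluded
by default; `include_ligand` adds each non-water HETATM group as one
centroid node.

Shortest paths use unit edge length: the closeness distance d(i,k) is
defined as the minimum number of edges, and most contact edges carry zero
H-bonds, which would be unusable as lengths. The stored weights can enter
the metric via `weights="inverse-hbond"` (length 1/(1+count)) for
sensitivity analysis. Degree, closeness (Dijkstra; equal to BFS on unit
weights, which the tests assert) and betweenness (Brandes, endpoints
excluded, normalized by 2/((N−1)(N−2))) are implemented in the package;
networkx serves only as an independent cross-check in the tests, next to
an exhaustive geodesic-enumeration oracle. On disconnected graphs,
closeness is component-scaled by (reachable−1)/(N−1) (the
Wasserman–Faust correction; a strict mode refuses disconnected input),
and Brandes runs per component natively; isolated nodes get closeness 0
with a warning. Weighted shortest-path ties are compared with a 1e-12
tolerance since inverse-count lengths are not exactly representable.

Pearson correlations between the three centralities are reported, with
NaN when a distribution is constant to within 1e-12 relative spread
(e.g., on vertex-transitive graphs). Threshold reports list residues
with C_B ≥ 0.05 (descending) along with the empirical percentile of the
threshold; state comparisons report |ΔC_B| per residue with flags at
0.02 (tabulation) and 0.03 (structure-mapping), residues matched by
author label and chain, unmatched residues listed separately.

## Synthetic data: what it emulates, and what it does not

The generator builds an idealized extended chain (N–CA 1.46, CA–C 1.52,
C–O 1.23, C–N 1.33 Å; Cα z alternates so the trace is never collinear)
with explicit amide hydrogens, then layers: per-residue isotropic
Gaussian displacements (the amplitude is the per-coordinate standard
deviation, so large-sample Cα RMSF converges to σ√3); designed
donor/acceptor pairs placed exactly on the N–H axis at 2.9 Å in
round(occupancy × n_frames) frames and at 5.5 Å otherwise, making
occupancy recovery exact by construction; and a collective mode — a unit
direction field with Gaussian per-frame amplitude. A plain 3-vector mode
direction gets a Gaussian envelope along the chain and, like any supplied
field, has its rigid-body component projected out, because a rigid
displacement would be silently removed by superposition;
`collective_mode_field` exposes the realized field that PC1 should
recover. Defaults (20 residues, 50 frames, 0.5 Å fluctuation, 100 ps
stride) are the desk-scale stand-in for a sampled production run.

The hub fixture places two clusters whose members are pairwise within
7 Å (each cluster is a clique at the contact cutoff) with all
inter-cluster distances above 12 Å and a hub within 7 Å of both gateway
residues. Note a hub within 7 Å of members of both clusters caps the
minimum inter-cluster distance below 14 Å by the triangle inequality;
12 Å is the practical margin, and it is far above the cutoff, so no
direct cluster–cluster edge can exist and the hub is provably the unique
articulation point with maximal betweenness. Hub-layout ensembles are
Cα-only (full side chains cannot pack at those spacings), so they cannot
host designed H-bond pairs.

Passing these fixtures establishes algorithmic correctness — geometry
predicates, estimator identities, graph theory — not realism: frames are
uncorrelated in time (no kinetics, no diffusive cosine-content regime),
noise is isotropic and unbonded, there is no solvent, no side-chain
chemistry beyond a Cβ, and energies are an arbitrary designed series.
Conclusions about a real system still depend entirely on the quality of
the supplied trajectory.

## Pipeline, determinism, problem sizes

The pipeline executes stability → H-bonds → essential dynamics → (FEL if
admissible) → representative → RIN centralities, writing each stage's
TSV/JSON (fixed `%.10g` formatting, sorted JSON keys, no wall-clock data)
before the next starts and recording a sha256 per output in the manifest,
so identical configuration and inputs give bit-identical outputs. When no
ligand is present the H-bond stage reports intra-protein bonds instead of
ligand–protein bonds. Configuration is a flat YAML document with CLI
overrides; defaults are the values quoted throughout this note (3.5 Å,
30°, 7 Å, 0.2, 0.05, 0.02/0.03, k = 20, 300 K).

Tests and the acceptance script run on deliberately small problems —
graphs with N ≤ 12 (where geodesic enumeration is exhaustive and exact),
chains of 5–40 residues, 4–200 frames — sizes at which every oracle is
affordable and the whole suite completes in seconds on one core. The
algorithms themselves are O(N·E) (Brandes), O(F·M) (per-frame fits) and
O(M²) (SASA, contacts) and scale to real single-domain proteins.

## Known limitations

- No mmCIF input, bond-order perception, or protonation assignment; the
  H-bond detector requires explicit hydrogens.
- Binary trajectory formats are supported only by conversion to
  multi-model PDB.
- Closeness on disconnected graphs is a documented variant of the plain
  reciprocal-mean definition, not the only possible one.
- The FEL is limited to two PCs and raw-count Boltzmann inversion; no
  multi-observable weighting or kernel density estimation.
- Energy-based representative selection is only as meaningful as the
  supplied energy series.
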