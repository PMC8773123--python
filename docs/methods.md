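# Methods

## Scope and model

The toolkit compares two conformational states of one multimeric assembly
through three complementary readings: per-residue-pair distance changes
(DDM), domain-averaged distance changes (block DDM, with a tertiary vs
quaternary split), and buried interface areas (an energy proxy).  A fourth
stage overlays evolutionary-couplings records on the DDM.  All stages
assume the two states are *the same molecule*: residue correspondence is by
author numbering under an explicit chain map, never by sequence alignment —
automatic chain matching is deliberately absent because protomer labels in
deposited assemblies are often permuted, and a silent mismatch would be
worse than an error.

## Residue frames and representative atoms

The representative atom is the alpha-carbon.  Residues lacking one (or
unresolved in either state) are dropped from the distance analyses at the
pairing step, with a log line; they still occlude in SASA.  Waters and
hydrogens are always excluded; heteroatom residues are excluded by default.
Altloc conformers keep the highest occupancy, ties broken by altloc letter.
All residue ranges are author-numbered and inclusive.

## DDM and the noise mask

ΔD[i,j] = |b_i − b_j| − |a_i − a_j| over the common residues (state B minus
state A; contraction negative).  Entries with |ΔD| below a threshold are
masked, not zeroed — the values are kept, the mask travels with them.  The
default threshold is 3.0 Å, half of a ~6 Å map resolution; a
`half_resolution_threshold(resolution)` helper exposes that heuristic for
other resolutions.  The matrix is NaN-free by contract: missing residues
are handled upstream by intersection, never by NaN propagation.

Block means are computed on raw signed values by default; masked averaging
(`use_mask=True`) excludes sub-threshold pairs and reports cells whose
pairs are all masked as absent (NaN with count 0) rather than zero.
Diagonal blocks exclude i = j self-pairs, which would dilute the mean with
structural zeros.  With one residue per block the block DDM reproduces the
element DDM exactly, and the count-weighted mean of all cells equals the
element-matrix mean — both are tested invariants.

## EC filtering and classification

The cn floor is inclusive (cn ≥ threshold) by default with a strict mode
available; the shipped default is 1.0.  The same-helix exclusion is
generalized to "same named segment" of a domain map, and a minimum sequence
separation (default 5) removes trivial near-diagonal couplings; segment
exclusion is applied *before* spatial classification.  A pair is "close"
iff its Cα–Cα distance is strictly below the cutoff (default 10 Å).
Sequence-to-structure numbering is reconciled by an explicit user offset —
again no automatic alignment, for the same misregistration reason.  Intra-
protomer distances are evaluated on one reference chain; inter-protomer
distances as the minimum over ordered chain pairs.

## SASA and interfaces

Shrake–Rupley with a deterministic golden-section-spiral point set — no
randomness anywhere in the surface code, so results are bit-reproducible.
Defaults: probe 1.4 Å, 960 points per atom, element-level Chothia-style
van der Waals radii (C 1.87, N 1.65, O 1.40, S 1.85, P 1.80 Å; unknown
elements 1.70 Å with a warning).  Point counts below 60 are refused as too
coarse.  At 960 points the isolated-sphere quadrature is exact to <0.5%,
two-sphere configurations match the spherical-cap closed form to <1%, and
doubling the point count moves a whole-model total by <0.3% (all enforced
by tests).  One caveat the tests document: the point sphere has a fixed
orientation, so quantities that are equal by molecular symmetry agree only
to quadrature error (~a few percent at 240 points) unless the point set is
co-rotated, which the `points=` argument allows.

Buried area is ASA(A) + ASA(B) − ASA(A∪B); interface area is half of it,
matching PISA so values are comparable with published interface tables.
Each interface is evaluated on the isolated A∪B subcomplex by default — the
same operation as submitting the two contacting domains alone to PISA; an
`include_context` option makes the rest of the assembly occlude instead,
for users who want in-assembly accessibility.  The strong/weak affinity
boundary is interface area > 2000 Å², strict.

## Synthetic assemblies and what they do (not) emulate

`make_ring_assembly` builds Cn-symmetric rings of idealized α-helices
(rise 1.5 Å, twist 100° per residue, helix radius 2.3 Å), one Cα plus one
dummy side-chain carbon per residue.  `apply_motions` plants named
rigid-body block motions plus optional isotropic Gaussian noise (σ up to
~1 Å emulates low-resolution coordinate uncertainty).  Expected block-DDM
means and buried areas are computed by an intentionally separate brute-force
path (plain double loops; a latitude-band point grid for SASA), so the
ground truth is an independent oracle for the pipeline, not a mirror of it.

These toys capture what the analyses actually consume — relative geometry
of rigid bodies, contact surfaces, distance distributions — but not real
protein features: no side-chain packing, no sequence, no secondary-structure
diversity, no map-dependent model error.  Passing tests therefore establish
the *algorithms* (and their numerical behaviour), not the biological
conclusions one would draw on deposited structures; the network-using
driver script exists for the latter.

Default generator conditions used in tests and the acceptance script:
rings of 3 or 6 protomers (the trimer/hexamer architectures of
outer-membrane channels and membrane-fusion-protein rings), 12 residues per
protomer for geometry checks, 60–120 for EC statistics (so that ≥200
contact pairs exist at the 10 Å cutoff), planted translations of 5–6 Å and
rotations of 30–45° — the magnitude scale of the quaternary motions the
DDM is meant to resolve — and noise σ ∈ {0, 0.5 Å}.

## Numerical choices

- Distance matrices are symmetrized by construction ((D + Dᵀ)/2) and get an
  exact zero diagonal; coincident points warn but do not fail.
- DDMs require ≥3 common residues; fewer is a degenerate-input error.
- Buried areas are accepted down to −1e-6 Å² (floating-point slack); below
  that the inputs are inconsistent and construction fails.
- Duplicate EC pairs, including (j,i) mirrors, collapse to the higher cn.
- The EC close rule and the affinity rule sit on opposite sides of their
  boundaries (strictly-less vs strictly-greater) deliberately, following
  the conventions stated with each: 10.0 Å is distant, 2000.0 Å² is weak.
- Every CLI command is deterministic given its inputs; audit records carry
  the version, parameters and SHA-256 checksums of inputs.

## Open design points resolved here

- Residues unresolved in one state: intersect-and-drop with logging (rather
  than imputation), since imputed coordinates would manufacture signal.
- Whether single-protomer DDMs are computed in isolation or cut from the
  full-assembly matrix: both are supported via selections; they differ only
  in which residues exist, not in any value.
- Interface decomposition on isolated domain pairs vs in-assembly context:
  isolated pairs are the default (matching how subcomplexes are submitted
  to interface servers); the context mode is available and documented.

## Known limitations

- SASA is O(N·k) with a k-d tree but evaluated per selection; very large
  assemblies at 960 points cost seconds to minutes — reduce `n_points` for
  surveys, the convergence test bounds the cost in accuracy.
- The EC overlay annotates pairs on one reference chain; couplings that are
  only satisfied across an interface appear through the inter-protomer
  distance, not the DDM annotation.
- No normal-mode/elastic-network analysis and no per-atom DDMs; the element
  DDM is Cα-only by design.
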