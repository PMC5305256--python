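# Methods

## Scope and data model

`coldadapt` analyses conformational ensembles of two homologous enzymes —
one cold-adapted, one warm-adapted — and classifies their sequence
differences. It does not run molecular dynamics: ensembles are consumed as
multi-model PDB files (one `MODEL` per frame) over a fixed topology, with
several independent replicates per system. Coordinates are stored in nm
internally (PDB I/O converts from/to Å); residues are indexed by a 0-based
ordinal internally, and all user-facing output goes through a numbering map
that defaults to the PDB residue number plus insertion code, so results can
be reported in a reference numbering convention shared between homologs.
Alternate locations other than `A`/blank are dropped with a warning, giving
a deterministic topology.

## Superposition and descriptors

All fitting is least-squares rigid-body (Kabsch) superposition; the
single-pair path goes through `scipy`'s rotation estimation, and the
all-pairs RMSD matrix is computed with blocked, batched 3×3 SVDs (with the
determinant sign correction for proper rotations). Superposition is
idempotent and never alters intra-frame geometry; both properties are
tested.

* **RMSD series** — per-frame fitted RMSD over a selection (main chain by
  default) against the starting structure.
* **Radius of gyration** — mass-weighted; RMSD and RMSF are unweighted over
  their selection. These weighting conventions are stated explicitly
  because they are a genuine choice.
* **Windowed RMSF** — Cα fluctuations over non-overlapping windows
  (default 10 ns, excluding the first 10 ns as equilibration; windows are
  converted to whole frame counts by floor and a trailing partial window is
  discarded). Within each window the frames are fitted to the window mean
  structure (one re-iteration of the mean after fitting), and fluctuations
  are taken about that refitted mean. The fitting reference per window was
  a genuinely open choice; the window mean is standard practice and is
  documented here so profiles are comparable. Profiles are averaged across
  windows per replicate, then across replicates; the reported spread is the
  across-replicate sample standard deviation (ddof = 1), with the
  across-window spread available from the single-replicate profile.
* **Covariance trace** — the trace of the 3N×3N Cα covariance matrix
  (ddof = 1), a basis-invariant scalar equal to the sum of the PCA
  eigenvalues; the identity is asserted in tests to 1e-9 relative. Frames
  must be superposed on a common reference first; the function does not
  re-fit.
* **Difference profiles** — cold minus warm per mapped residue; positions
  present in one profile but not mappable (insertions) are reported as
  explicit gap rows, never dropped.

## Ensemble-similarity metrics

* **PCA/RMSIP** — full eigendecomposition of the Cα coordinate covariance
  (so rank-deficient and constant trajectories are handled without error);
  RMSIP over the first D = 10 components. RMSIP(a, a) = 1 for any basis and
  the metric is invariant to eigenvector sign flips.
* **CES** — pooled frames, pairwise Cα-RMSD matrix, affinity propagation
  with similarity = −RMSD (nm), preference −10, damping 0.9, up to 1000
  iterations with a 50-iteration stability window (all exposed as
  parameters; non-convergence is an error, a single shared cluster is not).
  Each ensemble becomes a cluster-population probability vector; the
  reported value is the discrete Jensen–Shannon divergence in nats, which
  is also cross-checked in tests against an independent `scipy` JSD route.
  The preference value's units are those of the similarity (negative nm);
  note that two basins must differ in *internal geometry* by more than the
  preference scale for affinity propagation to split them — a rigid-body
  offset between basins is invisible after fitting, which is why the
  synthetic basin generator plants shape differences.
* **DRES** — stochastic proximity embedding (SPE) of the pooled RMSD matrix
  into 6 dimensions: random disjoint point pairs are iteratively pulled
  toward/pushed from each other to match the input dissimilarities, with
  the neighbourhood radius annealed from the maximum dissimilarity to its
  1st percentile and the learning rate decaying geometrically from 1.0 to
  0.01 over 300 cycles of 16 sweeps. Pairing each point at most once per
  sweep keeps the vectorised updates consistent (simultaneous updates from
  stale positions are what make naive batched SPE diverge). Per-ensemble
  densities are Gaussian KDEs (Scott's rule bandwidth); the JSD is
  estimated by Monte-Carlo with 10⁴ samples per pair, clipped to
  [0, ln 2], and is deterministic for a fixed seed. Whether the original
  methodology estimated densities by KDE is not documented anywhere we
  could rely on; KDE is our documented choice. The default cycle/sweep
  counts are the point at which the embedding is converged enough that an
  ensemble compared against an identical copy scores ≈ 0.03 — comfortably
  identifiable as "identical" against the 0.69 ceiling.
* **Stride** — the O(n²) RMSD step strides the pooled frames to at most
  3000 by default (configurable).
* **Outlier replicates** — the pipeline flags (never removes) replicates
  whose mean off-diagonal JSD exceeds a configurable threshold
  (default 0.5); deciding to discard a replicate is the analyst's call.

## Protein structure networks

Per frame, an interaction exists when its geometric criterion holds:

| class | criterion |
|---|---|
| hydrophobic | side-chain heavy-atom COM distance < 0.65 nm, residues in {ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO} |
| hydrogen bond | donor–acceptor distance ≤ 0.35 nm **and** donor–H–acceptor angle > 120° |
| salt bridge | charged-group COM distance < 0.45 nm, opposite signs |

"Below"/"lower than" cutoffs are strict (<); the H-bond distance is read
as inclusive (≤). All cutoffs are configurable. Charged groups are the ASP
and GLU carboxylates, the LYS ammonium and the ARG guanidinium; HIS is
excluded by default because its protonation state is unknown from
coordinates. Whole-residue COM for the hydrophobic criterion is available
by flag (side-chain COM is the default; residues whose side chain has no
heavy atoms, like glycine, simply cannot form hydrophobic edges). Hydrogen
bonds need explicit hydrogens; when a topology has none, backbone amide
hydrogens can be inferred geometrically (flagged, and warned about), and
side-chain donors without hydrogens are skipped. Residue pairs adjacent in
sequence (|i−j| < 2 within a chain) are excluded to avoid trivially
persistent covalent-neighbour contacts.

An edge's weight is its persistence — the fraction of frames satisfying
the criterion — and edges below the persistence threshold (default 0.2, a
documented free parameter) are dropped. Hubs are nodes with degree ≥ 5
("more than four edges"); clusters are connected components (including
singletons, so every residue is accounted for); network comparison
partitions mapped edges into shared/only-in-a/only-in-b, reports edges with
unmapped endpoints separately, and can exclude mainchain–mainchain H-bonds
from the polar counts. Edge-count summaries are a reporting feature, not a
validated quantity: the persistence cutoff behind published count tables
for this enzyme pair is not stated anywhere recoverable.

## Sequence classification

The two targets are compared column by column in a labeled alignment.
Psychrophilic and psychrotolerant sequences are pooled into one cold group
by default (separable by flag). Group consensus excludes the two targets
themselves — a substitution is only evidence of adaptation when echoed by
*other* organisms of the same thermal class. A substitution is a
*candidate* when both groups are conserved (modal frequency ≥ cutoff,
default 0.8 — "conserved" is never quantified in the literature this
mirrors, so the cutoff is a documented free parameter) on different
residues and each target matches its own group's mode; *drift* when the
mesophilic group is heterogeneous or both groups share the same modal
residue; *indeterminate* otherwise (including targets-only groups).
Raising the cutoff can only demote candidates, never promote drift — a
tested monotonicity. An optional similarity-class mode compares residues
through substitution groups (V/I/L, S/T, D/E, K/R, F/Y/W, N/Q) instead of
exact identity; exact identity is the default. Composition deltas count
ungapped target sequences per residue type, with grouped summaries over a
documented (overlapping) class table: charged DEKRH, polar STNQCY,
hydrophobic AVLIMFWP, aromatic FYWH.

## Synthetic-data conditions

The generators are pure functions of their spec and seed (one named RNG
stream per call, no global state) and write standard formats so synthetic
data flows through the same readers as real data.

* **Harmonic ensembles** — frames = reference + Σₘ aₘ z vₘ + isotropic
  noise with orthonormal modes; the expected RMSF (σ√3 per coordinate
  noise) and covariance trace (Σ aₘ² + 3Nσ²) are known in closed form and
  recovered within 5% at 5000 frames in the tests. Planted modes used for
  RMSF recovery are orthogonalised against the six rigid-body motions,
  since superposition necessarily absorbs those components.
* **Basin mixtures** — each frame picks a basin by the ensemble's weight
  vector and adds isotropic jitter. Basin references are generated with a
  prescribed *fitted* RMSD separation (shape difference, not translation),
  and the spec validates separation with fitted RMSD for the same reason.
  Disjoint weights give the ln 2 similarity endpoint; identical weights
  give 0; planted weights are recovered within binomial error.
* **Contact peptides** — four-residue toys (interacting side chains on
  residues 1 and 4, glycine scaffold between) built from idealised
  geometry, not a force field — only the geometric predicates matter. The
  interaction criterion holds in exactly round(p·n) frames by construction
  (deterministic frame toggling rather than Bernoulli sampling, so
  persistence recovery is an exact test), with sub-angstrom jitter that
  cannot cross any cutoff.
* **Labeled alignments** — planted candidate columns fix different
  residues across the two thermal groups; planted drift columns make the
  mesophilic group heterogeneous; everything else is identical across
  sequences, so candidate recovery has precision = recall = 1 by
  construction.

What the generators do **not** emulate: real fold topology, anisotropic or
correlated basin shapes, solvent and force-field energetics, alignment
gaps/indels beyond the target pair, or phylogenetic correlation between
group sequences. Passing tests therefore demonstrate correctness of the
measurement machinery under controlled conditions, not biological
conclusions about any particular enzyme pair.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale problems: 10–50 residue
Cα chains, 200–5000 frames, 500–1000 frames per ensemble for the
similarity endpoints (pooled matrices ≤ 2000 frames). Closed-form
recoveries are asserted at 3–5% at 5000 frames; stochastic DRES endpoints
at ±0.05; exact constructions (planted persistence, planted candidates,
analytic RMSIP/CES endpoints) exactly or to 1e-9. Degenerate inputs are
defined behaviour: constant trajectories give zero RMSF/eigenvalues (not
errors), a single frame has undefined variance (error), collinear or
sub-3-atom selections are degenerate fits (error), and an all-frames
single-cluster CES gives JSD 0 with a log message.

## Known limitations

* Binary trajectory formats (XTC/DCD) are not read; multi-model PDB is the
  ensemble interchange format (an adapter behind the same reader contract
  is the intended extension point).
* H-bond detection with inferred hydrogens covers backbone amides only.
* The pipeline's PSN stage pools all replicates of a system before
  computing persistence; per-replicate networks are available through the
  library API.
* PNG heatmaps cannot carry the config-hash stamp that text artifacts
  have; the manifest records it for all outputs.
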