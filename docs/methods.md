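# Methods

This note documents the models and procedures implemented in
`tunneltransit`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data
validation does and does not demonstrate.

## Landmark geometry and regions

All positional information is reduced to centre-of-mass (COM) distances:
ligand↔catalytic machinery (d_cat), ligand↔bottleneck of each tunnel T
(d_bt[T]), and catalytic↔bottleneck (the instantaneous tunnel length
L[T]).  COMs are mass-weighted when masses are available and geometric
otherwise, selectable by flag; the two differ negligibly for compact
residue groups, and both modes are provided because common practice
varies.  L[T] is recomputed every frame rather than taken from a static
structure — landmark stability is a property of the input, not an
assumption of the code — with a static-length option for quick checks.

Regions are classified from d_cat alone: cavity [0, r_cavity], tunnel
(r_cavity, r_bulk], bulk (r_bulk, ∞), with defaults r_cavity = 5 Å and
r_bulk = 19 Å (the latter reflecting the average length of the tunnels
of the system this pipeline was built around; both are plain
configuration values).  Closed/overlapping range notations are resolved
half-open-above, so a frame exactly at a cutoff belongs to the inner
region.  Distances are in Å and times in ps internally; reports use ns.

## Transit tracking

Per frame, with T\* the tunnel of the closest bottleneck (ties broken by
the declaration order of tunnels in the configuration), L = L[T\*] and
d = d_cat:

* `out_` if d > L + bt_cutoff_along (default 2 Å);
* `in_` if d < L − bt_cutoff_along;
* otherwise the bottleneck band: `bt_`(T\*) if d_bt[T\*] ≤
  bt_cutoff_across (default 5 Å), else `bt_unknown`.

Band boundaries are inclusive (equality falls in the band), and the
across-check governs `bt_` vs `bt_unknown` on both sides of the
bottleneck — the lateral criterion is about proximity to a known
bottleneck, not about which side the ligand approaches from.

The transition detector is a small state machine over this sequence.  It
remembers the side (`in`/`out`) of the last general frame and, while the
ligand is banded, a temporary bottleneck label rewritten on every band
frame (last write wins).  Reaching the opposite side completes an event;
returning to the origin side discards the band visit; leading band
frames before any general frame produce nothing.  Direct crossings take
the common closest tunnel of their two endpoint frames; when the
endpoints disagree, a side may be relabelled to the other side's tunnel
if that tunnel's bottleneck distance is within dist_tolerance (default
1 Å) of the side's own minimum — the destination side is tried first,
then the origin side, deterministically — and irreconcilable crossings
are *mixed*.  Band-mediated crossings take the temporary label at the
last band frame (*unknown* if it was `bt_unknown`); a band visit that
alternates known/unknown is therefore resolved by its final frame, and
the bottleneck label always wins over the endpoints for mediated events.
Every completed crossing counts once; repeated crossings are separate
events.  Scheme-level summaries use the sample standard deviation
(ddof = 1) over replicate totals.

The state machine is verified against an independent brute-force
enumerator (pair consecutive general-state frames with differing sides;
classify from the raw frames between them) on thousands of random state
sequences; the two agree exactly, including event frame spans.

## Markov-state-model stage

Featurised trajectories (by default the 1 + n_tunnels distance columns)
pass through:

1. **TICA** — symmetrised estimator: C(0) and C(τ) averaged over both
   time directions, generalised eigenproblem C(τ)v = λC(0)v, a ridge of
   1e-6 on C(0) for conditioning (no Koopman reweighting).  Components
   are ordered by eigenvalue; signs are fixed by making each component's
   largest-magnitude loading positive.  Default lag 2 ns, converted to
   frames via the frame interval.
2. **Microstates** — mini-batch k-means with a fixed seed (bit-identical
   assignments across calls); k defaults to 1000 and is clamped to the
   number of distinct points.
3. **Counting** — sliding-window counts at lag τ (default 20 ns);
   trajectories are never concatenated, so no pair spans a boundary.
   Estimation is restricted to the largest strongly connected component
   (preferring the component carrying the most counts).
4. **Transition matrix** — default reversible estimate: symmetrise the
   counts, (C + Cᵀ)/2, then row-normalise, which makes the row-sum
   distribution stationary and enforces detailed balance exactly; the
   non-reversible per-row MLE is available.  π comes from the row sums
   (reversible) or the leading left eigenvector (non-reversible).
5. **Validation** — implied timescales t_i(τ) = −τ/ln λ_i(τ) across
   lags (complex eigenvalues reported by modulus with a warning), and a
   Chapman–Kolmogorov test comparing macrostate self-transition
   probabilities of (P(τ))^k against a re-estimate at kτ, with a 95%
   band from bootstrap resampling of whole trajectories.
6. **Lumping** — k-means on the leading n right eigenvectors of P
   (π-weighted, column-normalised), a crisp simplification of
   PCCA++-style fuzzy membership built on the same invariant subspace.
   When the number of metastable states is not given it is chosen by
   the largest gap in the eigenvalue moduli (2–8 states); this is a
   heuristic and is flagged as such.
7. **MFPT and rates** — linear system m_i = 0 on the sink,
   m_i = τ + Σ_j P_ij m_j elsewhere; the reported MFPT is the π-weighted
   average over the source set.  k_on = 1/MFPT_on, k_off = 1/MFPT_off,
   K_d = k_off/k_on = MFPT_on/MFPT_off.  K_d is reported as this
   dimensionless ratio: converting to a molar constant requires a
   simulation-volume/standard-state correction that is left to the user.
   In the full pipeline the sink is the metastable state most prevalent
   inside the cavity (largest fraction of frames with d_cat ≤ r_cavity)
   and the source the states predominantly in bulk (> 50% of frames
   beyond r_bulk, falling back to the farthest median); both are
   overridable.

## Unified ligand states

Each metastable state is summarised by the mean and 25th/50th/75th
percentiles of its representative d_cat and d_bt distributions —
20 ordered values for a four-tunnel network.  Percentiles use linear
interpolation between order statistics.  Fingerprint columns are
standardised before PCA by default (they share units but differ widely
in spread; a flag disables this), the first three components are kept,
and HDBSCAN with min_cluster_size = 2 clusters the scores.  Noise points
become singleton states — real data does produce states seen in only
one replicate, and they must remain visible.  Two degenerate inputs are
handled explicitly: coincident points form one cluster, and when the
default tree labels *everything* noise (a single dense group plus
outliers, which HDBSCAN's root-cluster rule refuses) the clustering is
retried allowing a single cluster before falling back to all-singletons.
Cluster labels are renumbered by size then first-member order for
reproducibility.

## Seeding

Bulk-scheme seed candidates form an nx × ny × nz grid (default 5×5×5)
over the protein's bounding box expanded by a padding (default 5 Å).
Grid points sit at cell centres; the drawing routine this mirrors leaves
the lattice registration unspecified, so a corner-lattice mode is
available by flag.  Candidates within min_clash_dist of any protein atom
are dropped — 3 Å by default, roughly van-der-Waals contact, a value
this package chooses itself — and the survivors are ranked by distance
to the protein (most solvent-exposed first) with a seeded tie-break.

## Synthetic data and what it shows

The generators produce exactly the statistical structure the analysis
assumes: scripted ligand walks along tunnel axes with Gaussian jitter
(default sd 0.3 Å) and, in clean mode, a margin of 2·noise_sd (at least
0.5 Å) around every decision boundary; Markov chains with known
transition matrices mapped to jittered feature-space centres; and
metastable ensembles drawn around separated distance profiles.  They do
**not** emulate real MD: no force field, no correlated protein motion,
no landmark fluctuation, no tunnel gating, and band crossings follow
straight axes.  Passing tests therefore demonstrate the correctness of
the bookkeeping — state assignment, event detection, counting, matrix
estimation, MFPT algebra, clustering — not robustness to structural
noise sources absent from the generator.  Hard mode (margins removed)
exercises the tolerance rules near boundaries.

Validation problem sizes were chosen to make sampling error small
relative to the tolerances being checked: 50 planted transits across 10
walks, 1000 random sequences for oracle equivalence, 10^5 steps for
transition-matrix recovery (entries within 3 s.e., MFPTs within 5%,
K_d within 10%), 10^5 Monte-Carlo walkers for the MFPT cross-check
(agreement within 2 s.e.), 20×3000 and 50×2000 frames for the
Chapman–Kolmogorov contrast between Markovian data and a heavy-tailed
(Pareto-dwell) semi-Markov plant, and 10^4 frames for the 20/30/50%
region-occupancy recovery within 1%.

## Known limitations

* The spectral lumping is crisp; genuinely fuzzy membership (transition
  regions shared between basins) is squeezed into hard assignments.
* The reversible estimator symmetrises counts rather than maximising
  the reversible likelihood; for well-sampled data the difference is
  small, but it is not the constrained MLE.
* K_d has no unit conversion; comparisons with experimental molar
  values require a standard-state correction.
* The automatic metastable-state count (largest spectral gap) can be
  unstable when the spectrum decays smoothly; inspect the implied
  timescales and set it explicitly when it matters.
* No trajectory alignment, periodic-boundary imaging, or geometric
  tunnel detection: inputs are assumed imaged, and the tunnel network
  definition (landmark residue groups) is the user's responsibility.
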