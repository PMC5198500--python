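# Methods

This note documents the models, algorithmic choices and their parameters,
what the synthetic generators emulate, and the limits of what the test
suite demonstrates.

## Profiles

**State profiles.** A state profile maps a 3D model to a vector of discrete
states over a fixed alphabet; all models of an ensemble must have equal
residue counts so profiles align positionally. Alignment is positional
(0-based internally, 1-based in file reports): author residue numbering in
PDB inputs is ignored, because fixed-length profile comparison requires
that position i mean the same residue in every model.

- `ss-sa` — DSSP 8-class secondary structure collapsed to {H, E, C}
  (H,G,I→H; E,B→E; else C) crossed with relative solvent accessibility
  binned into up to 10 equal-width bins on [0, 1] (rsa = 1 clamps into the
  top bin). RSA = ACC / max-ASA with the Tien et al. theoretical max-ASA
  scale; the scale is a fixed documented constant, not configurable at run
  time. Composite state = ss_index·n_bins + sa_bin (30 states at the
  default 10 bins).
- `ca-ss-nc` — pseudo-secondary-structure from a Cα trace: residue i is H
  when d(CAᵢ, CAᵢ₊₃) < 6.0 Å (ideal α-helices give ≈ 5.1 Å), E when
  d(CAᵢ, CAᵢ₊₂) > 6.2 Å (extended chains give ≈ 7.6 Å), else C; chain-end
  residues for which the test is undefined default to C. The thresholds
  separate ideal helix/strand geometry and are keyword-configurable. The
  contact number counts Cα atoms within 10 Å excluding chain neighbours
  |i−j| ≤ 2 and saturates at bin 9.
- `ca-cm` / `rna-p-cm` — the upper triangle of the binary long-range
  contact map: positions are the ordered pairs (i, j), i < j, j−i ≥ 12,
  enumerated row-major; state 1 iff d < 8.5 Å (Cα) or 15.5 Å (P), with a
  strict inequality at the cutoff. Profile length is
  (L−12)(L−11)/2.
- `rna-ss-lw` / `rna-ss-ta` — stem/loop crossed with a 15-label coarse
  base-pair classification (or with 5 torsion classes). The 15-label set
  {cWW, tWW, cWH, tWH, cWS, tWS, cHH, tHH, cHS, tHS, cSS, tSS, bifurcated,
  water-inserted, Other} covers edge/orientation combinations plus the
  catch-all; unpaired residues carry Other. The label set is configurable
  at ingestion because annotation tools differ in their vocabulary.
  External assignment tools (DSSP-style, base-pair and torsion annotators)
  are ingested as files; they are never executed as subprocesses.
- `fragbag` — bag-of-fragments: every contiguous backbone window of the
  library's fragment length is assigned to the library fragment of minimum
  Kabsch RMSD (ties to the lowest fragment index) and the counts are
  accumulated; the vector is length-independent, so arbitrary structures
  can be compared. Tests use small synthetic libraries; any library in the
  documented block format (header line + one x y z line per point) works,
  including 400-fragment 11-mer protein or 92-fragment 5-mer RNA
  libraries.

Whether the SS/SA combination should be a composite per-residue state or
two concatenated sub-profiles is not observable from jury scores up to
position weighting; the composite encoding is used throughout.

## Jury ranking

score(m) = Σ_p counts[p][state_m(p)], where counts is the L×S per-position
state tally. This equals Σ_{m′} #(positions where m and m′ agree) including
the self term, which adds the constant L to every score and cannot change
the ranking; the self-inclusive form is kept because it is the plain
frequency sum. Ties rank by input order, so results are deterministic with
no hidden randomness. Positions and states are unweighted. For frequency
profiles, score(m) = v̂_m · Σ v̂_{m′} over unit-normalised vectors — the
summed cosine similarity — computed against the accumulated sum vector.

## Hashing

Keys are exact bitstrings (bit p = 1 iff the model differs from the
reference at p); grouping is exact equality, never locality-sensitive
approximation. The jury reference provably minimises the total key
popcount over all member references (its score maximises total agreement).
Frequency profiles enter the hashing path through per-dimension count
quantisation with default edges (1, 2, 4, 8) → bins 0, 1, 2–3, 4–7, ≥8;
the discretisation is configurable since nothing canonical fixes it.

## Clustering heuristics

**Hash(K, F).** Per-position key-bit entropies never change as positions
are dropped, so the removal order (descending entropy, ties to the lowest
index) is fixed up front; the loop regroups after each removal and stops
when the K largest groups cover F% of the models. If the target is
unreachable the best coverage seen is returned with a warning — K takes
precedence over F. Cluster centroids are the members with the highest
within-group jury score. Note that on *balanced* planted clusters the
high-entropy positions are exactly the cluster-discriminating ones, so
demanding coverage far above the natural plateau (e.g. 90% on a 3-balanced
fixture with 5% noise) forces cluster merging; the operating points used
in practice (F ≈ 60 for flat clustering, F = 100 with large K for tree
seeding) do not hit this regime.

**Rpart(K, F).** Works on binary keys; distances are Hamming distances
between key bitstrings. Up to K spheres are peeled off: the first is
centred on the jury reference with the bracketing radius r; each next
reference is the unassigned model of highest global jury score among
models closer than 2·r₀ (twice the *initial* radius, r₀ = ⌈D_max/4⌉ with
D_max the maximum distance to the jury reference) to the original
reference — falling back to all unassigned models when that window is
empty — and its sphere radius is its distance from the original reference
rescaled by r/r₀. At r = r₀ this is exactly the plain reset-to-distance
rule; the rescaling is what the outer loop adjusts. The outer loop is an
integer bisection on r over [1, D_max]: increase while coverage < F,
decrease once coverage ≥ F, returning the most granular (smallest-radius)
solution that attains F. Coverage at r = D_max is always 100%, so the
search cannot fail for F ≤ 100. Jury scores are computed once on the full
set, not per remainder, preserving the linear-time budget. Coverage
comparisons use a 0.5-percentage-point tolerance. All-identical inputs
yield a single cluster at coverage 100 (reported, not an error). A caveat
inherent to binary-key geometry: for alphabets with S > 2 states, two
non-reference clusters are closer to *each other* in key space
(≈ 2(L/S)(1−1/S)) than to the reference (≈ (1−1/S)L), so sphere-based
partitioning cannot separate them regardless of schedule; with binary
profiles (contact maps — the profile family this heuristic is normally
paired with) key space is isometric to profile space and the issue does
not arise.

**Tree.** Micro-clusters come from Hash or Rpart run with (K = k_micro,
F = 100), default k_micro = 1000; any models the seeding pass leaves
unassigned become singleton leaves so the dendrogram always covers the
ensemble. Each leaf is represented by its within-cluster jury centroid,
and unweighted average-linkage agglomeration (scipy) runs on the
centroid-to-centroid distances — Hamming on state profiles, cosine on
frequency profiles, or Kabsch RMSD on centroid coordinates (only
representatives are ever superimposed). A size-weighted Lance–Williams
variant is available as an option but is not the default, since plain
average linkage over representatives is the documented behaviour. When
every model is its own leaf the construction reduces exactly to full
average-linkage hierarchical clustering. Cutting removes the k−1 highest
merges (union–find over the remaining merge list); members inherit their
leaf's label. Where merge heights tie, any average-linkage implementation
may order the tied merges differently, so cut partitions are only defined
up to ties — cophenetic distances are the tie-safe equivalence.

**k-medoids.** PAM-style alternation with a seeded random first medoid and
farthest-point completion of the remaining K−1. Purely random medoid draws
can select duplicate items (zero mutual distance) and permanently strand a
cluster; farthest-point completion avoids this while remaining
deterministic for a fixed seed. Convergence: assignments and medoids
stable, or 100 iterations.

## Similarity kernels

- Kabsch superposition by SVD with the determinant correction, so only
  proper rotations are returned and chirality is preserved. Degenerate
  (colinear) point sets still return a solution; the rotation is then not
  unique. At least 3 points are required.
- MaxSub with d₀ = 3.5 Å, seed length 4, 4 refinement iterations, and the
  normalised score Σ_{i∈M} 1/(1+(dᵢ/d₀)²) / L: each contiguous seed is
  superimposed, the match set grows over iterations with threshold
  d₀·(iter/4) (reaching d₀), re-superimposing each round; the seed residues
  are always retained so the superposition never degenerates below 3
  points. All four parameters are keyword-configurable. Lengths must be
  equal (fixed-length mode), so the model-vs-reference normalisation
  question does not arise.

## Synthetic data generators

The generators define the study conditions for every test:

- `generate_ensemble(template, n_clusters, per_cluster, conformer_shift,
  noise_sigma, seed)` emulates an ensemble with planted conformational
  clusters: each base conformer is an independent smooth deformation of the
  template (a rigid hinge rotation at a random interior residue plus a
  low-frequency sinusoidal displacement, rescaled to RMS magnitude
  `conformer_shift`); members add i.i.d. Gaussian coordinate noise with
  sigma `noise_sigma`. Hinge-plus-bend deformations change both long-range
  contacts and RMSD, so the planted clusters are visible to contact-map
  and superposition metrics alike. Reference conditions used in the
  concordance experiment: 60 residues, 3 conformers × 1000 models,
  shift 8 Å, noise 0.5 Å.
- `compact_trace(n, seed)` supplies the template: a fixed-bond (3.8 Å)
  smooth random walk confined to a sphere at the empirical globular-protein
  radius-of-gyration scale (2.2·n^0.38 Å). A compact template is essential
  for contact-map profiles: an ideal straight helix has *no* contacts at
  sequence separation > 11, making its contact-map profile identically
  zero.
- `generate_profile_set(n, length, n_states, n_clusters, flip_prob, seed)`
  emulates categorical profile matrices with planted structure: archetypes
  drawn uniformly, members resampling each position to a uniformly random
  *other* state with probability `flip_prob` (so member–archetype Hamming
  distance is Binomial(L, p)). Reference conditions: N = 300, L = 60,
  3 balanced clusters, flip probability 0.05.

What the generators do **not** emulate: real decoy ensembles are not
balanced mixtures of equally-populated conformers — they typically have a
dominant consensus basin, heavy-tailed quality distributions, physically
correlated (not i.i.d.) coordinate noise, and profile positions with
correlated states. Passing the planted-recovery tests therefore shows the
heuristics are implemented correctly and behave as designed on separable
data, not that they will reach any particular accuracy on real prediction
benchmarks.

## Numerical and interface choices

- Determinism everywhere: every random choice flows from an explicit seed;
  ties break by input order or lowest index; reruns of the CLI with the
  same inputs and configuration are byte-identical.
- Coverage tolerance 0.5 percentage points; dendrogram height comparisons
  at 1e-9 relative tolerance; pairwise Hamming matrices computed by BLAS
  identities (|x|+|y|−2x·y for binary, per-state indicator products
  otherwise) and rounded back to exact integers.
- PDB ingestion via Biopython (first altloc kept, heteroatoms/waters
  skipped, insertion codes honoured in file order); writing via plain ATOM
  records at the format's 3-decimal precision. A whitespace xyz table
  (model_id, residue_index, x, y, z) is supported as a lightweight
  alternative. DCD/mmCIF are out of scope.
- The problem sizes in the tests (ensembles up to 3×1000 models of 60
  residues; 200 random jury instances up to N = 200) were chosen as the
  smallest scales at which the linear-vs-quadratic contrast and the
  concordance behaviour are cleanly measurable.

## Known limitations

- Hash(K, F) cannot reach high coverage on balanced well-separated
  clusters without merging them (see above); it is a granularity heuristic,
  not a model-based clustering.
- Rpart's sphere geometry degrades for multi-state alphabets (S > 2) as
  analysed above.
- MaxSub is exhaustive over seeds (O(L) superpositions of O(L) points per
  pair) — adequate for evaluation use, not tuned for all-pairs scoring of
  large ensembles; that is precisely what the profile pipeline avoids.
- The 1D-jury consensus assumes the ensemble's plurality is near the truth;
  on adversarial ensembles dominated by a wrong basin the reference will
  sit in that basin.
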