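# Methods

## The model

### Contact potential (CP)

Given a set of residue–residue contacts, the contact potential assigns each
amino-acid pair the log-odds pseudo-energy

    E(a,b) = -log[(N_obs(a,b) + eps) / (N_exp(a,b) + eps)],
    N_exp(a,b) = N_obs(a) * N_obs(b) * H(a,b) / N,

where `N_obs(a,b)` counts contacts between `a` and `b` in either order
(homotypic contacts once), `N_obs(a)` counts occurrences of amino acid `a` over
both contact slots, `N` is the total number of residues in the contact set
(twice the contact count), and `H(a,b) = 2 - 1[a=b]` doubles the heterotypic
expectation so the potential is directionless.

One property worth knowing: summed over unordered pairs this reference state
equals **twice** the contact count, so under pair-independent sampling the
potential sits at a uniform `+log 2` rather than at zero. A statistical
potential is defined only up to an additive constant — rankings, correlations,
and modified z-scores are all shift-invariant — but tests of the null
expectation must compare against `log 2`, and the package's null checks do.

### Contact degree (CD)

A contact is quantified by the probability-weighted fraction of mutually
interfering rotamer pairs. All rotamers of all amino acids are built onto both
backbone positions; rotamers whose side-chain heavy atoms come within 2.5 Å of
the main chain of non-adjacent residues are disallowed; two surviving rotamers
interfere when any pair of their heavy atoms is within 3 Å. Then

    CD(p_i, p_j) = sum_{a,b} sum_{r_i, r_j} C(r_i, r_j) P(a) P(b) P(r_i) P(r_j),

with `C` the interference indicator. Rotamer probabilities of disallowed
rotamers are *not* renormalized by default (heavily occluded positions
contribute less mass); a renormalized mode exists behind a flag. `P(a)`
defaults to the amino-acid frequencies of the loaded structure database, with
uniform and user-supplied alternatives. CD-balanced contact databases sample an
equal number of contacts from the 11 bins `[0, 2^-10), [2^-10, 2^-9), …,
[2^-1, 1]`.

Side-chain templates are built from chi angles plus idealized internal
coordinates (Engh–Huber-style bond lengths/angles, planar ring approximations),
verified against CCD ideal residue geometry to within ~0.1 Å at the branch
points. A minimal bundled rotamer set (1–4 rotamers per amino acid at common
chi values) serves tests and desk-scale runs; Dunbrack-style backbone-dependent
tables are loadable.

### Structure-conditioned energies (SCE)

For an interaction motif — two backbone segments of 2k+1 residues centered on a
contacting pair, k ∈ {0, 1, 2} — the match ensemble is every same-size
two-segment fragment of the search database within a best-fit backbone RMSD
cutoff of the query (default cutoffs 1.0 / 0.79 / 0.77 Å for k = 0 / 1 / 2,
max count 50,000; all four backbone atoms N, CA, C, O enter the superposition).
Both assignments of query segments to candidate windows are scored and the
better kept, with swapped matches contributing transposed pair counts. The SCE
matrix is

    SCE(a_i, a_j) = -log[(N_obs(a_i,a_j) + eps) / (N_exp(a_i,a_j) + eps)]

over the ensemble's central-pair counts, an *ordered* 20×20 matrix
(symmetrize before comparing with a CP).

The expected counts assume first-order preferences only. Per match m and
position, the background model E1 gives a softmax probability
`q_m(a) ∝ exp(-E1(a|m))`; a residual energy
`Delta(a) = -ln[(N_o(a)+delta)/(N_e(a)+delta)]` (with `N_e(a) = sum_m q_m(a)`,
smoothing `delta = 0.1` counts) pins the expected marginals to the observed
ones, and

    N_exp(a_i, a_j) = sum_m p_m(a_i at i) p_m(a_j at j),
    p_m(a) ∝ exp(-E1(a|m) - Delta(a)).

The correction is applied once (not iterated); the expected counts conserve the
ensemble size exactly, and with a flat background they reduce in closed form to
`N_o(a_i) N_o(a_j) / |M|`, making the SCE the plain log-odds against the
product of observed marginals — both properties are tested to machine
precision.

The per-pair pseudocount is `eps = max(N_obs, N_exp, 1)/20`, which bounds |SCE|
at `log 21 ≈ 3.04` for zero-count pairs; fixed-count (0.05) and Laplace (1)
alternatives are selectable. Ensembles below 1,000 matches trigger a sparsity
warning; the desk-scale analyses in this repository run far below that bound on
purpose and the note below discusses what that implies.

### Background model E1

Three conditional log-odds tiers, trained in sequence: (1) amino-acid
propensities over 10°×10° phi/psi bins (half-open `(lo, hi]`, −180 mapped into
the first bin); (2) omega propensities over cis ([−30°, 30°]) / trans bins,
conditioned on phi/psi expectations, with bins under 50 observations merged
away; (3) burial propensities conditioned on both. Burial is the count of CA
atoms within 12 Å excluding ±1 sequence neighbors, cut into 5 training-set
quantile levels (degenerate quantile edges are dropped). The modeling content
lies in the hierarchy of conditional tiers; the burial metric itself is a
standard coordination-number proxy chosen here. Pseudocount: 1 count per cell.
Descriptors missing at evaluation time (chain termini) drop the corresponding
tier.

### Evaluation and clustering

* *Identification*: the native pair is identified when it has the lowest
  energy of all 400; ranks break ties lexicographically; enrichment is the
  identified fraction over the 1/400 chance rate. The modified z-score is
  `(E_pair - median E) / MAD` over the 400 entries.
* *Model scoring*: every contact with CD ≥ 0.1 contributes the SCE of the
  model's own amino-acid pair from a fresh ensemble search; the score is the
  mean over contacts (mean CE from a contact potential on the same contacts as
  control). Contacts whose ensembles fall below a match floor are skipped.
* *ROC/AUC*: positives by quality threshold (≥ for GDT_TS-like, ≤ for
  RMSD-like metrics), classifier score = negated mean energy, trapezoid AUC
  with midrank tie handling (equals the Mann–Whitney U statistic; cross-checked
  against scikit-learn in tests).
* *Clustering*: greedy radius clustering — per round, sample n items, pick the
  sampled item with the most sampled neighbors within d as medoid, absorb
  everything within d, remove. Defaults d = 0.5 Å (structure) and 0.3
  (energetic distance r_E = 1 − Pearson r over the 400 entries, computed on
  symmetrized matrices), 100 rounds. The per-round sample size n is a free
  parameter; the default is 1,000 (effectively exhaustive at desk scale).
  Random controls repartition the items into size-matched clusters.

## Synthetic data: what it emulates and what it does not

The package ships a generator suite so every claim is testable without any
structure database:

* **Backbones from internal coordinates** (standard bond lengths/angles,
  omega = 180°), helix/strand templates with Gaussian dihedral noise; the
  builder round-trips phi/psi/omega exactly and produces right-handed helices.
* **Planted Potts ensembles**: central-pair sequences drawn exactly (by
  enumeration of the 400 outcomes) from
  `P(a,b) ∝ exp(-h_i(a) - h_j(b) - J(a,b))`. The known J is the ground truth
  for recovery tests; couplings are compared after double-centering, the gauge
  in which pair statistics identify J.
* **The geometry-coupled world**: structures holding six independent
  helix–strand contact units (60 Å apart). Within a unit, the strand's central
  CA sits 6.5 Å along the helix's central CB direction with its own CB facing
  back, and a latent coordinate theta ∈ [0, 1] spins the strand about the
  contact axis by up to 3 radians — motif RMSD grows nearly linearly with spin
  difference while the contact itself is preserved. The coupling field
  J(theta) is an RBF mixture of random symmetric matrices (correlation length
  0.15 in theta, entry scale 2.5), so structural similarity and energetic
  similarity are coupled by construction. Central-pair marginals are
  Sinkhorn-flattened: fields are chosen so each position's composition is
  uniform, isolating the second-order signal (pair statistics cannot identify
  the row/column gauge anyway). Using two different segment types keeps the
  motif asymmetric, so swapped segment assignment never aliases distant spin
  angles into one another's ensembles. Sequences elsewhere are uniform random.
* **Decoys**: Gaussian-coordinate decoys (label = backbone RMSD to native) and
  rigid placement decoys that rotate mobile chains about their contact axes by
  graded angles. The placement decoys drive the model-scoring experiment:
  realistic model errors keep local covalent geometry ideal while relative
  placement drifts, whereas isotropic per-atom noise produces non-protein
  backbones that leave fragment-searchable space at small amplitudes.

What passing these tests shows: the estimators are exact (oracle equivalence),
unbiased under their nulls, able to read back planted couplings, and the
qualitative structure–energy relationships hold end to end through real
searches, CD computation, and background training. What they do not show:
behavior on real protein diversity (loop geometries, heterogeneous
compositions, crystallographic artifacts), absolute energy scales comparable
with full-database analyses, or behavior at full-database ensemble sizes
(desk-scale ensembles hold ~10² matches, not 10³–10⁴).

## Study conditions of the shipped experiments

Sizes were chosen once to keep every experiment in the seconds-to-minutes
range on one CPU:

* CP null: 20,000 product-distributed contacts; deviations tested against the
  analytic `log 2` offset on the Poisson noise scale.
* SCE null: 100 ensembles × 10,000 matches, uniform product distribution. A
  single ensemble's entrywise noise is `~1/sqrt(M/400) ≈ 0.2`, so the
  zero-expectation claim is asserted on the ensemble-averaged matrix (noise
  ~0.02); individual ensembles are checked against their own noise scale.
  Skewed null marginals are avoided deliberately: rare cells would carry a
  small-count Jensen bias of order `1/(2 N_exp)`, a property of any log-ratio
  estimator rather than of this implementation.
* Coupling recovery: one ensemble of 5,000 matches, J entries N(0, 1).
* Convergence: 100 ensembles × 1,000 matches sharing one planted model
  (10⁵ pooled draws) against the pooled-contact CP.
* Identification: 40 geometric contexts, each with one strongly favored
  context-specific pair (coupling −4) over a flat landscape and a 5,000-match
  ensemble — the analog of sharply geometry-dependent interactions such as
  disulfides, which poison a pooled CP but not the SCP.
* Coupled world: 400 structures × 6 units; SCE matrices for 110 query motifs
  (flank 1, default 0.79 Å cutoff, ensembles of roughly 150–600 matches);
  greedy clustering with exhaustive per-round sampling; decoys over 6 targets ×
  5 spin levels (0.2–1.05 rad, spaced to sample the coupling-decay curve
  evenly) × 3 replicas plus natives, scored with a 20-match ensemble floor and
  centered per target before pooling (planted coupling magnitudes differ
  between targets, so raw offsets encode target identity, not quality).

## Numerical choices and degenerate inputs

* Alternate locations resolve to the highest-occupancy conformer; chain breaks
  (C–N beyond 2.0 Å) terminate dihedral computation like termini.
* Kabsch RMSD uses the singular-value form with the proper-rotation sign
  correction; the batched path is bit-compatible with the single-pair path and
  agrees with an independent quaternion (Horn) implementation to 1e-9 Å. The
  central-CA prefilter uses the conservative bound |Δd| ≤ 2√n·RMSD and is
  asserted to never change search results.
* Search ties (equal RMSD) break by (structure id, segment addresses);
  candidate windows pair within one structure only, same-chain windows
  separated by at least one residue.
* Degenerate cases are flagged rather than fudged: constant energy matrices
  give NaN modified z-scores, zero-variance matrices give NaN r_E, one-sided
  quality labels give NaN AUC, motifs with no qualifying contacts give empty
  model scores, positions with no placeable rotamers give CD 0 with a logged
  warning.

## Known limitations

* The fragment search is an exhaustive scan with a distance prefilter — correct
  and index-accelerated for repeated queries, but not built for
  full-PDB-scale databases.
* The bundled rotamer fixture is backbone-independent and sparse; absolute CD
  values depend on the library used and should not be compared across
  libraries.
* The omega tier defaults to cis/trans only, and the burial metric is a simple
  coordination count; both are configurable but deliberately plain.
* Sequence-identity filtering of input chain lists is the caller's
  responsibility (standard culling servers do this well); the chain filter
  enforces only length and resolution bounds.
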