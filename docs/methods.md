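# Methods

## Model

`locrec` predicts ranked multi-label subcellular localizations with a
network-based inference (NBI) recommender. The training data form a
bipartite graph between proteins and locations; its n×m binary incidence
`A` has protein degrees `d(p_t)` (number of annotated locations) and
location degrees `d(l_j)` (number of annotated proteins). A two-step
resource-allocation walk — each location splits one unit of resource
equally among its proteins, each protein splits what it received equally
among its locations — yields the m×m transfer matrix

    w_ij = (1 / d(l_j)) · Σ_t a_ti a_tj / d(p_t).

Two exact algebraic identities follow whenever all degrees are positive,
and are enforced as type invariants and verified against an explicit
edge-enumeration oracle in the tests:

* **column-stochasticity** — every column of `W` sums to 1;
* **mass conservation** — row k of `R = A·Wᵀ` sums to `d(p_k)`.

A query protein outside the network is scored as `Pred(p) = S(p)·R`, where
`S(p)` holds its interaction scores against the training proteins in [0, 1]
(missing pairs are 0). Scores are divided by their maximum, sorted
descending, and locations with normalized score ≥ τ are reported. The walk
never needs iteration or convergence machinery: `W` and `R` are closed-form
matrix products, so predictions are exact and deterministic.

### Assumptions

* Interacting (or sequence-similar) proteins tend to share compartments —
  the signal `S(p)·R` exploits; if the similarity source is uninformative
  the prediction degenerates to a prevalence-driven ranking.
* Annotations are trustworthy positives; absence of an annotation is not
  treated as evidence of absence (the incidence is binary, not signed).
* Every location in a training split must have at least one annotated
  protein; `w_ij` is undefined at zero degree, so zero-degree locations
  (e.g. after a jackknife removal) are pruned from that split's vocabulary
  and can simply never be predicted in that fold.

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ (`tau`) | 0.30 | reliability threshold on max-normalized scores; the conventional operating point. Raising it shortens prediction lists: recall falls, precision rises. The comparison is closed (≥), so the top location is always reported. |
| `min_similarity` | 0.0 (off) | optional confidence floor on interaction scores before scoring, for sources with many weak edges. |
| SW scheme | BLOSUM62, affine open 11 / extend 1 | field-standard protein alignment scoring; a gap of length L costs open + L·extend. A simple match/mismatch/linear-gap scheme is available for small, hand-checkable alphabets. |
| SW normalization | SW(a,b) / min(SW(a,a), SW(b,b)) | maps raw local-alignment scores to [0, 1]; identical sequences score exactly 1, and the ratio is invariant to uniformly rescaling all alignment scores. |
| k, repeats | 10, 30 | cross-validation defaults; fold sizes differ by at most one, repeat r's shuffle derives from sub-seed (seed, r). |

## Design choices at genuinely open points

* **Tie-breaking** among equal normalized scores follows location-vocabulary
  order, so output is reproducible byte-for-byte.
* **Cold start without signal**: if every raw score is zero the prediction
  is empty and flagged, rather than an arbitrary guess; the protein stays in
  the evaluation denominator and contributes 0 to precision-like terms, so
  cold-start failures are penalized, not hidden.
* **Empty-prediction terms** in the ratio metrics (division by |l′(p)| = 0)
  contribute 0 for the same reason; per-location F1 entries whose precision
  is undefined (location never predicted) are 0 but remain in the macro
  average over |C| (a `macro_denominator="defined"` switch averages only
  over locations with both terms defined).
* **W's diagonal** is kept exactly as the formula yields (self-transfer is
  part of the walk).
* **Exact-match rate (ATR)** compares truth and prediction as *sets*; the
  truth is unordered.
* **Pooling**: each repeat's metrics are computed over the pooled held-out
  predictions of all k folds (the jackknife is then exactly the k = |D|
  special case, and the implementation sorts pooled instances by protein id
  so the equality holds bit-for-bit); the aggregate is the mean across
  repeats.
* **Full recomputation per fold**: W and R are rebuilt from scratch on each
  training split. At desk scale (hundreds of proteins, m ≤ ~11) a fold
  costs O(n·m²), so the simplicity is worth far more than an incremental
  update scheme.

## Synthetic data generator

The generator emulates the two statistical features the method relies on,
and nothing else:

1. **Skewed multi-label annotations.** Each protein draws 1–3 distinct
   locations (weights halving per extra label) from a hub-dominated
   prevalence: one cytoplasm-like compartment carries ~42 % of annotation
   mass and the rest decay gently (0.09 → 0.06 before normalization), the
   shape of real annotation tables where one or two compartments dominate.
   With the default 9 compartments the canonical names (Cytoplasm, Nucleus,
   Membrane, ExR, Mit, ER, Cytoskeleton, GA, Peroxisome) are used.
2. **Co-localization-linked interaction scores.**
   `score(p, q) = clip(α·Jaccard(l(p), l(q)) + N(0, σ), 0, 1)`, observed
   with probability q, symmetric. Defaults α = 1, σ = 0.05, q = 0.8 define
   the reference condition (n = 150, m = 9) used by the acceptance script.
   Jaccard is the co-localization statistic because it is symmetric,
   bounded, and captures "share at least one location"; noise is clipped
   rather than resampled, for simplicity.
3. Optionally, per-location sequence motifs (length 12) are concatenated
   with 24 random residues and point-mutated at rate 0.05, so
   Smith–Waterman similarity also correlates with shared locations.

`permute_similarity` is the matched null: protein identities are shuffled
inside the score table only, preserving the marginal score distribution
while destroying its association with co-localization. The recovery
experiment (signal recall minus null recall under the jackknife at τ = 0.3)
is the generator's self-check: ~0.3–0.5 under the reference condition,
collapsing below 0.1 at σ = 10 where clipping makes scores essentially
independent Bernoulli draws.

**What passing on synthetic data does not show.** The generator produces
exchangeable proteins, a stationary noise model, and a score that depends
on labels only through Jaccard overlap. Real interaction networks have
hubs, study bias, evidence-channel artifacts and family structure that
violate all three, so synthetic results validate the *machinery* (algebra,
protocols, metrics), not expected field performance.

## Numerical notes

* All quantities are closed-form; the only tolerances are validation
  tolerances (1e-9 on column sums and row-sum mass conservation, 1e-12 in
  metric oracle tests).
* The Smith–Waterman DP is pure Python, O(len₁·len₂) per pair with
  pairwise-score caching in the sequence provider; adequate for hundreds of
  sequences of a few hundred residues. For the affine model the three-state
  (Gotoh) recurrence is used; the first gap residue costs open + extend.
* Fold assignment, simulation and permutation all derive from
  `numpy.random.default_rng` seeded via `SeedSequence(seed, spawn_key)`, so
  every result is bit-reproducible from one integer and serialized JSON is
  byte-identical across runs.
* Problem sizes in the test and acceptance runs (n = 150 proteins for the
  recovery study, n = 120 for k-fold concordance, 100 random networks for
  the algebra checks, alignment oracles at length ≤ 8) were chosen as the
  smallest scales at which the checked properties are stable; all run in
  seconds.

## Known limitations

* The recommender cannot predict a location absent from (or pruned out of)
  the training vocabulary, and offers no calibrated probabilities — the
  normalized score is a within-query reliability ranking, not a posterior.
* Dataset construction (mapping GO cellular-component terms to location
  labels, redundancy filtering of homologous sequences) is upstream of this
  package: it consumes already-labelled tables. A confidence floor
  (`min_similarity`) is the only built-in edge filter; a redundancy filter
  would slot in before `fit` the same way.
* Comparison against other predictors, and statistical testing between
  methods, are out of scope.
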