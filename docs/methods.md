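# Methods

This document records the model, the procedure, the parameter choices (with
units and defaults), what the synthetic data generator does and does not
emulate, the numerical decisions, and known limitations. Every number quoted
here is computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the repository does not itself verify.

## 1. Problem statement

Given a table of molecules with one measured endpoint (a continuous property
or a binary label), extract transformation rules "X→Y shifts the endpoint by
Δ" with uncertainty and significance, and — when an unlabeled candidate pool
is available — enlarge the evidence base for each rule with model-predicted
molecules that pass a stringent reliability filter.

## 2. Curation (`mmpaq.molprep`)

Input structures are parsed, the largest organic fragment is kept (most heavy
atoms containing at least one carbon; ties broken by canonical SMILES),
simple charges are neutralized (quaternary nitrogens retained), normalization
and canonical tautomer selection are applied with stereochemistry-preserving
settings, and duplicates are merged under a configurable conflict policy
(`mean` for continuous values, `majority` for labels, `strict` to reject
conflicts). Records carry provenance flags (`uncommon_element`,
`has_chirality`) rather than being silently dropped. Standardization is
idempotent: re-standardizing an output reproduces it byte-for-byte (tested).

## 3. Pair mining (`mmpaq.mmp`)

### 3.1 Fragmentation

Cut bonds are acyclic single bonds between heavy atoms. Subsets of 1–3 such
bonds are enumerated; a fragmentation is kept when exactly one connected
component carries all cut attachment points (the *variable* fragment) — the
remaining components form the *context*. With `hydrogen_mode` (default on) a
virtual cut at each heavy atom with an implicit hydrogen emits the variable
`[H][*:1]`, so X→H deletions and H→Y additions are first-class
transformations.

Constraints (defaults, rationale):

| parameter | default | meaning |
|---|---|---|
| `max_cuts` | 3 | bonds cut simultaneously; 1 = classic single-point MMP, 3 = linker/core swaps |
| `max_heavy_variable` | 13 heavy atoms | variable fragments above this are whole-subunit swaps, not "small local changes", and explode the index |
| `min_ratio_context_to_variable` | 1.0 | the conserved part must be at least as large as the exchanged part, otherwise "same context" is not meaningful |
| `hydrogen_mode` | `True` | without it, every grow/shrink rule at a CH position is invisible |

These are mining-resolution choices, not fitted values; the tests exercise
them only through their contractual behavior (monotonicity under tightening,
attachment-count bookkeeping).

### 3.2 Canonical keys

Context keys must be invariant to input atom order and to the arbitrary
numbering of attachment points, otherwise identical environments fail to
collide in the index. The package relabels context attachment points by the
atom output order of the *unlabeled* canonical context SMILES, sorts
multi-part contexts by their bare SMILES, and canonicalizes the variable
fragment over all label permutations that fix the context. Transformation
keys (X→Y) are additionally minimized over joint label permutations and the
two orientations, so A→B and B→A collapse to one canonical direction with a
sign. Correctness is established by the oracle test: on 20 random libraries
the indexed pair set equals the exhaustive O(n²) pair set exactly, and every
fragmentation reassembles (via attachment-point zipping) to its parent
canonical SMILES.

### 3.3 Pair generation

Within one context posting list, every unordered pair of entries with
distinct variable fragments yields a matched pair with
Δ = p(B) − p(A) in the canonical orientation. Duplicate observations of the
same (molecule pair, context, transformation) are emitted once.

## 4. Rule statistics (`mmpaq.rules`)

Per transformation: `n_pairs`, `mean_delta`, `sd_delta` (sample SD, ddof=1),
`sem_delta = sd/√n`; for binary endpoints the direction counts and
`toxicity_change = (n_increase − n_decrease)/n`.

- **Continuous:** Wilcoxon signed-rank on the deltas, zeros dropped, exact
  null distribution when n ≤ 25 with no tied magnitudes, normal approximation
  with continuity correction otherwise. All-zero deltas give the sentinel
  p = 1. Twenty strictly positive deltas give the exact two-sided
  p = 2·2⁻²⁰ ≈ 1.9·10⁻⁶ (frozen in a test).
- **Binary:** exact two-sided binomial test of the direction counts against
  p = ½; verified against explicitly summed tail probabilities for every
  (k, n) with n ≤ 30 to below 10⁻¹².
- **Rule criterion:** `n_pairs > min_pairs` (strict; defaults 10 for
  regression, 6 for classification) and p < α (default 0.05). Optional
  Benjamini–Hochberg correction across transformations (off by default, to
  keep single-rule p-values interpretable; turning it on can only reduce the
  rule set — tested).
- **Generality:** contexts are clustered with the Butina algorithm on Morgan
  fingerprints (radius 2, 2048 bits) at Tanimoto 0.7; a rule with ≥ 5 context
  clusters is flagged general. 0.7 is the conventional "same chemical
  neighborhood" similarity; 5 clusters means the effect was observed in at
  least five structurally distinct environments.
- **Calibration:** under a zero-centered continuous null (1000 simulations,
  n = 20) the rejection rate at α = 0.05 is 0.046 (acceptance script,
  seed 1) — within binomial noise of nominal.

## 5. Consensus QSAR (`mmpaq.qsar`)

`ConsensusModel` is a scikit-learn-compatible estimator. Eight single models:
{random forest, gradient boosting, SVM (standard-scaled), XGBoost} × {MACCS
(166 bits), `open2d` (a fixed panel of 43 open 2D descriptors)}. Each single
model's hyperparameters are chosen by grid search scored on a
scaffold-disjoint validation split (RMSE for regression, ROC-AUC for
classification; ties keep the first grid point), then refit on the training
portion only. The consensus prediction is the arithmetic mean of the eight
single predictions (regression) or of the eight positive-class probabilities
(classification); the identity "consensus = mean of singles" holds to
numerical zero (tested to 10⁻⁹, observed 0).

Feature hygiene: variance floor, then greedy correlation pruning (keep the
earlier column), optional recursive feature elimination. Splits are grouped
by Bemis–Murcko scaffold and assigned greedily by relative deficit, so no
scaffold leaks across the 0.8/0.1/0.1 train/validation/test partition.

Metrics: ACC, SE (sensitivity), SP (specificity), precision, recall, F1,
ROC-AUC; for regression RMSE, MAE, and Q²/R² as the coefficient of
determination 1 − SS_res/SS_tot (so a constant prediction at the mean scores
exactly 0 — tested). A published formula sheet in this area prints a squared
error under the label "MAE"; MAE here is the mean absolute error.

## 6. Applicability domain (`mmpaq.adfilter`)

For single-model predictions X₁…X_N with consensus X̄ = mean(Xᵢ):

- `Ensemble_SD = sqrt( Σᵢ (Xᵢ − X̄)² / (N − 1) )` over the single models only
  (hand value: singles (1.0, 3.0) → √2);
- `CONCORDANCE = 1 + Σᵢ 1[label(Xᵢ) = label(X̄)]`, counting the consensus as
  agreeing with itself (all eight agree → 9).

Diagnostics (`ad_curve`): sweeping the Ensemble_SD threshold from loose to
tight orders the cumulative RMSE almost perfectly on a heteroscedastic
ensemble (Spearman ρ = 0.9999 at n = 2000, acceptance script); restricting
to full concordance raises classification precision over the whole-set value
(+0.13 in the same run) at the cost of recall.

Expansion policy defaults: accept when Ensemble_SD < 0.6 (strict inequality —
0.59 passes, 0.61 fails, tested) for regression; full concordance *and*
consensus probability > 0.95 (positives) or < 0.025 (negatives) for
classification. These thresholds are deliberately stringent: expansion only
helps if the added labels are nearly as trustworthy as measurements.
Accepted molecules are deduplicated against the experimental set and tagged
`source="predicted"`.

## 7. Pipeline (`mmpaq.pipeline`)

`run_mmpa`: validate → mine pairs → compile rules → report.
`run_mmpa_by_qsar`: plain MMPA on the labeled set → scaffold split → fit
consensus model → AD diagnostics on the held-out test scaffolds → score the
unlabeled pool → AD filter → merge → MMPA on the expanded set → compare rule
sets. An empty pool or a zero-acceptance filter degrades to the plain result
with an explicit warning (tested). The comparison reports R² between
expanded and experimental per-rule mean deltas, sign agreement, how many
experimental rules persist, how many non-rules became rules, and mean pair
growth.

## 8. Synthetic data generator (`mmpaq.fixtures`)

**What it emulates:** a congeneric SAR series — molecules built as scaffold +
substituents at fixed sites, with an *additive* planted endpoint
p = base(scaffold) + Σ contrib(substituentᵢ) + ε, ε ~ N(0, σ²), σ = 0.1 by
default. Substituent contributions follow the sign and rough magnitude of
hydrophobicity increments (H 0.0, F 0.14, Cl 0.71, Br 0.86, CH₃ 0.56, OH
−0.67, NH₂ −1.23, CN −0.57). Two fused bicyclic scaffolds × 8 substituents ×
2 inequivalent sites = 128 molecules by default; a six-scaffold variant (384
molecules) supports scaffold-disjoint QSAR splits. Fused-ring scaffolds with
compact substituents make the substituent attachment bonds the only cuttable
bonds, so the mined transformation table is *closed* over the planted one —
exact deltas at σ = 0 (max |error| 2·10⁻¹⁶ observed), and at σ = 0.1 every
one of the 28 transformations recovers its planted delta within 3 SEM.

**What it does not emulate:** non-additive SAR (activity cliffs,
intramolecular interactions between substituents), assay heteroscedasticity,
scaffold–substituent interaction terms, chirality, tautomer-dependent
endpoints, or realistic library redundancy. Conclusions about model accuracy
on this generator therefore bound only the machinery, not real-assay
performance.

Default generator parameters *are* the study conditions: σ = 0.1 and the
seed conventions were fixed before outcomes were inspected and are not tuned.

## 9. Numerical choices

- Exact tests wherever feasible (Wilcoxon exact for n ≤ 25 without ties,
  binomial always exact); approximations are continuity-corrected.
- Sample (ddof = 1) standard deviations throughout, including Ensemble_SD.
- Q²/R² is the coefficient of determination, not a squared Pearson r, so the
  constant-mean predictor scores exactly 0 and the metric penalizes bias.
- Strict inequalities at every acceptance threshold (`n_pairs > min_pairs`,
  `Ensemble_SD < 0.6`, `p < α`) so boundary cases are decided one way, and
  tested at the boundary.
- All stochastic components consume `numpy.random.default_rng` generators
  seeded from a single user-visible seed; derived seeds are 31-bit.
- Floating-point comparisons in contracts use explicit tolerances (10⁻⁹ for
  the consensus identity, 10⁻¹² for exact-test agreement).

## 10. Open design points

- Problem sizes in the verification suite (20 oracle libraries of ≤ 25
  molecules, 1000 null simulations, 2000-point AD curves) are this package's
  own choices, sized to give tight checks within a minute-scale budget.
- The `open2d` descriptor panel is a pragmatic open-source stand-in for
  proprietary 2D descriptor sets; the consensus architecture does not depend
  on which 2D panel is used.
- The expansion policy treats the AD thresholds as fixed constants rather
  than calibrating them per dataset; calibration (e.g., by conformal
  methods) is a natural extension and deliberately out of scope.

## 11. Limitations

- MMPA assumes transferability of substitution effects across contexts;
  the generality flag mitigates but does not remove this assumption.
- Rules from expanded datasets inherit any systematic bias of the consensus
  model inside its AD; the comparison report (R², sign agreement) quantifies
  agreement with experimental rules but cannot certify new chemistry.
- Fragmentation is constitutional only: stereochemistry is preserved through
  curation but not used to distinguish transformations.
- The exact Wilcoxon path is limited to n ≤ 25 without ties; larger samples
  use the corrected normal approximation (standard practice, but p-values
  very near α can shift by ~10⁻³ at the crossover).
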