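# Methods

This note records the models the package implements, the defaults it
chooses where the workflow leaves them open, and what the synthetic-data
tests do and do not demonstrate.

## Activity labelling

Potency is expressed as pLC50 (−log10 LC50, unitless). The active class is
`pLC50 ≥ 4.5`; the boundary value is active. Duplicate compound identifiers
are rejected at ingestion rather than aggregated — there is no universally
right way to merge repeated assay measurements, and silently averaging them
would hide a data problem. Structure handling is syntactic only (RDKit
parse validation); salt stripping and tautomer normalization are out of
scope and must happen upstream.

## QSAR model

A scikit-learn `RandomForestClassifier` with 250 trees and a single seed;
`n_jobs=1` so probabilities are bit-reproducible. Constant descriptor
columns are dropped before fitting (they carry no signal and some forest
implementations handle them badly); a warning records which.

**Partitioning.** Stratified 80/20; per class the test size is
round-half-even of `0.2 × class size` (so a 91/75 library yields an 18+15
test set), with the class members shuffled by the seed before slicing.

**Evaluation.** All rates come from one confusion matrix obtained by
thresholding the forest's active-class probability at 0.5 (boundary →
predicted active). Cross-validation (default k = 10, stratified, seeded)
is scored on the pooled out-of-fold predictions — one confusion matrix and
one ROC for the whole procedure, not per-fold averages — because the
screen's downstream consensus consumes a single specificity number per
validation mode. MCC with a zero marginal (e.g. a degenerate constant
predictor) is reported as 0, the random-forecast value.

**ROC/AUC.** AUC is the Mann–Whitney concordance over active/inactive
pairs with ties counted half. The curve points come from scikit-learn's
`roc_curve` without intermediate dropping, and the trapezoidal area under
them equals the pair-counting AUC to 1e−9 — the test suite holds the two
routes against each other.

**Applicability domain.** `APD = d̄ + Z·σ`, Z = 0.5. Among several
published readings of this formula the package uses the
pairwise-distance-subset procedure: compute all training pairwise
Euclidean distances, retain those no larger than their grand mean, and
take d̄ and σ (population standard deviation) of the retained subset. A
query is in-domain when its nearest training neighbour is within APD;
boundary equality is in-domain. Degenerate geometry behaves sensibly:
identical training points give APD = 0, and Z = 0 reduces the threshold to
d̄. Both d̄/σ and Z are exposed, so alternative conventions can be swapped
in.

## Docking normalization

`Prob_Dc = E_lig / E_mlig`, conditional on `E_lig < E_inib` (strictly
stronger binding than the reference insecticide). Scores must be negative:
a non-negative (repulsive) energy would push the ratio outside (0, 1] and
is rejected at validation instead of silently producing a nonsense
probability. `E_mlig` is the minimum over the table handed to
`call_actives` — the screened set defines the normalization scope, which
matters when only a subset of a larger campaign is available; reports
record the scope implicitly through the table fingerprint. Secondary
(GoldScore-style) scores are ingested and carried through for comparison
but never enter the probability. Ligand efficiency divides the score by
the supplied heavy-atom count; published LE columns often follow
unstated atom-count conventions, so the package does not claim to
reproduce any particular printed LE value.

## Consensus and multi-target selection

`Prob_Comb = (Prob_Dc + (1+ESP)·P_Activity) / (2+ESP)` — a weighted mean
with weights 1 and 1+ESP, the only convex reading of the fusion rule that
keeps the result in [0, 1]. ESP defaults to the mean of the model's test
and cross-validation specificities; `test`, `cross`, and `mean` modes are
exposed because the "specificity statistic" is a modelling choice, not a
law. Compounds failing the docking condition contribute `Prob_Dc = 0`
rather than being dropped, which caps a docking-less compound's consensus
at `(1+ESP)/(2+ESP)` — with ESP ≈ 0.76 that ceiling is ≈ 0.64, so a strong
QSAR signal alone can still clear 0.5 but can never reach the top of the
ranking.

Selection is strict (`> 0.5`; a compound at exactly 0.5 is excluded), the
multi-target call requires selection at every required enzyme (a missing
evaluation counts as not selected), and hits are ranked by mean
`Prob_Comb` over the required enzymes, descending, ties broken
lexicographically by compound identifier.

When consensus probabilities were produced against a larger screening bank
than the docking subset at hand, they cannot be recomputed locally (the
bank minimum `E_mlig` and the exact ESP are unknown); the
`screen_with_reported_consensus` route therefore treats them as data,
recomputes only the docking activity condition, and applies the strict
rule to the reported values. The bundled worked-example campaigns use this
route.

## Toxicity filter

Four ordinal parameters (mutagenic, tumorigenic, reproductive effect,
irritant) with levels none/low/high; "No" and "None" parse to the same
level. The filter is strict all-none: a single "low" flag excludes a
compound. This is pinned by the bundled fruit-fly campaign, where the one
compound carrying only a low irritant flag is absent from the 27-compound
clean list. The filter is idempotent and monotone (lowering any level
never removes a survivor) — both are property-tested.

## Conservation statistics

Percent identity divides identical columns by columns where at least one
of the pair has a residue (gap–gap columns excluded); an optional flag
additionally trims columns under either sequence's terminal gap runs,
matching the practice of excluding unshared end regions. Aligner
conventions differ here, so numeric comparability with any specific tool's
identity values is not claimed. Active-site positions are 1-based in the
template's ungapped coordinates (the residue-label convention, e.g.
"W245"); a query gap at a site column counts as not conserved.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
chemistry:

* **Library** — `n` compounds at an active fraction defaulting to 91/166
  (the class balance of a typical curated modelling set); actives draw
  pLC50 uniformly from [4.5, 7.5), inactives from [2.0, 4.5). Descriptors
  are i.i.d. standard normal in three named blocks (`getaway_*`, `whim_*`,
  `rdf_*`); a random 30% column subset is informative, with the active
  class mean shifted by `effect_size` standard deviations there. The
  informative subset can be fixed externally so a screening bank can share
  the signal geometry of a modelling library.
* **Docking** — per enzyme, `score = −150 − coupling·signal + N(0,
  noise_sd)`, clipped strictly negative, on the MolDock magnitude scale;
  the reference inhibitor energy sits at a chosen quantile of the
  generated scores (default 0.75, i.e. three quarters of ligands beat it).
* **Toxicity** — all-none with probability `clean_rate`, otherwise one to
  four parameters flagged low or high.

All generators are deterministic under their seed, to the byte, through
the same CSV dialects the ingestion modules read.

What passing synthetic tests shows: the pipeline recovers planted signal
(null libraries give chance AUC, 3σ libraries give AUC > 0.95, and at
effect 2σ with docking coupling 10 and noise 5 the final multi-target
risk-free list is ≥2× enriched in planted actives over a 0.2 prevalence).
What it does not show: behaviour on real descriptor distributions (which
are correlated, heavy-tailed, and block-structured in ways Gaussians are
not), real docking error modes, or real toxicophore correlations between
parameters.

## Problem sizes and determinism

Distributional tests average over 20 seeds with libraries of 200 compounds
× 30 descriptors (QSAR recovery) and 500 compounds for the end-to-end
enrichment check — sizes at which a 250-tree forest trains in well under a
second while the statistics of interest are already stable. Every source
of randomness (splits, forests, generators) flows from an explicit integer
seed; re-running any pipeline stage with the same configuration and inputs
is byte-identical, and reports embed a configuration hash plus an input
fingerprint for audit.

## Known limitations

* Descriptor computation, docking, and toxicity prediction are consumed as
  inputs, never recomputed; the package's claims start at those tables.
* The consensus reading of the fusion rule and the ESP definition are
  documented defaults, not uniquely determined conventions; both are
  parameters.
* The applicability-domain procedure is one published interpretation of
  the distance formula; others (e.g. k-nearest-neighbour means) are not
  implemented.
* CSV duplicate-measurement aggregation is intentionally unsupported
  (rejected) — curate upstream.
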