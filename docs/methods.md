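# Methods

## Data model and observation conventions

The unit of analysis is a **count vector**: a mapping from behavior
category to the number of observations of that behavior for one analysis
unit (animal, session, or condition). Counts are integer tallies, the
natural output of instantaneous/scan sampling. Whether an "observation"
is a scan, a bout, or a duration is not standardised in the behavioral
literature; this package adopts the integer-scan convention throughout,
with one escape hatch: the Shannon index additionally accepts a
pre-normalised proportion vector (`shannon(p, proportions=True)`), since
it is the only index in the battery defined purely on proportions. The
Simpson family, Menhinick, Margalef and Chao1 all require raw integer
counts — Simpson's pair-counting and Chao1's singleton/doubleton logic
are meaningless on durations.

Behavior labels are opaque, case-sensitive strings. Ethogram granularity
(lumping vs. splitting categories) changes every index and is the user's
responsibility; no ontology mapping is attempted. Categories present in
an ethogram but never observed have count 0 and contribute to nothing:
observed richness S counts strictly positive categories.

**Out-of-sight scans.** A scan where the focal animal is invisible is a
sampling-effort confound, not a behavior: including it as a category
would reward enclosures with hiding places with higher "diversity".
Aggregation therefore excludes out-of-sight records from N by default,
retaining their number as metadata (`CountVector.out_of_sight_count`) so
effort-sensitive indices can be audited. The `category` policy instead
tallies them under an `out_of_sight` pseudo-label for sensitivity
analyses.

## Index formulas and numerical choices

- **Shannon–Wiener** `H' = −Σ p_i ln p_i`, natural logarithm everywhere
  (no base-2 option); `0·ln 0 := 0`, and the `−0.0` that IEEE negation
  produces for a single behavior is normalised to `0.0`. Range: 0 (one
  behavior) to `ln S` (perfect evenness).
- **Simpson's D** uses the without-replacement (finite-sample) form
  `Σ n_i(n_i−1) / (N(N−1))`: the probability that two distinct scans
  record the same behavior. This form — rather than `Σ p_i²` — is what
  makes the index genuinely count-sensitive: at fixed proportions the
  value shifts with N, which is the property the effort-sweep scenario
  demonstrates and the sensitivity matrix asserts. Undefined for N < 2
  (no pair exists). Its complement `1−D` and reciprocal `1/D` are
  derived from the same computation; the reciprocal is undefined at
  D = 0 (all categories singletons).
- **Menhinick** `S/√N` and **Margalef** `(S−1)/ln N` are effort-corrected
  richness measures; both depend on the data only through (S, N), hence
  their evenness-blindness is an exact algebraic identity, not an
  approximation. Margalef is undefined for N ≤ 1.
- **Chao1** defaults to the bias-corrected estimator
  `Sobs + F1(F1−1)/(2(F2+1))`, which is defined for every non-empty
  sample (including F2 = 0), equals Sobs exactly when F1 ≤ 1, and never
  falls below Sobs. The classic `Sobs + F1²/(2F2)` is available as
  `chao1(cv, bias_corrected=False)` for cross-checks against software
  that defaults to it; it is reported undefined when F1 > 0 and F2 = 0.
- **BVI** `(Ob/Ex)·100` is a presence/absence measure. When computed
  from label sets, Ob counts only expected categories seen at least once;
  observed behaviors outside the expected repertoire do not raise the
  score (the index measures expression of the wild-type repertoire) but
  are flagged in the result notes, and Ob > Ex supplied directly is
  allowed with a flag rather than rejected.

**Undefined values are results, not exceptions.** Parameter sweeps
routinely hit degenerate cells (N = 1, S = 1 with N < 2, empty vectors).
Every index therefore returns an `IndexResult` whose `value` is `None`
with a machine-readable note (`"undefined: insufficient observations
(N<2)"`), serialised as an empty CSV field plus the note. One documented
tension: the count-sensitivity scenario's narrative treats Simpson as
"not generated" for a single behavior category, but the formula is
perfectly defined there (D = 1 for any N ≥ 2); the implementation
follows the formula.

Every `IndexResult` carries the (S, N, F1, F2) snapshot of its input so
batch outputs are auditable without re-reading the raw data.

## Simulation scenarios

The scenario module generates the synthetic count profiles that
characterise each index, as fully deterministic constructions — there is
no random number generation anywhere in the package outside the
acceptance script's choice of free parameters. Re-running any sweep
yields byte-identical tables.

Four profile kinds over richness grid S ∈ 1..10 (configurable):

- `equal` — S categories each observed m times;
- `dominant_first` — the first category observed k·m times
  (k ∈ {1, 2, 10, 100}), the rest m each: an evenness gradient;
- `effort_sweep` — equal counts with m swept over
  {1, 2, 3, 4, 5, 10, 100}: a sampling-effort gradient at fixed
  richness and perfect evenness;
- `singleton_sweep` — at fixed S, `n_singletons` categories reduced to
  count 1, the rest held at base count m ≥ 2: a rarity gradient for
  Chao1.

The canonical figure grids (1–7) wire these together: (1) Shannon and
(3) Simpson under the dominance design, (2) the three Simpson variants
on one shared equal-abundance grid, (4–6) Simpson/Menhinick/Margalef
under the effort sweep, (7) Chao1 under the singleton sweep at S = 10.
Two base counts are not pinned by the scenario descriptions and are
package defaults: m = 10 for the dominance designs (Shannon's curves are
m-invariant, so only the Simpson dominance curve depends on this
choice), and m = 5 for the singleton sweep's non-singleton categories.
Both are `Scenario` fields and configurable.

What these scenarios emulate — and what they do not: they are exact
count profiles with prescribed richness, evenness and effort, ideal for
isolating each index's algebraic sensitivities. They contain no
multinomial sampling noise, no observer error, no out-of-sight process
and no temporal autocorrelation between scans, so passing them
demonstrates the indices' mathematical behavior, not robustness to the
stochasticity of real observation data. A seeded multinomial-draw
scenario is a natural extension point.

## Verification strategy

- Simpson's D is checked against a brute-force oracle that materialises
  every scan as a slot and counts matching pairs in exact rational
  arithmetic — exhaustively over all count vectors with N ≤ 8 on up to 4
  categories, and property-based beyond.
- Shannon, Menhinick, Margalef and Chao1 (both variants) are
  cross-checked against scikit-bio's independent implementations on
  fixed vectors.
- Invariants are asserted as hypothesis properties (derandomised):
  Shannon's bounds and its maximum only at equal abundance; Shannon's
  scale invariance against Simpson's strict scale sensitivity for S ≥ 2;
  the `1−D` and `1/D` identities; Chao1 ≥ S with equality iff F1 ≤ 1 and
  monotonicity in the number of singletons; Menhinick/Margalef's
  dependence on (S, N) alone; aggregation's permutation invariance,
  record-count conservation and additivity over disjoint record sets.
- The sensitivity matrix (which index responds to richness, evenness,
  effort) is asserted by three perturbation pairs, each isolating one
  property: richness changed at fixed N; evenness changed at fixed
  (S, N) with F1 = F2 = 0 so Chao1 is a fair control; all counts scaled
  ×3 at fixed proportions.

All grids are desk-scale (the largest vector in the suite has N = 1000);
the full suite runs in seconds.

## Known limitations

- No confidence intervals, rarefaction, bootstrap or jackknife; the
  indices are point values.
- No evenness-specific index (e.g. Pielou's J = H'/ln S) and no Hill-
  number unification; both are straightforward extensions.
- No between-condition hypothesis testing; the results CSV is designed
  to feed standard statistics tooling instead.
- Duration-based data enters only through the Shannon proportion path;
  there is no general duration-weighted variant of the other indices.
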