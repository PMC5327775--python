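# Methods

## Score equations and category boundaries

The four score equations are fixed-coefficient functions of the six
baseline variables; the coefficients are constants taken from the original
publications and are never re-estimated here. Two type-setting ambiguities
in common secondary renderings of the formulas are resolved the only way
that makes the published cut-offs reachable:

* **Sokal**: the exponential applies to the *entire* centered linear
  predictor, not only to the age term. Under the alternative reading the
  score could not straddle the 0.8 / 1.2 boundaries for realistic patients.
* **Hasford**: the ×1000 factor applies to the *whole* six-term sum, not
  only to the platelet indicator. Otherwise scores of 780–1480 would be
  unreachable.

Boundary conventions, chosen to be total and gap-free on the real line:

| System  | low | intermediate | high |
|---|---|---|---|
| Sokal   | < 0.8 | [0.8, 1.2] | > 1.2 |
| Hasford | ≤ 780 | (780, 1480] | > 1480 |
| EUTOS   | < 87 | — | ≥ 87 |
| ELTS    | ≤ 1.5680 | (1.5680, 2.2185] | > 2.2185 |

The published Hasford bands are printed as integers (≤ 780 / 781–1480 /
≥ 1481), leaving (780, 781) and (1480, 1481) formally undefined for a
continuous score; extending each lower band up to the next cut keeps the
integer bands intact. The ELTS value 1.5680 is printed in both the low and
intermediate ranges; it is assigned to low, matching the "≤" wording of the
low band. ELTS uses age in completed years (floored); the other scores
accept real-valued age.

Validation is strict by default (out-of-range percentages raise, naming the
field), with a lenient mode that logs warnings instead, because silently
accepted out-of-range values corrupt scores without any visible symptom.
Non-finite inputs and non-positive platelet counts always raise: the ELTS
platelet term diverges at zero.

## Dichotomization, accuracy and the consensus/conflict partition

Three-level categories collapse to two under either merge rule
(intermediate→low, "strategy 1", or intermediate→high, "strategy 2");
EUTOS is unaffected by both. The accuracy convention — HIGH predicts MMR
failure, the merged low level predicts achievement — is not stated
explicitly alongside the reference tables; it is the unique convention
under which every accuracy in those tables is recovered from its 2×2
cells, and is treated as derived.

Accuracies are computed at full precision and rounded half-up to two
decimals for display; JSON reports carry both. The reference tables
themselves mix rounding and truncation at the second decimal (the same
60/95 appears as 63.15 and 63.16), so comparisons against them should
allow ±0.01.

The partition is computed on the dichotomized labels: a patient whose four
labels agree is in the consensus group, all others in the conflict group;
the full 2⁴ combination table is enumerated in a fixed order (system order
Sokal, Hasford, EUTOS, ELTS; merged-low before high, so the all-low pattern
is first and the all-high pattern last). Per-score accuracy is then
reported within each subgroup (all / consensus / conflict).

Two presentational caveats are worth knowing when comparing against the
reference tables:

* Consensus-group misclassification is sometimes quoted against the whole
  cohort rather than the consensus group; the report exposes both
  denominators explicitly (20 misclassified = 30.77 % of 65 consensus
  patients = 21.05 % of 95).
* The reference single-score whole-cohort summary quotes Sokal, EUTOS and
  ELTS under strategy 1 but Hasford under strategy 2 (58.95 rather than the
  strategy-1 value 67.37). The report therefore always exposes every
  system's whole-cohort accuracy under *both* strategies, so either
  comparison can be read off without recomputation.

Records with a missing MMR flag are excluded on read, before any analysis,
and the exclusion is logged with ids and counts.

## Synthetic cohort generator

`generate_cohort` draws the six baseline variables independently from
truncated distributions calibrated to the reference cohort's marginals
(median, SD, observed range per variable):

| variable | median | SD | range | family |
|---|---|---|---|---|
| age (years) | 40.21 | 15.13 | 18–74 | truncated normal, floored to integers |
| spleen (cm BCM) | 8.33 | 7.53 | 0–25 | truncated normal |
| platelets (×10⁹/L) | 510.97 | 439.88 | 4.42–2876 | truncated log-normal |
| blasts (%) | 1.50 | 1.39 | 0–10 | truncated normal |
| eosinophils (%) | 0.83 | 1.24 | 0–7 | truncated normal |
| basophils (%) | 1.32 | 1.10 | 0–7 | truncated normal |

Platelets are modelled log-normal because the reported median sits far
below the mean implied by the SD and the range extends to 2876 — a clearly
right-skewed distribution; the other variables are treated as truncated
normals. The reported eosinophil range of 0–0.07 is internally inconsistent
with its median of 0.83 and is taken as 0–7, symmetric with basophils. The
underlying location of each (log-)normal is solved numerically (Brent's
method) so that the *truncated* median equals the target median — naive use
of the target as the location would bias the spleen median upward by ~14 %
because of the asymmetric truncation at 0. The underlying scale is the
reported SD (for platelets, the log-scale σ solved from the SD/median ratio
of an untruncated log-normal); the truncated sample SD is therefore
somewhat smaller than the target SD, a deliberate simplification since the
medians and ranges are what downstream category frequencies are sensitive
to. At n = 10 000 all sample medians land within ~1 % of their targets.

The MMR outcome is Bernoulli with

    logit P(MMR) = logit(p₀) − a · c,

where c is the standardized composite of the four score values (mean of
per-score z-scores, re-standardized), p₀ the baseline achievement rate
(default 62/95 ≈ 0.653, the reference prevalence) and a the association
coefficient in log-odds per SD of composite risk (default 1.0 — a moderate,
clinically plausible effect; a = 0 gives an outcome independent of risk).
A two-parameter Newton logistic fit (`fit_logistic_slope`) is implemented
in-package so that slope recovery can be checked without delegating the
check to the same library that might one day generate the data; at
n = 10 000 the re-estimated slope lies within 3 standard errors of −a.

What the generator deliberately does **not** emulate: correlations between
baseline variables (a real CML cohort's spleen size, blast count and
platelet count co-vary with disease burden), measurement error, treatment
heterogeneity, or time-to-response structure (MMR is a single binary
endpoint). Tests passing on these cohorts demonstrate the correctness of
the scoring and analysis machinery, not the clinical behaviour of the
scores on real patients.

## Cohort reconstruction from aggregate tables

`reconstruct_cohort` builds a patient-level cohort whose aggregate tables
reproduce a `TargetTables` object *exactly*. The targets are the 16
combination-pattern counts split by MMR (strategy-1 labels) plus, for each
three-level system, the high-risk counts under strategy 2; the difference
between the two high counts fixes how many merged-low patients must carry
the intermediate category, per system and per MMR stratum.

The algorithm:

1. Validate the targets (all 16 patterns present, non-negative, EUTOS
   marginals consistent, strategy-2 high ≥ strategy-1 high).
2. Allocate each system's required intermediates greedily over the pattern
   cells in enumeration order, separately per MMR stratum. With the packaged
   targets the all-low consensus cell absorbs every intermediate, so all
   conflict-cell patients are unambiguous (pure low/high) — but the
   allocation is general.
3. Every patient now has an exact four-way category tuple. One exemplar
   patient per distinct tuple is found by searching a clinical box wider
   than the reference ranges (age 16–85, spleen 0–30 cm, platelets
   4.42–2876, blasts 0–15 %, eosinophils/basophils 0–10 %): first uniform
   rejection sampling (up to 10⁶ draws, vectorized), then — for tuples whose
   feasible region is a thin sliver, e.g. Sokal-high with Hasford-low and
   EUTOS-high, which pins three scores near their boundaries at once — a
   seeded differential-evolution search minimizing the summed distance of
   each score from its target category interval. Both stages draw from a
   PRNG stream keyed by (seed, canonical tuple index), so each pattern's
   exemplar is reproducible independently of the others.
4. Patients sharing a tuple share covariates; ids are sequential and MMR
   flags are assigned deterministically from the stratum (the targets fix
   them exactly, so nothing is sampled).
5. The assembled cohort is re-scored with the score engine and every
   patient's categories are verified against the plan; the search's
   bookkeeping is never trusted.

Because the targets pin all aggregates, the analysis results are identical
for every seed; the seed only moves the individual covariate values.
Reconstruction of the 95-patient reference cohort takes under a second.

## Problem sizes and numerical choices

Generator calibration checks use n = 10 000 (median tolerance 5 %,
binomial/logistic checks at 3 SD/SE); property cross-checks use 100 random
cohorts of up to 80 patients; the reconstruction and full consistency
analysis run on the 95-patient reference cohort. CSV output uses `%.17g`
and reads with round-trip float parsing, so cohort files preserve doubles
bit-exactly. Report accuracies render as "n/a" for empty subgroups rather
than 0. CLI exit codes: 0 success, 2 validation failure, 3 infeasible
reconstruction.

## Known limitations

* Baseline variables are generated independently; no attempt is made to
  model their joint distribution.
* Reconstruction reuses one exemplar per category tuple, so reconstructed
  cohorts contain repeated covariate rows; they are aggregate-faithful
  stand-ins, not realistic patient samples.
* The accuracy statistic ignores class imbalance (65 % of the reference
  cohort achieves MMR, so "predict achievement for everyone" scores 65.26);
  no significance testing between accuracies is performed, mirroring the
  scope of the analysis the package implements.
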