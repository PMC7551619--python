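# Methods

## Data model

All analyses operate on long-format records (one row per
panelist × concentration level) aligned to a fixed ascending
`ConcentrationSeries` in ng/L. Levels are aligned by sorted
concentration, not file order. All logarithms are base 10; the choice
only rescales slopes and leaves every threshold unchanged, but it is
fixed for reproducibility. Hypothetical one-step extensions of the
ladder use the *local* step ratio between the two adjacent extreme
levels (0.2→0.02 and 2000→20,000 on the decade ladder; 750→1500 on the
non-uniform preference ladder), because the ladders are not required to
be geometric throughout.

## Best-estimate thresholds

The three-branch decision rule is evaluated in a fixed order: the
standard rule whenever the top-level answer is correct; otherwise the
adaptation rule whenever a run of ≥ 3 consecutive correct answers
precedes a miss at a higher level; otherwise non-responder imputation.
Two deliberate interpretations where the rule as usually stated is
silent:

* **Runs longer than three qualify.** The chance argument
  ((1/3)³ ≈ 3.7%) is only strengthened by longer runs.
* **Multiple qualifying runs** are resolved to the run with the lowest
  starting concentration — the most conservative sensitivity claim, and
  a tie-break that real five-level data essentially never exercise.

Imputed non-responder BETs (√(cₖ · r·cₖ), one hypothetical step above
the ladder) are retained for histograms only; every statistic —
geometric mean, sd of log BET, t-test — uses responders alone. The
between-condition comparison is a pooled-variance (Student) rather than
Welch t-test, so its degrees of freedom are n₁ + n₂ − 2; `sd_log_bet`
is the sample SD of log₁₀ BETs (a dimensionless decade count).

## Graphical group threshold

The fit is ordinary least squares on the *individual* 0/1 outcomes
against log₁₀ concentration — identical, for complete balanced panels,
to fitting per-level proportions weighted by level counts (a property
the tests assert numerically). Logistic regression would be the modern
choice but is deliberately not the default: the method's lineage is a
straight-line fit, and fidelity to it is the point. The threshold is
the antilog of (criterion − intercept)/slope with criterion
(1 + chance)/2.

Confidence bounds are computed by inverse prediction: the two
concentrations where the pointwise (1 − α) confidence band for the
regression mean crosses the criterion, found by bracketed root-finding
outward from the point estimate. This is algebraically the Fieller
construction for this calibration problem. When the slope is not
separated from zero at the chosen level the band never crosses and the
corresponding bound is reported absent. Degenerate geometries are
reported, not raised: a non-positive (or arithmetic-dust, < 1e-9)
slope yields `flag="undefined-slope"`; a crossing beyond the floating
range yields `flag="criterion-unreachable"`; a crossing outside the
tested ladder is returned with `flag="extrapolated"` rather than
clamped.

## Rejection thresholds

Consistency gating examines the top `k_top = 3` choices; the chance
probability of consistency is (1/2)^k per direction (12.5% for k = 3)
and twice that for either direction. The preference regression reuses
the same OLS-on-0/1 machinery with spike coded 1. A rejection threshold
is read off only when the slope is negative and the 0.25 crossing lies
within one hypothetical ladder step of the tested range (an
*extrapolation guard*): near-flat fits otherwise produce absurd
crossings far outside the ladder. Preference thresholds at 0.75 are
symmetric for rising fits. Segments of fewer than 10 panelists (e.g. a
small preferer minority) are reported descriptively — per-level spike
proportions — without a fitted threshold, since a group line through a
handful of individuals invites over-interpretation.

## Synthetic panels

The generator encodes the population structure the analyses assume,
with defaults describing a consumer panel for a peppery odorant in red
wine:

| parameter | default | meaning |
|---|---|---|
| `anosmic_fraction` | 0.40 | specific-anosmia point mass; anosmics never detect |
| `threshold_median` | 100 ng/L | median of the log-normal responder thresholds |
| `threshold_log_sd` | 1.3 decades | SD of log₁₀ thresholds; wide enough that ≈ 2% of responders sit below a 0.2 ng/L ladder floor, matching the observed rate of panelists correct at every level |
| `psychometric_slope` | 2.0 /decade | logistic detection steepness; detection = 0.5 at threshold |
| `adaptation_carryover` | 0.8 | multiplier on detection probability at the level after a detection; a calibration choice producing occasional run-then-miss patterns, as no quantitative adaptation magnitude is available |
| `preferer_fraction` | 0.25 | share of detectors who like the spike (≈ 8 of 34 consistent responders) |
| `chance_level` | 1/3 | triangle guessing rate (2AFC preference uses 1/2 internally) |

Detection follows a **pure high-threshold guessing model**: an
undetected difference is answered correctly at exactly the chance rate,
which is the model under which the chance-corrected criterion
arithmetic ((1 + chance)/2) is exact. Adaptation is a one-step
carryover multiplier — the minimal mechanism that produces
correct-run-then-miss patterns — with no cumulative fatigue state.
Preference polarization is tied directly to detection probability
(P(choose spike) = 1/2 ± detection/2) with no separate liking
magnitude. All stage randomness derives from one integer seed through
fixed, label-keyed substreams, so identical configs reproduce
byte-identical CSVs.

What the generator does **not** emulate: serving-order and positional
biases, replicate triads, intensity ratings, taste/chemesthetic
contributions under retronasal delivery, non-monotone (inverted-U)
preference patterns, and panelist inattention. Passing recovery tests
therefore demonstrate estimator correctness under the stated
psychophysical model, not robustness to those real-world effects.

## Estimator behavior worth knowing

Two structural biases, both visible in the recovery diagnostics and
deliberately not "corrected" away:

* **Chance inflation of the responder count.** A true anosmic passes
  the BET responder gate with probability ≈ 0.375 (top-level answer
  correct by luck, or a lucky run of three), so a panel with a 40%
  anosmia rate yields a measured responder fraction near 0.69, not
  0.60. The same inflation operates on real panels scored by this rule.
* **Secant bias of the graphical inversion.** The OLS line through a
  saturating group psychometric curve crosses the criterion below the
  true crossing when the ladder brackets the threshold asymmetrically;
  with the default spread the median graphical estimate sits at ≈ 0.7×
  the generating crossing concentration — within the ×1.5 recovery
  tolerance, but a real property of the method.

Recovery tests summarize nine replicate panels (n = 200 each, seeds
0–8) by their median, so they test the estimator's central tendency
rather than a single Monte-Carlo draw; the estimator-ordering check
(ASTM geometric mean below the graphical estimate under adaptation
carryover ≤ 0.3) uses 50 replicates of the study-sized n = 109 panel.
These problem sizes keep the full suite under a few seconds while
holding Monte-Carlo noise well below the tolerances tested.

## Numerical choices

* OLS via `statsmodels`; pooled t-test via `scipy.stats.ttest_ind`.
  Independent test oracles use hand-written normal equations and
  closed-form t formulas.
* Inverse-prediction roots are bracketed in 0.25-decade steps out to
  ±12 decades from the point estimate; beyond that the bound is
  reported absent.
* Geometric means are computed as antilogs of means of log₁₀ values
  throughout; `sd_log_bet` uses ddof = 1 and is 0.0 for a single
  responder.
* Zero-responder groups summarize with absent (None) geometric mean
  rather than raising; empty or single-panelist regression segments
  raise an insufficient-data error.
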