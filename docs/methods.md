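# Methods

## Model and assumptions

The classifier is a counterpropagation network: a Kohonen self-organizing
map (SOM) whose units quantize the scaled feature space, cascaded into a
Grossberg readout trained by the outstar rule. The architecture assumes
that diagnostic structure in the five clinical features (age, years of
education, MMSE, FAQ, GDS) is captured by a vector quantization of the
joint feature space, with the local MCI prevalence of each quantization
cell serving as the score. This is a strong but convenient assumption: the
readout can represent any piecewise-constant score over the Voronoi cells
of the prototypes, and the lattice neighborhood regularizes adjacent cells
toward similar prototypes early in training.

Design points that the architecture description leaves open, resolved here:

- **Output encoding.** One Grossberg output unit carrying an MCI score in
  [0, 1], with desired output d ∈ {0, 1}. A single unit makes the
  threshold sweep (and hence the ROC) canonical; a two-unit one-hot
  encoding would need an extra score-combination rule.
- **Neighborhood kernel.** Crisp membership: every unit within the radius
  receives the full rate α, all others none. No Gaussian weighting — the
  update rule is used exactly as written.
- **Lattice metric.** Chebyshev distance on square lattices; hexagonal
  lattices use odd-row offset coordinates and the standard cube (hex)
  distance. Toroidal wrap takes the minimum over copies of the target unit
  shifted by ± rows and ± cols (minimum image). On hexagonal tori with odd
  wrap lengths the row parity flips at the seam, so hex toroidal distances
  are approximate there; all lattice geometries used by default have even
  dimensions.
- **Tie-breaking.** Winner competition breaks distance ties toward the
  lowest unit index. This makes seeded runs exactly replayable.
- **Simultaneous training.** Both layer updates are applied on every
  presentation; there is no separate SOM-then-readout phase.
- **Classification rule.** A record is called MCI when its score strictly
  exceeds the threshold; a score exactly at the threshold is a control
  call.

## Training schedule and parameters

With t the presentation counter and T = epochs × n_records:

| parameter | default | meaning |
|---|---|---|
| epochs | 100 (training), 30 (subset search) | passes over the training set |
| α₀ | 0.5 | initial SOM rate; α(t) = α₀(1 − t/T) |
| γ₀ | 0.1 | initial outstar rate; γ(t) = γ₀(1 − t/T) |
| radius₀ | max(rows, cols)/2 | neighborhood radius, linear to 0 over the first half of training, winner-only thereafter |
| lattice | 8×8 (training), 6×6 toroidal square (search) | units = rows × cols |
| θ | balanced operating point | score threshold |

Prototypes initialize uniformly in [0, 1]^k (seeded); the readout starts at
0.5, i.e. maximal uncertainty. Because inputs are scaled to [0, 1] and both
updates are convex pulls, prototypes never leave the unit hypercube and the
readout never leaves [0, 1] — both are enforced by property tests. All
randomness flows from a single master seed through a counter-based
`SeedSequence` derivation.

The search defaults (6×6 toroidal map, 30 epochs, one geometry, one seed
per subset) are the package's standard fitness configuration for the
wrapper: on the reference synthetic cohort they keep a full 25-subset
exhaustive search under a few seconds while reproducing the expected
subset ranking behavior (FAQ-bearing subsets on top). The
repeated-search check in the acceptance suite runs 20 such searches on
freshly generated cohorts.

## Feature scaling and splitting

Features are min–max scaled to [0, 1] per feature, with bounds learned on
the training split only; test values outside the training range are clipped
so the SOM always sees the unit hypercube. Scaling is linear and
order-preserving. A constant training feature is an error, not a silent
drop.

Stratified splitting draws the test set per label without replacement from
a seeded generator. The number of MCI cases in the test set is
ceil(test_count × prevalence): the case stratum is rounded up so the rarer
class is never under-represented in the held-out evaluation. For the
reference cohort (331 subjects, 128 MCI, 76-subject test set) this yields
30 cases and 46 controls — the composition implied by the published
per-rate denominators, where every reported sensitivity is a multiple of
1/30 and every specificity a multiple of 1/46.

## Synthetic cohort generator

The generator emulates the published group-wise marginal structure — mean,
SD and observed range per feature, per diagnostic group (203 controls, 128
MCI) — using one truncated normal per feature, rounded to integers for the
discrete scales (all but age). What it deliberately does **not** emulate:

- **Inter-feature correlation.** Features are drawn independently within a
  group; the published table carries no covariance information. Real
  cognitive and functional scores are correlated, so a network trained on
  synthetic data faces an easier (more factorized) problem.
- **Distribution shape beyond two moments and a range.** FAQ in the MCI
  group is strongly zero-inflated in real cohorts; a truncated normal on
  [0, ∞) cannot exceed a coefficient of variation of 1, so the printed
  SD of 4.4 at mean 3.6 is unreachable. The realized SD (~3.5) is the
  closest the family allows.

Because truncation and rounding shift moments (drastically for the skewed
scales), the generator calibrates the parent distribution at generation
time: the parent location is solved by bisection on the monotone map from
location to realized post-truncation/post-rounding mean (computed with
log-space tail-accurate interval probabilities), so the realized
expectation equals the printed mean exactly; the parent scale is then
chosen by bounded scalar minimization to bring the realized SD as close as
the family allows. Sample means are the tested contract (within 3 standard
errors at 20× group sizes); SDs are best-effort.

Consequently, passing tests on synthetic cohorts demonstrate that the
pipeline recovers *which* features carry signal and that the evaluation
machinery is correct — not that real-data AUC levels are reproduced. The
published real-data AUCs (e.g. 95.11% for Age+MMSE+FAQ) depend on the
access-controlled source cohort and are reproduced only qualitatively
(FAQ-dominated rankings, AUCs in the same high range).

## Evaluation suite

- **ROC sweep.** Thresholds are the distinct scores plus sentinels below
  the minimum and above the maximum, so the curve always contains (0,0)
  and (1,1). Positive calls require score strictly above the threshold,
  matching the classifier. The trapezoid AUC of this sweep equals the
  Mann–Whitney rank statistic; a property test checks agreement to 1e-12.
- **Convex hull.** Upper envelope (Andrew monotone chain) over the sweep
  points plus the corners. Hull AUC is the wrapper's fitness and the
  ranking statistic; the raw AUC is also reported. Hull points that are
  interpolations (not sweep points) carry no threshold.
- **Balanced threshold.** The sweep threshold minimizing
  |sensitivity − specificity|, ties toward higher sensitivity.
- **Single-scale cut-offs.** Integer mid-point cut-offs of one scale used
  as a univariate classifier: FAQ/GDS call impairment above the cut-off,
  MMSE below (clinical orientation). The chosen cut-off maximizes
  accuracy, ties toward higher sensitivity; cut-off labels like "0/1" name
  the two adjacent scores the boundary separates. Accuracy (rather than
  the Youden index) is the criterion because it is the quantity the
  comparison tables report alongside their chosen cut-offs.
- **Clinical utility.** CUI+ = sensitivity × PPV, CUI− = specificity ×
  NPV, graded at 0.81/0.64/0.49. When a system makes no false-positive
  calls but some true positives, PPV is defined as 1 (every positive call
  is correct); symmetrically NPV = 1 when there are no false negatives.
  This convention is required to evaluate raters with 100% specificity.
- **Confusion reconstruction from printed rates.** tp and tn are the
  nearest integers to sen × n_pos and spc × n_neg; re-derived rates must
  agree with the inputs to within 0.55 of one unit in the last printed
  digit. The tolerance is slightly above half an ulp because published
  tables occasionally double-round (three decimals, then two), which
  shifts boundary cases; inconsistent inputs are an error naming the
  nearest consistent counts.
- **Pooled rater summaries** are arithmetic means, reported under both
  rounding and truncation conventions because published summaries have
  used either.

## Numerical and degenerate-input choices

- Zero training epochs returns the initialized model (usable, score 0.5
  everywhere).
- A single-unit SOM degenerates to a running average: the readout follows
  an exponentially weighted mean of the labels under the decaying γ
  sequence and converges to the training prevalence (tested against an
  independent replay oracle to 1e-2).
- Evaluation with a single-class cohort, a constant scale, or undefined
  rate denominators raises a named error rather than returning NaN.
- CSV round trips are exact, including float age values
  (round-trip-precision parsing).

## Known limitations

- The wrapper evaluates a single train/test split, as in the original
  protocol; no cross-validation or AUC confidence intervals.
- Hexagonal toroidal distance is approximate at odd wrap lengths (see
  above).
- The generator's independence assumption means synthetic multi-feature
  subsets understate the redundancy present in real data; subset rankings
  beyond the leading (FAQ-bearing) group should not be over-interpreted.
- No longitudinal records, missing-data handling, or class-label noise.
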