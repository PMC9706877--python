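# Methods

## Cohort model

A patient record holds a sub-cohort label (`moderate_severe`: GCS < 13;
`unrecorded`: intubated before a GCS was recorded), a sampling delay in
hours since injury (0–24), six strictly positive serum concentrations
(GFAP, NSE, S100B in ng/ml; NFL, Tau, UCH-L1 in pg/ml), and an
Adams-Gentry stage. The original grading has stages 1–3 (hemispheres,
corpus callosum, brainstem); we add stage 0 as the explicit "no axonal
injury" code. `brainstem_injury` is not stored: it is defined as
`adams_gentry == 3`, so the equivalence between flag and stage holds by
construction.

Group summaries print `median (q1–q3)` with quartiles by linear
interpolation between order statistics (the default convention of
mainstream statistics software; reported quartiles from other conventions
can differ slightly at small n) and counts as `n (percent%)` with the
percent rounded half-up to an integer.

## Synthetic cohorts

Patient-level source data is access-restricted, so the generator emulates
its published statistical structure:

- **Sizes and prevalences.** n = 30 (moderate-severe) + 35 (unrecorded);
  brainstem-injury probability 17/30 and 16/35 respectively. Within
  "brainstem absent", stage 0 takes the published no-axonal-injury margin
  (11 of the 32 brainstem-absent patients, i.e. 11/32 conditionally), and
  stages 1 and 2 split the remainder evenly; these splits are config fields.
- **Marginals.** Each of the 24 (sub-cohort × brainstem status × protein)
  cells is a log-normal fitted to the published `median (q1–q3)`:
  `mu = ln(median)`, `sigma = ln(q3/q1) / (2·0.6745)`. Log-normality is the
  standard positive-support assumption for serum proteins. Note the fit
  preserves the median and the quartile *ratio*; a published cell that is
  asymmetric on the log scale (q1·q3 ≠ median², e.g. the moderate-severe
  UCH-L1 brainstem-present cell) cannot have both quartiles matched
  individually by any log-normal with that median. Tests therefore check
  median recovery (within 2% at n = 10⁵) and quartile-ratio recovery.
- **Dependence.** The six log-concentrations are drawn jointly with an
  exchangeable Gaussian copula, `z = √ρ·common + √(1−ρ)·own`, default
  ρ = 0.5 — a plausible value for co-released injury markers; no published
  correlation exists, so ρ is a knob and nothing downstream depends on its
  value.
- **Sampling delay.** Log-normal fitted to the overall published summary
  16 (11–21) h, truncated to [0, 24] by rejection sampling (~97% acceptance).
- **Sub-cohort contrast.** The moderate-severe defaults carry a real
  biomarker–brainstem association because the fitted arm marginals differ;
  the unrecorded arms overlap heavily, reproducing the published negative
  finding by construction rather than by an extra mechanism.

What the generator does *not* emulate: biomarker kinetics (concentration–
delay dependence), transfusion dilution, measurement error or assay floors,
and within-stage lesion-burden heterogeneity. Passing tests therefore show
the pipeline behaves correctly under the assumed structure, not that the
published thresholds or p-values would be recovered on real patients.

## Rank tests and multiplicity

Both tests are implemented from first principles (scipy/statsmodels serve
only as independent oracles in the test suite).

- **Mann–Whitney U** with `U = #{x_a < y_b} + ½·#ties`. For
  n_x + n_y ≤ 12 without ties, the p-value is exact by full enumeration of
  the C(n, n_x) group labelings; otherwise a normal approximation with
  tie-corrected variance `n_x n_y/12 · [(n+1) − Σ(t³−t)/(n(n−1))]` and a
  0.5 continuity correction. Two-sided p = 2·min(P(U≤u), P(U≥u)), capped
  at 1.
- **Jonckheere–Terpstra** `J = Σ_{i<j} U_ij` over stage-ordered group
  pairs. Exact by enumeration of all distinct assignments for total
  n ≤ 10; otherwise the tie-corrected normal approximation (the classical
  variance `[N²(2N+3) − Σnᵢ²(2nᵢ+3)]/72` plus the standard tie terms) with
  continuity correction, or an optional seeded Monte-Carlo permutation
  scheme (default 10⁴ draws, vectorised). The method used is recorded in
  the result. The two-sided p is 2·min(P(J≥j), P(J≤j)) capped at 1 — on a
  discrete null both tails include the observed value's mass. With the
  continuity correction the normal approximation tracks permutation
  p-values within ~0.012 for balanced groups of size 8.
- **Benjamini–Hochberg** step-up: sort ascending,
  `adj_(i) = min_{k≥i} m·p_(k)/k`, cap at 1, return in input order. The
  adjustment family is one displayed table — the six proteins plus the
  sampling-delay row, matching the published per-sub-cohort layout; whether
  the delay row belongs to the family is not documented anywhere, so it is
  an `include_sample_time` flag. Rows are flagged significant at adjusted
  p < 0.05.

The exact/approximate switchover points (12 and 10) keep enumeration at
desk scale; they are arguments, not constants.

## Constrained cutpoints

The triage rule is "transfer iff concentration ≥ c". Candidates are the
observed concentrations: with a "≥" rule they enumerate every distinct
empirical operating point (a "> v" rule equals "≥ next observed value"), so
exhaustive search is exact. Among candidates with sensitivity ≥ the floor,
the maximiser of specificity is returned; ties are broken toward the
smallest threshold, which maximises the sensitivity margin — the original
analysis' tie-break is unreported, so this is a package choice. The
all-positive rule (c = min observed value) has sensitivity 1, so the
constraint is always feasible for floors ≤ 1. With 17 positives the
achievable sensitivities are k/17, making 16/17 ≈ 0.94 the binding level
under a 0.90 floor. Sensitivity and specificity are rounded to two decimals
in reports only.

## Cost model

Per patient: `cost_triage = cost_assay + fraction_above · cost_MRI` and
`savings = cost_MRI − cost_triage = (1 − fraction_above)·cost_MRI −
cost_assay` (may be negative; cost-neutral at fraction_above = 1 −
cost_assay/cost_MRI). Unit costs live in YAML configs: UK (GBP; MRI incl.
transfer 385.80; research-assay costs per protein 13.68–22.45) and US (USD;
MRI 2758.56; the FDA-approved i-stat point-of-care platform at 65.16,
pricing only GFAP and UCH-L1 — other proteins report "–"). The UK assay
costs were derived from the published per-patient strategy-cost rows, whose
arithmetic they reproduce exactly; whether they intentionally differ per
protein is unknown. Missed-injury costs are deliberately excluded: the
safety trade-off enters only through the sensitivity floor.

## Pipeline

`run_pipeline` runs both association outcomes in three scopes (each
sub-cohort and pooled), then cutpoints + costs on the moderate-severe
sub-cohort at each requested sensitivity floor (0.90 and 1.00 by default).
Degenerate scopes (one outcome class) are skipped with a logged notice and
recorded in the manifest. Every stochastic step consumes the run seed; the
manifest stores SHA-256 hashes of all outputs, and re-running with the same
inputs reproduces identical hashes.

## Numerical and degenerate-input choices

- CSV floats are written with `repr` and parsed with round-trip precision,
  so write-then-read is the identity on valid cohorts.
- Zero-variance situations (all observations tied) return p = 1.
- Monte-Carlo permutation p-values use the add-one correction
  `(count+1)/(B+1)` and are therefore never exactly 0.
- Empty groups, single-class labels, out-of-range probabilities and
  malformed configs raise typed errors before any computation.

## Known limitations

- Published thresholds (e.g. GFAP 5.73 ng/ml) and p-values depend on the
  restricted patient-level data and are not reproduction targets; the
  package reproduces the arithmetic identities of the published operating
  points and costs, and the method's statistical guarantees, instead.
- The generator's marginal independence from sampling delay and the
  exchangeable-correlation assumption are simplifications (see above).
- No ROC smoothing, confidence intervals, QALY modelling or
  transfer-complication risk model; empirical operating points only.
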