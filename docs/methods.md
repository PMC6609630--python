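# Methods

`dmetpk` implements a two-stage meta-analysis of literature-reported
drug-metabolizing-enzyme (DME) protein abundances and the downstream
derivation of physiologically based pharmacokinetic (PBPK) input parameters
by in vitro–in vivo extrapolation (IVIVE). This note records the models,
the assumptions behind them, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Data model and inclusion criteria

A repository row is one published observation: a central value (mean or
median) of abundance for one protein in one tissue preparation, with SD,
range and/or %CV as reported, donor count, pooled-sample flag, analytical
method, quantification mode, verbatim unit, demographics and a citation
key. Nothing is imputed at load time: missing cells stay missing, units are
preserved verbatim (a canonical-unit flag is derived), and a reported %CV
that contradicts 100·SD/mean by more than 0.5 percentage points is rejected
as a data error rather than silently reconciled.

The meta-analysis inclusion filter retains records that are
(i) individual-donor (not pooled), (ii) absolute quantification by LC-MS/MS
or Western blotting, (iii) expressed per mg microsomal protein — the
canonical `pmol/mg microsomal protein` or an exact power-of-ten respelling
(`fmol/µg`, `pmol/µg`); any other unit is excluded, never converted
heuristically — and (iv) reported by at least two distinct laboratories per
protein/tissue group, operationalized as distinct citation keys because no
finer laboratory identifier exists in literature metadata. Every input
record is accounted for exactly once: it is either retained or counted
against the first criterion it fails, and the exclusion report carries the
per-criterion tallies.

Two deliberate inclusivity choices: median-reported studies are pooled as
if they were means (the provenance is flagged on the observation) because
excluding them would silently change the number of studies; and studies
lacking both SD and %CV are retained — they still inform the sample-size
weighted mean — but are counted (`range_only_studies`) and excluded from
every variance-based computation.

## Heterogeneity stage (inverse-variance weighting)

For studies with means X_j and reported SD_j > 0, the fixed-effect (FE)
summary is μ_F = Σw_j X_j / Σw_j with w_j = 1/SD_j², and Cochran's
Q_F = Σw_j (X_j − μ_F)². The weights are the inverse of the *study
variance*, not the squared standard error: heterogeneity between
laboratories is judged against the biological spread each laboratory itself
reports. The random-effects (RE) model uses the method-of-moments
(DerSimonian–Laird) between-study variance
τ̂² = (Q_F − df) / (Σw_j − Σw_j²/Σw_j) when Q_F > df and τ̂² = 0 otherwise
(the tie Q_F = df counts as the zero case), re-weights by
w*_j = 1/(w_j⁻¹ + τ̂²), and reports μ_R and Q_R analogously. When τ̂² = 0
the RE results collapse exactly onto the FE results.

Indices: H² = Q/df; I² = (H² − 1)/H² · 100, floored at zero; P is the
upper-tail χ² probability of Q at df (computed with `scipy.stats.chi2.sf`,
cross-checked in the tests against direct quadrature of the hand-written
density to 1e−10). Classification uses the conventional anchors 0%, ~25%,
~50%, ~75%: I² = 0 is "none", (0, 37.5) "low", [37.5, 62.5) "medium",
≥ 62.5 "high" (midpoint boundaries); H² > 1.5 is flagged as considerable
heterogeneity concern, H² < 1.2 as little, otherwise intermediate.

Studies without a positive SD are excluded from this stage only; `k_used`
is reported next to `k` so the reader can see how many studies carried
weight. No Hartung–Knapp adjustment, REML/ML τ² estimator, meta-regression
or publication-bias test is provided — the estimator set is deliberately
the method-of-moments one.

## Pooling stage (sample-size weighting)

The pooled abundance is WM = Σn_j X_j / N over all studies. Three %CV
estimators are computed, differing in what variability they count:

* **Method I** — between-study only: ν = Σn_j (X_j − WM)²/N,
  %CV = 100·√ν/WM.
* **Method II** — between plus within: overall sum of squares
  Σ[(SD_j² + X_j²)·n_j] − N·WM², i.e. exactly the pooled sum of squares of
  the N individuals implied by each study's mean and (population) SD;
  %CV = 100·√(SS/N)/WM. Method II ≥ method I always, with equality iff all
  SD_j = 0 (identity SS = N·ν + Σn_j SD_j², verified in the tests against a
  brute-force pseudo-individual expansion).
* **Method III** — sample-size-weighted mean of the study-level CVs.

Confidence intervals are geometric, assuming lognormal abundances:
σ = √ln[(%CV/100)² + 1] and CI = exp[ln WM ± z·σ/√k], z = 1.96 by default.
The interval is symmetric on the log scale, always contains WM, widens
strictly with z, and degenerates to a point at %CV = 0. Method II is the
default source of the %CV fed into downstream scale factors because it is
the widest of the three and the least sensitive to a small number of
studies.

`run_meta` prefers a partial report over a failure: any component whose
required fields are missing is left unset with the reason in `notes`.
Per-study forest-plot intervals are presentational only (mean ± z·SD_j/√n_j
on the arithmetic scale; no per-study interval convention exists for these
data) and never feed any pooled quantity.

## IVIVE chain

With clinical intravenous plasma clearance CL_IV and renal fraction
f_CL,renal: CL_R = f_CL,renal·CL_IV and CL_H = (1 − f_CL,renal)·CL_IV
(a user-supplied CL_H overrides). The well-stirred liver model gives the
unbound intrinsic hepatic clearance

    CLu_int,H = Q_H,B·CL_H / (fu_p·(Q_H,B − CL_H/B:P)),

defined only while CL_H/B:P < Q_H,B; the algebraic inverse
(`well_stirred_forward`) is provided for round-trip validation and
approaches flow-limited clearance Q_H,B as CLu_int,H → ∞. The per-isoform
partition is CLu_int,DMEj = f_m,j·CLu_int,H / (1 − f_CL,renal); nested
pathway specifications (a pathway total split by percentages) are
normalized to absolute fractions at construction. Conversion to a
per-mg-microsomal-protein in vitro CL_int divides by
MPPGL·liver-weight·60·10⁻⁶ (L/h → µL/min and whole-liver → per-mg; the
factor appears exactly once in the code), and

    Vmax,j = in-vitro-CL_int,j · Km,j · fu_mic / (abundance_j · ISEF_j)

yields pmol/min per pmol enzyme. Both round trips (forward/backward
well-stirred; Vmax back to CLu_int through the scaling module with unit
scale factors) hold to 1e−9 relative and are enforced in the tests.

**Hepatic blood flow calibration.** The packaged adult physiology sets
Q_H,B = 81.8 L/h. This is a calibration, not a physiological claim: it is
the flow under which the well-stirred back-calculation maps the packaged
lamotrigine parameters (CL_H = 1.8 L/h, fu_p = 0.45, B:P = 1) onto
CLu_int,H = 4.09 L/h exactly, making the packaged parameter set internally
consistent. Users with a preferred flow should supply their own physiology
file; the chain is otherwise flow-agnostic.

The packaged lamotrigine asset uses the published split: glucuronidation
0.86 of clearance divided 10%/90% between UGT1A3 (Km 70 µM, abundance 7.6
pmol/mg) and UGT1A4 (Km 550 µM, abundance 7.9 pmol/mg), a minor CYP pathway
at 0.04, ISEF = fu_mic = 1, MPPGL = 38 mg/g, liver 1637.7 g. Recomputing
the chain without intermediate rounding gives Vmax(UGT1A4) = 65.58; the
published table prints 65.54 because it chains rounded intermediates, a
0.06% discrepancy inside the comparison policy below. Intestinal metabolism
is not modelled (oral bioavailability of the reference drug is near-unity),
and no absorption or concentration–time simulation exists in this package:
the output is a parameter sheet for an external PBPK simulator.

## Scale factors

All adjustments are multiplicative, so SF = 1 is the identity and SF then
1/SF cancels exactly.

* `SF_CI` = (pooled CI bound)/(pooled WM) converts pooled-abundance
  uncertainty into Vmax bounds (mode `"ci"`).
* `SF_DME` = population/adult abundance ratio and `SF_MPPGL` =
  population/adult MPPGL ratio scale Vmax for age or disease
  (mode `"population"`); forward IVIVE with the population liver weight and
  MPPGL gives the scaled CLu_int.
* `SF_fu×GFR` = (fu·GFR)_population/(fu·GFR)_adult scales renal plasma
  clearance; GFR values carry explicit unit tags and mismatched tags are an
  error.

Every `ScaleFactorSet` requires a provenance string so that separately
derived sets (e.g. alcoholic- vs HCV-cirrhosis, whose UGT1A4 abundances are
12- and 4-fold below healthy adult respectively) cannot be conflated. The
packaged population files carry the published liver weights (592.12 g at
4 y, 726.23 g at 7 y, 906.24 g at 9 y, 867.97 g for Child-Pugh C at 30 y)
and ages/weights; paediatric and HI fu_p and GFR are *not* published, so
those fields ship as nulls and every operation that needs them raises
rather than defaulting silently. Paediatric MPPGL is written explicitly as
the adult 38 mg/g in the data files, as data a user can edit, not as a
hidden code default. Paediatric gastric-emptying and absorption settings
are out of scope (no absorption model exists here).

The model-evaluation interval (`acceptance_range`) reuses the geometric CI
at z = 4.26 (99.998%), with k equal to the number of subjects in the
clinical study whose %CV is used — per-subject variability is what a
clinical %CV describes. A missing %CV yields "not applicable" (None), never
a fabricated interval.

## Synthetic data generator

`generate_study_set` emulates the data-generating process the pooling
assumes: individual abundances lognormal with geometric mean
`true_gm · b_j`, within-study log-SD σ_w = √ln(gcv_within² + 1), and a
per-laboratory bias b_j ~ lognormal(0, bias_sd_log). Each study reports its
sample mean, sample SD (population convention, matching the method II
identity) and n. Defaults — geometric mean 40 pmol/mg, gcv_within 0.5,
bias_sd_log 0.5, k = 10 laboratories of 5–40 donors — describe a typical
hepatic UGT meta-analysis in which inter-laboratory spread rivals the
biological spread. Randomness is counter-based: study j draws from
`default_rng([seed, j])`, so early studies are invariant to k.

Closed-form targets: the all-donor population is lognormal with total
log-variance σ_w² + bias_sd_log², hence arithmetic mean
`true_gm·exp(σ_tot²/2)` (target of WM) and total CV √(exp(σ_tot²) − 1)
(target of method II). The generator does not emulate peptide-level LC-MS
noise, digestion efficiency, calibration error, reporting/rounding error,
demographic covariate structure, or non-lognormal tails — so passing
recovery tests demonstrate estimator correctness under the assumed model,
not robustness of literature data to violations of it.

Heterogeneity-detection checks use gcv_within = 0.3 with n = 25 donors per
study: at zero lab bias the study means scatter only by sampling error
(≈ SD/5), which is tiny against the SD used as the FE weight, so mean I²
over 500 replicates is ~0; at bias_sd_log = 0.5 the between-laboratory
spread exceeds the biological SD and mean I² exceeds 50%. The %CV-recovery
check (k = 20, n = 50, 500 replicates) recovers the analytic total CV
within 10% relative; a small negative bias (~4%) remains because the
pooled estimator at finite k slightly under-weights the between-laboratory
variance component.

## Numerical and comparison policy

* Comparisons against published, rounded values use one unit in the last
  printed decimal place or 0.5% relative, whichever is larger, because the
  source tables chain rounded intermediates. When the *input* of a
  reconstruction is itself rounded (the 2-dp Q feeding I²), the tolerance
  additionally absorbs the propagated input rounding (dI²/dQ = 100·df/Q²,
  giving ≤ 0.1 percentage points on I²).
* One published pooled row (CES1, method III) fails its own CI relation:
  the printed bounds imply a log-SD about twice the one implied by the
  printed %CV. The row ships verbatim in the data asset with
  `consistent=0` and is skipped by reconstruction checks.
* P-values are stored at full double precision; table renderers may round
  for display but nothing downstream consumes a rounded P.
* Degenerate inputs fail loudly and specifically: no usable SD, single
  study (df = 0), renal-only clearance (f_CL,renal = 1), clearance
  exceeding hepatic flow, missing population fu/GFR, zero abundance, and
  GFR unit mismatches each raise a named error.
* Monte-Carlo problem sizes (500 replicates; k = 10–20 studies; 25–50
  donors per study) were chosen as the smallest sets at which the
  Monte-Carlo error is comfortably below the tolerances being checked.

## Known limitations

* The heterogeneity stage weights by 1/SD², so studies reporting no SD are
  invisible to it; a study-count discrepancy (`k_used < k`) is reported but
  no imputation is attempted.
* Unit handling converts only exact power-of-ten respellings of the
  canonical unit; per-gram-tissue or per-million-cells data are excluded,
  not converted, since the conversion factors are preparation-specific.
* The package derives PBPK *inputs*; it does not simulate concentration–
  time profiles, absorption, or tissue partitioning, and therefore cannot
  itself validate predictions against clinical exposure data beyond
  providing the z = 4.26 acceptance interval machinery.
* Population scale factors are ratios of means (or CI bounds); no
  uncertainty propagation across the ratio is performed.
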