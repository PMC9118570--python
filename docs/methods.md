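# Methods

## Overview

The package implements the computational side of a two-tracer isotope-dilution
study of glucagon kinetics in humans: generation of the targeted-MS transition
list for isotopically labeled glucagon species, calibration-curve quantitation
of tracer plasma concentrations, and estimation of glucagon turnover (rate of
appearance Ra, rate of disappearance Rd, volume of distribution Vd) by the
non-steady-state isotope-dilution method. A forward simulator generates
synthetic studies with known ground truth so every stage can be validated by
parameter recovery.

## Exact-mass model

Glucagon is the 29-mer `HSQGTFTSDYSKYLDSRRAQDFVQWLMNT`. Tracer species are
defined by residue-indexed isotope substitutions: F22 (Phe22 ¹³C₉,¹⁵N₁, the
internal standard), FF (Phe6 + Phe22), and FFLA (FF plus Leu14 ¹³C₆,¹⁵N₁ and
Ala19 ¹³C₃). Masses are computed from a hard-coded table of IUPAC monoisotopic
residue masses (cross-checked in the test suite against pyteomics' independent
table) plus one water (18.010565 Da) for the intact peptide. Label shifts are
exact per-atom differences: ¹³C−¹²C = 1.0033548 Da, ¹⁵N−¹⁴N = 0.9970349 Da, so
one labeled Phe adds 10.02723 Da and the full FFLA set 30.08168 Da.

Precursor m/z at charge z and isotopologue M+k is
`(M + Δlabels + z·m_p + k·1.0033548)/z` with proton mass m_p = 1.0072765 Da
(the physical proton; configurable, since conventions differ in the fourth
decimal). b-ion fragments (N-terminal acylium ions) omit the water term and
carry only the label shifts at positions ≤ n. Isotopologue spacing uses the
¹³C mass difference throughout — for peptides the M+k envelope is dominated by
¹³C substitution, and the sub-m/z-unit error of ignoring ¹⁵N/²H contributions
is far below the ±0.01 m/z tolerance of the targeted method.

The default transition layout mirrors the acquisition scheme: SIM precursors
at 4+, with the unlabeled species monitored from M+1 (its M+0 is monitored
less favorably in matrix) and labeled species from M+0, and PRM b25/b26/b27 at
3+ with two isotopologues each. The layout (charges, fragments, isotopologue
sets) is fully configurable. Only m/z positions are produced, not envelope
intensities; y/a-ions and neutral losses are out of scope.

## Calibration and validation

Quantitation uses analyte/internal-standard peak-area ratios (IS spiked at
50 pg/ml). Calibration fits a least-squares line of mean area ratio on nominal
concentration over the seven-level ladders (tracers 1.56–100 pg/ml, unlabeled
3.125–200 pg/ml); weighting options are none (default), 1/x and 1/x². For
multiplicative (constant-CV) assay noise, 1/x² is the statistically matched
weighting and is what the analysis scripts use when back-calculating low-end
levels: unweighted OLS over a 64-fold range leaves an intercept uncertainty of
a few tenths of pg/ml, which alone can push the 1.56 pg/ml level past the 25%
relative-error limit. Pearson r is always reported on the unweighted points.

Decision rules:

* **LOD** — lowest level with every replicate S/N ≥ 3 and mean response above
  blank mean + 3·SD(blank). S/N values come from upstream peak integration
  and are inputs, not recomputed.
* **LOQ** — lowest level with replicate CV ≤ 25% and |mean−nominal|/nominal
  ≤ 25%.
* **QC precision** — intra-day CV is the root-mean-square of per-day CVs;
  inter-day CV is by default the total CV of all measurements pooled across
  days (a deliberately simple estimator that upper-bounds the between-day
  component), with a one-way variance-components (ANOVA) alternative behind a
  flag. Note the ANOVA between-day component is not bounded by the total CV
  in small samples.

Back-calculated concentrations below zero are returned with a flag, never
clipped, so QC summaries remain unbiased. Blank (plasma-only, no IS) records
are excluded from curve fitting.

## Turnover model

With TTR = C_FF/C_total (tracer over ELISA total; the classical
tracer-over-tracee denominator is available behind a flag), the
non-steady-state equations are

    Ra = F_FF/TTR − F_FF − F_FFLA − p·Vd·C·(dTTR/dt)/TTR
    Rd = Ra + F_FF + F_FFLA − Vd·(dC/dt)

Units: rates pg/kg/min, concentrations pg/ml, Vd ml/kg — then every term is
pg/kg/min and no explicit body-weight division appears (it is absorbed by
expressing Vd per kg). The pool fraction p defaults to 1 (the single
well-mixed pool is taken literally); a multiplier is exposed for sensitivity
analysis. For a one-compartment system these equations are *exact* in
continuous time — substituting dC_FF/dt = F_FF/Vd − k·C_FF and the analogous
total-pool balance into C·dTTR/dt reproduces Ra identically — so the only
estimation error on simulated data is discretization and noise.

Discretization: two-point finite differences on consecutive samples, TTR and
C as two-point interval means, infusion rates at the interval midpoint,
results assigned to midpoints (n samples → n−1 estimates). An optional
moving-average smoother (off by default) can precede differencing for noisy
series. Negative Ra/Rd transients are reported with flags, never truncated.

Vd comes from FF-bolus decay: nonlinear least squares of C(t) = C0·e^(−kt)
(log-linear start values; a non-negative log-linear slope is reported as a
fit failure), with Vd = (dose/C0)/TBW and standard errors from the fit
covariance.

## Synthetic data

Each pool (endogenous, FF, FFLA) follows dC/dt = input(t)/Vd − k·C, integrated
by fixed-step RK4 on a 0.1-min grid (well below any sampling interval; the
piecewise-constant infusions make adaptive steppers awkward and the linear
ODEs make RK4 error negligible at this step). A bolus contributes
C(0+) = dose/(Vd·TBW); a primed study can start all pools at their
steady states. Total = endogenous + FF + FFLA, mirroring an ELISA that cannot
distinguish the species.

Noise is multiplicative Gaussian per channel (CV-proportional, matching how
assay precision is quoted), truncated at −3σ by default so concentrations stay
positive; a flag allows negative excursions for robustness testing. Identical
seeds give bit-identical output.

Default study conditions, chosen once as a realistic emulation: Vd = 40 ml/kg
(the cohort bolus-decay estimate), k = 0.1/min (≈7-min half-life), basal
endogenous Ra = 280 pg/kg/min so fasting endogenous glucagon ≈ 70 pg/ml,
tracer infusions 14 pg/kg/min each (≈5% enrichment, ≈3.5 pg/ml at steady
state), LC-MS channel CVs 5.5% (FF) and 4.5% (FFLA) with a 13% between-day
batch effect, ELISA total CV 7%, sampling dense in the first 15 min after a
bolus then sparse to the 350-min end point. The postprandial scenario doubles
endogenous Ra with a gamma-like pulse `basal + (peak−basal)·(t/t_p)^a·
exp(a(1−t/t_p))` peaking at t_p = 60 min (shape a = t_p/decay, default a = 1).
The bolus scenario uses 7×10⁵ pg (C0 = 250 pg/ml at 70 kg) with 12 samples
over 50 min and 10% FF noise for estimator characterization.

What the simulator does **not** emulate: chromatographic peak shape and
integration, enrichment/recovery losses, ELISA cross-reactivity, hepatic
extraction, multi-compartment distribution, or within-subject physiological
variability beyond the single Ra pulse. Passing recovery tests therefore
demonstrates correctness of the computational pipeline under the model's own
assumptions, not accuracy of the one-compartment model for real subjects.

## Numerical choices and edge cases

* Non-positive TTR denominators or intervals yield NaN estimates plus a flag,
  never exceptions mid-series; strictly increasing sample times are enforced.
* Zero FF administration combined with nonzero TTR is rejected as
  inconsistent input.
* Calibration requires ≥ 3 distinct levels; LOQ requires ≥ 3 replicates per
  level; inter-day precision requires ≥ 2 days × 2 replicates.
* Analysis problem sizes: recovery studies use 50 seeds (Vd) and 200 seeds
  (calibration r), 1-min sampling over 350 min for discretization checks —
  large enough that the stochastic summaries are stable to the stated
  tolerances.

## Known limitations

* Two published transition-table entries (FF b26, FFLA b27) and one M+1 value
  disagree with label-shift arithmetic by ≈1 Da/3 (consistent with transcribed
  typos); the generator emits the computed values.
* The "Label m/z" identifier strings attached to published transition rows are
  internally inconsistent with the label shifts and are treated as opaque row
  labels.
* Published QC nominals differ between the tabulated design (13.33/40 pg/ml)
  and the validation text (13.3/44); the tabulated values are the default.
* The inter-day CV estimator is not uniquely defined in standard practice;
  both implemented estimators can differ appreciably for 3-day designs.
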