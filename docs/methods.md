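# Methods

## The selection ensemble

The screening problem is a small-n / large-p classification: four cohorts
(NCAD, CAD, STEMI-pre, STEMI-PCI), six samples each, 809 miRNA expression
values per sample. Instead of one model, the package runs a grid of
sparse penalized logistic regressions and aggregates *which features are
selected how often*:

* **Contrasts.** For four cohorts ordered chronic → acute, eleven binary
  contrasts are enumerated: the six unordered pairs plus five merged
  contrasts (NCAD+CAD vs STEMI-pre; NCAD+CAD vs STEMI-PCI; NCAD vs
  STEMI-pre+STEMI-PCI; CAD vs STEMI-pre+STEMI-PCI; NCAD+CAD vs
  STEMI-pre+STEMI-PCI). The first-listed side is the reference (y = 0),
  so a positive coefficient means higher expression raises the odds of
  the acute side.
* **Penalties.** LASSO (convex, biases large coefficients) and SCAD
  (non-convex, asymptotically unbiased for large coefficients; shape
  a = 3.7, the conventional default).
* **Feature subsets.** Four nested sets induced by a per-feature
  annotation: cardiac (450) ⊂ +vasculature (565) ⊂ +cerebral/rare (576)
  ⊂ all (809).

Each of the up-to-88 configured models is tuned by leave-one-out
cross-validation (chosen for n as small as 12 per contrast), refit on all
its samples at the tuned λ, and contributes its nonzero-coefficient
features. A *comparison* is dropped only if **all** of its penalty ×
subset models are empty at the tuned λ (an option extends the emptiness
scan to the whole λ path). Counts over the retained models feed two named
tiers: report (count ≥ 6) and panel (count ≥ 10). The bipartite
model–feature graph (the "drum plot") is exported as node-link JSON with
edge sign and |coefficient|.

Terminology note: "comparison" (contrast) and "configured model"
(comparison × penalty × subset) are kept distinct, since study designs of
this kind count 11 of the former and up to 88 (or 64 after dropping) of
the latter.

## The solver

The objective is the mean negative log-likelihood plus λP(β) on
internally standardized columns (zero mean, unit population SD; penalties
are scale-sensitive, and both reference implementations of this model
family standardize by default). Coefficients are reported back on the
original scale; the intercept is unpenalized. λ_max =
max_j |x_jᵀ(y−ȳ)|/n is the exact threshold above which the solution is
identically zero; the path takes 100 log-spaced values down to
0.01·λ_max, warm-started.

Rather than IRLS with working weights (whose Newton-style steps can
overshoot), each coordinate step minimizes an exact quadratic majorizer
of the loss with curvature 1/4 — the global bound on the logistic second
derivative — so the penalized objective is provably non-increasing across
sweeps for both penalties. The SCAD one-dimensional proximal problem is
solved exactly by enumerating the stationary points and boundaries of its
three regions, which stays correct in the regime where the subproblem is
non-convex (curvature below 1/(a−1)).

SCAD's full objective is non-convex, so descent only finds a stationary
point. Fits use a deterministic two-start scheme: (i) the LASSO solution
at the same λ (the local-linear-approximation initializer) and (ii) a
denser start from the LASSO solution at λ/10; the path solver also tries
the previous-λ SCAD solution. The stationary point with the lower
objective wins. On every two-feature fixture in the test suite this
reaches the brute-force grid minimum.

Numerical choices: convergence when the largest absolute coefficient
change in a sweep falls below 1e−7 (at most 10 000 sweeps); probabilities
clipped to [1e−12, 1−1e−12] before logarithms; zero-variance columns get
coefficient exactly 0 with a logged warning; ties in cyclic descent are
broken by feature order, making every fit deterministic. Because the
cohort fits are separable at small λ, the path is truncated once the fit
explains 99.9 % of the null deviance (the saturated regime), carrying the
last solution forward — the same device glmnet uses to avoid chasing
divergent separable fits.

LOOCV scores each held-out sample with the binomial deviance (a
misclassification metric is available); per-λ means and standard errors
over the n folds yield λ_min (the default rule) and λ_1se (the largest λ
within one SE of the minimum). Fold-local standardization is used, and a
fold whose training set loses a class raises an error naming the fold.
Fits report the penalized objective in the standardized parameterization,
consistent with the λ_max convention above.

## Sensor quantification

In the linear region of the Langmuir isotherm the membrane sensor's
voltage shift is ΔV = A·(RT/F)·log₁₀(C/C_r) with F = 9.648×10⁴ C mol⁻¹,
R = 8.314 J mol⁻¹ K⁻¹, T = 298 K (RT/F ≈ 25.68 mV). The log₁₀ form is
the default because it renders the panel's fitted A values (4.09–5.94)
commensurate with the theoretical slope 2 ln 10 ≈ 4.605 of an ideal
over-limiting IEM response (~118 mV/decade); a natural-log variant sits
behind a switch. Units are volts and pM throughout.

Calibration regresses ΔV on log₁₀ C by ordinary least squares: A =
slope·F/(RT), C_r = 10^(−intercept/slope), residual SD on n−2 degrees of
freedom. A fitted A outside [0.5, 2] × 2 ln 10 triggers a plausibility
warning. The limit of detection is the concentration whose predicted
shift equals a minimum resolvable shift — by default 3 × the calibration
residual SD, falling back to 10 mV for exact (noise-free) fits, since no
universal LOD rule exists for this readout. Quantified values below the
LOD are flagged, never censored (profile summaries draw the LOD as a
reference line). Group profiles report mean and maximum concentration and
the below-LOD fraction per (cohort, analyte), ordered by the nine-marker
panel.

The nine built-in (A, C_r) pairs ship as a versioned constant table
(`mirpanel.constants.BUILTIN_ISOTHERM_CONSTANTS`).

## Panel evaluation

Panel scores are the linear predictor of a penalized logistic model refit
on the panel features alone (one-vs-rest and pairwise contrasts); a raw
single-marker mode covers per-miRNA ROCs. The underlying axes of
cluster-style scatter summaries are not uniquely defined for this kind of
data, so scoring deliberately reuses the same model family as the
selection stage rather than an ad-hoc clustering. AUC is computed as the
Mann–Whitney pair statistic with ties counted ½ and is verified to equal
the trapezoidal area under the (FPR, TPR) polyline; an AUC below 0.5 is
reported as-is (the score ranks the reference side higher).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the assay chemistry:

* **Expression.** log2 intensities ~ Normal(baseline + shift, σ), by
  default exponentiated to linear pseudo-counts that the pipeline re-logs
  (log2(v+1)). Defaults: baseline 7.0 (≈128 counts), σ = 1.0, features
  independent (an equicorrelation option exercises selection
  instability). No platform normalization, background subtraction or
  probe-chemistry effects are modeled; the distributional form is an
  assumption, made because the downstream regressions only require a
  roughly Gaussian feature scale.
* **Planted markers.** Nine markers (defaults: +3 σ shifts) inside the
  cardiac subset so every nested subset can detect them, with
  stage-structured group patterns mirroring cardiac miRNA panels: two
  chronic markers elevated in CAD (one persisting into STEMI-pre), one
  acute marker unique to STEMI-pre that normalizes after intervention,
  three reperfusion markers elevated only post-PCI, and three injury
  markers sustained through both STEMI stages. Planted ids, shifts and
  the seed are recorded in the matrix metadata, so recovery tests are
  self-describing.
* **Sensor side.** Calibration points are the forward isotherm plus
  Gaussian voltage noise; cohort voltage tables map per-(group, analyte)
  true concentrations through the forward model (zero-noise tables invert
  exactly). The pipeline's default concentration profile places baseline
  cohorts at 2 × LOD and planted-elevated cohorts at 20 × LOD — within
  the sensor's linear regime and roughly the order-of-magnitude contrast
  seen between acute and reference cohorts.

Everything is a pure function of its seed; identical seeds give
bit-identical outputs.

**What passing tests do and do not show.** The synthetic cohorts are
cleaner than real plasma data: independent features, exactly Gaussian
noise, no batch or age structure, and planted effects of a single known
size. Recovery results therefore demonstrate the machinery's
correctness, not clinical performance. One consequence worth noting:
with clean +3 σ effects at n = 6 per cohort every signal contrast is
linearly separable, so tuned LASSO models keep only a minimal separating
subset of the redundant planted markers and tuned SCAD models are
extremely sparse (a single unshrunk marker already separates the
classes — the penalty's unbiasedness region at work). Selection
frequencies concentrate on a dominant subset, and the weakest planted
marker can fall below the panel tier; on noisier real data the tuned
models are denser and frequencies spread more evenly.

## Scale of the shipped checks

The study-scale recovery check runs the full ensemble (24 × 809, all
comparisons, both penalties, four subsets, LOOCV) for five seeds, about
1–2 minutes per seed on one CPU. Unit and property tests use scaled-down
cohorts (16–24 samples, 20–40 features) chosen to keep the whole suite
comfortably under typical CI budgets while exercising identical code
paths.

## Known limitations

* The final curation step of a real biomarker study (literature-driven
  manual screening) is not algorithmic; panel selection here stops at the
  frequency threshold, and the nine-marker panel is supplied as a named
  constant for the sensor modules.
* No elastic-net/MCP penalties, multinomial or survival families; dense
  linear algebra only (p = 809 is small-dense).
* The saturating (non-linear) region of the Langmuir isotherm is out of
  scope; curves extrapolate the linear-region law.
* LOOCV treats all samples as independent; paired pre/post-intervention
  sampling, if present, would make its error estimates optimistic.
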