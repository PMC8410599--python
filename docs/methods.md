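# Methods

This note documents the models, conventions and design choices behind
`odortune`, in the order data flows through the package.

## The assay model

The pipeline targets high-throughput calcium-flux plate assays for
chemoreceptor deorphanization: cells co-expressing a candidate receptor
and a fluorescent calcium indicator are read continuously; after a 30 s
baseline, a ligand is added and fluorescence is read for a further
2 min. Each receptor × ligand pair is tested over a seven-point,
three-fold serial dilution topping at 0.5 mM, with four technical
replicate wells per concentration; each plate additionally carries a
positive control (wild-type receptor + cognate agonist) and a negative
control (indicator transfected alone).

### Trace quantification

For each well: baseline `F` is the arithmetic mean over the half-open
window `[addition − 30 s, addition)`; the response is the mean over the
last 10 s of the read, window `(end − 10 s, end]`; `ΔF` is their
difference and `ΔF/F = ΔF / F`. Half-open boundaries avoid counting the
addition-time sample in both windows. Wells with `F ≤ 0` or too few
window samples are excluded with a logged reason, never imputed; a
condition's biological replicate is the mean of its surviving technical
replicates (count recorded).

Normalization is a pure ratio: each ΔF/F is divided by the positive
control's maximum ΔF/F on the same plate, taken as the control's
technical-replicate-averaged ΔF/F maximized over its concentration
series (at saturation this coincides with the top-concentration value).
Any multiplicative plate effect — transfection efficiency, cell count,
instrument gain — cancels exactly in this ratio, which is the property
the invariance tests assert. Baseline activity is `F` divided by the
mean `F` of the plate's negative-control wells; buffer-only wells are
processed and reported but never subtracted (no subtraction is part of
the assay definition).

### Dose–response model

Responses are baseline-subtracted, so the Hill model fixes the lower
asymptote at zero:

    response(c) = A · c^n / (c^n + EC50^n)

with parameters log₁₀ EC50 (molar), amplitude `A` (normalized ΔF/F at
saturation; negative for inhibitors) and Hill coefficient `n`. Fitting
is unweighted least squares on replicate-mean responses
(`scipy.optimize.curve_fit`, trust-region reflective), parameterized in
log₁₀ EC50 for stability. Initialization: `A ←` response at the top
concentration; log EC50 ← the half-maximum crossing by linear
interpolation in log-concentration (median log concentration when no
crossing exists); `n ← 1`. Bounds: `n ∈ [0.2, 10]`,
log EC50 ∈ [−12, 3]. Tolerances are set to machine-level
(`xtol = ftol = gtol = 1e-14`) so noise-free data reproduce planted
parameters to ≈1e-9. Optimizer failure is reported through a
`converged` flag, never an exception. An all-zero response vector skips
the optimizer and is flagged `degenerate` with amplitude 0.

**Censoring.** A curve that never saturates inside the tested range has
no identifiable EC50. The operational trigger is: the fit did not
converge, or the fitted EC50 exceeds the highest tested concentration.
Such fits get the placeholder log₁₀ EC50 = −2 (10 mM — more than an
order of magnitude above the 0.5 mM top), so that censored ligands still
enter tuning summaries with a defined, conservatively small affinity
term. The placeholder and trigger are configurable
(`censor_value`, `censor_on_top_exceed`).

Two scalar summaries per curve: **max ΔF/F**, the across-replicate mean
response at the highest tested concentration (sign preserved), and the
**activity index**, `−log₁₀(EC50) × max ΔF/F`. For censored ligands the
index is exactly `2 × max ΔF/F`.

Both pooled-mean fitting (default: one curve per receptor × ligand on
across-replicate means) and per-replicate fitting (one curve per
biological replicate; feeds the group statistics) are provided, since
either convention is defensible and they coincide in expectation.

## Tuning metrics

**Lifetime sparseness** over a panel of n responses res_i:

    S = (1 / (1 − 1/n)) · (1 − (Σ res_i / n)² / (Σ res_i² / n))

computed after setting negative (inhibitory) responses to zero. S ∈
[0, 1]; 0 iff all zeroed responses are equal, 1 iff exactly one is
nonzero; invariant to positive rescaling. The all-zero case is 0/0 and
raises an explicit error rather than silently returning 0 or 1. The
response metric defaults to the activity index; max ΔF/F is equally
accepted.

**Tuning curves** order the panel by descending response in a reference
receptor (ties broken by ligand name for determinism); mutant vectors
are re-ordered identically for overlay. **Agonist counting** uses an
explicit, configurable predicate (default: non-censored fit AND activity
index > 0) that is echoed into the output record, because any activation
cutoff is a choice that must travel with the number it produced.

**Mutant vs wild-type comparisons** act on per-replicate log EC50s. The
decision rule: one-way ANOVA with Dunnett-adjusted pairwise contrasts
against the control (scipy's multivariate-t implementation); a mutant
whose group (or whose control) contains censored values is instead
compared by the Brown–Forsythe procedure when Bartlett's test across all
groups rejects variance homogeneity at α = 0.05 (configurable). The
Brown–Forsythe variant used is the median-centred Levene procedure — an
ANOVA on absolute deviations from group medians — chosen as the robust
test that remains well defined when a censored group is pinned at the
placeholder with near-zero variance; a fully pinned group makes
Bartlett's statistic itself degenerate, which is treated as rejection
(the conservative reading of non-homogeneous variance). Significance
labels map from configurable p thresholds (default ****: 1e-4,
***: 1e-3, *: 1e-2) because label conventions legitimately differ
between analyses.

## Descriptor regression

The ligand panel carries 11 physicochemical descriptors (polar surface
area, logP, water solubility, H-bond donors/acceptors, molecular weight,
rotatable bonds, heavy atoms, aromatic rings, vapour pressure, density);
ligands with any missing descriptor are excluded up front and itemized.
Every single descriptor and every unordered pair (11 + 55 = 66 models)
is fitted by OLS with intercept (scikit-learn `LinearRegression`,
residual-sum-of-squares optimal) and scored by R², the squared Pearson
correlation of observed vs modelled activity — identical to the
coefficient of determination for OLS with intercept. Ordered pairs are
not enumerated separately: they are the same model. Zero-variance
degeneracies score R² = 0 with a flag (keeping the ranking total), and
rank-deficient designs are flagged and left unranked. Coefficient signs
are reported (direction matters scientifically) but ranking uses R²
alone; no multiple-testing correction is applied to a ranking.

## The synthetic-data generator

The generator emulates exactly the protocol above: per-well traces are a
constant baseline `F₀ · plate_scale · baseline_factor` (F₀ = 100
fluorescence units) which, from the addition time on, relaxes
exponentially (time constant `kinetic_tau`, default 10 s) toward
`baseline · (1 + Hill(c))`, with additive i.i.d. Gaussian noise per
sample. Negative-control wells carry no receptor and hence no response;
`baseline_factor` lets mutants show elevated baseline activity. Sampling
defaults to 1 Hz — coarse rates suffice for 30 s/10 s window means — and
the rate, windows and dilution protocol are all configurable. Plate
effects are a single multiplicative scale per plate (lognormal, sd 0.25
in log space, when not given explicitly), which is precisely the
nuisance the positive-control normalization removes. Inhibition is
modelled as negative Hill amplitude on top of the nonzero baseline.

The descriptor panel generator draws descriptors i.i.d. standard normal
(the regression stage is affine-invariant, so real units would add
nothing) and plants a linear activity relation with configurable weights
and noise; by default 6 of 54 ligands — the water-soluble tastants and
the oversized synthetic modulator, under their real names — carry
missing descriptor cells, so the completeness filter's 48-of-54
behaviour is exercised under realistic labels.

What the generator does **not** emulate: indicator photophysics and
photobleaching, well-to-well crosstalk, addition artefacts, drifting
baselines, non-Gaussian or heteroscedastic read noise, and any
concentration-dependent kinetics. Passing recovery tests therefore
demonstrate correctness of the computation under the stated model, not
robustness to every artefact of real plate data; the window conventions
and exclusion rules are deliberately minimal and explicit so real
exports can be audited against them.

## Determinism and problem sizes

Every stochastic component is driven by `numpy.random.default_rng`
seeded from a single configuration seed; identical seeds give
byte-identical outputs (the provenance header hashes the analysis
parameters, not file paths). The test suite and the acceptance script
use deliberately small problem sizes chosen to make their statistical
assertions sharp but cheap: one 384-well-scale plate per recovery check,
200 Monte-Carlo seeds for noisy EC50 recovery (response noise sd 0.05,
median |Δlog EC50| ≤ 0.1), 1000 permutations for the regression null at
n = 48, and 1000 simulated null panels for the Dunnett family-wise
error calibration (observed ≈ 0.04–0.06 at nominal 0.05).

## Known limitations

* The Hill fit has no lower-asymptote parameter; assays with constitutive
  drift in ΔF/F would need a 4-parameter variant.
* Censoring collapses all non-saturating ligands onto one placeholder;
  ranking among them is then driven entirely by max ΔF/F.
* The Brown–Forsythe branch tests dispersion/location robustly on two
  groups at a time and is not Dunnett-adjusted; with many censored
  mutants its family-wise error is not controlled.
* Per-replicate Hill fits on 7-point series can be unstable at high
  noise; the pooled-mean default is the recommended estimator.
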