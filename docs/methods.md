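# Methods

This note documents the models, conventions and numerical choices behind
`gipet`, in the order the pipeline runs.

## Standardized uptake values

A gamma-counter measurement (organ, time post injection, activity, sample
mass, animal) is converted to SUV = (A/m)/(A_inj/BW). Times are stored in
minutes with t = 0 at injection; PK and dosimetry outputs are reported in
hours. Decay-correction state is an explicit boolean on every sample and
curve: organ-distribution reporting uses activities corrected back to
injection time, while residence-time integration requires the as-counted
(decay-uncorrected) values, and the two must never be mixed. Operations
check the flag and raise rather than guess.

Per-organ curves carry mean, SD (n−1 convention; SD = 0 for a single
animal) and n at every time, preserving the sampling design (the reference
design is eight times from 5 to 180 min with two animals each). Group
comparisons (baseline vs co-injected excess unlabeled peptide) use the
general one-way ANOVA, which for two groups reduces to the two-sample
t-test (F = t²). No multiple-testing correction is applied across organs;
the result objects say so.

## Non-compartmental pharmacokinetics

Terminal half-life: least-squares regression of ln C on t over either an
explicit window or the last 3 positive uncensored points (default; the
window is configurable because published half-lives rarely state their
regression span). t_½ = ln2/|slope|, with R² reported. A slope ≥ 0 is a
"no terminal decline" error.

AUC∞: linear trapezoid (log-trapezoid is deliberately not used — the
plain trapezoid is the rule named for the analogous dosimetry integral)
with (0, 0) prepended for extravascular dosing, plus a C_last/k tail from
the terminal slope. Below-LOD samples are *assigned zero*: by default
those zeros enter the trapezoid as observations and a profile ending on
one gets no exponential tail. This mirrors the reporting convention of the
plasma data the pipeline was built around; an alternative mode
(`exclude_extrapolate`) drops censored points and extrapolates from the
last positive observation, and every result is labeled with the mode used.
The default mode therefore *over*-counts the 120→240 min triangle but adds
no tail; on the reference profile the two effects make the design-grid AUC
about 8% higher than the analytic dose/CL, which is an honest property of
the convention, not a bug.

Clearance: CL = dose/AUC∞ with explicit unit conversion
(mg/kg ÷ h·ng/mL → L/h/kg, factor 1000).

## Saturation binding and autoradiography

Specific binding is total minus the blocked (non-specific) arm, clamped at
zero with a warning count. The one-site model B(C) = B_max·C/(K_d + C) is
fitted by `scipy.optimize.curve_fit` with deterministic data-driven
starting values (B_max⁰ = max specific bound; K_d⁰ = concentration at half
of B_max⁰ by interpolation); standard errors come from the fit covariance.
Because non-specific binding is measured separately in the reference assay
design, the default fit has no free NS term; an optional one-step fit of
total binding with a linear NS slope exists for datasets lacking a
blocking arm. A fitted K_d outside [min conc/100, max conc×100] is flagged
as extrapolation.

Internalization counts (acid-wash membrane fraction, NaOH lysate fraction)
are normalized by the added-dose standard and the cell count to %ID per
million cells; the internalized share of total is reported, with share
undefined (NaN, not 0/0) where total binding is zero.

Autoradiograms are pixel grids with labeled ROIs. Calibration is
counts/mm² × (reference activity / reference counts) → Bq/mm², then
÷ molar activity (Bq/fmol) → fmol/mm². The co-exposed reference droplet
absorbs the exposure-time integration constant, which makes the
quantification exactly invariant to doubling the exposure. Optional
background-ROI subtraction happens in counts/mm² before calibration.

## Rat-to-human dosimetry

Human organ fractions: fraction(t) = SUV_A(t)·m_organ/(1000·m_body,kg),
a dimensionless fraction (the percent form of the same relation divides by
10 instead). Organ labels pass through an explicit, editable alias table
(e.g. "osteogenic cells" → bone surface, "urinary bladder (rinsed)" →
bladder wall).

Residence times: trapezoid over [0, t_last] with (0, 0) prepended, plus a
tail ∫_{t_last}^∞ A·e^{−kt} dt from a log-linear single-exponential fit to
the last 3 points (configurable). If the fitted k is slower than physical
decay — apparent accumulation, which decay-uncorrected data cannot sustain
to infinity — the tail is clamped to λ_phys acting on the last observed
value; this is the standard conservative treatment for excretory organs
with monotone uptake (the kidney of this tracer engages it by design).
Each organ's annotation records the rule used and the points fitted.

Red marrow uses the blood-volume model: marrow activity concentration =
blood concentration × RMBLR (red-marrow-to-blood ratio, default 1.0,
configurable), converted through phantom marrow and blood masses and then
integrated like any organ. The remainder term defaults to the conservative
no-excretion closure, T_½/ln2 − Σ τ_organ (clamped at 0); a whole-body-curve
mode is available when such a curve exists. Under the default closure the
total residence time equals the physical bound T_½/ln2 ≈ 1.628 h exactly.

Organ doses follow the MIRD schema D(T) = Σ_S τ_S·S(T←S) against an
S-value table loaded from CSV. The shipped table is a demonstration
*self-dose-only* approximation S(T←T) = Δ_np/m_T built from the Ga-68 mean
non-penetrating energy (0.74 MeV/decay) and the phantom masses; it ignores
photon cross-dose entirely and is labeled non-clinical. Any published
S-value library in the same CSV schema drops in.

Effective dose applies ICRP-60 tissue weights as classic OLINDA 1.1 usage
does: colon H = 0.57·H_ULI + 0.43·H_LLI; thymus dose stands in for the
esophagus; gonads are testes (male) or ovaries (female); the 0.05
remainder weight goes to the mass-weighted mean dose of the remainder
organs, except that a remainder organ out-dosing every named tissue takes
half the remainder weight itself (the split rule) with the mass-weighted
mean of the rest taking the other half. Contributions per tissue are
returned and must sum to E to 1e−9.

## Reference data

Ga-68 half-life (67.71 min) and emission constants are shipped as an
editable JSON of standard nuclear data. Phantom organ masses follow the
Cristy–Eckerman adult male (73.7 kg) and adult female (56.8 kg) reference
phantom series, shipped as editable CSVs so ICRP-89 masses can be
substituted; the ICRP-60 effective dose computed from a given organ-dose
table depends on them only through the mass-weighted remainder mean, which
muscle dominates, so the result is insensitive to small mass differences.
The per-organ equivalent-dose table and the EC₅₀ potency table of the
Ga-68 GIPR tracer are shipped as example data consumed (not derived) by
the pipeline.

## Synthetic data

Generators define the study conditions the tests run under:

- **Biodistribution**: per-organ biological fractions follow
  F·(e^{−k_w t} − e^{−k_u t})/norm (washout organs) or F·(1 − e^{−k_u t})
  (kidney-like monotone accumulation); measured activities multiply by
  e^{−λt}. Defaults qualitatively match the reference pattern — fast
  washout everywhere, liver SUV < 1 after 5 min, kidney accumulating —
  and are illustrative, not measured values. Noise is multiplicative
  lognormal (CV 10% default, mean-preserving); design 8 × 2 animals.
  The truth record carries each organ's closed-form ∫SUV_A dt, from which
  the analytic residence time for any phantom follows.
- **Plasma PK**: one-compartment first-order absorption (Bateman),
  parameterized by dose 1 mg/kg, elimination t_½ 0.38 h, absorption t_½
  0.1 h and clearance 0.73 L/h/kg, sampled at 3–240 min; values below the
  5 ng/mL LOD are assigned zero and flagged. Truth: AUC∞ = dose/CL,
  terminal t_½ = elimination t_½.
- **Saturation assay**: hyperbola (K_d 18.3 nM, B_max 2.4 pmol/Mcells) +
  linear NS term, triplicates at 0.3–300 nM, proportional Gaussian noise
  (CV 10%), values clipped at 0.
- **Internalization**: surface pool approaching a plateau at rate k_b with
  first-order transfer to an internalized pool (k_i = 0.7 h⁻¹ at 37 °C, 0
  at 4 °C), solved in closed form.
- **Autoradiogram**: Poisson counts proportional to density × molar
  activity × exposure × pixel area over square pellet ROIs, plus a flat
  background strip and a reference droplet of known activity.

A single seed fans out to per-generator substreams
(`SeedSequence.spawn`), so each generator is reproducible independently of
the others. What the generators do *not* emulate: inter-animal kinetic
variability (noise is i.i.d. per sample), partial-volume or spill-over
effects, plasma protein binding and metabolite formation, and anatomical
heterogeneity within organs. Passing recovery tests therefore demonstrate
the correctness of the estimators under the stated error models, not the
biological fidelity of any particular parameter value.

## Problem sizes and tolerances

Unit and property tests run on the study-scale designs (8×2
biodistribution, 8-point PK, 7×3 assays) plus dense grids (≤5000 points)
where closed forms are compared; the saturation-recovery check uses 200
simulated assays. Decay round trips are exact to 1e−12 relative; trapezoid
integrals are exact for piecewise-linear inputs; residence times at the
8-point design are accepted within 5% of closed forms (the trapezoid/tail
discretization error at that design is ~1–3%); the grid-search
cross-check of the saturation fit agrees within 1%.

## Known limitations

- The shipped S-value table is self-dose-only; organ doses and the
  effective dose computed from it are demonstrations of the MIRD plumbing,
  not clinical estimates.
- The marrow model's RMBLR and the remainder closure are conventions, not
  fitted quantities; both are configurable and annotated in outputs.
- The assigned-zero censoring convention biases AUC relative to standard
  NCA practice (see above); use `exclude_extrapolate` for the conventional
  estimate.
- No image-derived inputs: PET volumes, DICOM and vendor counter formats
  are out of scope; tabulated time–activity data are the ingestion
  boundary.
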