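# gipet

Preclinical evaluation pipeline for a ⁶⁸Ga-labelled GIPR-targeting PET
peptide radioligand. The package implements, as tested and reusable code,
the full computational chain behind a first-in-animal tracer evaluation:

- **Biodistribution** — standardized uptake values from ex vivo
  gamma-counting, per-organ time courses, tissue ratios, and blocking
  (displacement) statistics;
- **Pharmacokinetics** — non-compartmental analysis of plasma profiles
  (terminal half-life, AUC∞, clearance) including the assigned-zero
  convention for below-LOD samples;
- **Receptor binding** — one-site saturation fits (K_d, B_max),
  internalization fractions, autoradiogram calibration to fmol/mm², and
  EC₅₀-based fold selectivities;
- **Internal dosimetry** — rat-to-human extrapolation through reference
  phantom masses, residence-time integration (trapezoid + exponential
  tail), a bone-marrow blood-volume model, the MIRD schema
  D(T) = Σ_S τ_S·S(T←S), and the ICRP-60 effective dose with OLINDA-style
  conventions (colon split 0.57 ULI/0.43 LLI, thymus as esophagus
  surrogate, split-remainder rule);
- **Synthetic data** — seed-deterministic generators for every stage, each
  emitting a closed-form truth record, so the whole pipeline is testable
  without animal data.

It is aimed at radiopharmaceutical scientists who want the arithmetic of a
tracer evaluation — SUV, NCA, saturation binding, residence times,
effective dose — to be explicit, auditable and unit-tested rather than
buried in spreadsheet or GUI workflows.

## Core quantities

SUV = (A_tissue/m_tissue) / (A_injected/m_body), dimensionless; the
decay-correction state of every curve is an explicit flag.

Human organ fraction from decay-uncorrected rat SUVs (SUV_A):
fraction(t) = SUV_A(t) · m_organ(g) / (1000 · m_body(kg)).

Residence time τ = ∫₀^∞ fraction(t) dt, evaluated as a linear trapezoid
over the sampled span plus a single-exponential tail; tails fitted slower
than physical decay are clamped to λ_phys = ln2/T_½ (Ga-68: T_½ =
67.71 min, so Σ τ ≤ T_½/ln2 ≈ 1.628 h).

Effective dose E = Σ_T w_T·H_T with the ICRP-60 weight set (w sums to 1).

## Worked example

```python
from gipet import reference
from gipet.dosimetry import effective_dose, load_reported_organ_doses

weights = reference.load_tissue_weights("icrp60")
for sex in ("male", "female"):
    phantom = reference.load_phantom(f"adult_{sex}")
    res = effective_dose(load_reported_organ_doses(sex), weights, phantom)
    print(sex, round(res.effective_dose_msv_per_mbq, 4),
          res.remainder_report["rule"])
```

prints

```
male 0.0219 split
female 0.0239 split
```

i.e. weighting the tracer's reported per-organ equivalent doses with
ICRP-60 factors gives a whole-body effective dose of ≈0.022 (male) and
≈0.024 (female) mSv/MBq; the kidney — the highest-dosed tissue of this
renally excreted tracer — triggers the split-remainder rule and receives
half the remainder weight on its own.

The numbered scripts under `analysis/` run the full study on synthetic
data (`python analysis/01_simulate_study.py --seed 1`, then 02–05 in
order). For example, stage 03 prints

```
terminal t1/2 = 0.390 h (R^2 0.9996); generating elimination t1/2 was 0.38 h
AUC_inf = 1478 h*ng/mL (0.0% extrapolated; ...)
CL = 0.68 L/h/kg from dose 1.0 mg/kg
```

— the log-linear regression over the 30–120 min window recovers the
generating elimination half-life to within 3% despite the residual
absorption phase, and the AUC includes the trailing assigned-zero segment
per the censoring convention.

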