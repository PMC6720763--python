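# odormix

Odor-intensity modelling for binary odorant mixtures: psychophysical law
fitting, perceptual mixture models with interaction coefficients, a
Mamdani fuzzy-logic engine that maps 8-channel electronic-nose signals to
a perceived intensity, and the gas-generation arithmetic needed to plan
the stimuli.

## Who this is for

Odor-nuisance monitoring ultimately asks a perceptual question — *how
strong does this air smell?* — of instrumental measurements.  Sensory
panels rating the VDI 3940 scale (0 = not perceptible … 6 = extremely
strong) are the reference method but are slow and expensive; electronic
noses measure continuously but their signals must be translated into a
perceived intensity, and in mixtures the components interact (mask,
suppress, occasionally enhance one another), so intensities do not simply
add.  `odormix` implements the modelling stack that connects these
pieces for binary mixtures of eight reference odorants (*n*-hexane,
cyclohexane, toluene, *o*-xylene, trimethylamine, triethylamine,
α-pinene, β-pinene).

## The models

**Single odorants.**  Perceived intensity follows the Weber–Fechner law
OI = k_WF·log₁₀(C/C_OT) (fitted as OLS of OI on log₁₀C) or Stevens' power
law OI = k_S·Cⁿ (OLS of log₁₀OI on log₁₀C).  Inverting the
Weber–Fechner law gives the concentration that produces a target
intensity — the basis for planning mixture experiments.  Panelists are
screened by the repeatability criterion 10^s ≤ 2.3 on repeated ratings.

**Binary mixtures.**  With OI_A, OI_B the intensities the components
would elicit alone, the package implements four perceptual models:

| model      | prediction OI_AB                            | coefficient source            |
|------------|---------------------------------------------|-------------------------------|
| Euclidean  | √(OI_A² + OI_B²)                            | none (no-interaction reference) |
| vectorial  | √(OI_A² + OI_B² + 2·OI_A·OI_B·cosα)         | sensory panel (inverse formula) |
| U          | OI_A + OI_B + 2·cosα·√(OI_A·OI_B)           | sensory panel (inverse formula) |
| UPL        | U formula with cosα_X = 2^(n_X−1) − 1       | Stevens exponents only        |

cosα ∈ [−1, 1] quantifies the interaction (negative = suppression).
Models are compared by the mean squared prediction error between paired
intensity series.

**Fuzzy e-nose.**  Labeled array samples calibrate one Gaussian
membership function per (sensor, VDI level); Wang–Mendel learning builds
IF–THEN rules ("IF S₁ weak AND … AND S₈ weak THEN OI weak"); inference
uses min-AND, min-implication, max-aggregation and centroid
defuzzification over the VDI axis, returning a continuous intensity.

Because no raw panel or sensor data are published for this system,
`odormix.synthetic` generates both — VDI-rounded panel ratings and
log-saturating, mixture-suppressed sensor responses — with the generating
truth attached, so every estimator is testable as a parameter-recovery
problem.

## Worked example

```python
from odormix import predict_euclidean, predict_vectorial, predict_u
from odormix.reference import reference_cos_matrix, reference_profile
from odormix.psychophysics import concentration_for_oi

toluene = reference_profile("toluene")
print(concentration_for_oi(toluene.wf, 1.0))   # 1.1009... ppm at OI = 1
print(concentration_for_oi(toluene.wf, 3.0))   # 11.536... ppm at OI = 3

cos = reference_cos_matrix("vectorial", oi_level=2)
print(predict_euclidean(2, 2))                          # 2.828... no interaction
print(predict_vectorial(2, 2, cos.cos("toluene", "alpha-pinene")))  # 1.939...
```

Inverting toluene's fitted law (k_WF = 1.96, C_OT = 0.34 ppm) says 1.1 ppm
smells "very weak" (OI 1) and 11.5 ppm "distinct" (OI 3).  The vectorial
prediction for a toluene + α-pinene mixture at component level 2 is 1.94 —
well below the Euclidean 2.83, because the fitted coefficient (−0.53) says
the two odors suppress each other.

Longer narrative scripts live in `examples/` (law fitting from a
simulated panel, the four mixture models side by side, the fuzzy e-nose
pipeline end to end, generator flow planning), and a thin CLI mirrors the
main operations (`odormix predict`, `odormix estimate-cos`,
`odormix enose-calibrate`, `odormix enose-infer`, `odormix plan`,
`odormix simulate`, `odormix fit-laws`, `odormix compare`).

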