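# arterymech

Quantitative analysis of elastic-artery biomechanics and extracellular-matrix
microstructure, built for studies of the common carotid artery under
hypertension and interventions such as renal denervation.

The package covers both halves of a typical workup:

- **Biaxial extension–inflation mechanics.** A cannulated artery is held at a
  fixed axial stretch λz while luminal pressure P is stepped (0–120 mmHg in
  10 mmHg increments), recording outer diameter dₒ and axial force f. Treating
  the wall as a thin incompressible cylinder, the mean biaxial Cauchy stresses
  are

  σ_θ = P·rᵢ/h,  σ_z = (f + P·π·rᵢ²) / (π·h·(2rᵢ + h)),

  with the deformed inner diameter from wall incompressibility
  dᵢ = √(dₒ² − (Dₒ² − Dᵢ²)/λz), where Dₒ, Dᵢ are the traced unloaded ring
  diameters. On top of this the package estimates the **in vivo axial
  stretch** (the λz at which axial force stays constant during
  pressurization, judged against a 50 μN plateau criterion), interpolates the
  mechanical state at **mean arterial pressure (MAP)**, and computes the
  **circumferential tangent modulus** dσ_θ/dλ_θ there.

- **Multiphoton image microstructure.** From z-stacks of collagen (SHG) or
  elastin (2PEF): FFT-based fiber **orientation histograms** on [−90°, 90°)
  (0° = vessel axis), per-depth orientation maps that locate the abrupt
  adventitia→media orientation flip, circumferential-to-axial ratios
  **Qc/Qa**, and the collagen **straightness parameter** Ps = endpoint
  distance / arc length of traced fibers, summarized as per-slice medians and
  their mean ± SD.

Because raw pressure-myograph records and multiphoton stacks are rarely
shared, the package ships first-class synthetic twins with exact ground
truth: a four-fiber-family membrane constitutive simulator whose presets are
*designed* to possess a force-invariant axial stretch, and a wavy-fiber image
renderer with prescribed von Mises orientations and closed-form Ps. Every
analysis routine is validated against these generators.

## Worked example

`python examples/mechanics_workflow.py` simulates a normotensive-rat-like
carotid and analyzes it:

```
estimated in vivo axial stretch: 1.750
axial force variation at that stretch: 16 μN (threshold 50 μN, satisfied: True)

state at MAP = 100 mmHg:
  circumferential stretch λθ = 1.600
  circumferential stress σθ  = 85.0 kPa
  axial stress σz            = 122.0 kPa
  wall thickness             = 79.0 μm
  circumferential tangent modulus = 0.85 MPa
```

The plateau detector found the designed in vivo stretch (1.75) with a force
drift well under the 50 μN criterion, and the at-MAP state lands at
physiological rat-carotid values. The other examples each demonstrate one
capability: `force_plateau.py` (why force invariance pinpoints λz*),
`orientation_analysis.py` (depth-resolved orientation and the
adventitia/media interface), `straightness_analysis.py` (Ps recovery against
the analytic oracle and the straightening plateau under axial stretch), and
`group_comparison.py` (three-group mean ± SEM tables with Bonferroni post
hoc).

## Library layout

| module | contents |
| --- | --- |
| `arterymech.mechanics` | thin-wall analysis: stresses, stretches, in vivo stretch, MAP state, tangent modulus |
| `arterymech.simulate` | membrane constitutive simulator, presets, force-invariant stretch oracle |
| `arterymech.orientation` | FFT directionality histograms, stack means, depth maps, Qc/Qa |
| `arterymech.straightness` | preprocessing, distance-transform fiber tracing, Ps statistics |
| `arterymech.synthfibers` | synthetic fiber images/stacks with analytic ground truth |
| `arterymech.stats` | SEM/SD summaries, one-way ANOVA, Bonferroni pairwise, group tables |
| `arterymech.pipeline` | seeded end-to-end runs (`run_mechanics`, `run_imaging`) |
| `arterymech.io` | myograph CSV + YAML sidecars, TIFF stacks, tidy outputs |

See `docs/methods.md` for the models, assumptions, parameter defaults, and
numerical choices.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full pipeline from scratch: it simulates cohorts from both
constitutive presets, analyzes every specimen (in vivo stretch, MAP state,
tangent modulus), prints the group comparison table, renders synthetic
depth-graded fiber stacks, and runs the orientation and straightness
analyses, writing intermediate CSV/JSON outputs next to the results file.
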