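# qabl — quantitative air- and blood-corrected lung FDG kinetics

Dynamic ^18F-FDG PET of the lung is used to measure parenchymal
inflammation (e.g. in COPD), but a lung region of interest is mostly air
and partly blood: the air dilutes the measured signal and the blood adds a
background that is not tissue metabolism.  `qabl` implements a fully
quantitative kinetic analysis that corrects for both, alongside the
normalised Patlak and SUV endpoints used by earlier lung studies, the
effect-size statistics needed to compare groups, and a synthetic-data
generator (TAC cohorts and 4-D digital phantoms) with known ground truth.

## The model

The measured concentration in a lung ROI is a volume-weighted mixture

    C_M(t) = V_B · C_B(t) + (1 − V_B − V_A^CT) · C_T(t; K1, k2, k3, C_B)

where `C_B` is the blood input function (image-derived from the descending
aorta, scaled by the plasma-to-whole-blood ratio 1.056) and `C_T` follows
the irreversible two-tissue compartment model standard for FDG.  The
fractional air volume is fixed from co-registered CT,

    V_A^CT = 1 − (H̄U_R − HU_air) / (HU_tissue − HU_air),   HU_air = −1024, HU_tissue = 40,

leaving four parameters (K1, k2, k3, V_B) for bounded weighted least
squares.  The endpoint is the tissue metabolic rate constant

    Ki = K1·k3 / (k2 + k3)     [ml cm⁻³ min⁻¹].

For comparison, the package also fits the Patlak graphical analysis
(t\* = 10 min) and its normalised ratio nKi = slope/intercept, which is not
a clean metabolic readout but the composite

    nKi = (1 − V_B − V_A)·Ki / [ (1 − V_B − V_A)·V_ss + V_B ],

so air/blood-fraction differences between groups move it even when tissue
Ki is identical — the central dissociation this package demonstrates on
synthetic cohorts.

## Worked example

`examples/04_phantom_pipeline.py` builds a 4-D digital phantom (PET frames,
CT in Hounsfield units, masks, per-slice aorta centres) with a known truth
and a +13 s blood-to-tissue delay, then runs the full image pipeline:

```
estimated delay: +13 s (truth +13 s)
           truth  pipeline
    va    0.7200    0.7200
    vb    0.1400    0.1400
    K1    0.0500    0.0500
    k2    0.4000    0.4000
    k3    0.0600    0.0600
    ki    0.0065    0.0065
```

Every number on the right is re-derived from the images alone — CT air
fraction, aorta IDIF with plasma correction, delay grid search (−50…+50 s,
1 s step), corrected compartmental fit.  The other examples cover air
fractions and axial lung thirds (`01`), fitting a noisy TAC (`02`), the
fraction-shift dissociation between normalised Patlak and corrected Ki
(`03`), and the effect-size arithmetic (`05`); e.g. `03` prints

```
Hedge's g, corrected Ki     : +0.017 [-0.86 +0.89]
corrected-Ki group shift    : -0.58%
normalised-Patlak group shift: -8.15% (composite prediction -6.30%)
```

— two groups with identical tissue kinetics but emphysema-like air/blood
fraction shifts: the corrected Ki shows no effect, the normalised Patlak
ratio shifts by the amount its composite algebra predicts.

A thin CLI mirrors the library: `qabl simulate` writes a synthetic cohort
or phantom dataset, `qabl analyze` runs the full analysis on it, and
`qabl report` produces summary tables and group-comparison figures.

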