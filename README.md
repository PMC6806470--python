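# proton-interplay

Simulation of the interplay between intrafraction prostate motion and
layered proton delivery, for medical physicists studying motion robustness
of passive delivery techniques.

In **double scattering (DS)** a rotating range modulator sweeps the whole
spread-out Bragg peak (SOBP) every 0.1 s, so a moving target always sees
the full dose field. In **uniform scanning (US)** energy layers are
delivered one at a time from the distal to the proximal end of the SOBP,
so target motion during delivery *interplays* with the layer sequence and
can carve hot and cold spots into the clinical target volume (CTV). This
package builds every ingredient of that comparison as tested, reusable
code:

- an analytic SOBP beam model: pristine Bragg peaks, energy-layer
  decomposition (range 30.1 g/cm², modulation 8.4 g/cm² → 14 layers at
  0.6 g/cm² spacing), NNLS-flattened layer weights, separable 3D dose
  grids with aperture penumbra;
- a synthetic 10 Hz prostate-motion cohort with drifts, transient
  excursions, persistent offsets and correlated SI–AP noise, calibrated so
  the cohort systematic/random components recover
  (0.3, 0.5, 0.6) / (0.7, 1.4, 1.9) mm in (LR, SI, AP);
- per-second 4D dose accumulation of a rigidly moving CTV through static
  (DS) or layer-indexed (US) dose matrices,

  D_CTV(v) = Σ_t d_t(v + u(t)),

  with a 25 s pre-beam delay, 2 Gy/min dose rate and 0.5 s layer
  switching (2 Gy fraction: 60 s beam-on; 7.25 Gy SBRT fraction:
  217.5 + 13×0.5 = 224 s);
- DVH analysis (V100, V95, V110, D100, D95, D5; hot = V110 > 2%,
  cold = D95 < 95%) and cohort summaries with paired DS-vs-US t-tests at
  the single-fraction and fraction-cumulative level.

See `docs/methods.md` for model assumptions, parameter defaults and
limitations.

## Worked example

```python
import dataclasses
import proton_interplay as pi
from proton_interplay.config import RunConfig
from proton_interplay.motion import CohortSpec

# default study geometry, 4-patient cohort for a quick look
cfg = dataclasses.replace(RunConfig(seed=1),
                          cohort=CohortSpec(n_patients=4, n_fractions=14))
result = pi.run_cohort(cfg)
print(result.summaries["single_fraction"].table().round(2))
```

prints the single-fraction summary (percent of prescription):

```
                    V100     V95  V110   D100    D95      D5
stat    technique
Mean    DS         32.88  100.00   0.0  97.98  98.93  100.63
        US         34.40   99.97   0.0  97.57  98.57  100.80
STD     DS          0.65    0.00   0.0   0.08   0.05    0.05
        US          9.62    0.18   0.0   0.85   0.69    0.33
Max     DS         33.25  100.00   0.0  98.30  99.09  100.69
        US         72.68  100.00   0.0  98.79  99.43  101.85
Min     DS         29.70  100.00   0.0  97.91  98.77  100.46
        US         18.46   99.06   0.0  94.80  95.94  100.15
P value             0.25    0.16   1.0   0.00   0.00    0.00
```

Reading it: with this modest-motion cohort both techniques keep V95 near
100% and D95 near the static baseline (98.9%), but the US rows have
several-fold larger standard deviations for every metric — the signature
of layer–motion interplay — while the DS spread stays tiny. (V100
fluctuates around the SOBP ripple because the plan is normalised to 100%
at the CTV centre; see the methods note.) On high-motion cohorts US
additionally develops V110 hot spots that DS never shows, and
fraction-cumulative summaries of the two techniques converge.

The same pipeline is scriptable from the shell:

```sh
proton-interplay generate-traces --out runs/traces --seed 1
proton-interplay report --seed 1 --out runs/report          # tables + figures
proton-interplay full-run --seed 1 --out runs/full          # both arms
```

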