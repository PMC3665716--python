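# nbhfsonar

Analysis pipeline for **narrow-band high-frequency (NBHF) echolocation
clicks** of porpoises recorded on a vertical six-element hydrophone array —
the click type (~130 kHz centroid, ~15 kHz rms bandwidth, ~100 µs duration)
convergently evolved by porpoises, *Cephalorhynchus* dolphins and *Kogia*,
apparently to stay above the hearing range of killer whales.

The package is aimed at marine bioacousticians who want to

* **simulate** the full recording chain — directional NBHF sources
  (circular-piston beam), spherical spreading plus frequency-dependent
  seawater absorption, a 500 kHz / 16-bit six-channel vertical array, with
  ground truth attached to every rendered scene;
* **extract** the standard click source parameters (−10 dB duration, peak
  and centroid frequency, −3 dB/−10 dB/rms bandwidths, Q values, peak-peak
  / rms / energy-flux-density levels) from calibrated snippets;
* **localize** clicking animals from time-of-arrival differences across
  the over-determined array, gate localizations by range (≤65 m) and by
  the rms error of the implied transmission loss (<3 dB), and
  back-compute apparent source levels `SL = RL + 20·log10(r) + α·r`;
* **select on-axis clicks** by the six classical criteria (all channels;
  part of a scan; strongest of the scan; peaking on a middle hydrophone;
  direct path stronger than trailing reflections; one click per scan),
  with buzzes excluded;
* **estimate beam patterns**: off-axis angles from localizations,
  composite vertical beam (clicks within 20 m), equivalent piston
  aperture `b(θ) = 2·J1(ka·sinθ)/(ka·sinθ)` and directivity index
  `DI = 10·log10(2 / ∫ b²(θ)·sinθ dθ)`;
* **discriminate species** acoustically: ROC selection of a
  centroid-frequency criterion between Dall's porpoise (137±3 kHz) and
  sympatric harbour porpoise (141±2 kHz) populations, audiogram
  filtering, and Monte Carlo classification of N-click sets mixed 1:5
  on-axis:off-axis;
* **model detection range** with the active sonar equation: ΔENR of
  clicks with centroid frequency 32.5/65/130/200 kHz and rms bandwidth
  15/45 kHz relative to the 130 kHz / 15 kHz NBHF reference, combining
  absorption, the ambient low-noise window near 100–150 kHz, and the
  `10·log10(BW)` masking-bandwidth term.

## Worked example

Run the packaged demo scene — a Dall's-type source (137 kHz, 104 µs,
183 dB re 1 µPa pp, 10 cm aperture) scanning its beam across the array
from 30 m in 9.2 °C / 33.9 ‰ water with ambient noise:

```python
from importlib import resources
from nbhfsonar import interface

cfg = interface.load_scene_config(
    resources.files("nbhfsonar.data") / "demo_scene.yaml")
result = interface.run_pipeline(cfg)
print(result["log"])
print(result["clicks"].iloc[0])
```

prints (abridged):

```
{'n_scans': 1, 'n_clicks_detected': 7, 'rejections': {}, 'n_accepted': 1}
range_m             30.16
tl_rms_error_db      0.24
f_centroid         136.92
duration_10db      102.99
sl_pp_db           183.10
```

Seven clicks form one scan; exactly one is accepted as on-axis.  The
localization (30.16 m against a true 30.07 m, TL error 0.24 dB) passes
the 65 m / <3 dB gate, and the back-computed source level (183.1 dB pp)
and centroid frequency (136.9 kHz) recover the emitted ground truth.
(No beam pattern is fitted here: the source is beyond the 20 m beam
gate.)

The species-discrimination chain, on synthetic populations:

```python
import numpy as np
from nbhfsonar import population_analysis as pa

rng = np.random.default_rng(1)
roc = pa.roc_criterion(rng.normal(137, 3, 20_000), rng.normal(141, 2, 20_000))
# {'criterion_khz': 139.0, 'criterion_int_khz': 139, 'accuracy': 0.796, ...}

dalls   = pa.build_discrimination_dataset("bc_dalls", 60, seed=2)
harbour = pa.build_discrimination_dataset("bc_harbour", 60, seed=3)
mc = pa.monte_carlo_discrimination(
    dalls.f_centroid_khz.to_numpy(), harbour.f_centroid_khz.to_numpy(),
    criterion_khz=139.0, set_sizes=(1, 2, 4, 8, 16, 32), seed=4)
print(mc.to_frame())
```

| set size | % correct | SEM |
|---------:|----------:|----:|
| 1  | 81.2 | 0.82 |
| 2  | 89.8 | 0.57 |
| 4  | 97.4 | 0.24 |
| 8  | 98.9 | 0.31 |
| 16 | 99.9 | 0.07 |
| 32 | 100.0 | 0.00 |

Single clicks separate the two sympatric species only ~80% of the time;
sets of eight clicks are classified correctly far above 90%.

A CLI mirrors the library
(`nbhfsonar simulate | extract | classify | sonar-model | run-all`), e.g.

```sh
nbhfsonar run-all --config src/nbhfsonar/data/demo_scene.yaml --out out/
nbhfsonar sonar-model --out curves.csv
```

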