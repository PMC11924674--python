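# endoraman

A pipeline for discriminating intracranial tissues from fiber-optic Raman
spectra acquired through the nose, built around the workflow of an endonasal
probe study in sheep heads: nine tissue classes sampled across several heads,
conditioned into standard-normal-variate (SNV) fingerprints, quality-gated,
compared by spectral angle, and classified by a sparse two-stage linear SVM
evaluated only on heads the model never saw.

## The scientific problem

During endoscopic endonasal surgery for pituitary adenomas the surgeon must
tell the gland, its dural covering, the sellar bone and nearby neural tissue
apart through a narrow corridor, without staining and without excising tissue.
Raman spectroscopy reads out molecular composition label-free: a fingerprint
spectrum (800–1800 cm⁻¹) carries bands such as the 961 cm⁻¹ calcium-phosphate
stretch of bone mineral, the 1004 cm⁻¹ phenylalanine ring breathing mode, CH
deformation bands near 1438–1450 cm⁻¹ and the amide-I band near 1650 cm⁻¹.
The hard pair is dura versus bone: the dura is thin, so an in-place
measurement of dura also excites the bone beneath it, mixing the two
signatures.

Because no public spectra exist for this setting, the package ships a
synthetic generator whose nine tissue profiles encode the band registry of the
study (ordinal 1–5 band strengths, including the dura←bone admixture), plus
per-head amplitude effects, autofluorescence baselines, shot noise, cosmic
rays and the three gland preparation methods (`in_situ`, `ex_situ`,
`in_section`). The generator's defaults are the frozen study conditions; all
statistical claims in the test suite are recovery checks against this
generator's known truth or closed-form anchors.

## The model

1. **Preprocessing** (`preprocess`): dark-count subtraction, across-frame
   median/MAD despiking, polynomial axis calibration against acetaminophen
   reference lines, instrument-response correction, accumulation averaging,
   **BubbleFill** baseline removal (largest circular arc grown under the
   spectrum, recursing at touch points, minimum bubble width 50 cm⁻¹),
   Savitzky–Golay smoothing (order 3, window 1 — a declared no-op),
   truncation to 800–1800 cm⁻¹, SNV normalization.
2. **Quality gating** (`quality`): QF = (1/N)·Σ sgn(rᵢ)·rᵢ² on the SNV
   fingerprint — near 0 for pure noise, near 1 for a few strong narrow peaks;
   records with QF < 0.3 are discarded.
3. **Similarity** (`similarity`): spectral angle mapper (SAM, degrees)
   between mean spectra, within/between-class tables, and a paired
   preparation-method comparison over heads measured with every method.
4. **Classification** (`classify`): stage one sweeps an L1-penalized linear
   SVM over a 13-point regularization grid restricted to known band regions,
   scoring each candidate bin subset by the cross-validated accuracy of the
   downstream model; stage two fits an L2 linear SVM on the winning subset
   (always < 20 bins). Seven gland-vs-other binary tasks ("model I") and one
   four-class task gland/bone/dura/chiasm ("model II"). Train/test splits are
   **head-disjoint** and certified; any overlap raises `LeakageError` rather
   than degrading a metric.

## Worked example

```python
import warnings

import numpy as np

from endoraman import (
    GeneratorConfig, default_calibration, gate, generate_raw,
    pairwise_sam, preprocess_dataset, run_model_II,
)

warnings.filterwarnings("ignore")

cfg = GeneratorConfig(seed=0, tissues=("pituitary_gland", "st_bone", "optic_chiasm", "st_dura"))
raw = generate_raw(cfg)
processed = preprocess_dataset(raw, default_calibration(cfg))
kept, qreport = gate(processed)
print(f"records: {len(raw)} raw -> {len(kept)} kept (QF >= {qreport.threshold})")

sam_tbl = pairwise_sam(kept)
print("mean SAM, gland vs others (deg):")
for t in ("st_bone", "st_dura", "optic_chiasm"):
    print(f"  {t:13s} {sam_tbl.pair('pituitary_gland', t):5.1f}")

model, report = run_model_II(kept, seed=0)
print(f"selected {model.selected_idx_.size} bins at "
      + ", ".join(f"{s:.0f}" for s in np.sort(model.selected_shifts_)) + " cm^-1")
print(f"held-out heads {model.split_.test_heads}: accuracy {report.accuracy:.3f}")
```

Output:

```text
records: 150 raw -> 150 kept (QF >= 0.3)
mean SAM, gland vs others (deg):
  st_bone        66.1
  st_dura        54.3
  optic_chiasm   20.8
selected 19 bins at 862, 875, 947, 958, 960, 1001, 1007, 1059, 1061, 1068, 1080, 1109, 1128, 1131, 1296, 1297, 1438, 1440, 1450 cm^-1
held-out heads (4, 5): accuracy 0.975
```

The selected bins cluster around the phosphate (961), phenylalanine (1004),
C–C/C–N stretch (1060–1130), lipid twist (1298) and CH-deformation
(1438–1450) regions — the discriminative chemistry, recovered from data.

The same chain is available from the command line:

```sh
endoraman simulate --seed 5 --heads 5 --out raw/
endoraman preprocess --in raw/ --out proc/
endoraman qc --in proc/ --report qc.json
endoraman similarity --in proc/ --out sam/
endoraman train --in proc/ --task four-class --seed 5 --report model.json
endoraman run-all --seed 5 --out run/        # everything above in one run
```

## Reproduction

* Full test suite (unit, property and acceptance tests):

  ```sh
  pytest -q
  ```

* Standalone acceptance targets (SAM anchors, QF noise anchor, maximum
  selected-feature count across all trained models), written as JSON:

  ```sh
  python scripts/acceptance.py --seed 1 --out results/acceptance.json
  ```

* The worked example above is `scripts/_readme_example.py`; its printed
  output is pasted verbatim.

Every randomized step is seeded; `run-all` embeds the configuration and its
hash in `manifest.json` so a run can be reproduced exactly. See
`docs/methods.md` for the methods note, parameter table and limitations.
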