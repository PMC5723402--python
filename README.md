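# fsfcd — frequency-specific functional connectivity density

Resting-state fMRI studies usually analyze BOLD fluctuations in one broad
band (0.01–0.08 Hz), but the brain's slow oscillations are not a single
process: different sub-bands can carry different group effects in clinical
cohorts.  `fsfcd` implements a frequency-resolved voxelwise connectivity
analysis for researchers who want to ask *in which band* a patient group's
functional organization differs, and whether those band-specific
differences discriminate patients from controls:

1. **Band decomposition.**  Each voxel's series x(t) is decomposed by
   CEEMDAN (complete ensemble empirical mode decomposition with adaptive
   noise) into intrinsic mode functions, x(t) = Σᵢ IMFᵢ(t) + r(t), with the
   reconstruction exact by construction.  Each mode is summarized by its
   Hilbert weighted frequency — the energy-weighted mean instantaneous
   frequency of its analytic signal.
2. **Frequency-of-interest (FOI) bands.**  Per mode order, the pooled
   within-group HWF distributions give empirical 95% intervals; the
   group-consistent band is [max of lower limits, min of upper limits].
   Bands are labeled FOI-1… by descending frequency; the conventional
   0.01–0.08 Hz band is FOI-N.
3. **FCD mapping.**  In every band, two voxels are functionally connected
   when Pearson r > 0.6.  Global FCD is a voxel's connection count to the
   whole mask; short-range FCD (S-FCD) counts connections from the seed
   into its region-grown local cluster; long-range FCD (L-FCD) = global −
   short.  Maps are z-scored within the mask and smoothed (6-mm FWHM).
4. **Group inference.**  Voxelwise two-sample t-tests with Monte-Carlo
   cluster-extent correction (null volumes smoothed to the estimated map
   FWHM; corrected p < 0.05 via a minimum cluster extent at uncorrected
   p < 0.001), partial correlation with covariates and FDR, and
   demographic-table tests.
5. **Classification.**  Leave-one-out linear SVM where the difference
   clusters — and hence the features (cluster-mean S-FCD/L-FCD values) —
   are re-derived inside every training fold, so the held-out subject
   never leaks into feature definition.  Performance is reported as
   accuracy / sensitivity / specificity and the AUC of the pooled ROC.

No clinical data ships with the package.  A first-class synthetic-cohort
generator produces 4-D BOLD-like NIfTI volumes (TR = 3 s, 190 volumes,
band-limited oscillators, spatially contiguous planted connectivity
effects, Table-style covariates) so that every stage is testable and every
reported number is recomputable from code alone.

## Worked example

Generate a 15-vs-15 cohort with a band-specific connectivity effect
(correlation gain 1.5 in 0.02–0.04 Hz) planted in a ~60-voxel region of the
patients, map S-FCD/L-FCD in the conventional band, and classify:

```python
import dataclasses
import numpy as np

from fsfcd.cohort import planted_effect_spec, generate_cohort
from fsfcd.prep import prepare
from fsfcd.fcd import FcdConfig, compute_fcd, zscore_map, smooth_map
from fsfcd.stats import CorrectionConfig
from fsfcd.classify import loocv_classify

spec, region = planted_effect_spec()          # 15 patients / 15 controls
spec = dataclasses.replace(spec, seed=123)
subjects, table = generate_cohort(spec)

cfg = FcdConfig()                             # r > 0.6, 26-connectivity, 6-mm FWHM
stacks, geom = {"short": [], "long": []}, None
for s in subjects:
    prepared = prepare(s, 0.01, 0.08, steps=("detrend", "filter"))
    maps = compute_fcd(prepared, cfg, band="FOI-N")
    for kind in stacks:
        sm = smooth_map(zscore_map(maps[kind]), cfg)
        stacks[kind].append(sm.values)
        geom = (sm.voxel_index, spec.grid_shape, spec.voxel_size_mm)

cohort_maps = {("FOI-N", k): np.vstack(v) for k, v in stacks.items()}
cohort_maps["geometry"] = geom
report = loocv_classify(cohort_maps, np.asarray(table["group"]),
                        cfg=CorrectionConfig(n_sims=1000), min_extent=3)
print(f"folds: {len(report.folds)}")
print(f"accuracy: {report.accuracy_pct:.2f}%  sensitivity: {report.sensitivity_pct:.2f}%"
      f"  specificity: {report.specificity_pct:.2f}%  AUC: {report.auc:.4f}")
```

Output:

```
folds: 30
accuracy: 100.00%  sensitivity: 100.00%  specificity: 100.00%  AUC: 1.0000
```

One fold ran per subject; in every fold the in-fold t-test found the
planted region, its cluster-mean FCD separated the groups, and the pooled
decision scores gave a perfect ROC — the planted effect (within-region
correlation ~0.7 in patients vs ~0.2 in controls, across the 0.6 threshold)
is far above the noise floor by design.  With permuted labels the same
pipeline drops to 50% accuracy.

The same analysis is scriptable from the shell via the `fsfcd` CLI
(`simulate`, `prep`, `decompose`, `foi`, `fcd`, `stats`, `classify`,
`report` subcommands with a YAML config); every run directory carries a
manifest with the config hash and master seed, and reruns are
byte-identical.

## Layout

- `src/fsfcd/cohort.py` — synthetic two-group BOLD cohorts
- `src/fsfcd/prep.py` — detrend / filter / nuisance regression / FD
- `src/fsfcd/emd.py` — EMD, CEEMDAN, Hilbert weighted frequency
- `src/fsfcd/foi.py` — FOI band selection and band signals
- `src/fsfcd/fcd.py` — global / short-range / long-range FCD maps
- `src/fsfcd/stats.py` — group statistics and cluster correction
- `src/fsfcd/classify.py` — leave-one-out SVM with in-fold features
- `src/fsfcd/io.py`, `pipeline.py`, `cli.py` — NIfTI/TSV/JSON I/O,
  orchestration, command line
- `docs/methods.md` — model assumptions, parameter choices, limitations
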