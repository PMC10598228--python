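# semint

Analysis pipeline for intracranial-EEG studies of sentence-level semantic
integration: from raw multichannel recordings and word-locked event tables
to broadband-gamma percent-change traces, condition contrasts, and
population-level cortical-surface statistics with cluster-corrected
familywise error control.

## The scientific problem

In rapid-serial-visual-presentation (RSVP) sentence paradigms, patients
implanted with depth or subdural electrodes read word-by-word descriptions
(500 ms per word) and name the described object. Conditions factor into
**reference** (whether the sentence denotes a nameable object), **coherence**
(whether a non-referential sentence is semantically well-formed), and
**narrowing** (whether norming participants can identify the referent
before the final word). The neural index of interest is **broadband gamma
activity** (BGA, 70–150 Hz analytic amplitude), a proxy for local cortical
processing. Because each patient contributes only a sparse sample of
cortex, population inference pools per-subject effect estimates on a shared
cortical mesh with a **surface-based mixed-effects multilevel analysis
(SB-MEMA)** and corrects for multiple comparisons over the surface with a
Monte-Carlo white-noise cluster criterion.

The core computations:

- **Band amplitude.** A frequency-domain Hilbert transform with paired
  logistic flanks: the one-sided spectrum is multiplied by
  `W(f) = L((f−f_lo)/h) · L((f_hi−f)/h)` (logistic `L`, half-width
  `h = 1.5 Hz`) and doubled; the magnitude of the inverse transform is the
  analytic amplitude, smoothed with a Savitzky–Golay FIR (3rd order, 251 ms
  frame) and expressed as percent change from the per-trial baseline
  (−500 to −100 ms before the first word).
- **Pointwise activation.** One-tailed one-sample *t*-tests per time point,
  Benjamini–Hochberg corrected at *q* < 0.05 across the trace.
- **Window contrasts.** Per unit (electrode or subject), the window-mean
  percent-change difference between conditions; two-sided paired *t* at
  α = 0.01. The mean paired difference is the reported β, the SD of the
  differences its dispersion.
- **SB-MEMA.** Per mesh node, a DerSimonian–Laird random-effects
  combination of per-subject effects β_i with within-subject variances
  s_i²: weights `w_i = 1/(s_i² + τ̂²)`, pooled effect `Σw_iβ_i/Σw_i`,
  `t = pooled·√(Σw_i)`, df = k−1, after geodesic Gaussian smoothing
  (3 mm FWHM) and masking below a minimum patient coverage (≥3; ≥2 for
  conjunction maps).
- **Cluster FWER.** The minimum surviving cluster size is the upper
  (1−α) quantile (+1) of the maximal suprathreshold cluster of smoothed,
  re-standardized white noise on the same mesh with the same kernel.
- **Conjunction maps.** Contrast maps binarized at %BGA > 5 %, t > 2.57,
  coverage ≥ 2, combined into per-node Boolean codes (R, C, N, R+C, …).

Patient recordings of this kind are not publicly distributable, so the
package ships a first-class synthetic-cohort generator (`semint.synthetic`)
that reproduces the statistical structure the analysis assumes — 1/f
background, 60 Hz line noise with harmonics, the RSVP trial timeline (42
referential + 42 non-referential trials, 3–12 words), sparse electrode
coverage of a shared mesh, and condition-locked band-limited gamma bursts
with *known* injected percent-change amplitudes — which makes every stage
testable against ground truth.

## Worked example

Inject a 60 % referential BGA effect on a connected six-node patch of a
100-vertex mesh, run the full chain (notch filter, common-average
reference, Hilbert band amplitude, Savitzky–Golay smoothing, per-trial
percent change, electrode→node projection, geodesic smoothing, SB-MEMA,
Monte-Carlo cluster correction) for eight synthetic subjects:

```python
import numpy as np
from semint.pipeline import (load_config, split_epochs, group_surface_map,
                             preprocess_recording, subject_bga_epochs,
                             subject_contrast_map)
from semint.stats import paired_contrast
from semint.surface import (estimate_cluster_threshold, smoothing_kernel,
                            threshold_map)
from semint.synthetic import EffectSpec, SyntheticConfig, make_cohort, make_mesh

mesh = make_mesh(100, radius=50.0, seed=77)
adj = mesh.adjacency(weighted=False)
effect_nodes = tuple(int(v) for v in np.r_[0, adj[[0]].nonzero()[1]])

effect = EffectSpec(name="reference", condition={"condition": "referential"},
                    band=(70.0, 150.0), window_ms=(100.0, 400.0),
                    amplitude_pct=60.0, nodes=effect_nodes)
cohort = make_cohort(
    SyntheticConfig(n_subjects=8, electrodes_per_subject=8, mesh_vertices=100,
                    anchor_nodes=effect_nodes, effect_specs=(effect,),
                    rng_seed=31),
    mesh=mesh)

cfg = load_config()
cfg["cluster"]["n_iter"] = 200
kernel = smoothing_kernel(mesh, cfg["smooth"]["fwhm_mm"])
maps, unit_a, unit_b = [], [], []
for sid, sub in cohort.subjects.items():
    clean = preprocess_recording(sub.recording, cfg)       # notch + CAR
    pct = subject_bga_epochs(clean, sub.events, cfg,       # %BGA epochs
                             lock="final_word", window=(-200.0, 600.0))
    ep_a = split_epochs(pct, "condition", "referential")
    ep_b = split_epochs(pct, "condition", "non_referential")
    maps.append(subject_contrast_map(mesh, sub.electrodes, ep_a, ep_b,
                                     (100.0, 400.0), sid))
    w = pct.time_mask((100.0, 400.0))
    unit_a.append(ep_a.data[:, :, w].mean())
    unit_b.append(ep_b.data[:, :, w].mean())

res = paired_contrast(np.array(unit_a), np.array(unit_b), (100.0, 400.0),
                      unit="subject")
print(f"referential vs non-referential, 100-400 ms: "
      f"beta = {res.beta:.2f}% (SD: {res.dispersion:.2f}); "
      f"t({res.df}) = {res.t_stat:.2f}; p = {res.p_value:.2g}")

gmap = group_surface_map(mesh, maps, cfg, kernel)          # SB-MEMA
ct = estimate_cluster_threshold(mesh, cfg["smooth"]["fwhm_mm"], 2.5758,
                                alpha=0.01, n_iter=200, seed=5, kernel=kernel)
mask = threshold_map(gmap, t_min=2.57, pct_min=5.0, min_coverage=3,
                     cluster=ct, adjacency=adj)
print("injected nodes:  ", sorted(effect_nodes))
print("surviving nodes: ", sorted(np.flatnonzero(mask).tolist()))
print("pooled %BGA there:", np.round(gmap.effect[mask], 1))
```

Output:

```
referential vs non-referential, 100-400 ms: beta = 46.63% (SD: 1.30); t(7) = 101.74; p = 2.3e-12
injected nodes:   [0, 22, 26, 43, 55, 78]
surviving nodes:  [0, 22, 26, 43, 55, 78]
pooled %BGA there: [60.1 58.5 56.9 60.  58.3 58. ]
```

The subject-level β of ≈47 % is the montage average (six of eight
electrodes per subject carry the 60 % effect); the cluster-corrected
surface map recovers exactly the injected node set, with pooled node
effects within a few percent of the injected 60 %.

The same chain is available as a CLI:

```sh
semint simulate --config cohort.toml --out cohort/ --seed 1
semint run      --config cohort.toml --out results/ --seed 1
semint validate --config cohort.toml
```

`semint run` writes per-word SB-MEMA maps, final-word contrast maps,
grouped traces, narrowing labels, reaction-time tables, the conjunction
map, and a checksummed `manifest.json` (re-running with the same config and
seed reproduces identical checksums).

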