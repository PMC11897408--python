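# decondenseq

Quantification of mitotic chromatin decondensation from fluorescence
microscopy.

When cells exit mitosis, their condensed chromosomes relax back into
diffuse interphase chromatin. Two complementary readouts capture this in
images:

* **Border smoothness** of fixed in-vitro chromatin substrates. A
  condensed cluster keeps a ragged outline of individual chromosomes; a
  decondensed mass is smooth and compact. With `M` the segmented binary
  mask and `soft(M)` a binary-median (majority-vote) filtered version of
  it, the score is the intersection-over-union

  ```
  s = |M ∩ soft(M)| / |M ∪ soft(M)|,   s ∈ [0, 1]
  ```

  Smooth masses are near fixed points of the median filter (s → 1);
  roughness below the kernel scale is shaved off and lowers s.

* **Anaphase-aligned chromatin area** in live-cell H2B time-lapses. The
  first frame where two daughter masses are segmentable defines t = 0;
  the summed daughter area A(t), normalized to A(0), tracks
  decondensation (approximately A(t)/A(0) = 1 + k·t over the telophase
  window), and size-rule phase labels give per-phase dwell times, with
  telophase dwell as the headline number.

The package also quantifies perichromatin marker intensity (mean over the
chromatin mask, background-corrected by a randomly placed cytoplasmic
ROI), 200-sample line scans, and bright cytoplasmic foci — and applies
the accompanying statistics: Shapiro-Wilk-gated Welch t / Mann-Whitney U,
Fisher's exact test for count data, and hierarchical
per-experiment/overall summaries.

Because such analyses are usually validated against data that cannot be
redistributed, `decondenseq` ships a first-class synthetic generator:
chromatin masses with a tunable boundary-roughness amplitude, mitotic
time-lapses with known onset frame and expansion rate, and two-channel
cells with known rim/cytoplasm intensities and foci — every downstream
stage is testable against exact ground truth.

Intended users: cell biologists and image analysts quantifying mitotic
exit phenotypes (e.g. decondensation defects after perturbing chromatin
or perichromatin factors), and anyone needing a transparent, oracle-tested
implementation of the IoU border-smoothness statistic.

## Worked example

```python
from decondenseq import (
    MassParams, make_chromatin_mass, segment_invitro,
    border_smoothness, SmoothnessConfig,
)

for label, a in (("decondensed", 0.02), ("condensed", 0.35)):
    frame, _, _ = make_chromatin_mass(
        MassParams(image_size_px=(160, 160), radius_px=50,
                   roughness_amplitude=a, seed=1, noise_sd=5.0,
                   blur_sigma_px=1.0))
    mask = segment_invitro(frame)
    res = border_smoothness(mask, SmoothnessConfig(soft_kernel_px=15))
    print(f"{label:12s} s = {res.score:.3f}  (area {res.area_px2} px^2)")
```

```
decondensed  s = 0.991  (area 7861 px^2)
condensed    s = 0.968  (area 7923 px^2)
```

The decondensed substrate scores near 1 (its outline is nearly a fixed
point of the median filter) while the condensed cluster loses boundary
pixels to the majority vote and scores lower; the ~equal areas show the
score separates shape, not size. A live-cell trajectory works the same
way:

```python
from decondenseq import (
    TimelapseParams, make_decondensation_timelapse, SegmentationConfig,
    segment_livecell, extract_objects, link_objects,
    detect_anaphase_onset, normalize_area_curve, fit_expansion_rate,
)

params = TimelapseParams(expansion_rate_per_min=0.05, onset_frame=8,
                         seed=4, noise_sd=19.0, blur_sigma_px=1.0)
lapse, truth = make_decondensation_timelapse(params)
cfg = SegmentationConfig(to_8bit=False, min_object_area_px2=50)
objs = [extract_objects(segment_livecell(f, cfg), 50, frame_index=i)
        for i, f in enumerate(lapse)]
traj = link_objects(objs, params.frame_interval_min, cell_id="cell0")
onset = detect_anaphase_onset(traj)
curve = normalize_area_curve(traj, onset)
print(f"anaphase onset frame: {onset} (truth {truth.info['onset_frame']})")
print(f"fitted expansion rate: {fit_expansion_rate(curve):.4f} /min (truth 0.05)")
```

```
anaphase onset frame: 8 (truth 8)
fitted expansion rate: 0.0478 /min (truth 0.05)
```

The onset is recovered frame-perfectly and the fitted slope of the
normalized-area curve lands within a few percent of the simulated
expansion rate despite the SNR-10 noise.

## Command line

```sh
decondenseq simulate mass --seed 5 --out sim/            # + timelapse, twochannel
decondenseq smoothness --in sim/mass.tif --out scores.csv
decondenseq timecourse --in crop.tif --interval-min 3 --out tc/
decondenseq intensity --chromatin c0.tif --marker c1.tif --seed 1
decondenseq stats --groups a.csv b.csv --design two-sample
decondenseq run-invitro --condition mock=dir_a --condition depleted=dir_b
decondenseq run-livecell --condition ctrl=dir_c --interval-min 3
```

A YAML file (see `decondenseq.io.PipelineConfig`) governs a run; CLI
flags override it, and reports are stamped with the package version and a
config hash so reruns are byte-identical.

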