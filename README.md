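# fishbeam

Analysis toolkit for localized heavy-ion irradiation experiments in small
fish.  In such experiments a low-energy carbon beam (e.g. ¹²C⁶⁺ at
26.7 MeV/u, surface LET 78.4 keV/μm) stops ~2.2 mm into the animal, so a
dorsal or ventral exposure irradiates only one side of the body; the
biological readouts are video heart-rate recordings and serial-section
histology reconstructed in 3D.  `fishbeam` implements that quantitative
chain end to end for researchers who need the numbers, not the renderings:

- **dosimetry** — fluence ↔ dose via LET
  (`D = Φ · LET · 10⁷ · 1.602×10⁻¹⁶` Gy), parametric depth-LET (Bragg)
  profiles pinned to reported beam constants, Bragg–Kleeman range
  estimates, and per-ray beam-penetration masks over an oval body
  cross-section.
- **cardiometry** — the video heart-rate pipeline: heart/reference ROI
  mean-intensity traces, common-mode ventilation subtraction, 21-frame
  moving average, end-of-diastole minima → interbeat intervals →
  beat-by-beat rate → 3-min steady-state rate (fps·60/IBI per beat).
- **morphometry3d** — translation registration of labeled serial sections
  (cross-correlation of foreground masks with a plateau-centroid
  tie-break), anisotropic voxel volumetry, blood-cell composition profiles
  and dorsal/ventral or in-field/out-of-field splits.
- **stats** — one-way ANOVA (from raw values *or* from printed mean ± SD
  summaries, which is exact) and Tukey–Kramer HSD.
- **synthetic** — seeded, ground-truthed generators for beating-heart
  traces/videos and jittered labeled kidney section stacks, so the whole
  chain is testable without the original recordings.

## Worked example

Recover a heart rate from a synthetic 30-s, 300-fps recording
(`examples/heart_rate_from_video.py`):

```text
video: 9000 frames of (96, 128) at 300 fps
detected beats          : 84
steady-state heart rate : 170.0 +/- 2.6 bpm (true rate 170 bpm)
mean interbeat interval : 105.9 frames (353 ms)
```

The generator hid a 170 bpm heart under a 2 Hz ventilation artifact and
sensor noise; the pipeline's reference subtraction cancels the artifact and
the steady-state mean lands on the true rate.  Quantify a dorsally damaged
kidney (`examples/kidney_volumetry.py`):

```text
sections: 70, registration shift error RMS: 0.00 px
kidney volume  : 9.043e+06 um^3 (analytic ellipsoid 9.048e+06 um^3)
blood fraction : total 0.126 | dorsal 0.000 | ventral 0.253
beam field     : in-field 0.000 | out-of-field 0.238
```

Blood cells are missing exactly inside the beam field while the rest of the
organ sits at the 0.25 baseline — the signature of a localized hit, as
opposed to whole-body exposure which depletes the organ uniformly.  The
other examples cover beam geometry/dosimetry and group statistics; each
prints what its numbers mean.  A thin CLI wraps the same functions:
`fishbeam dose|heartrate|volumetry|stats|simulate --help`.

## Layout

```
src/fishbeam/      dosimetry, cardiometry, morphometry3d, stats,
                   synthetic, io, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    models, assumptions, parameter choices, limitations
```
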