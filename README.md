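# foveastrain

Quantifies eyestrain on anaglyph (red–green) 3D stereoscopic displays from a
glasses-mounted NIR eye camera and the displayed video. The pipeline:

1. **eye_image** — pupil detection by circular edge detection (ring-contrast
   maximization) with local-binarization refinement, detection of the four
   corneal specular reflections (SRs) marking the monitor corners, and
   open/closed eye state from dark-pixel counts.
2. **gaze** — SR-quad → monitor homography mapping of the pupil center,
   one-point angle-kappa calibration, the gaze-error circle radius
   `N·v·tan(e)`, and optional dispersion-based (I-DT) saccade suppression.
3. **foveation** — inside the gaze-error circle the point with maximal total
   directional Sobel magnitude (0°/45°/90°/135°) becomes the refined
   foveation point; a contrast-sensitivity weight is assigned to every
   coefficient of a 4-level Daubechies DWT (self-contained implementation in
   `wavelet.py`, periodized orthonormal filters with exact reconstruction),
   and masking = forward DWT → multiply → inverse DWT.
4. **stereo_factors** — four per-frame eyestrain factors: change of
   stereoscopic disparity (CSD), stereoscopic disparity (SD) via in-repo SAD
   block matching with a left-right consistency check, frame cancellation
   effect (FCE = |W/2 − gaze_x|), and edge component (EC, summed Canny edge
   magnitude of both foveated half-images).
5. **windows_stats** — 60 s windows advanced by 10 s, blink-rate counting
   (closed→open transitions only), min–max normalization, Pearson/OLS
   correlation, exact 2² factorial decomposition with effect ratios,
   Cohen's d with small/medium/large labeling, paired two-tailed t-test.
6. **synthetic** — seeded, byte-reproducible generators for eye frames
   (dark pupil, four SR dots, scheduled blinks), anaglyph videos with known
   ground-truth disparity and scene changes, and gaze scanpaths; every stage
   is validated by parameter recovery against these generators.

## CLI

```sh
foveastrain simulate eye --fps 15 --duration 60 --out eye_frames/
foveastrain track --eye-dir eye_frames/ --fps 15 --out track.csv
foveastrain gaze --track track.csv --monitor 1280x720 --out gaze.csv
foveastrain mask --image frame.png --gaze 320,240 --v 3 --e 1.12 --out mask.png
foveastrain factors --video-dir video_frames/ --gaze gaze.csv --monitor 1280x720 --out factors.csv
foveastrain stats --blinks track.csv --factors factors.csv --out report/
```

Each subcommand accepts `--config <yaml>` where applicable to override
detection thresholds, block-matching parameters, and viewing geometry.

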