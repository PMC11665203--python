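# Default pipeline configuration.
# Values stated by the published workflow are plain; values the publication
# leaves unspecified are marked "# paper-gap" with the chosen default.

preprocess:
  equalize: true
  clahe: false                # paper-gap: plain global equalization, CLAHE off
  background_method: median   # paper-gap: background region unstated; median fallback
  background_roi: null        # set [r0, r1, c0, c1] for an explicit background region

vesselness:
  small:
    kernel_px: 3              # small-vessel kernel scale
    beta: 0.5                 # paper-gap: canonical ridge-sensitivity default
    c_mode: adaptive          # paper-gap: half of max Hessian norm
    c_value: null
  large:
    kernel_px: 30             # large-vessel kernel scale
    beta: 0.5                 # paper-gap
    c_mode: adaptive          # paper-gap
    c_value: null

threshold:
  factor: 1.1                 # threshold = 1.1 x mean background level
  map2_method: otsu           # paper-gap: vesselness binarization unstated
  map2_level: null
  map3_method: otsu           # paper-gap; "fixed" + map3_level keeps mid-size vessels
  map3_level: null
  min_object_px: 0            # paper-gap: no small-object cleanup by default

morphometry:
  prune_len_px: 10.0          # paper-gap: spur-pruning length
  tip_correction: false
  bins_um: [0, 10, 20, 30, 40, 50, .inf]   # paper-gap: full edge set inferred

plaque:
  spot_fwhm_um: 15.0          # paper-gap: plaque spot scale
  min_sep_um: 30.0
  rel_threshold: 0.3

stats:
  welch: false                # pooled-variance Student's t

pixel_pitch_um: 3.90625       # 2 x 2 mm field over 512 x 512 px
seed: 0
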