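# File formats

All physical quantities are SI (metres, seconds, Pa). Pixel indices are
0-based and pixel-centre registered: pixel `i` spans
`[i*spacing, (i+1)*spacing)` with centre `(i + 0.5) * spacing`.

## Image stacks (`*.tiff` + `*.json`)

Multi-page 32-bit float TIFF, one page per frame, frame axis first.
The JSON sidecar (same stem) holds:

```json
{"pixel_spacing": [axial_m_per_px, lateral_m_per_px],
 "frame_interval": 0.000666, "t0": 0.0}
```

## Velocity fields (`*.npz`)

Compressed NumPy archive with `u`, `v` (T x Ny x Nx, m/s; `u` lateral,
`v` axial), grid node coordinates `x`, `y` (px), boolean `valid`
(False = rejected/interpolated vector), `pixel_spacing`, `times` (s).

## Ground truth (`ground_truth.h5`)

HDF5 with datasets `velocity_u`, `velocity_v` (float32, at inter-frame
pair times), `pair_times`, `frame_times`, `radius_pairs`,
`radius_frames`, `wss` (Pa, analytic, signed forward-positive),
`vmean_pairs`, `wall_points` (frames x points x 2, metres), and the
phantom configuration as a YAML string attribute `config`.

## Masks (`masks.tiff`)

Multi-page uint8 TIFF, 1 = lumen.

## Boundaries (`boundaries.csv`)

Columns: `frame, vessel, side, index, x_m, y_m, theta_rad` — ordered
wall polylines in physical coordinates with the local tangent angle.

## WSS tables (`wss.csv`)

Columns: `frame, vessel, side, arc_length_m, tau_pa` — signed in-plane
wall shear stress per boundary station; forward flow positive.

## Validation report (`validation_report.json`)

Flat JSON of the `ValidationReport` dataclass: waveform errors (%),
point-by-point velocity magnitude (% of global truth maximum) and
direction (degrees) errors, DSC, MADW (m), WSS RMSE (Pa) and Pearson
correlation, problem sizes, seed and config hash.
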