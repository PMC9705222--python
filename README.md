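# quadcal

Calibration and complex-signal reconstruction for full-range swept-source
OCT with passive quadrature demultiplexing.

A passively demultiplexed SS-OCT system measures the interference signal on
two channels that are nominally in quadrature (a 90° phase offset at every
wavelength). Real demodulation circuits deviate from that ideal in two
separable ways: a *chromatic* (wavenumber-dependent) amplitude ratio and
phase offset between the channels, and an *RF/spatial* (depth-dependent)
amplitude and phase response from the detection electronics. Both leave a
residual complex-conjugate ("mirror") artifact after reconstruction.

`quadcal` provides:

* **`quadcal.sim_forward`** — a forward simulator of the two-channel signal
  with controllable chromatic and depth-dependent imbalances, white noise,
  and per-A-line phase jitter (presets: `ideal`, `chromatic-only`,
  `rf-only`, `realistic`, `rf-sharp`, `bandlimited`);
* **`quadcal.preprocess`** — background/DC removal, coherent averaging with
  a shared per-A-line phase correction, and side-aware analytic-signal
  amplitude/phase extraction;
* **`quadcal.calibrate`** — the calibration pipeline: per-depth extraction
  of the amplitude ratio β(k) and phase offset Δϕ(k) from mirror
  measurements, wavenumber fits, depth-dependent vector fitting with gauge
  normalization at zero-delay, spatial correction, and chromatic-vector
  averaging into a persistable `CorrectionSet`;
* **`quadcal.reconstruct`** — quadrature reconstruction
  `s_Q = (β·s_II − cosΔϕ·s_I)/sinΔϕ`, complex-signal assembly, and metrics
  (extinction ratio, mirror suppression, peak height/FWHM/noise-floor
  preservation, sweep evaluation, sampling-density study);
* **`quadcal.io_cli`** — a `quadcal` command-line tool with HDF5/YAML
  persistence and full run-configuration provenance in every output.

## CLI

```sh
# simulate a 31-depth mirror sweep with the "realistic" imbalance preset
quadcal simulate --config examples/run.yaml --out sweep.h5

# run the calibration pipeline
quadcal calibrate --config examples/run.yaml --in sweep.h5 --out corrections.h5

# reconstruct depth profiles (modes: standard | direct | calibrated)
quadcal reconstruct --config examples/run.yaml --in sweep.h5 \
    --corrections corrections.h5 --mode calibrated --out profiles.h5

# per-depth extinction report (TSV)
quadcal evaluate --config examples/run.yaml --in sweep.h5 \
    --corrections corrections.h5 --out report.tsv
```

Configuration is a flat YAML mapping (unknown keys are rejected); every
option can also be left at its default. See `examples/run.yaml` for the
schema. Exit codes: 0 success, 2 configuration error, 3 data error.

## Conventions

* Depth is the normalized axis `zbar ∈ [−π/2, π/2)` with zero-delay at
  index `N//2`; a reflector on an integer depth bin is a pure DFT tone.
* Channel II leads channel I by +π/2 in the ideal system; the measured
  inter-channel phase offset is wrapped to the branch nearest +π/2.
* Depth profiles are oriented so a reflector at `zbar` appears at `+zbar`
  and its residual mirror artifact at `−zbar`.
* dB values are `20·log10` of magnitude ratios throughout.
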