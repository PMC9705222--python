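# quadcal run configuration (all keys optional; unknown keys rejected)
seed: 1
preset: realistic        # ideal | chromatic-only | rf-only | realistic | rf-sharp | bandlimited
n_samples: 1024          # spectral samples per A-line
m_alines: 64             # A-lines per mirror position (coherent averaging)
n_depths: 31             # calibration mirror positions
depth_span: 0.95         # fraction of +-pi/2 covered by the sweep
snr_db: 50.0             # single-shot depth-domain SNR (overrides noise_sigma)
jitter: 0.3              # per-A-line global phase jitter half-width (rad)
sim_mode: exact          # exact | dirac
k_fit_method: polynomial # polynomial | smoothing-spline
k_poly_degree: 7
z_fit_method: spline     # spline | polynomial | smoothing-spline
edge_fraction: 0.05      # distrusted spectral samples per edge
dc_exclusion_bins: 3.0   # zero-delay exclusion radius (depth bins)
mode: calibrated         # reconstruction mode: standard | direct | calibrated
log_level: INFO
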