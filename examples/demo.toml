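# dyadsync demo configuration: 4 simulated dyads through the full analysis.
# Every parameter of the reference analysis is spelled out; delete a line to
# fall back to the same value as the package default.

seed = 7
chromophore = "HbO"      # "HbO" (primary) or "HbR" (replication)
output_dir = "dyadsync_out"

[simulation]             # omit this table and set input_dir to analyse files
n_dyads = 4
duration_s = 240.0       # 4-min free conversation
fs = 7.81                # Hz
coupling_base = 0.6      # shared-band weight kappa_0
behavior_link = 0.02     # per-epoch kappa slope per SD of turn-taking

[preprocess]
iqr_alpha = 1.5          # wavelet motion-correction outlier threshold (IQRs)
motion_wavelet = "db5"
cardiac_band_hz = [0.6, 1.5]
power_ratio_min = 0.2    # heart-band QC: min cardiac/broadband power ratio
low_hz = 0.01            # Butterworth band-pass corners (2nd order,
high_hz = 0.5            # 12 dB/octave, zero-phase)

[coherence]
band_hz = [0.06, 0.15]   # analysis band (~6-16 s periods)
epoch_len_s = 30.0       # 8 epochs over 4 min
omega0 = 6.0             # Morlet centre frequency
dj = 0.08333333333333333 # 1/12 scale resolution

[surrogates]
surrogate_kind = "random_pair"   # random_pair | phase_randomized | none
n_draws = 1000           # distinct non-partner pairings are cached, so
                         # 1000 draws cost no more than n_dyads - 1 each

[stats]
ladder_upto = "M7"
# roi = "TPJ-L"          # uncomment for a per-ROI model
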