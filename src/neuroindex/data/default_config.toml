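# Reference configuration for `neuroindex run --config <file>`.
# Every key is optional; values below are the defaults.

[welch]
epoch_seconds = 4.0   # Welch epoch length; frequency resolution = 1/epoch_seconds
overlap = 0.5         # fractional epoch overlap in [0, 1)
window = "hann"

[iaf]
channels = ["O1", "O2"]     # occipital channels for the EC-EO reactivity peak
search_band_hz = [7.0, 14.0]
smooth = false              # 3-bin moving average of the difference spectrum

[predictor]
channels = ["C3", "C4"]
fit_band_hz = [2.0, 35.0]
two_peaks = true            # include the second (beta) Gaussian peak
scale = "linear"            # "linear" or "db"
degenerate_tol = 0.01       # fallback when model-powerlaw gap < tol * max PSD
# truncate_eo_s = 120.0     # uncomment to truncate the EO recording

[cardiac]
nn_plausibility_s = [0.3, 2.0]
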