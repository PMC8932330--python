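"""Run the denoising chain on one contaminated window.

The chain is low-pass (100 Hz ECG / 500 Hz sEMG) → adaptive 50 Hz notch →
EMD + wavelet thresholding of the initial intrinsic mode functions. The
printed numbers are the 50 Hz powerline amplitude before/after the notch
and the signal-to-noise ratio of the sEMG channel before/after denoising,
measured against the generator's clean component.
"""

import numpy as np

from fatiguefuse import PreprocessConfig, SynthParams, generate_window, preprocess_record


def tone_amplitude(x, freq, fs):
    spec = np.abs(np.fft.rfft(x)) / len(x) * 2
    f = np.fft.rfftfreq(len(x), 1 / fs)
    return spec[np.argmin(np.abs(f - freq))]


params = SynthParams(state=0, duration_s=10.0, seed=7,
                     powerline_amp=0.10, noise_sd=0.05)
raw = generate_window(params)
out = preprocess_record(raw, PreprocessConfig(wavelet_level=4))

clean = raw.ground_truth["clean"]["semg_r"]
for label, rec in (("raw", raw), ("preprocessed", out)):
    x = rec.channel("semg_r")
    p50 = tone_amplitude(x, 50.0, rec.fs)
    snr = 10 * np.log10(np.mean(clean**2) / np.mean((x - clean) ** 2))
    print(f"{label:13s}  50 Hz amplitude={p50 * 1e3:6.1f} µV   "
          f"sEMG SNR={snr:5.1f} dB")
# The notch removes the powerline tone; EMD+DWT lifts the SNR.
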