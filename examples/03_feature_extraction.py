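"""Extract the 11 fatigue features from synthetic windows of each state.

Features: mean RR interval, RR low-frequency band power and LF/HF ratio
from ECG; integrated amplitude (IEMG), RMS, mean power frequency (MPF) and
median frequency (MF) per sEMG channel. With fatigue the heart beats
faster (ECG_mean down, LF/HF up), the muscle works harder (IEMG/RMS up)
and its spectrum compresses (MPF/MF down).
"""

from fatiguefuse import extract_features, generate_dataset
from fatiguefuse.preprocess import PreprocessConfig, preprocess_record

records = generate_dataset(n_per_state=1, window_s=30.0, seed=3)
pconf = PreprocessConfig(denoise=False)

header = False
for rec in records:
    fv = extract_features(preprocess_record(rec, pconf))
    row = fv.as_dict()
    if not header:
        print("label " + "  ".join(f"{k:>11s}" for k in row))
        header = True
    print(f"{rec.label:5d} " + "  ".join(f"{v:11.4f}" for v in row.values()))
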