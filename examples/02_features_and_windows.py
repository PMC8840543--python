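"""Filter a sequence, cut it into 5 s windows and extract the 62 features.

Shows the preprocessing chain (4th-order Butterworth low-pass at 15 Hz,
3rd-order median despiking, 160-sample windows with 20% overlap) and a few
named feature values for the first window.
"""

from privhar import FilterSpec, GeneratorConfig, WindowSpec, generate_dataset
from privhar.features import FEATURE_NAMES, extract_features
from privhar.preprocessing import preprocess

sequences = generate_dataset(
    GeneratorConfig(n_subjects=2, n_activities=1, reps_per_activity=1, seed=0)
)
seq = sequences[0]
windows = preprocess(seq, FilterSpec(), WindowSpec())
print(f"{len(seq)} samples -> {len(windows)} windows of 160 samples (stride 128)")

fv = extract_features(windows[0])
print(f"feature vector length: {len(fv)} (48 time + 14 frequency)")
for name in ("mean_x", "std_smv", "corr_xy", "n_peaks_smv",
             "spectral_centroid_smv", "spectral_entropy_smv"):
    print(f"  {name:24s} {fv[list(FEATURE_NAMES).index(name)]: .4f}")
# mean_x is the posture (gravity) component of the x axis in g; the spectral
# centroid is the power-weighted mean frequency of the motion in Hz
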