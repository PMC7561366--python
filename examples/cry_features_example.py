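"""Extract F0 and F0var from a synthetic cry and compare with ground truth.

Synthesizes a five-phase cry bout (harmonic source, known per-phase F0
contour), runs the full acoustic pipeline (segmentation -> YIN pitch
tracking -> frame/phase filtering -> aggregation), and prints the recovered
features next to the generator's truth.
"""

import numpy as np

from crygaze import CrySpec, extract_cry_features, synth_cry

spec = CrySpec(seed=7, n_expiratory=5, f0_base_mean_hz=460.0,
               f0_base_sd_hz=30.0, f0_within_sd_hz=15.0, snr_db=25.0)
rec, truth = synth_cry(spec)
features, tracks = extract_cry_features(rec)

true_means = [s["f0_mean_hz"] for s in truth["segments"]]
true_sds = [s["f0_sd_hz"] for s in truth["segments"]]
print(f"recording: {rec.duration_s:.1f} s at {rec.sample_rate_hz} Hz, "
      f"{len(truth['segments'])} expiratory phases")
print(f"F0     estimated {features.f0_hz:7.2f} Hz | truth {np.mean(true_means):7.2f} Hz")
print(f"F0var  estimated {features.f0var_hz:7.2f} Hz | truth {np.mean(true_sds):7.2f} Hz")
print(f"phases used: {features.n_phases_used}, usable: {features.usable}")
# F0 is the mean of the per-phase frame-level F0 means over the first five
# expiratory phases; F0var is the mean of the per-phase F0 standard
# deviations. Estimates should sit within ~1% of the generator contour.
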