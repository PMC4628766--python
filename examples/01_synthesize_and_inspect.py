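"""Generate one clean and one severely dysphonic synthetic vowel and
print the morphological parameters that tell them apart.

The clean phonation concentrates its modulation energy at 0 Hz (LMR
near 0 dB, few points above the modulus mean), while jitter, tremor and
noise spread energy into side bands (lower LMR, higher PALA/RALA and
contrast).
"""

import numpy as np

from msmorph import (MorphConfig, VoiceSpec, compute_modspec, estimate_pitch,
                     extract_features, synth_vowel)
from msmorph.morphology import feature_names

RATE = 25000

clean_spec = VoiceSpec(f0=180.0, duration=0.5, sample_rate=RATE, seed=7)
severe_spec = VoiceSpec(f0=180.0, duration=0.5, sample_rate=RATE, seed=7,
                        jitter_pct=3.0, shimmer_pct=9.0,
                        tremor_freq=6.0, tremor_extent_pct=6.0,
                        am_tremor_extent_pct=10.0, hnr_db=8.0)

cfg = MorphConfig(nb=6)
names = feature_names(cfg.nb)

for label, spec in (("clean (level 0)", clean_spec),
                    ("severe (level 3)", severe_spec)):
    w = synth_vowel(spec)
    frame = w.samples[:3500]                     # one 140 ms frame
    f0, voiced = estimate_pitch(frame, RATE)
    vec = extract_features(frame, RATE, f0, cfg)
    print(f"\n{label}: estimated f0 = {f0:.1f} Hz")
    for key in ("lmr", "pala", "rala", "msw_mod", "cil"):
        print(f"  {key:8s} = {vec[names.index(key)]: .4f}")

print("""
LMR (dB, <= 0) drops as sub-25 Hz side bands appear; PALA/RALA (share /
odds of modulation-spectrum points above the modulus mean) and MSW
(Weber contrast of the spectrum image) rise with perturbation; CIL (dB)
tracks the overall dispersion of spectrum levels.""")
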