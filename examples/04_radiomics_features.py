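"""Extract the 1,750-value radiomics vector from one phantom case.

Per key frame the bank yields 350 features: 16 intensity statistics,
54 texture statistics (GLCM/GLRLM/GLSZM on the 32-level quantized image)
and 280 wavelet-domain features (35 per Haar subband, 8 subbands).
"""

from dsaflow import detection, phantom, radiomics, temporal

sched = phantom.build_schedule("AVM", "high", n_frames=35, rng_seed=2)
case = phantom.render_case(sched, (96, 96), noise_sd=8.0, rng_seed=2)

det = detection.reference_detect(case.frames)
events = temporal.structure_events(det)
key = temporal.select_key_frames(events, case.frames.n_frames)
vec = radiomics.case_radiomics_vector(case.frames, key)

print(f"key frames: {key}")
print(f"radiomics vector length: {len(vec)}  (5 frames x 350)")
frame0 = radiomics.frame_features(case.frames[key[0]])
print(f"per-frame bank: {len(frame0)} features")
print("a few values from the first key frame:")
for name in ("intensity_mean", "intensity_entropy", "glcm_contrast",
             "glrlm_sre", "glszm_zp", "wav_HH1_intensity_std"):
    # intensity_mean is in gray levels; entropy in bits; the texture and
    # wavelet statistics are dimensionless
    print(f"  {name:25s} = {vec[f'f0_{name}']:.4f}")
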