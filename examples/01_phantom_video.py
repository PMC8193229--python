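"""Generate one synthetic DSA run and inspect its ground truth.

Builds an AVM hemodynamic schedule (early sinus filling, no capillary
gap), renders it into a 30-frame phantom video, and prints the schedule
windows, truth boxes and the schedule-derived temporal features.
"""

from dsaflow import phantom

sched = phantom.build_schedule("AVM", grade_class="low", n_frames=30, rng_seed=7)
case = phantom.render_case(sched, image_size=(96, 96), noise_sd=8.0, rng_seed=7)

print(f"diagnosis: {case.diagnosis} (grade {case.grade_class})")
print(f"frames: {case.frames.n_frames} at {sched.frame_interval_ms:.0f} ms/frame")
for cls in phantom.STRUCTURE_CLASSES:
    print(f"  {cls:15s} frames {sched.onset[cls]:2d}..{sched.offset[cls]:2d}")
print(f"capillary gap: {sched.capillary_gap}  "
      f"nidus diameter: {sched.nidus_diameter_px}px")
print(f"truth boxes: {len(case.truth_boxes)} rows")
# T1..T5 = 1 means: sinus before artery end / Willis end / venous vessels,
# vein before Willis end, and no capillary phase -- the AVM shunt signature.
print(f"truth temporal features T1..T5: {case.truth_temporal}")
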