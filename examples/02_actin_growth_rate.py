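"""Track actin shell growth on a homogeneous GUV and fit its rate.

A 13-frame hour-long lapse is rendered with a programmed polymerization
speed; the per-frame shell thickness is measured from the images and the
ordinary-least-squares slope recovers the rate.
"""

import numpy as np

import guvkit as g

RATE = 0.2  # um/min, inside the observed 0.1-0.3 um/min envelope

spec = g.SynthSpec(
    guv_diameter_um=16.0, pixel_size_um=0.2, image_shape=(360, 360),
    actin_structure="symmetric_shell", actin_thickness_um=0.5,
    shot_noise=True, seed=12,
)
times = np.linspace(0.0, 60.0, 13)
lapse = g.render_time_lapse(spec, times, growth_rate_um_per_min=RATE)

thickness = []
for frame in lapse.frames:
    contour = g.segment_guv_contour(frame, pixel_size_um=lapse.pixel_size_um)
    thickness.append(g.actin_thickness(frame, contour).max_thickness_um)

fitted = g.fit_growth_rate(times, thickness)
print("time (min) :", "  ".join(f"{t:5.0f}" for t in times))
print("thick (um) :", "  ".join(f"{t:5.2f}" for t in thickness))
print(f"programmed rate {RATE} um/min -> fitted {fitted:.3f} um/min "
      f"({100 * abs(fitted - RATE) / RATE:.1f}% off)")
print("The quasilinear thickness increase mirrors branched-network growth on a")
print("vesicle; the slope is the actin polymerization speed.")
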