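"""Radial fluorescence profiling of a phase-separated GUV.

Renders a vesicle with four bright Ld arcs carrying an actin coat, draws
the 360 per-degree profiles, normalizes them, calls Ld domains at the 0.2
threshold, and scores the actin fluorescence on the domains.
"""

import guvkit as g

spec = g.SynthSpec(
    guv_diameter_um=24.0, pixel_size_um=0.2, image_shape=(200, 200),
    n_domains=4,
    actin_structure="symmetric_shell", actin_thickness_um=2.0,
    actin_on_ld_only=True,           # actin colocalizes with the Ld arcs
    shot_noise=True, seed=3,
)
frame = g.render_guv_frame(spec).frames[0]

contour = g.segment_guv_contour(frame, pixel_size_um=spec.pixel_size_um)
profiles, domains, score = g.profile_guv(frame, contour)

print(f"generated {spec.n_domains} Ld arcs; called n_d = {domains.n_d} domains "
      f"(lipid_norm > {domains.threshold}, min width {domains.min_width_deg:.1f} deg)")
for a, b in domains.intervals_deg:
    print(f"  Ld interval [{a:5.1f}, {b % 360:5.1f}) deg")
print(f"actin on Ld score = {score:.3f}  (1 = uniform actin at its own maximum")
print("over the Ld angles, 0 = background); domain intervals come from the")
print("normalized per-degree lipid profile, exactly as the count time courses do.")
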