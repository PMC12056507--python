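"""Generate a small synthetic dataset of debris-obscured spheroids.

Renders brightfield-like 16-bit frames: a dark, radially perturbed
spheroid with center darkening, a textured dead-cell debris cloud
extending well beyond it, background noise and an illumination ramp.
The ground-truth mask covers the spheroid only — debris is clutter,
not target.
"""

import numpy as np

import spheroidseg as ss

config = ss.synth.desk_scale_config(seed=0)
samples, entries = ss.generate_dataset(config, n=6, images_per_spheroid=2)

print(f"{len(samples)} images of {len({e.spheroid_id for e in entries})} spheroids")
print(f"frame {config.image_size} px at {config.pixel_size} um/px")
for s in samples[:4]:
    v = s.image.values
    d_um = 2 * np.sqrt(s.target.sum() / np.pi) * config.pixel_size
    print(
        f"  {s.spheroid_id} t{s.metadata['step']}: intensity {v.min()}..{v.max()} "
        f"(16-bit), spheroid diameter {d_um:.0f} um, "
        f"debris radius {s.metadata['debris_radius_px']:.0f} px"
    )

# the darkest pixel often lies in the debris, outside the spheroid —
# this is precisely what defeats plain intensity thresholding
heavy = ss.synth.desk_scale_config(seed=1, debris_opacity=0.9)
outside = 0
for i in range(50):
    s = ss.generate_sample(heavy, i)
    r, c = np.unravel_index(np.argmin(s.image.values), s.image.values.shape)
    outside += not s.target[r, c]
print(f"heavy debris: darkest pixel outside the spheroid in {outside}/50 frames")
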