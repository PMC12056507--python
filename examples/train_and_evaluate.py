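"""Train the compact U-Net on synthetic spheroids and evaluate it.

A deliberately small run (48 training images at 64×64, 12 epochs) so
the example finishes in about a minute on one CPU core; the full
desk-scale conditions (128×128, 60/20/20, up to 40 epochs) are what
scripts/acceptance.py reproduces.
"""

import numpy as np

import spheroidseg as ss
from spheroidseg.nn import ModelConfig, TrainConfig, build_model, predict_probmap, train

config = ss.synth.desk_scale_config(seed=0, image_size=(64, 64))
samples, entries = ss.generate_dataset(config, n=80, images_per_spheroid=1)
entries = ss.split_by_spheroid(entries, (0.6, 0.2, 0.2), seed=0)
split_of = {e.spheroid_id: e.split for e in entries}
items = {"train": [], "val": [], "test": []}
for s in samples:
    items[split_of[s.spheroid_id]].append((s.image, s.target, s.spheroid_id))

model = build_model(ModelConfig(depth=3, base_channels=8, input_size=(64, 64)), seed=0)
history = train(
    model, items["train"], items["val"],
    TrainConfig(loss="dice", epochs=12, patience=6, seed=0),
)
print(f"trained {len(history.rows)} epochs; best val JCD "
      f"{history.best_val_jcd:.3f} at epoch {history.best_epoch}")

records = []
otsu_js = []
for image, target, _sid in items["test"]:
    pm = predict_probmap(model, image, 1.0)
    records.append(ss.evaluate_image(ss.extract_spheroid(pm.values), target, config.pixel_size))
    otsu = ss.otsu_baseline(ss.to_8bit(image))
    otsu_js.append(ss.jcd(otsu.spheroid_mask, target))

summ = ss.summarize(records)
print(f"test n={summ.n}: JCD {summ.mean['jcd']:.3f} ± {summ.sd['jcd']:.3f}, "
      f"RDD {summ.mean['rdd']:.3f}, delta_r {summ.mean['delta_r_um']:.1f} um")
print(f"ISF {summ.isf:.2f} ± {summ.isf_se:.2f}, ASF {summ.asf:.2f} ± {summ.asf_se:.2f}")
print(f"Otsu baseline on the same images: JCD {np.mean(otsu_js):.3f} "
      "(debris drags the threshold off the spheroid)")
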