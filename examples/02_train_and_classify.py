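"""Train the surrogate tool-presence classifier and score it on held-out videos.

The loss is binary cross-entropy with logits, each class scaled by
CW_k = N / (K * n_k) computed on the training split, optimized with Adam and
linear warmup.  The split is video-level: all frames of a video stay on one
side, as frames within a video are strongly correlated.
"""

from pathlib import Path

import numpy as np
from PIL import Image

import surgloc as sl

data = Path("scratch/example_scenes")
if not (data / "manifest.csv").exists():
    sl.generate_dataset(sl.SceneConfig(seed=7), 200, 4, data)
manifest = sl.load_manifest(data, sl.SceneConfig(seed=7))

plan = sl.make_splits(manifest.video_ids(), "fixed_fraction", 0.5, seed=0)
train_videos, test_videos = plan.folds[0]
print(f"training on videos {train_videos}, testing on {test_videos}")

config = sl.surrogate_train_config(seed=0)
model = sl.train("surrogate_small", manifest, train_videos, config, data, zero_count_policy="unit")
print("class weights:", np.round(model.class_weights.weights, 2))
print("per-epoch training loss:", [round(x, 3) for x in model.loss_history])

test = [r for r in manifest.records if r.video_id in set(test_videos)]
frames = [np.asarray(Image.open(data / r.frame_path).convert("RGB")) for r in test]
probs = model.predict_batch(np.stack([model.preprocess(f) for f in frames]))
labels = np.array([r.labels for r in test])
report = sl.classification_report(probs, labels, manifest.config.class_names, skip_undefined_ap=True)

print("\nheld-out classification report (percent):")
for name, m in report.per_class.items():
    print(f"  {name:>12}: recall {m['recall']:6.2f}  F1 {m['f1']:6.2f}  AP {m.get('ap', float('nan')):6.2f}")
print(f"  {'mean':>12}: recall {report.mean_recall:6.2f}  F1 {report.mean_f1:6.2f}  mAP {report.mean_ap:6.2f}")
print(
    "\nAP is the area under each class's precision-recall curve; the rare classes"
    "\nkeep high AP because the class-weighted loss keeps them from being ignored."
)

model.save(Path("scratch/example_model"))
print("\ncheckpoint saved to scratch/example_model.{npz,json}")
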