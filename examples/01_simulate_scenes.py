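"""Generate a synthetic laparoscopic-like dataset and inspect its imbalance.

Frames carry bright, elongated, edge-anchored "tools" over a dark tissue-like
texture; per-class presence probabilities default to the Cholec80 occurrence
proportions, so hook and grasper dominate and scissors is rare.
"""

from pathlib import Path

import surgloc as sl

out = Path("scratch/example_scenes")
config = sl.SceneConfig(seed=7)
manifest = sl.generate_dataset(config, n_frames=200, n_videos=4, out_dir=out)

counts = manifest.class_counts()
print(f"wrote {len(manifest.records)} frames to {out}")
print("frames containing each tool (of 200):")
for name, count in zip(config.class_names, counts):
    print(f"  {name:>12}: {int(count):3d}")
print(
    "\nThe counts mirror the real dataset's imbalance: the two workhorse tools"
    "\nappear in most frames while scissors shows up in only a handful, which is"
    "\nexactly the regime the class-weighted loss is meant to handle."
)
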