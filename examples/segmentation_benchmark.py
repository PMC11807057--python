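"""Benchmark a predicted mask movie against ground truth.

Builds a 3-frame synthetic movie of rod-shaped cells, corrupts each frame
with a known number of segmentation mistakes, and scores the corrupted
movie both pixel-wise and object-wise. The object-level report counts
errors the pixel scores barely register: note how IoU stays high while
every planted mistake is itemized.
"""

import numpy as np

import cyanobench as cb

gt_frames, pred_frames = [], []
for i in range(3):
    frame = cb.generate_rod_mask(45, 256, seed=10 + i)
    frame = cb.LabeledMask(frame.pixels, frame_index=i)
    plan = cb.CorruptionPlan(n_split=2, n_merge=1, n_delete=1, n_add=2,
                             jitter_frac=0.05, seed=20 + i)
    corrupted, planted = cb.corrupt_mask(frame, plan)
    gt_frames.append(frame)
    pred_frames.append(corrupted)
    print(f"frame {i}: planted {planted.as_dict()}")

gt = cb.MaskMovie(tuple(gt_frames))
pred = cb.MaskMovie(tuple(pred_frames))

px = cb.movie_pixel_scores(gt, pred)
print(f"\npixel scores : IoU={px.iou:.3f} precision={px.precision:.3f} "
      f"recall={px.recall:.3f}")

reports, pooled = cb.movie_error_report(gt, pred, cb.ToleranceConfig(tol=0.10))
print(f"object errors: {pooled.as_dict()}")
print("\nPixel scores stay near 1 because each planted mistake moves few")
print(f"pixels; the object report itemizes all {pooled.total} of them:")
print(f"{pooled.over_seg} splits, {pooled.under_seg} merges, "
      f"{pooled.false_neg} missing cells, {pooled.false_pos} spurious objects.")
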