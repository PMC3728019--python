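"""Planted-truth demonstration of the imaging pipeline.

Renders a synthetic scene (bright-field + two FISH channels) with known
per-cell transcript counts, then runs segmentation, automatic-threshold spot
detection, and spot-to-cell assignment, and compares against the truth.
"""

import numpy as np
import pandas as pd

from thfish import imgquant, synth

rng = np.random.default_rng(1)
n = 12
counts = pd.DataFrame({
    "cell_id": np.arange(1, n + 1),
    "tbx21": rng.integers(5, 41, n),
    "gata3": rng.integers(5, 41, n),
})
scene = synth.SceneParams(n_cells=n, seed=1)
fish, brightfield, truth = synth.make_scene(scene, counts)

mask = imgquant.segment_cells(brightfield, min_area_px=500)
print(f"segmented {mask.n_cells} cells (planted {n})")

exact = total = 0
for gene in ("tbx21", "gata3"):
    spots = imgquant.detect_spots(fish[gene])  # auto plateau threshold
    detected, n_bg = imgquant.assign_spots(spots, mask)
    for i, (cx, cy) in enumerate(truth.centers_px):
        lab = int(mask.labels[int(round(cy)), int(round(cx))])
        det = int(detected.loc[lab, gene]) if lab > 0 else -1
        total += 1
        exact += det == counts[gene].iloc[i]
print(f"exact per-cell count recovery: {exact}/{total} cells")

# At spot-peak SNR 10 and resolvable spot densities the chain recovers the
# planted count exactly for essentially every cell.
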