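import numpy as np
import pandas as pd
import pytest

from thfish import imgquant, synth


def make_planted_scene(seed: int, n_cells: int = 20, lo: int = 5, hi: int = 40):
    """A rendered scene with resolvable per-cell counts and its ground truth."""
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "tbx21": rng.integers(lo, hi + 1, n_cells),
            "gata3": rng.integers(lo, hi + 1, n_cells),
        }
    )
    scene = synth.SceneParams(n_cells=n_cells, seed=seed)
    fish, bf, truth = synth.make_scene(scene, counts)
    return fish, bf, truth, counts


def counts_vs_truth(mask: imgquant.LabelMask, truth: synth.SceneTruth, detected: pd.DataFrame, gene: str):
    """Per-truth-cell (true, detected) count pairs, matching each planted cell
    to the segmented label containing its centre."""
    out = []
    for i, (cx, cy) in enumerate(truth.centers_px):
        lab = int(mask.labels[int(round(cy)), int(round(cx))])
        det = float(detected.loc[lab, gene]) if lab > 0 and gene in detected.columns and lab in detected.index else np.nan
        out.append((float(truth.true_counts.iloc[i][gene]), det))
    return out


@pytest.fixture(scope="session")
def planted_scene():
    return make_planted_scene(seed=1)
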