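import warnings

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from gliaquant import IhcSceneParams, analyze_image, generate_ihc_image

warnings.filterwarnings("ignore", category=FutureWarning)
# MixedLM routinely reports boundary/convergence warnings on simulated
# null data with zero between-animal variance; they are expected.
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def default_scene():
    """One synthetic microglia scene plus its analysis, shared per session."""
    params = IhcSceneParams(n_cells=20, seed=42)
    rgb, truth = generate_ihc_image(params)
    records, summary, masks = analyze_image(rgb)
    return {"params": params, "rgb": rgb, "truth": truth,
            "records": records, "summary": summary, "masks": masks}


def soma_precision_recall(soma, truth):
    """Centroid-matching precision/recall with match radius = max soma radius."""
    if soma.n_soma == 0:
        return 0.0, 0.0
    d = cdist(soma.centroids, truth.soma_centers)
    r = truth.soma_radii.max()
    precision = float((d.min(axis=1) <= r).mean())
    recall = float((d.min(axis=0) <= r).mean())
    return precision, recall


def truth_process_mask(truth):
    """Rasterize the ground-truth polylines (minus soma) to a pixel mask."""
    mask = np.zeros_like(truth.tissue_mask)
    for lines in truth.process_polylines:
        for line in lines:
            pix = np.rint(line).astype(int)
            mask[pix[:, 0], pix[:, 1]] = True
    return mask & ~truth.soma_mask
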