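import numpy as np
import pytest

from melanotype import default_archetypes, render_scene, sample_feature_table
from melanotype.segmentation import DetectionParams, segment_image
from melanotype.synthetic_data import CohortConfig, NoiseParams


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def seg_scene(archetypes):
    """A rendered scene of 50 well-separated, in-range nuclei plus its
    detections — shared by segmentation, morphometry and acceptance tests."""
    noise = NoiseParams(hematoxylin_mean=0.5, hematoxylin_sd=0.1)
    rec = sample_feature_table(archetypes, "primary_tumor", 80, seed=11, noise=noise)
    rec = (
        rec[(rec.nucleus_area >= 12) & (rec.nucleus_area <= 150)]
        .head(50)
        .reset_index(drop=True)
    )
    cfg = CohortConfig(specimens=[], scene_shape_um=(300, 300), seed=11, noise=noise)
    scene = render_scene(rec, cfg, seed=11)
    params = DetectionParams(pixel_size_um=scene.pixel_size_um)
    detections, od, nuclei = segment_image(scene.image, params)
    return {
        "scene": scene,
        "params": params,
        "detections": detections,
        "od": od,
        "nuclei": nuclei,
    }


def match_detections(scene, detections):
    """Pair each detection with its ground-truth label; returns (det, gt_row, iou)."""
    out = []
    for det in detections:
        r0, c0, r1, c1 = det.bbox
        window = scene.nucleus_labels[r0:r1, c0:c1]
        votes = np.bincount(window[det.nucleus_mask])
        gt_label = int(votes.argmax())
        if gt_label == 0:
            continue
        gt = scene.nucleus_labels == gt_label
        full = np.zeros_like(gt)
        full[r0:r1, c0:c1] = det.nucleus_mask
        iou = (gt & full).sum() / (gt | full).sum()
        out.append((det, scene.records.iloc[gt_label - 1], float(iou)))
    return out
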