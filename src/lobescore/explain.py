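"""Examination-level score aggregation and Grad-CAM relevance maps.

The six per-lobe ordinal predictions of one examination sum to the overall
0-12 severity score.  Grad-CAM maps are computed from the last convolutional
layer of each view stream: channel weights are the spatial mean of the class
logit's gradient with respect to the feature maps, the relevance is the
rectified weighted channel sum, normalised to [0, 1] over the whole lobe
sample and upsampled to slice resolution.  Because slice evidence is
max-pooled, the gradient reaches only the slices that carry each channel's
maximum — the slices the prediction actually relied on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .geometry import ViewGeometry
from .model import DualViewLobeClassifier, PredictionRecord, _to_channels
from .preprocess import CropInfo, LobeSample

__all__ = [
    "ExamScore",
    "RelevanceVolume",
    "overall_score",
    "aggregate_examination",
    "gradcam_slices",
    "gradcam_volume",
]


@dataclass
class ExamScore:
    """Per-exam lobar scores and their 0-12 sum."""

    patient_id: str
    exam_id: str
    pathology: str
    lobe_scores: tuple[int, ...]
    overall: int
    source: str  # "reference" | "predicted"

    def __post_init__(self) -> None:
        if self.overall != sum(self.lobe_scores) or not 0 <= self.overall <= 12:
            raise ValueError("overall must equal the lobe-score sum in [0, 12]")


@dataclass
class RelevanceVolume:
    """Grad-CAM relevance resampled into a source view's voxel grid."""

    values: np.ndarray
    geometry: ViewGeometry
    threshold: float
    class_index: int

    def __post_init__(self) -> None:
        if self.values.min() < 0 or self.values.max() > 1 + 1e-9:
            raise ValueError("relevance values must lie in [0, 1]")


def overall_score(lobe_scores) -> int:
    """Sum of the six lobar ordinal scores (range 0-12)."""
    scores = list(lobe_scores)
    if len(scores) != 6:
        raise ValueError(f"expected 6 lobe scores, got {len(scores)}")
    if any(s not in (0, 1, 2) for s in scores):
        raise ValueError(f"lobe scores must be in {{0,1,2}}, got {scores}")
    return int(sum(scores))


def aggregate_examination(records: list[PredictionRecord]) -> ExamScore:
    """Combine one exam's six lobe predictions into its overall score."""
    if len(records) != 6:
        raise ValueError(f"expected 6 prediction records, got {len(records)}")
    exams = {(r.patient_id, r.exam_id, r.pathology) for r in records}
    if len(exams) != 1:
        raise ValueError(f"records mix examinations/pathologies: {sorted(exams)}")
    lobes = sorted(r.lobe_id for r in records)
    if lobes != [1, 2, 3, 4, 5, 6]:
        raise ValueError(f"need exactly lobes 1..6, got {lobes}")
    by_lobe = {r.lobe_id: r.predicted_score for r in records}
    lobe_scores = tuple(by_lobe[i] for i in range(1, 7))
    r = records[0]
    return ExamScore(
        patient_id=r.patient_id, exam_id=r.exam_id, pathology=r.pathology,
        lobe_scores=lobe_scores, overall=overall_score(lobe_scores),
        source="predicted",
    )


def gradcam_slices(
    model: DualViewLobeClassifier, sample: LobeSample, class_index: int
) -> dict[str, np.ndarray]:
    """Per-slice relevance maps for one lobe sample, per view.

    Returns ``{"coronal": (S_c, side, side), "axial": (S_a, side, side)}``
    arrays in [0, 1], jointly normalised over all slices of the sample and
    upsampled to the stored slice resolution.
    """
    if class_index not in (0, 1, 2):
        raise ValueError(f"class_index must be 0, 1 or 2, got {class_index}")
    if not hasattr(model, "head_"):
        raise ValueError("model is not fitted")

    maps: dict[str, np.ndarray] = {}
    c = model.backbones_["coronal"].feature_channels
    head_w = model.head_.W[class_index]
    view_grads = {"coronal": head_w[:c], "axial": head_w[c:]}
    raw_max = 0.0
    for view, stack in (("coronal", sample.coronal_stack), ("axial", sample.axial_stack)):
        backbone = model.backbones_[view]
        feat = backbone.forward(_to_channels(stack))  # (S, C, h, w)
        s, ch, h, w = feat.shape
        desc = feat.mean(axis=(2, 3))
        arg = desc.argmax(axis=0)
        # d(logit)/d(feat[s,c,:,:]) is constant over space: head weight routed
        # through the slice max, divided by the average-pool area
        alpha = np.zeros((s, ch))
        alpha[arg, np.arange(ch)] = view_grads[view] / (h * w)
        rel = np.maximum(np.einsum("sc,schw->shw", alpha, feat), 0.0)
        side = stack.shape[1]
        up = np.stack([
            _sk_resize(r, (side, side), order=1, mode="constant",
                       anti_aliasing=False, preserve_range=True)
            for r in rel
        ])
        maps[view] = up
        raw_max = max(raw_max, float(up.max()))
    if raw_max > 0:
        for view in maps:
            maps[view] = maps[view] / raw_max
    return maps


def gradcam_volume(
    slices: np.ndarray,
    crop_info: CropInfo,
    threshold: float = 0.5,
    class_index: int = 0,
) -> RelevanceVolume:
    """Resample per-slice relevance maps back into the source volume grid.

    Inverts the lobe crop using its recorded provenance (slice indices,
    bounding box, letterbox padding, resize factor); values below
    ``threshold`` are zeroed.  The output shares the source view's shape and
    geometry, so it can be exported as NIfTI and overlaid on the MRI.
    """
    if crop_info is None:
        raise ValueError("crop provenance is required to rebuild the volume")
    slices = np.asarray(slices, dtype=float)
    if slices.shape[0] != len(crop_info.slice_indices):
        raise ValueError("slice count does not match the crop provenance")
    out = np.zeros(crop_info.source_shape, dtype=float)
    side = crop_info.padded_side
    h = crop_info.row_stop - crop_info.row_start
    w = crop_info.col_stop - crop_info.col_start
    for s_idx, rel in zip(crop_info.slice_indices, slices):
        if side != crop_info.out_side:
            rel = _sk_resize(rel, (side, side), order=1, mode="constant",
                             anti_aliasing=crop_info.out_side > side,
                             preserve_range=True)
        plane = rel[crop_info.pad_rows : crop_info.pad_rows + h,
                    crop_info.pad_cols : crop_info.pad_cols + w]
        out[s_idx, crop_info.row_start : crop_info.row_stop,
            crop_info.col_start : crop_info.col_stop] = plane
    out = np.clip(out, 0.0, 1.0)
    out[out < threshold] = 0.0
    return RelevanceVolume(
        values=out, geometry=crop_info.geometry, threshold=threshold,
        class_index=class_index,
    )
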