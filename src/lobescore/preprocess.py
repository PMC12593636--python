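"""Intensity normalisation, cross-view mask transfer and per-lobe cropping.

The fixed pipeline order is: bias correction -> z-score normalisation ->
(coronal-to-axial mask resampling, morphological closing) -> per-lobe crop
-> rescale to [0, 1].  All cross-view operations go through physical (mm)
space using the acquisition geometry, which is what aligns the two views of
one examination without any image registration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from ._tables import LOBE_NAMES
from .geometry import ViewGeometry, to_sitk

logger = logging.getLogger(__name__)

__all__ = [
    "CropInfo",
    "LobeSample",
    "correct_bias",
    "zscore_normalize",
    "rescale_unit",
    "resample_mask_to_view",
    "close_mask",
    "crop_lobe",
    "extract_lobe_samples",
]


@dataclass(frozen=True)
class CropInfo:
    """Provenance of a per-lobe slice-stack crop.

    Records everything needed to map crop pixels back into the source
    volume: which slices were kept, the in-plane bounding box, the symmetric
    letterbox padding, and the resize factor to the square output side.
    """

    view: str  # "coronal" | "axial"
    slice_indices: tuple[int, ...]
    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    pad_rows: int
    pad_cols: int
    out_side: int
    source_shape: tuple[int, int, int]
    geometry: ViewGeometry

    @property
    def padded_side(self) -> int:
        return max(self.row_stop - self.row_start, self.col_stop - self.col_start)


@dataclass
class LobeSample:
    """Paired dual-view slice stacks of one lobe: the classifier's unit of work.

    Stacks are ``(S, side, side)`` float arrays in [0, 1]; ``label`` is the
    ordinal severity (None at inference time).
    """

    coronal_stack: np.ndarray
    axial_stack: np.ndarray
    lobe_id: int
    pathology: str
    patient_id: str
    exam_id: str
    label: int | None = None
    coronal_crop: CropInfo | None = None
    axial_crop: CropInfo | None = None

    def __post_init__(self) -> None:
        for name, stack in (("coronal", self.coronal_stack), ("axial", self.axial_stack)):
            if stack.ndim != 3 or stack.shape[0] < 1:
                raise ValueError(f"{name} stack must be (S>=1, side, side)")
            if stack.shape[1] != stack.shape[2]:
                raise ValueError(f"{name} slices must be square")
            if stack.min() < -1e-6 or stack.max() > 1 + 1e-6:
                raise ValueError(f"{name} intensities must lie in [0, 1]")
        if not 1 <= self.lobe_id <= 6:
            raise ValueError(f"lobe_id must be 1..6, got {self.lobe_id}")


def correct_bias(
    volume: np.ndarray, mask: np.ndarray, shrink_sigma_fraction: float = 0.25
) -> np.ndarray:
    """Remove a smooth multiplicative intensity field (homomorphic estimate).

    The field is estimated as a large-kernel Gaussian smoothing of the
    log-intensity inside ``mask`` (normalised convolution, so the estimate
    extrapolates smoothly outside the mask), exponentiated back, and divided
    out.  The mean intensity inside the mask is preserved.  An external
    N4-style corrector can replace this function anywhere a callable with
    the same ``(volume, mask) -> volume`` signature is accepted.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("bias correction requires a non-empty mask")
    volume = np.asarray(volume, dtype=np.float64)
    shift = 0.0
    vmin = volume[mask].min()
    if vmin <= 0:
        shift = -vmin + 1e-3
    v = volume + shift

    extents = [np.ptp(np.nonzero(mask)[a]) + 1 for a in range(3)]
    sigma = [max(shrink_sigma_fraction * e, 1.0) for e in extents]
    logv = np.where(mask, np.log(v, where=v > 0, out=np.zeros_like(v)), 0.0)
    w = mask.astype(np.float64)
    num = ndimage.gaussian_filter(logv, sigma=sigma)
    den = ndimage.gaussian_filter(w, sigma=sigma)
    log_field = np.where(den > 1e-8, num / np.maximum(den, 1e-8), 0.0)
    log_field -= log_field[mask].mean()
    field = np.exp(log_field)

    corrected = v / field - shift
    scale = volume[mask].mean() / corrected[mask].mean()
    return corrected * scale


def zscore_normalize(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Standardise intensities to zero mean, unit (population) SD inside mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("z-score normalisation needs at least 2 mask voxels")
    vals = volume[mask]
    mu, sd = vals.mean(), vals.std()
    if sd == 0:
        raise ValueError("z-score normalisation undefined for constant volume")
    return (volume - mu) / sd


def rescale_unit(stack: np.ndarray) -> np.ndarray:
    """Affinely map intensities to [0, 1] (min -> 0, max -> 1).

    A constant input maps to all 0.5 by convention, with a logged warning.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if not np.all(np.isfinite(stack)):
        raise ValueError("rescale_unit requires finite values")
    lo, hi = stack.min(), stack.max()
    if hi == lo:
        logger.warning("rescale_unit: constant input mapped to 0.5")
        return np.full_like(stack, 0.5)
    return (stack - lo) / (hi - lo)


def resample_mask_to_view(
    mask: np.ndarray,
    src: ViewGeometry,
    dst: ViewGeometry,
    dst_shape: tuple[int, int, int],
) -> np.ndarray:
    """Carry a label mask into another view's grid (nearest neighbour, mm space)."""
    img = to_sitk(mask.astype(np.uint8), src)
    ref = to_sitk(np.zeros(dst_shape, dtype=np.uint8), dst)
    out = sitk.Resample(img, ref, sitk.Transform(), sitk.sitkNearestNeighbor, 0)
    res = sitk.GetArrayFromImage(out)
    if mask.any() and not res.any():
        logger.warning("resample_mask_to_view: fields of view do not overlap")
    return res.astype(mask.dtype)


def close_mask(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological closing per label to smooth slice-thickness edge artefacts.

    Applied independently to each positive label with a ball structuring
    element; the output is a superset of the input (voxels are only added,
    and only where no other label already sits).
    """
    if radius < 0:
        raise ValueError("closing radius must be >= 0")
    mask = np.asarray(mask)
    if radius == 0:
        return mask.copy()
    from skimage.morphology import ball

    selem = ball(radius)
    out = mask.copy()
    for lab in np.unique(mask):
        if lab == 0:
            continue
        m = mask == lab
        closed = ndimage.binary_closing(m, structure=selem) | m
        out[closed & (out == 0)] = lab
    return out


def _letterbox_resize(plane: np.ndarray, out_side: int) -> np.ndarray:
    h, w = plane.shape
    side = max(h, w)
    pad_r, pad_c = (side - h) // 2, (side - w) // 2
    padded = np.zeros((side, side), dtype=plane.dtype)
    padded[pad_r : pad_r + h, pad_c : pad_c + w] = plane
    if side == out_side:
        return padded
    return _sk_resize(padded, (out_side, out_side), order=1, mode="constant",
                      anti_aliasing=side > out_side, preserve_range=True)


def crop_lobe(
    volume: np.ndarray,
    lobe_map: np.ndarray,
    lobe_id: int,
    margin: int = 2,
    out_side: int = 256,
    view: str = "coronal",
    geometry: ViewGeometry | None = None,
) -> tuple[np.ndarray, CropInfo]:
    """Crop the slice stack of one lobe and letterbox-resize it to a square.

    Keeps only slices (axis 0) that intersect the lobe; crops the in-plane
    tight bounding box plus ``margin`` voxels (clipped to the volume); pads
    to a square to preserve aspect ratio; resizes to ``out_side``.
    """
    lobe = lobe_map == lobe_id
    if not lobe.any():
        raise ValueError(
            f"lobe {lobe_id} ({LOBE_NAMES[lobe_id - 1]}) absent from lobe map"
        )
    slices = np.flatnonzero(lobe.any(axis=(1, 2)))
    rows = np.flatnonzero(lobe.any(axis=(0, 2)))
    cols = np.flatnonzero(lobe.any(axis=(0, 1)))
    r0 = max(rows[0] - margin, 0)
    r1 = min(rows[-1] + margin + 1, volume.shape[1])
    c0 = max(cols[0] - margin, 0)
    c1 = min(cols[-1] + margin + 1, volume.shape[2])

    h, w = r1 - r0, c1 - c0
    side = max(h, w)
    stack = np.stack(
        [_letterbox_resize(volume[s, r0:r1, c0:c1], out_side) for s in slices]
    )
    info = CropInfo(
        view=view,
        slice_indices=tuple(int(s) for s in slices),
        row_start=int(r0),
        row_stop=int(r1),
        col_start=int(c0),
        col_stop=int(c1),
        pad_rows=int((side - h) // 2),
        pad_cols=int((side - w) // 2),
        out_side=out_side,
        source_shape=tuple(volume.shape),
        geometry=geometry if geometry is not None
        else ViewGeometry((0, 0, 0), (1, 1, 1)),
    )
    return stack, info


@dataclass
class PreprocessConfig:
    """Tunables of the preprocessing pipeline (defaults used throughout).

    ``mask_to_lobe`` zeroes (to the volume minimum, i.e. darkest) all voxels
    outside the cropped lobe, so each sample shows only its own lobe's
    content rather than whatever neighbouring lobes fall inside the
    bounding box.
    """

    closing_radius: int = 1
    crop_margin: int = 2
    out_side: int = 256
    bias_correct: bool = True
    mask_to_lobe: bool = True
    bias_corrector: object = field(default=None, repr=False)  # plug-in point


def extract_lobe_samples(
    exam,
    lobe_map_coronal: np.ndarray,
    labels: dict[str, np.ndarray] | None = None,
    config: PreprocessConfig | None = None,
) -> dict[str, list[LobeSample]]:
    """Run the full preprocessing pipeline on one examination.

    ``labels`` optionally maps pathology -> 6 ordinal scores (training
    targets); at inference it is omitted.  Returns pathology -> list of six
    :class:`LobeSample` in lobe-label order.

    Pipeline: bias correction and z-score normalisation per view (over the
    whole volume, before any segmentation is consulted), coronal lobe map
    carried into the axial grid by header geometry, per-label closing,
    per-lobe dual-view crops, then [0, 1] rescaling per stack.
    """
    cfg = config or PreprocessConfig()
    corrector = cfg.bias_corrector or correct_bias

    views = {}
    for view, vol, geom in (
        ("coronal", exam.coronal_volume, exam.coronal_geometry),
        ("axial", exam.axial_volume, exam.axial_geometry),
    ):
        full = np.ones(vol.shape, dtype=bool)
        v = corrector(vol, full) if cfg.bias_correct else np.asarray(vol, float)
        views[view] = (zscore_normalize(v, full), geom)

    ax_shape = exam.axial_volume.shape
    lobe_ax = resample_mask_to_view(
        lobe_map_coronal, exam.coronal_geometry, exam.axial_geometry, ax_shape
    )
    lobe_cor = close_mask(lobe_map_coronal, cfg.closing_radius)
    lobe_ax = close_mask(lobe_ax, cfg.closing_radius)

    pathologies = list(labels) if labels is not None else ["bronchiectasis_wall", "mucus"]
    out: dict[str, list[LobeSample]] = {p: [] for p in pathologies}
    for lobe_id in range(1, 7):
        cor_vol, ax_vol = views["coronal"][0], views["axial"][0]
        if cfg.mask_to_lobe:
            cor_vol = np.where(lobe_cor == lobe_id, cor_vol, cor_vol.min())
            ax_vol = np.where(lobe_ax == lobe_id, ax_vol, ax_vol.min())
        cor_stack, cor_info = crop_lobe(
            cor_vol, lobe_cor, lobe_id, cfg.crop_margin, cfg.out_side,
            view="coronal", geometry=views["coronal"][1],
        )
        ax_stack, ax_info = crop_lobe(
            ax_vol, lobe_ax, lobe_id, cfg.crop_margin, cfg.out_side,
            view="axial", geometry=views["axial"][1],
        )
        cor_stack = rescale_unit(cor_stack)
        ax_stack = rescale_unit(ax_stack)
        for pathology in pathologies:
            out[pathology].append(
                LobeSample(
                    coronal_stack=cor_stack,
                    axial_stack=ax_stack,
                    lobe_id=lobe_id,
                    pathology=pathology,
                    patient_id=exam.patient_id,
                    exam_id=exam.exam_id,
                    label=int(labels[pathology][lobe_id - 1]) if labels else None,
                    coronal_crop=cor_info,
                    axial_crop=ax_info,
                )
            )
    return out
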