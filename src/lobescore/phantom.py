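"""Synthetic dual-view chest-MRI phantoms with lobe-level severity ground truth.

Every downstream stage (preprocessing, lobe approximation, the dual-view
classifier, the agreement metrics) is exercised on cohorts produced here,
since the clinical MRI data the method was developed on are not public.

A phantom patient is two ellipsoid-like lung halves in physical (mm) space,
each partitioned into three lobar regions by oblique planes (left: upper,
lingula, lower = labels 1-3; right: upper, middle, lower = labels 4-6).
Per examination, two bright pathology classes are planted inside lobes —
filled blobs emulating mucus plugging and branching tubes with bright wall
rings emulating bronchiectasis/wall thickening — such that the planted
voxel coverage fraction of each lobe reproduces a sampled ordinal severity
score: 0 = absent, 1 = under half the lobe affected, 2 = at least half.
The anatomy is rendered once on the coronal grid and the axial view is a
genuine geometric resampling of it (different spacing and orientation),
followed by an independent multiplicative bias field and Rician noise per
view — the artefacts the preprocessing stage must undo.

Default score marginals per lobe follow the reference cohort's observed
score distribution (see :mod:`lobescore._tables`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from ._tables import LOBE_NAMES, PATHOLOGIES, default_score_marginals
from .geometry import ViewGeometry, to_sitk

import SimpleITK as sitk

__all__ = [
    "PhantomConfig",
    "Examination",
    "GroundTruth",
    "LungAnatomy",
    "CohortManifest",
    "score_from_fraction",
    "synthesize_pathology",
    "generate_examination",
    "generate_cohort",
    "sample_anatomy",
]

# array-axis -> world-axis permutations; world axes are (X=left-right,
# Y=anterior-posterior, Z=inferior-superior).  Coronal slices stack along Y,
# axial slices along Z; both are (slice, row, col) with row/col = in-plane.
_CORONAL_DIRECTION = (0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0, 1.0, 0.0)
_AXIAL_DIRECTION = (0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0)

_TISSUE_INTENSITY = 0.35
_LUNG_INTENSITY = 0.08
_VESSEL_INTENSITY = 0.45
_MUCUS_INTENSITY = 1.0
_WALL_INTENSITY = 0.85


@dataclass
class PhantomConfig:
    """Conditions of a synthetic cohort.

    ``grid_shape``/``coronal_spacing`` define the coronal acquisition grid;
    the axial grid is derived to cover the same physical field of view at
    ``axial_spacing``.  The two spacings are anisotropic in opposite ways
    (each view is fine in-plane, coarse through-plane) so the cross-view
    resampling step is a real geometric operation.  ``score_marginals`` maps
    pathology -> (6 lobes x 3 scores) probabilities; the default is the
    reference cohort's per-lobe score distribution.
    """

    n_patients: int = 10
    exams_per_patient: tuple[int, int] = (1, 4)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    coronal_spacing: tuple[float, float, float] = (3.0, 1.5, 1.5)
    axial_spacing: tuple[float, float, float] = (5.0, 1.2, 1.2)
    score_marginals: dict[str, np.ndarray] = field(default_factory=default_score_marginals)
    bias_field_amplitude: float = 0.3
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.exams_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("exams_per_patient must be an increasing range >= 1")
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 per axis")
        for sp in (self.coronal_spacing, self.axial_spacing):
            if any(s <= 0 for s in sp):
                raise ValueError("spacings must be positive")
        if self.bias_field_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("bias_field_amplitude and noise_sigma must be >= 0")
        for pathology in PATHOLOGIES:
            if pathology not in self.score_marginals:
                raise ValueError(f"score_marginals missing pathology {pathology!r}")
            m = np.asarray(self.score_marginals[pathology], dtype=float)
            if m.shape != (6, 3):
                raise ValueError(f"score_marginals[{pathology!r}] must be 6x3")
            if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(
                    f"score_marginals[{pathology!r}] rows must be distributions"
                )
            self.score_marginals[pathology] = m

    @property
    def fov_mm(self) -> np.ndarray:
        """Physical field of view per world axis (X, Y, Z)."""
        shp, sp = self.grid_shape, self.coronal_spacing
        # coronal axes (slice,row,col) lie along world (Y, Z, X)
        return np.array([shp[2] * sp[2], shp[0] * sp[0], shp[1] * sp[1]])

    def coronal_geometry(self) -> ViewGeometry:
        sp = self.coronal_spacing
        # half-voxel origin so voxel centres tile [0, fov]
        origin = (sp[2] / 2, sp[0] / 2, sp[1] / 2)  # world (X, Y, Z)
        return ViewGeometry(origin=origin, spacing=sp, direction=_CORONAL_DIRECTION)

    def axial_geometry_and_shape(self) -> tuple[ViewGeometry, tuple[int, int, int]]:
        sp = self.axial_spacing
        fov = self.fov_mm
        # axial axes (slice,row,col) lie along world (Z, Y, X)
        shape = (
            max(int(np.ceil(fov[2] / sp[0])), 1),
            max(int(np.ceil(fov[1] / sp[1])), 1),
            max(int(np.ceil(fov[0] / sp[2])), 1),
        )
        origin = (sp[2] / 2, sp[1] / 2, sp[0] / 2)
        geom = ViewGeometry(origin=origin, spacing=sp, direction=_AXIAL_DIRECTION)
        return geom, shape


@dataclass
class LungAnatomy:
    """Analytic lung-half geometry of one patient, in mm world space.

    ``centers``/``semi_axes`` are (2, 3) arrays (rows: left, right half);
    ``plane_normals``/``plane_offsets`` define, per half, the two oblique
    planes carving the three lobar regions.
    """

    centers: np.ndarray
    semi_axes: np.ndarray
    plane_normals: np.ndarray  # (2, 2, 3) unit normals
    plane_offsets: np.ndarray  # (2, 2) signed mm offsets from the half centre

    def translated(self, shift_mm: np.ndarray) -> "LungAnatomy":
        return LungAnatomy(
            centers=self.centers + np.asarray(shift_mm),
            semi_axes=self.semi_axes.copy(),
            plane_normals=self.plane_normals.copy(),
            plane_offsets=self.plane_offsets.copy(),
        )

    def half_mask(self, geom: ViewGeometry, shape: tuple[int, int, int]) -> np.ndarray:
        """Label volume {0=background, 1=left, 2=right} on the given grid."""
        pts = geom.grid_physical(shape)
        out = np.zeros(shape, dtype=np.uint8)
        for h in range(2):
            rel = (pts - self.centers[h]) / self.semi_axes[h]
            inside = np.einsum("...i,...i->...", rel, rel) <= 1.0
            out[inside] = h + 1
        return out

    def lobe_map(self, geom: ViewGeometry, shape: tuple[int, int, int]) -> np.ndarray:
        """Label volume {0, 1..6} partitioning each half into 3 lobar regions."""
        pts = geom.grid_physical(shape)
        half = self.half_mask(geom, shape)
        out = np.zeros(shape, dtype=np.uint8)
        for h in range(2):
            inside = half == h + 1
            rel = pts - self.centers[h]
            s1 = np.einsum("...i,i->...", rel, self.plane_normals[h, 0])
            s2 = np.einsum("...i,i->...", rel, self.plane_normals[h, 1])
            base = 3 * h
            upper = inside & (s1 >= self.plane_offsets[h, 0])
            middle = inside & ~upper & (s2 >= self.plane_offsets[h, 1])
            lower = inside & ~upper & ~middle
            out[upper] = base + 1
            out[middle] = base + 2
            out[lower] = base + 3
        return out


@dataclass
class Examination:
    """One synthetic dual-view acquisition."""

    patient_id: str
    exam_id: str
    coronal_volume: np.ndarray
    axial_volume: np.ndarray
    coronal_geometry: ViewGeometry
    axial_geometry: ViewGeometry
    lung_half_mask_coronal: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coronal_volume)):
            raise ValueError("coronal volume contains non-finite values")
        if not np.all(np.isfinite(self.axial_volume)):
            raise ValueError("axial volume contains non-finite values")
        if self.lung_half_mask_coronal.shape != self.coronal_volume.shape:
            raise ValueError("lung-half mask shape must equal coronal volume shape")


@dataclass
class GroundTruth:
    """Phantom ground truth accompanying one examination.

    ``scores[p][j]`` and ``coverage_fractions[p][j]`` are indexed by lobe in
    :data:`lobescore._tables.LOBE_NAMES` order.  ``lung_half_mask_axial`` is
    the analytically rendered axial half mask, available because the phantom
    anatomy is known in world space; it serves as the reference when testing
    cross-view mask resampling.
    """

    lobe_map_coronal: np.ndarray
    pathology_masks: dict[str, np.ndarray]
    scores: dict[str, np.ndarray]
    coverage_fractions: dict[str, np.ndarray]
    lung_half_mask_axial: np.ndarray


def score_from_fraction(f: float) -> int:
    """Ordinal severity from the affected-volume fraction of a lobe.

    0 = absent, 1 = under half the lobe affected, 2 = at least half.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"coverage fraction must be in [0, 1], got {f}")
    if f == 0.0:
        return 0
    return 2 if f >= 0.5 else 1


def _target_voxel_count(n_lobe: int, target_score: int, rng: np.random.Generator) -> int:
    """Pathology voxel count whose fraction maps back to ``target_score``.

    Severity classes are kept well separated by construction: moderate
    lobes cover 15-40% of the lobe (clearly present, clearly under half),
    severe lobes 55-75% (clearly over half).  Fractions abutting the 0 or
    0.5 decision boundaries would make the ordinal classes visually
    ambiguous, which is a property of reader disagreement, not of the
    planted ground truth this phantom represents.
    """
    if target_score == 1:
        hi = int(np.ceil(n_lobe / 2)) - 1  # strictly under half
        if hi < 1:
            raise ValueError(
                f"cannot plant score-1 pathology in a {n_lobe}-voxel lobe"
            )
        count = int(round(rng.uniform(0.15, 0.40) * n_lobe))
        return int(np.clip(count, 1, hi))
    # score 2: at least half
    lo = int(np.ceil(n_lobe / 2))
    count = int(round(rng.uniform(0.55, 0.75) * n_lobe))
    return int(np.clip(count, lo, n_lobe))


def _blob_mask(lobe_region: np.ndarray, count: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly ``count`` lobe voxels nearest to 1-3 random seeds (filled blobs)."""
    lobe_idx = np.flatnonzero(lobe_region)
    n_seeds = int(rng.integers(1, 4))
    seeds = rng.choice(lobe_idx, size=min(n_seeds, lobe_idx.size), replace=False)
    seed_mask = np.ones(lobe_region.shape, dtype=bool)
    seed_mask.flat[seeds] = False
    dist = ndimage.distance_transform_edt(seed_mask)
    d = dist.flat[lobe_idx]
    order = np.lexsort((lobe_idx, d))  # deterministic tie-break by index
    chosen = lobe_idx[order[:count]]
    out = np.zeros(lobe_region.shape, dtype=bool)
    out.flat[chosen] = True
    return out


def _tube_voxels(
    lobe_region: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    """Centerline of one random branching walk inside the lobe."""
    lobe_idx = np.argwhere(lobe_region)
    start = lobe_idx[rng.integers(len(lobe_idx))]
    stack = [(start.astype(float), _random_unit(rng), 0)]
    pts: list[tuple[int, int, int]] = []
    while stack:
        pos, direction, depth = stack.pop()
        for _ in range(int(rng.integers(10, 30))):
            v = np.round(pos).astype(int)
            if np.any(v < 0) or np.any(v >= np.array(lobe_region.shape)):
                break
            if not lobe_region[tuple(v)]:
                break
            pts.append(tuple(v))
            if depth < 2 and rng.random() < 0.08:
                stack.append((pos.copy(), _random_unit(rng), depth + 1))
            direction = direction + 0.4 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction) + 1e-12
            pos = pos + direction
    return pts


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / (np.linalg.norm(v) + 1e-12)


def _wall_ring(center_mask: np.ndarray) -> np.ndarray:
    """Bright-wall ring of a tube: a one-voxel shell around the lumen."""
    ball1 = ndimage.generate_binary_structure(3, 3)
    lumen = ndimage.binary_dilation(center_mask, structure=ball1)
    outer = ndimage.binary_dilation(lumen, structure=ball1)
    return outer & ~center_mask


def synthesize_pathology(
    lobe_region: np.ndarray,
    target_score: int,
    kind: str,
    rng: np.random.Generator,
    max_retries: int = 200,
) -> tuple[np.ndarray, float]:
    """Plant a bright pathology inside one lobar region.

    ``kind='mucus'`` produces filled blobs; ``kind='bronchiectasis_wall'``
    produces branching tubular structures with bright wall rings.  The
    achieved coverage fraction of the lobe maps back to ``target_score``
    under :func:`score_from_fraction`, and pathology voxels never leave the
    lobe.  Returns ``(mask, achieved_fraction)``.
    """
    if kind not in PATHOLOGIES:
        raise ValueError(f"unknown pathology kind {kind!r}")
    if target_score not in (0, 1, 2):
        raise ValueError(f"target_score must be 0, 1 or 2, got {target_score}")
    lobe_region = np.asarray(lobe_region, dtype=bool)
    n_lobe = int(lobe_region.sum())
    if n_lobe == 0:
        raise ValueError("lobe_region is empty")
    if target_score == 0:
        return np.zeros(lobe_region.shape, dtype=bool), 0.0

    count = _target_voxel_count(n_lobe, target_score, rng)

    if kind == "mucus":
        mask = _blob_mask(lobe_region, count, rng)
        return mask, mask.sum() / n_lobe

    # bronchiectasis/wall thickening: accumulate wall rings in addition order,
    # then cut at the exact voxel count so the score band is guaranteed.
    ordered: list[int] = []
    seen = np.zeros(lobe_region.shape, dtype=bool)
    retries = 0
    while len(ordered) < count and retries < max_retries:
        retries += 1
        center = np.zeros(lobe_region.shape, dtype=bool)
        for v in _tube_voxels(lobe_region, rng):
            center[v] = True
        ring = _wall_ring(center) & lobe_region & ~seen
        new = np.flatnonzero(ring)
        seen.flat[new] = True
        ordered.extend(new.tolist())
    if len(ordered) < count:
        # dense lobes: grow the accumulated set by shells until enough voxels
        while len(ordered) < count:
            grown = ndimage.binary_dilation(seen) & lobe_region & ~seen
            new = np.flatnonzero(grown)
            if new.size == 0:
                raise RuntimeError(
                    f"could not reach score {target_score} coverage in a "
                    f"{n_lobe}-voxel lobe after {max_retries} tube attempts"
                )
            seen.flat[new] = True
            ordered.extend(new.tolist())
    mask = np.zeros(lobe_region.shape, dtype=bool)
    mask.flat[np.array(ordered[:count])] = True
    return mask, mask.sum() / n_lobe


def _vessel_mask(half_region: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Branching vascular tree inside one lung half.

    Pulmonary vessels are the bright structures every lung shows on
    T2-weighted MRI even without pathology; they anchor the per-stack
    intensity rescaling so a healthy lobe does not degenerate into a
    noise-stretched crop.
    """
    n_lung = int(half_region.sum())
    target = rng.uniform(0.03, 0.06)  # visible vascular volume fraction
    centers = np.zeros(half_region.shape, dtype=bool)
    struct = ndimage.generate_binary_structure(3, 1)  # thin, 6-connected
    vessels = np.zeros_like(centers)
    shape = np.array(half_region.shape)
    lobe_idx = np.argwhere(half_region)
    for _ in range(60):
        # one short unbranched segment at a time for fine-grained control
        pos = lobe_idx[rng.integers(len(lobe_idx))].astype(float)
        direction = _random_unit(rng)
        for _ in range(int(rng.integers(5, 12))):
            v = np.round(pos).astype(int)
            if np.any(v < 0) or np.any(v >= shape) or not half_region[tuple(v)]:
                break
            centers[tuple(v)] = True
            direction = direction + 0.3 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction) + 1e-12
            pos = pos + direction
        vessels = ndimage.binary_dilation(centers, structure=struct) & half_region
        if vessels.sum() >= target * n_lung:
            break
    return vessels


def sample_anatomy(rng: np.random.Generator, fov_mm: np.ndarray) -> LungAnatomy:
    """Draw one patient's lung geometry, scaled to the field of view."""
    fov = np.asarray(fov_mm, dtype=float)
    centers = np.array([[0.32, 0.50, 0.52], [0.68, 0.50, 0.52]]) * fov
    centers += rng.uniform(-0.015, 0.015, size=(2, 3)) * fov
    semi = np.array([[0.14, 0.30, 0.34], [0.15, 0.32, 0.36]]) * fov
    semi *= rng.uniform(0.92, 1.08, size=(2, 3))
    normals = np.empty((2, 2, 3))
    offsets = np.empty((2, 2))
    for h in range(2):
        n1 = np.array([rng.uniform(-0.2, 0.2), 0.2, 1.0])
        n2 = np.array([rng.uniform(-0.2, 0.2), 0.45, 0.9])
        normals[h, 0] = n1 / np.linalg.norm(n1)
        normals[h, 1] = n2 / np.linalg.norm(n2)
        a_z = semi[h, 2]
        offsets[h, 0] = 0.22 * a_z * rng.uniform(0.9, 1.1)
        offsets[h, 1] = -0.18 * a_z * rng.uniform(0.9, 1.1)
    return LungAnatomy(centers, semi, normals, offsets)


def _smooth_bias_field(
    shape: tuple[int, ...], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Exponentiated low-order random field (what N4-style correction removes).

    Blurred at ~1/3 of the field of view per axis: coil inhomogeneity is
    smooth at the FOV scale, clearly smoother than the anatomy, which is
    the premise every homomorphic/N4-style corrector rests on.
    """
    g = rng.standard_normal(shape)
    g = ndimage.gaussian_filter(g, sigma=[max(s / 3, 2.0) for s in shape])
    g = (g - g.mean()) / (g.std() + 1e-12)
    return np.exp(amplitude * g)


def _rician(volume: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: |v + n1 + i n2| with n ~ N(0, sigma)."""
    n1 = rng.normal(0.0, sigma, volume.shape)
    n2 = rng.normal(0.0, sigma, volume.shape)
    return np.sqrt((volume + n1) ** 2 + n2**2)


def _resample_to(
    volume: np.ndarray,
    src: ViewGeometry,
    dst: ViewGeometry,
    dst_shape: tuple[int, int, int],
    interpolator=sitk.sitkLinear,
    default_value: float = 0.0,
) -> np.ndarray:
    img = to_sitk(volume.astype(np.float32), src)
    ref = to_sitk(np.zeros(dst_shape, dtype=np.float32), dst)
    out = sitk.Resample(img, ref, sitk.Transform(), interpolator, default_value)
    return sitk.GetArrayFromImage(out)


def generate_examination(
    config: PhantomConfig,
    patient_id: str,
    exam_id: str,
    rng: np.random.Generator,
    anatomy: LungAnatomy | None = None,
) -> tuple[Examination, GroundTruth]:
    """Build one dual-view examination with full ground truth.

    ``anatomy`` fixes the patient geometry across repeated examinations; when
    omitted it is drawn from ``rng``.  The exam applies a small rigid shift
    (repositioning between scans), samples per-lobe scores from the
    configured marginals, plants pathologies, renders the coronal grid,
    resamples it into the axial grid, and degrades each view independently
    with a multiplicative bias field and Rician noise.
    """
    if anatomy is None:
        anatomy = sample_anatomy(rng, config.fov_mm)
    shift = np.clip(rng.normal(0.0, 1.0, 3), -3.0, 3.0)
    anat = anatomy.translated(shift)

    cor_geom = config.coronal_geometry()
    cor_shape = tuple(config.grid_shape)
    ax_geom, ax_shape = config.axial_geometry_and_shape()

    half_cor = anat.half_mask(cor_geom, cor_shape)
    lobe_map = anat.lobe_map(cor_geom, cor_shape)
    half_ax = anat.half_mask(ax_geom, ax_shape)

    lobe_sizes = np.array([(lobe_map == lab).sum() for lab in range(1, 7)])
    if np.any(lobe_sizes == 0):
        missing = [LOBE_NAMES[i] for i in np.flatnonzero(lobe_sizes == 0)]
        raise RuntimeError(f"degenerate anatomy: empty lobes {missing}")

    scores: dict[str, np.ndarray] = {}
    fractions: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for pathology in PATHOLOGIES:
        marg = config.score_marginals[pathology]
        s = np.array([rng.choice(3, p=marg[j]) for j in range(6)], dtype=int)
        combined = np.zeros(cor_shape, dtype=bool)
        f = np.zeros(6)
        for j in range(6):
            region = lobe_map == j + 1
            m, f[j] = synthesize_pathology(region, int(s[j]), pathology, rng)
            combined |= m
        scores[pathology] = s
        fractions[pathology] = f
        masks[pathology] = combined

    intensity = np.full(cor_shape, _TISSUE_INTENSITY, dtype=np.float32)
    intensity[half_cor > 0] = _LUNG_INTENSITY
    vessels = _vessel_mask(half_cor > 0, rng)
    intensity[vessels] = _VESSEL_INTENSITY
    intensity[masks["bronchiectasis_wall"]] = _WALL_INTENSITY
    intensity[masks["mucus"]] = np.maximum(
        intensity[masks["mucus"]], _MUCUS_INTENSITY
    )

    axial = _resample_to(intensity, cor_geom, ax_geom, ax_shape,
                         default_value=_TISSUE_INTENSITY)
    coronal = intensity.copy()

    for vol in (coronal, axial):
        if config.bias_field_amplitude > 0:
            vol *= _smooth_bias_field(vol.shape, config.bias_field_amplitude, rng)
    if config.noise_sigma > 0:
        coronal = _rician(coronal, config.noise_sigma, rng)
        axial = _rician(axial, config.noise_sigma, rng)

    exam = Examination(
        patient_id=patient_id,
        exam_id=exam_id,
        coronal_volume=coronal.astype(np.float32),
        axial_volume=axial.astype(np.float32),
        coronal_geometry=cor_geom,
        axial_geometry=ax_geom,
        lung_half_mask_coronal=half_cor,
    )
    truth = GroundTruth(
        lobe_map_coronal=lobe_map,
        pathology_masks=masks,
        scores=scores,
        coverage_fractions=fractions,
        lung_half_mask_axial=half_ax,
    )
    return exam, truth


@dataclass
class CohortManifest:
    """In-memory index of a generated cohort."""

    config: PhantomConfig
    patients: dict[str, list[str]]  # patient_id -> exam_ids
    exams: list[tuple[Examination, GroundTruth]]
    scores: pd.DataFrame  # patient_id, exam_id, pathology, lobe, score, fraction


def _scores_table(exams: list[tuple[Examination, GroundTruth]]) -> pd.DataFrame:
    rows = []
    for exam, truth in exams:
        for pathology in PATHOLOGIES:
            for j, lobe in enumerate(LOBE_NAMES):
                rows.append(
                    {
                        "patient_id": exam.patient_id,
                        "exam_id": exam.exam_id,
                        "pathology": pathology,
                        "lobe": lobe,
                        "score": int(truth.scores[pathology][j]),
                        "fraction": float(truth.coverage_fractions[pathology][j]),
                    }
                )
    return pd.DataFrame(rows)


def generate_cohort(
    config: PhantomConfig, out_dir: str | Path | None = None
) -> CohortManifest:
    """Generate a reproducible multi-exam cohort.

    Patients contribute a variable number of repeated examinations of the
    same anatomy (``exams_per_patient`` range).  Randomness fans out from
    ``config.seed`` through per-patient and per-exam substreams, so the
    cohort (including the score CSV written when ``out_dir`` is given) is
    byte-identical across runs with the same configuration.
    """
    ss = np.random.SeedSequence(config.seed)
    patient_seeds = ss.spawn(config.n_patients)
    exams: list[tuple[Examination, GroundTruth]] = []
    patients: dict[str, list[str]] = {}
    for i, pseed in enumerate(patient_seeds):
        pid = f"P{i:03d}"
        prng = np.random.Generator(np.random.PCG64(pseed))
        anatomy = sample_anatomy(prng, config.fov_mm)
        lo, hi = config.exams_per_patient
        n_exams = int(prng.integers(lo, hi + 1))
        exam_seeds = pseed.spawn(n_exams)
        patients[pid] = []
        for e, eseed in enumerate(exam_seeds):
            eid = f"{pid}_E{e:02d}"
            erng = np.random.Generator(np.random.PCG64(eseed))
            exams.append(
                generate_examination(config, pid, eid, erng, anatomy=anatomy)
            )
            patients[pid].append(eid)
    scores = _scores_table(exams)
    manifest = CohortManifest(config=config, patients=patients, exams=exams, scores=scores)
    if out_dir is not None:
        write_cohort(manifest, out_dir)
    return manifest


def write_cohort(manifest: CohortManifest, out_dir: str | Path) -> None:
    """Write per-exam NIfTI volumes/masks, the score CSV and a JSON manifest."""
    import nibabel as nib

    from .geometry import affine_from_geometry

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for exam, truth in manifest.exams:
        d = out / exam.exam_id
        d.mkdir(exist_ok=True)
        cor_aff = affine_from_geometry(exam.coronal_geometry)
        ax_aff = affine_from_geometry(exam.axial_geometry)
        nib.save(nib.Nifti1Image(exam.coronal_volume, cor_aff), d / "coronal.nii.gz")
        nib.save(nib.Nifti1Image(exam.axial_volume, ax_aff), d / "axial.nii.gz")
        nib.save(
            nib.Nifti1Image(exam.lung_half_mask_coronal.astype(np.uint8), cor_aff),
            d / "lung_half_mask_coronal.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(truth.lobe_map_coronal.astype(np.uint8), cor_aff),
            d / "lobe_map_coronal.nii.gz",
        )
        for pathology, mask in truth.pathology_masks.items():
            nib.save(
                nib.Nifti1Image(mask.astype(np.uint8), cor_aff),
                d / f"pathology_{pathology}.nii.gz",
            )
    manifest.scores.to_csv(out / "scores.csv", index=False, float_format="%.8f")
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "seed": manifest.config.seed,
                "n_patients": manifest.config.n_patients,
                "patients": manifest.patients,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
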