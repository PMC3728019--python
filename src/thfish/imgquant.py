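"""Image quantification: from fluorescence stacks to per-cell transcript counts.

The stages mirror a standard smFISH workflow on monolayer cells imaged with a
bright-field reference:

1. :func:`segment_cells` — edge detection on the central bright-field slice,
   marker-guided watershed on the distance transform of the cell boundaries.
2. :func:`detect_spots` — per-slice Laplacian-of-Gaussian enhancement, a global
   threshold, and one spot per 3-D connected supra-threshold region.
3. :func:`select_threshold` — automatic threshold at the widest plateau of the
   spot-count-versus-threshold curve.
4. :func:`assign_spots` / :func:`quantify_fluorescence` — per-cell counts and
   background-subtracted total fluorescence.
5. :func:`extrapolate_counts` — linear fluorescence calibration for cells whose
   transcript content is too dense to resolve as individual spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import canny
from skimage.morphology import closing, disk
from skimage.segmentation import relabel_sequential, watershed

__all__ = [
    "ImageStack",
    "LabelMask",
    "Spot",
    "CellQuant",
    "segment_cells",
    "detect_spots",
    "select_threshold",
    "assign_spots",
    "quantify_fluorescence",
    "extrapolate_counts",
]


@dataclass
class ImageStack:
    """A single-channel 3-D image stack indexed (z, y, x), 0-based.

    Parameters
    ----------
    pixels : ndarray
        Non-negative intensities, shape ``(n_z, n_y, n_x)``.
    pixel_size_um : float
        Lateral pixel size in micrometres.
    z_step_um : float
        Axial distance between optical slices (default 0.4 µm).
    channel : str
        Channel name, e.g. a gene symbol or ``"brightfield"``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    z_step_um: float = 0.4
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 1:
            raise ValueError("pixels must be a 3-D (z, y, x) array with n_z >= 1")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixels must be finite")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")

    @property
    def n_z(self) -> int:
        return self.pixels.shape[0]

    @property
    def central_slice(self) -> np.ndarray:
        """The optical slice at the central plane, index floor(n_z/2)."""
        return self.pixels[self.n_z // 2]


@dataclass
class LabelMask:
    """2-D integer label image: 0 = background, k > 0 = cell k (contiguous)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(1, self.n_cells + 1)

    def areas(self) -> np.ndarray:
        """Pixel area of each labelled cell, in label order."""
        if self.n_cells == 0:
            return np.zeros(0, dtype=int)
        return np.bincount(self.labels.ravel(), minlength=self.n_cells + 1)[1:]

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) centroids in (y, x) pixel coordinates."""
        if self.n_cells == 0:
            return np.zeros((0, 2))
        return np.asarray(ndi.center_of_mass(np.ones_like(self.labels), self.labels, self.cell_ids))


@dataclass
class Spot:
    """A detected mRNA spot at the regional maximum of its connected region."""

    gene: str
    z: int
    y: int
    x: int
    peak_value: float


@dataclass
class CellQuant:
    """Per-cell quantification record."""

    cell_id: int
    counts: dict = field(default_factory=dict)
    total_fluor: dict = field(default_factory=dict)
    centroid_um: tuple = (0.0, 0.0)
    area_px: int = 0


def segment_cells(
    brightfield: ImageStack,
    canny_sigma: float = 2.0,
    min_area_px: int = 100,
    max_area_px: int | None = None,
) -> LabelMask:
    """Segment cells from a bright-field stack.

    Pipeline: Canny edge detection (gradient magnitude with hysteresis) on the
    central slice, morphological closing of the boundaries, centroid markers of
    the enclosed regions, then a marker-guided watershed on the distance
    transform of the boundaries.  Regions outside ``[min_area_px, max_area_px]``
    are discarded (automated replacement for manual curation of
    mis-segmentations) and the survivors relabelled 1..n.

    A blank or constant image yields zero labels without raising.
    """
    img = brightfield.central_slice
    rng_span = float(img.max() - img.min())
    if rng_span == 0:
        return LabelMask(np.zeros(img.shape, dtype=np.int32))
    norm = (img - img.min()) / rng_span

    edges = canny(norm, sigma=canny_sigma)
    boundaries = closing(edges, disk(3)).astype(bool)
    filled = ndi.binary_fill_holes(boundaries)
    interiors = filled & ~boundaries

    seeds, n_seed = ndi.label(interiors)
    if n_seed == 0:
        return LabelMask(np.zeros(img.shape, dtype=np.int32))
    # drop marker specks so noise-born micro-contours do not seed regions
    seed_areas = np.bincount(seeds.ravel())[1:]
    keep = np.flatnonzero(seed_areas >= 20) + 1
    markers = np.zeros(img.shape, dtype=np.int32)
    for new_id, lab in enumerate(keep, start=1):
        cy, cx = ndi.center_of_mass(seeds == lab)
        markers[int(round(cy)), int(round(cx))] = new_id
    if markers.max() == 0:
        return LabelMask(np.zeros(img.shape, dtype=np.int32))

    dist = ndi.distance_transform_edt(~boundaries)
    labels = watershed(-dist, markers, mask=filled)

    areas = np.bincount(labels.ravel(), minlength=labels.max() + 1)
    bad = areas < min_area_px
    if max_area_px is not None:
        bad |= areas > max_area_px
    bad[0] = False
    labels[bad[labels]] = 0
    labels, _, _ = relabel_sequential(labels)
    return LabelMask(labels.astype(np.int32))


def _log_response(stack: np.ndarray, sigma_px: float) -> np.ndarray:
    """Negated per-slice Laplacian-of-Gaussian; bright spots become positive peaks."""
    resp = np.empty_like(stack, dtype=np.float64)
    for z in range(stack.shape[0]):
        resp[z] = -ndi.gaussian_laplace(stack[z].astype(np.float64), sigma_px)
    return resp


def detect_spots(fish: ImageStack, sigma_px: float = 1.5, threshold: float | None = None) -> list[Spot]:
    """Detect diffraction-limited spots in a FISH stack.

    A LoG filter is run over each optical slice; voxels whose (negated)
    response exceeds ``threshold`` form 3-D connected regions (26-connectivity,
    so a spot spanning z-slices counts once), and each region yields one
    :class:`Spot` at its regional response maximum.

    If ``threshold`` is None it is chosen by :func:`select_threshold`.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    resp = _log_response(fish.pixels, sigma_px)
    if threshold is None:
        threshold = _plateau_threshold(resp, image_scale=float(np.abs(fish.pixels).max()))
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = resp > threshold
    labels, n = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return []
    positions = ndi.maximum_position(resp, labels, index=np.arange(1, n + 1))
    return [
        Spot(gene=fish.channel, z=int(z), y=int(y), x=int(x), peak_value=float(resp[z, y, x]))
        for (z, y, x) in positions
    ]


def _count_regions(resp: np.ndarray, threshold: float) -> int:
    _, n = ndi.label(resp > threshold, structure=np.ones((3, 3, 3), dtype=bool))
    return n


def _plateau_threshold(
    resp: np.ndarray,
    n_steps: int = 40,
    span: float = 1e-3,
    rel_tol: float = 0.05,
    image_scale: float | None = None,
) -> float:
    vmax = float(resp.max())
    # a flat image leaves only numerical residue in the LoG response
    blank_floor = 1e-3 * (image_scale if image_scale is not None else 0.0)
    if vmax <= max(blank_floor, 0.0):
        warnings.warn("no positive LoG response; returning sweep midpoint", stacklevel=3)
        return max(vmax, 1e-12) if vmax > 0 else 1.0
    # thresholds below the noise floor only count noise speckle or merged
    # blobs; start the sweep at 3x a robust (MAD) noise scale
    noise_sigma = float(np.median(np.abs(resp - np.median(resp)))) / 0.6745
    lo = max(vmax * span, 3.0 * noise_sigma)
    if lo >= vmax:
        warnings.warn("response does not rise above the noise floor", stacklevel=3)
        return float(np.sqrt(vmax * span * vmax))
    sweep = np.geomspace(lo, vmax, n_steps)
    counts = np.array([_count_regions(resp, t) for t in sweep])

    # widest log-threshold run over which the count is stable (successive
    # changes within rel_tol) and nonzero
    best_width, best_lo, best_hi = -1.0, None, None
    i = 0
    while i < len(sweep):
        j = i
        while (
            j + 1 < len(sweep)
            and counts[j + 1] > 0
            and abs(int(counts[j + 1]) - int(counts[j])) <= rel_tol * max(counts[j], 1)
        ):
            j += 1
        if counts[i] > 0 and j > i:
            width = np.log(sweep[j] / sweep[i])
            if width > best_width:
                best_width, best_lo, best_hi = width, sweep[i], sweep[j]
        i = j + 1
    if best_lo is None:
        warnings.warn("no plateau in spot-count curve; returning sweep midpoint", stacklevel=3)
        return float(np.sqrt(sweep[0] * sweep[-1]))
    return float(np.sqrt(best_lo * best_hi))


def select_threshold(fish: ImageStack, sigma_px: float = 1.5, n_steps: int = 40) -> float:
    """Choose a spot-detection threshold at the widest plateau of the
    spot-count-vs-threshold curve (log-spaced sweep over the LoG response).

    The plateau criterion makes the detected count insensitive to the exact
    threshold and equivariant to global intensity rescaling.  A monotone curve
    with no plateau (e.g. a blank stack) returns the sweep midpoint with a
    warning.
    """
    resp = _log_response(fish.pixels, sigma_px)
    return _plateau_threshold(resp, n_steps=n_steps, image_scale=float(np.abs(fish.pixels).max()))


def assign_spots(spots: list[Spot], mask: LabelMask) -> tuple[pd.DataFrame, int]:
    """Assign each spot to the cell label under its (y, x) position.

    Returns a (cell × gene) count table covering every labelled cell, and the
    number of spots discarded for landing on background (label 0).
    """
    genes = sorted({s.gene for s in spots})
    counts = pd.DataFrame(
        0, index=pd.Index(mask.cell_ids, name="cell_id"), columns=genes, dtype=int
    )
    n_background = 0
    for s in spots:
        lab = int(mask.labels[s.y, s.x])
        if lab == 0:
            n_background += 1
        else:
            counts.loc[lab, s.gene] += 1
    return counts, n_background


def quantify_fluorescence(
    channel: ImageStack, mask: LabelMask, z_mode: str = "central"
) -> dict[int, float]:
    """Background-subtracted total fluorescence per cell.

    With ``z_mode="central"`` the central optical slice is analysed: the mean
    fluorescence per pixel of each cell is computed, the minimum of these means
    is taken as the background, and each cell's total is the sum of
    (pixel − background) over its pixels, clamped at zero.  With
    ``z_mode="sum"`` the same rule is applied to the z-summed stack, giving an
    integrated intensity suitable for calibrating unresolvably dense cells.
    """
    if mask.n_cells == 0:
        return {}
    if z_mode == "central":
        img = channel.central_slice
    elif z_mode == "sum":
        img = channel.pixels.sum(axis=0)
    else:
        raise ValueError(f"unknown z_mode {z_mode!r}")
    ids = mask.cell_ids
    means = np.asarray(ndi.mean(img, mask.labels, index=ids))
    background = means.min()
    sums = np.asarray(ndi.sum_labels(img, mask.labels, index=ids))
    areas = mask.areas()
    totals = np.clip(sums - background * areas, 0.0, None)
    return {int(i): float(t) for i, t in zip(ids, totals)}


def extrapolate_counts(
    counts: np.ndarray,
    fluor: np.ndarray,
    resolvable_max: int = 200,
    min_calibration: int = 5,
) -> tuple[np.ndarray, float]:
    """Extrapolate counts of unresolvably dense cells from total fluorescence.

    Individual transcripts cannot be resolved above ``resolvable_max`` spots
    per cell, so a through-origin least-squares line ``fluor = slope · count``
    is fitted on resolvable cells (0 < count < resolvable_max) and dense cells
    get ``count ← fluor / slope``.  A cell is treated as dense when either its
    detected count or its fluorescence-implied count reaches
    ``resolvable_max`` — in crowded cells spot detection saturates below the
    true count, so fluorescence is the more reliable trigger.  The calibration
    is refit once with fluorescence-implied high expressers removed.

    Returns the updated (float) counts and the fitted slope.
    """
    counts = np.asarray(counts, dtype=float)
    fluor = np.asarray(fluor, dtype=float)
    if counts.shape != fluor.shape:
        raise ValueError("counts and fluor must be aligned")

    def _fit(sel: np.ndarray) -> float:
        denom = float(np.sum(counts[sel] ** 2))
        if denom == 0:
            raise ValueError("degenerate calibration set")
        return float(np.sum(fluor[sel] * counts[sel]) / denom)

    calib = (counts > 0) & (counts < resolvable_max)
    if calib.sum() < min_calibration:
        raise ValueError(
            f"need >= {min_calibration} calibration cells with 0 < count < {resolvable_max}"
        )
    # robust first pass: a saturated dense cell (detected count far below its
    # true content but huge fluorescence) would drag a least-squares slope up
    # and mask itself; the median per-cell ratio is immune to such outliers
    slope = float(np.median(fluor[calib] / counts[calib]))
    if slope <= 0:
        raise ValueError("non-positive calibration slope")
    implied = fluor / slope
    calib2 = calib & (implied < resolvable_max)
    if calib2.sum() >= min_calibration:
        slope = _fit(calib2)
        if slope <= 0:
            raise ValueError("non-positive calibration slope")
        implied = fluor / slope

    out = counts.copy()
    dense = (counts >= resolvable_max) | (implied >= resolvable_max)
    out[dense] = implied[dense]
    return out, slope
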