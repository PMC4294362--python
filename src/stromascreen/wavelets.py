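"""À trous B3-spline wavelet decomposition and spot/large-object detection.

The undecimated ("with holes") wavelet transform smooths the image with a
separable B3-spline kernel [1/16, 1/4, 3/8, 1/4, 1/16] whose taps are
dilated by inserting 2^(i-1)-1 zeros at scale i; the wavelet plane
W_i = A_{i-1} - A_i isolates structure of characteristic size ~2^i px.
Because no decimation takes place the planes sum back to the input
exactly: A_0 = A_J + sum_i W_i.

Spot detection hard-thresholds each selected wavelet plane at k times a
robust noise scale (median absolute deviation / 0.67449) and multiplies
the thresholded planes across scales; structures supported at every
selected scale survive the product while single-scale noise is
suppressed.  Connected components of the positive product within an area
band are the spot candidates — in this assay, the compact bright nuclei
of leukemic blasts.  Nuclei far above the spot area band (the stromal
feeder layer) are picked up separately by thresholding the coarsest
smooth plane.

Boundary handling is mirror reflection throughout.  Thresholds scale
linearly with the image, so detection is invariant to a global positive
rescaling of intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu

#: 1-D B3-spline refinement kernel; sums to 1.
B3_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0

#: Conversion from median absolute deviation to a Gaussian sigma.
MAD_TO_SIGMA = 0.67449

SOURCE_SPOT = "SPOT"
SOURCE_LARGE = "LARGE_OBJECT"


def _dilated_kernel(scale: int) -> np.ndarray:
    """B3 kernel with 2^(scale-1)-1 zeros inserted between taps."""
    step = 2 ** (scale - 1)
    k = np.zeros(4 * step + 1)
    k[::step] = B3_KERNEL
    return k


def _b3_smooth(image: np.ndarray, scale: int) -> np.ndarray:
    k = _dilated_kernel(scale)
    out = ndi.correlate1d(image, k, axis=0, mode="mirror")
    return ndi.correlate1d(out, k, axis=1, mode="mirror")


@dataclass
class WaveletDecomposition:
    """Smooth planes A_0..A_J and wavelet planes W_1..W_J of one image."""

    smooth: list[np.ndarray]
    planes: list[np.ndarray]
    n_scales: int

    def reconstruct(self) -> np.ndarray:
        """A_J + sum of wavelet planes; equals A_0 up to float error."""
        out = self.smooth[-1].copy()
        for w in self.planes:
            out += w
        return out


def atrous_decompose(image: np.ndarray, n_scales: int = 3) -> WaveletDecomposition:
    """Undecimated B3-spline wavelet decomposition of a 2-D image.

    Raises ``ValueError`` for non-2-D input, ``n_scales < 1``, or an
    image smaller than the dilated kernel support at the coarsest scale.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("atrous_decompose expects a 2-D image")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    support = 4 * 2 ** (n_scales - 1) + 1
    if min(image.shape) < support:
        raise ValueError(
            f"image of shape {image.shape} smaller than kernel support {support} "
            f"at scale {n_scales}"
        )
    smooth = [image]
    planes = []
    for s in range(1, n_scales + 1):
        nxt = _b3_smooth(smooth[-1], s)
        planes.append(smooth[-1] - nxt)
        smooth.append(nxt)
    return WaveletDecomposition(smooth, planes, n_scales)


@dataclass(frozen=True)
class DetectionParams:
    """Tuning of the multiscale spot detector and the large-object path.

    ``detection_scales`` selects the wavelet planes entering the
    multiscale product (defaults to {2, 3}, matched to nuclei a few
    pixels across); ``k`` is the threshold in robust sigmas; objects
    above ``max_spot_area_px`` are left to the large-object path.
    """

    n_scales: int = 3
    detection_scales: tuple[int, ...] = (2, 3)
    k: float = 3.0
    min_spot_area_px: int = 4
    max_spot_area_px: int = 250
    border_margin_px: int = 4

    def __post_init__(self) -> None:
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if not self.detection_scales:
            raise ValueError("detection_scales must be non-empty")
        if any(s < 1 or s > self.n_scales for s in self.detection_scales):
            raise ValueError("detection_scales must be a subset of 1..n_scales")
        if self.k <= 0:
            raise ValueError("threshold multiplier k must be positive")
        if not (0 < self.min_spot_area_px < self.max_spot_area_px):
            raise ValueError("need 0 < min_spot_area_px < max_spot_area_px")
        if self.border_margin_px < 0:
            raise ValueError("border_margin_px must be non-negative")


@dataclass
class SpotCandidate:
    """One detected connected pixel region (spot or large object)."""

    object_id: str
    well_id: str | None
    field_index: int
    centroid: tuple[float, float]
    coords: np.ndarray  # (n, 2) int pixel indices, 0-based (row, col)
    area_px: int
    total_intensity: float
    source: str


def robust_sigma(plane: np.ndarray) -> float:
    """MAD-based sigma-equivalent noise scale of a wavelet plane."""
    med = np.median(plane)
    return float(np.median(np.abs(plane - med)) / MAD_TO_SIGMA)


def _candidates_from_labels(
    label_image: np.ndarray,
    image: np.ndarray,
    source: str,
    min_area: int,
    max_area: float,
    border_margin: int,
    well_id: str | None,
    field_index: int,
    id_prefix: str,
) -> list[SpotCandidate]:
    h, w = image.shape
    out = []
    for prop in measure.regionprops(label_image, intensity_image=image):
        area = int(prop.area)
        if area < min_area or area > max_area:
            continue
        total = float(image[prop.coords[:, 0], prop.coords[:, 1]].sum())
        if total > 0:
            cy, cx = prop.centroid_weighted
        else:
            cy, cx = prop.centroid
        if source == SOURCE_SPOT and border_margin > 0:
            if (
                cy < border_margin
                or cx < border_margin
                or cy > h - 1 - border_margin
                or cx > w - 1 - border_margin
            ):
                continue
        out.append(
            SpotCandidate(
                object_id=f"{id_prefix}{len(out):04d}",
                well_id=well_id,
                field_index=field_index,
                centroid=(float(cy), float(cx)),
                coords=prop.coords.copy(),
                area_px=area,
                total_intensity=total,
                source=source,
            )
        )
    return out


def detect_spots(
    image: np.ndarray,
    params: DetectionParams = DetectionParams(),
    well_id: str | None = None,
    field_index: int = 0,
) -> list[SpotCandidate]:
    """Detect compact bright spots by the thresholded multiscale product.

    Each selected wavelet plane is hard-thresholded at ``k`` robust
    sigmas; the pixelwise product of the thresholded planes is taken and
    its positive 8-connected components within the spot area band become
    candidates.  Centroids are intensity-weighted on the input image.
    Deterministic; an empty or blank image yields an empty list.
    """
    image = np.asarray(image, dtype=float)
    dec = atrous_decompose(image, params.n_scales)
    product = np.ones_like(image)
    for s in params.detection_scales:
        w = dec.planes[s - 1]
        sigma = robust_sigma(w)
        product = product * np.where(w > params.k * sigma, w, 0.0)
    labels = measure.label(product > 0, connectivity=2)
    return _candidates_from_labels(
        labels,
        image,
        SOURCE_SPOT,
        params.min_spot_area_px,
        params.max_spot_area_px,
        params.border_margin_px,
        well_id,
        field_index,
        id_prefix="s",
    )


def segment_large_objects(
    image: np.ndarray,
    params: DetectionParams = DetectionParams(),
    spots: list[SpotCandidate] | None = None,
    well_id: str | None = None,
    field_index: int = 0,
) -> list[SpotCandidate]:
    """Segment nuclei far above the spot size band (the stromal path).

    The coarsest smooth plane A_J is thresholded at the larger of the
    Otsu threshold and median + k robust sigmas (the floor prevents Otsu
    from splitting pure background noise); components larger than
    ``max_spot_area_px`` become LARGE_OBJECT candidates.  Pixels already
    claimed by spot candidates are removed first, so spot and
    large-object masks are disjoint.
    """
    image = np.asarray(image, dtype=float)
    dec = atrous_decompose(image, params.n_scales)
    smooth = dec.smooth[-1]
    if smooth.max() == smooth.min():
        return []
    floor = np.median(smooth) + params.k * robust_sigma(smooth)
    threshold = max(float(threshold_otsu(smooth)), floor)
    mask = smooth > threshold
    if spots:
        for cand in spots:
            mask[cand.coords[:, 0], cand.coords[:, 1]] = False
    labels = measure.label(mask, connectivity=2)
    return _candidates_from_labels(
        labels,
        image,
        SOURCE_LARGE,
        params.max_spot_area_px + 1,
        math.inf,
        0,
        well_id,
        field_index,
        id_prefix="L",
    )
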