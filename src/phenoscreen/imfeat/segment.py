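"""Segmentation primitives: illumination correction, thresholding, puncta,
skeletons, object morphometry and marker-positive cell calling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, restoration, segmentation


class ParameterError(ValueError):
    pass


def correct_illumination(image: np.ndarray, sigma: float = 50.0) -> np.ndarray:
    """Divide out a smooth flat-field estimate, preserving the image mean.

    The flat field is a large-kernel Gaussian of the image itself; adequate
    for the slowly varying vignetting this pipeline needs to remove.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    mean = img.mean()
    if mean == 0:
        warnings.warn("constant-zero image: illumination correction skipped")
        return img.copy()
    flat = ndimage.gaussian_filter(img, sigma)
    flat = np.clip(flat, 1e-9 * mean, None)
    out = img / flat
    return out * (mean / out.mean())


def auto_threshold(pixels: np.ndarray) -> float:
    """Otsu threshold with a robust noise floor.

    Emulates per-plate empirical thresholding when fed the pooled per-plate
    pixel sample.  The floor (median + 6 scaled MADs) keeps Otsu from
    splitting pure background noise on object-free images.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size == 0 or np.ptp(pixels) == 0:
        return np.inf
    med = np.median(pixels)
    mad = np.median(np.abs(pixels - med))
    floor = med + 6.0 * 1.4826 * mad
    return float(max(filters.threshold_otsu(pixels), floor))


def segment_channel(
    image: np.ndarray,
    threshold: float | None = None,
    min_size: int = 20,
    plate_sample: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold + connected components + minimum-size filter.

    ``threshold=None`` selects the automatic policy: Otsu on ``plate_sample``
    when given (per-plate mode), else on the image itself.
    """
    img = np.asarray(image, dtype=float)
    if threshold is None:
        threshold = auto_threshold(plate_sample if plate_sample is not None else img)
    mask = img > threshold
    mask = morphology.remove_small_objects(mask, max_size=min_size - 1)
    return measure.label(mask, connectivity=2)


def segment_mitochondria(
    image: np.ndarray,
    ball_radius: int = 15,
    tophat_radius: int = 5,
    min_area: int = 4,
    n_sigma: float = 6.0,
) -> np.ndarray:
    """Detect mitochondrial puncta on a varying background.

    Rolling-ball background subtraction, then a white top-hat with a disc
    structuring element, then a robust threshold (median + n_sigma scaled
    MADs) and a minimum-area filter.
    """
    if tophat_radius < 1 or ball_radius <= tophat_radius:
        raise ParameterError("require ball_radius > tophat_radius >= 1")
    if min_area < 1:
        raise ParameterError("min_area must be >= 1")
    img = np.asarray(image, dtype=float)
    background = restoration.rolling_ball(img, radius=ball_radius)
    flat = img - background
    hat = morphology.white_tophat(flat, morphology.disk(tophat_radius))
    med = np.median(hat)
    mad = np.median(np.abs(hat - med))
    thr = med + n_sigma * 1.4826 * max(mad, 1e-9)
    mask = morphology.remove_small_objects(hat > thr, max_size=min_area - 1)
    return measure.label(mask, connectivity=2)


def skeletonize_neurites(mask: np.ndarray):
    """Skeletonize a binary neurite mask.

    Returns ``(skeleton, branch_points, end_points, total_length)`` where
    branch points are *nodes* (adjacent branch pixels merged into one) and
    total length is the skeleton pixel count.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask), np.zeros((0, 2), int), np.zeros((0, 2), int), 0
    skel = morphology.skeletonize(mask)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    neighbors = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    branch_pix = skel & (neighbors >= 3)
    end_pix = skel & (neighbors == 1)
    # merge 8-connected clusters of branch pixels into single nodes
    lab, n = ndimage.label(branch_pix, structure=np.ones((3, 3)))
    branch_points = (
        np.array(ndimage.center_of_mass(branch_pix, lab, range(1, n + 1)))
        if n
        else np.zeros((0, 2))
    )
    end_points = np.argwhere(end_pix)
    return skel, branch_points, end_points, int(skel.sum())


def build_somata(
    nuclei_labels: np.ndarray, marker_mask: np.ndarray, radius: float = 10.0
) -> np.ndarray:
    """Grow a soma label around each nucleus, constrained by the marker mask.

    Fixed-radius label expansion; soma pixels are the expansion restricted to
    marker-positive pixels, always including the seed nucleus itself.
    """
    expanded = segmentation.expand_labels(nuclei_labels, distance=radius)
    somata = np.where(np.asarray(marker_mask, bool) | (nuclei_labels > 0), expanded, 0)
    return somata


@dataclass
class Morphometry:
    """Per-object shape summaries of a label image."""

    labels: np.ndarray  # object ids
    area: np.ndarray
    perimeter: np.ndarray
    form_factor: np.ndarray
    compactness: np.ndarray
    eccentricity: np.ndarray
    centroids: np.ndarray  # (n, 2)


def morphometry(label_image: np.ndarray) -> Morphometry:
    """Area, perimeter, form factor (4*pi*A/P^2), compactness and eccentricity.

    Compactness is A / (pi * r_max^2) with r_max the largest centroid-to-
    boundary-pixel distance: 1 for a disc, toward 0 for elongated objects.
    """
    props = measure.regionprops(label_image)
    n = len(props)
    out = Morphometry(
        labels=np.zeros(n, int),
        area=np.zeros(n),
        perimeter=np.zeros(n),
        form_factor=np.zeros(n),
        compactness=np.zeros(n),
        eccentricity=np.zeros(n),
        centroids=np.zeros((n, 2)),
    )
    for i, p in enumerate(props):
        area = float(p.area)
        # Crofton estimator: unbiased for discs, does not collapse for
        # 1-px-wide lines the way the marching-squares perimeter does
        perim = max(float(p.perimeter_crofton), 1.0)
        centroid = np.asarray(p.centroid)
        dists = np.linalg.norm(p.coords - centroid, axis=1)
        r_max = float(dists.max()) + 0.5
        out.labels[i] = p.label
        out.area[i] = area
        out.perimeter[i] = perim
        out.form_factor[i] = 4 * np.pi * area / perim**2
        out.compactness[i] = area / (np.pi * r_max**2)
        out.eccentricity[i] = float(p.eccentricity)
        out.centroids[i] = centroid
    return out


def classify_cells(
    marker_means: np.ndarray,
    threshold: float | None = None,
    min_contrast: float = 1.5,
) -> np.ndarray:
    """Positive/negative call per cell from its mean marker intensity.

    With ``threshold=None`` an Otsu threshold is computed on the supplied
    intensities (pool them across the plate for per-plate behaviour).  The
    automatic split is accepted only when the positive/negative mean ratio
    reaches ``min_contrast`` — otherwise the population is considered
    marker-negative throughout (Otsu would happily split pure noise).
    Degenerate inputs (constant or < 2 cells) are all-negative.
    """
    v = np.asarray(marker_means, dtype=float)
    if v.size == 0:
        return np.zeros(0, dtype=bool)
    if threshold is not None:
        return v > threshold
    if v.size < 2 or np.ptp(v) == 0:
        return np.zeros(v.size, dtype=bool)
    flags = v > filters.threshold_otsu(v)
    if flags.all() or not flags.any():
        return flags
    neg_mean = v[~flags].mean()
    if neg_mean <= 0 or v[flags].mean() / neg_mean < min_contrast:
        return np.zeros(v.size, dtype=bool)
    return flags
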