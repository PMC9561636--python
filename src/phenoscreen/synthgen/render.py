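"""Render synthetic multi-channel fluorescence fields with exact ground truth.

Not a microscope simulator: objects are parametric blobs, lines and puncta
with a Gaussian PSF and Poisson photon noise, sufficient for segmentation
round-trip tests.  Images are (row, col)-indexed, origin top-left, 16-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..catalogue import PANEL_CHANNELS


class CapacityError(ValueError):
    """Field too small for the requested object count."""


@dataclass(frozen=True)
class OpticsParams:
    """Rendering parameters for one field."""

    size: int = 256
    background: float = 100.0
    read_noise_sd: float = 2.0
    psf_sigma: float = 0.8
    nucleus_sigma: float = 3.5
    soma_sigma: float = 6.0
    min_nucleus_sep: float = 16.0
    punctum_sigma: float = 1.3
    min_punctum_sep: float = 7.0
    nucleus_level: float = 2500.0
    soma_level: float = 1500.0
    neurite_level: float = 1200.0
    punctum_level: float = 3000.0
    gradient_level: float = 120.0


@dataclass(frozen=True)
class FieldSpec:
    """Requested content of one rendered field."""

    panel: str = "panelA"
    n_nuclei: int = 40
    cell_fraction: float = 0.8  # nuclei with a soma
    th_fraction: float = 0.5  # of cells (panelA/panelLAMP1)
    map2_fraction: float = 0.9  # of cells
    branches_per_cell: int = 2
    neurite_length: float = 40.0
    n_mito_per_cell: int = 4  # panelMito
    intensity_factors: dict = field(default_factory=dict)  # channel -> factor


@dataclass
class FieldTruth:
    """Exact object inventory of a rendered field."""

    nuclei_centers: np.ndarray  # (n, 2) row/col
    cell_index: np.ndarray  # indices into nuclei that carry a soma
    th_pos: np.ndarray  # bool per cell
    map2_pos: np.ndarray  # bool per cell
    n_branch_points: int
    mito_centers: np.ndarray  # (m, 2)

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei_centers)

    @property
    def n_mito(self) -> int:
        return len(self.mito_centers)


def _scatter_points(
    rng: np.random.Generator, n: int, size: int, margin: float, min_sep: float,
    near: np.ndarray | None = None, near_sd: float = 0.0,
) -> np.ndarray:
    """Rejection-sample n points with a minimum pairwise separation."""
    if n == 0:
        return np.zeros((0, 2))
    pts: list[np.ndarray] = []
    tries = 0
    max_tries = 2000 * n
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise CapacityError(
                f"cannot place {n} objects with separation {min_sep} in a {size}px field"
            )
        if near is not None and len(near):
            anchor = near[rng.integers(len(near))]
            p = anchor + rng.normal(0, near_sd, 2)
            if not (margin <= p[0] < size - margin and margin <= p[1] < size - margin):
                continue
        else:
            p = rng.uniform(margin, size - margin, 2)
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_sep:
            continue
        pts.append(p)
    return np.array(pts)


def _add_blob(img: np.ndarray, center, sigma: float, amplitude: float) -> None:
    r0, c0 = center
    rad = int(np.ceil(4 * sigma))
    r_lo, r_hi = max(0, int(r0) - rad), min(img.shape[0], int(r0) + rad + 1)
    c_lo, c_hi = max(0, int(c0) - rad), min(img.shape[1], int(c0) + rad + 1)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    img[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)
    )


def _draw_segment(img: np.ndarray, p0, p1, amplitude: float) -> None:
    length = max(int(np.hypot(*(np.asarray(p1) - p0))), 1)
    t = np.linspace(0.0, 1.0, 2 * length + 1)
    rr = np.clip(np.round(p0[0] + t * (p1[0] - p0[0])).astype(int), 0, img.shape[0] - 1)
    cc = np.clip(np.round(p0[1] + t * (p1[1] - p0[1])).astype(int), 0, img.shape[1] - 1)
    img[rr, cc] = np.maximum(img[rr, cc], amplitude)


def _draw_tree(
    imgs: list[np.ndarray], rng: np.random.Generator, root, n_branches: int,
    length: float, amplitude: float,
) -> int:
    """Piecewise-linear neurite tree; returns the number of branch nodes."""
    theta = rng.uniform(0, 2 * np.pi)
    tip = np.asarray(root) + length * np.array([np.sin(theta), np.cos(theta)])
    segments = [(np.asarray(root, float), tip)]
    for _ in range(n_branches):
        p0, p1 = segments[rng.integers(len(segments))]
        t = rng.uniform(0.35, 0.75)
        node = p0 + t * (p1 - p0)
        base = np.arctan2(p1[0] - p0[0], p1[1] - p0[1])
        ang = base + rng.choice([-1, 1]) * rng.uniform(0.7, 1.2)
        new_tip = node + length * rng.uniform(0.5, 0.9) * np.array([np.sin(ang), np.cos(ang)])
        segments.append((node, new_tip))
    for img in imgs:
        for p0, p1 in segments:
            _draw_segment(img, p0, p1, amplitude)
    return len(segments) - 1


def render_fields(
    spec: FieldSpec,
    optics: OpticsParams | None = None,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], FieldTruth]:
    """Render one field; returns channel-name -> uint16 image plus the truth."""
    optics = optics or OpticsParams()
    channels = PANEL_CHANNELS[spec.panel]
    if len(channels) < 2:
        raise ValueError("panel must define at least two channels")
    rng = np.random.default_rng(seed)
    size = optics.size
    factors = {ch: float(spec.intensity_factors.get(ch, 1.0)) for ch in channels}
    canvas = {ch: np.zeros((size, size), dtype=float) for ch in channels}

    margin = 3 * optics.nucleus_sigma
    nuclei = _scatter_points(rng, spec.n_nuclei, size, margin, optics.min_nucleus_sep)
    for p in nuclei:
        _add_blob(canvas["hoechst"], p, optics.nucleus_sigma, optics.nucleus_level * factors["hoechst"])

    n_cells = int(round(spec.cell_fraction * len(nuclei)))
    cell_index = rng.choice(len(nuclei), size=n_cells, replace=False) if n_cells else np.array([], int)
    th_pos = rng.random(n_cells) < spec.th_fraction
    map2_pos = rng.random(n_cells) < spec.map2_fraction

    soma_channel = "calcein" if spec.panel == "panelMito" else "map2"
    n_branch_points = 0
    for j, i in enumerate(cell_index):
        p = nuclei[i]
        _add_blob(canvas[soma_channel], p, optics.soma_sigma, optics.soma_level * factors[soma_channel])
        if "asyn" in canvas:
            _add_blob(canvas["asyn"], p, optics.soma_sigma, 0.6 * optics.soma_level * factors["asyn"])
        if "th" in canvas and th_pos[j]:
            _add_blob(canvas["th"], p, optics.soma_sigma, optics.soma_level * factors["th"])
        if "lamp1" in canvas:
            _add_blob(canvas["lamp1"], p, 0.7 * optics.soma_sigma, 0.8 * optics.soma_level * factors["lamp1"])
        if "map2" in canvas and map2_pos[j]:
            targets = [canvas["map2"]]
            if "th" in canvas and th_pos[j]:
                targets.append(canvas["th"])
            n_branch_points += _draw_tree(
                targets, rng, p, spec.branches_per_cell,
                spec.neurite_length, optics.neurite_level * factors["map2"],
            )

    mito = np.zeros((0, 2))
    if spec.panel == "panelMito":
        # smooth diagonal illumination gradient under the puncta
        rr, cc = np.mgrid[0:size, 0:size]
        canvas["tmrm"] += optics.gradient_level * (rr + cc) / (2 * size)
        n_mito = spec.n_mito_per_cell * n_cells
        anchors = nuclei[cell_index] if n_cells else None
        mito = _scatter_points(
            rng, n_mito, size, 3 * optics.punctum_sigma, optics.min_punctum_sep,
            near=anchors, near_sd=2.5 * optics.soma_sigma,
        )
        for p in mito:
            _add_blob(canvas["tmrm"], p, optics.punctum_sigma, optics.punctum_level * factors["tmrm"])

    images: dict[str, np.ndarray] = {}
    for ch in channels:
        img = ndimage.gaussian_filter(canvas[ch], optics.psf_sigma) + optics.background
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
        img += rng.normal(0.0, optics.read_noise_sd, img.shape)
        images[ch] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    truth = FieldTruth(
        nuclei_centers=nuclei,
        cell_index=cell_index,
        th_pos=th_pos,
        map2_pos=map2_pos,
        n_branch_points=n_branch_points,
        mito_centers=mito,
    )
    return images, truth
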