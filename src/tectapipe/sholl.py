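"""Sholl quantification of neuronal arborization from confocal z-stacks.

Pipeline: 3-D median filter -> maximum-intensity z-projection -> binary
threshold (Otsu by default) -> concentric-circle intersection counting in
physical (um) units -> normalization of the summed intersection count by
the number of neurons in the imaged area.  Projection-mode (2-D) Sholl
only; the stacks are dorsal views in which arbors spread laterally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import ConfigError, InputError
from .synthetic import ImageStack

__all__ = [
    "ShollConfig",
    "ShollResult",
    "median_filter_3d",
    "z_project_max",
    "binarize",
    "sholl_intersections",
    "normalized_arbor_score",
    "sholl_pipeline",
    "detect_somata",
]


@dataclass
class ShollConfig:
    """Parameters of the Sholl pipeline.

    median_kernel : odd window per axis for the 3-D median filter.
    threshold : "auto" (Otsu between-class-variance maximization) or a
        fixed intensity value.
    center : "centroid" (intensity centroid of the thresholded projection)
        or an explicit (x, y) pixel coordinate.
    radius_step_um : spacing of the concentric circles (default 2 um).
    max_radius_um : largest circle; None = distance from the center to the
        nearest image edge.
    n_neurons : number of neurons in the imaged area, supplied by the
        caller (soma counting is not automated).
    """

    median_kernel: tuple[int, int, int] = (3, 3, 3)
    threshold: float | str = "auto"
    center: tuple[float, float] | str = "centroid"
    radius_step_um: float = 2.0
    max_radius_um: float | None = None
    n_neurons: int = 1

    def __post_init__(self) -> None:
        if any(k % 2 == 0 or k < 1 for k in self.median_kernel):
            raise ConfigError("median kernel dims must be odd and positive")
        if self.radius_step_um <= 0:
            raise ConfigError("radius_step_um must be positive")
        if self.n_neurons < 1:
            raise InputError("n_neurons must be >= 1")


@dataclass
class ShollResult:
    radii: np.ndarray
    counts: np.ndarray
    n_neurons: int
    center_px: tuple[float, float]

    @property
    def total(self) -> int:
        return int(np.sum(self.counts))

    @property
    def normalized(self) -> float:
        return self.total / self.n_neurons

    def to_dict(self) -> dict:
        return {
            "radii_um": [float(r) for r in self.radii],
            "counts": [int(c) for c in self.counts],
            "total": self.total,
            "n_neurons": self.n_neurons,
            "normalized": self.normalized,
            "center_px": [float(c) for c in self.center_px],
        }


def median_filter_3d(
    stack: ImageStack, kernel: tuple[int, int, int] = (3, 3, 3)
) -> ImageStack:
    """Order-statistic (median) filter; removes isolated single-voxel noise."""
    if any(k % 2 == 0 or k < 1 for k in kernel):
        raise ConfigError("median kernel dims must be odd and positive")
    filtered = ndimage.median_filter(stack.voxels, size=kernel)
    return ImageStack(filtered, stack.pixel_um, stack.z_step_um)


def z_project_max(stack: ImageStack) -> np.ndarray:
    """Maximum-intensity projection along z."""
    if stack.voxels.shape[0] < 1:
        raise InputError("stack has no slices")
    return stack.voxels.max(axis=0)


def binarize(image: np.ndarray, method: float | str = "auto") -> np.ndarray:
    """Threshold a 2-D image to a boolean foreground mask.

    ``method="auto"`` picks the threshold by Otsu's between-class-variance
    maximization on the image histogram; a numeric ``method`` is used as a
    fixed threshold.  Foreground = strictly above threshold.
    """
    image = np.asarray(image)
    if isinstance(method, str):
        if method != "auto":
            raise ConfigError(f"unknown threshold method {method!r}")
        if np.all(image == image.flat[0]):
            raise InputError("constant image: automatic threshold undefined")
        thr = threshold_otsu(image)
    else:
        thr = float(method)
    return image > thr


def sholl_intersections(
    binary: np.ndarray,
    center: tuple[float, float],
    radii: Sequence[float],
    pixel_um: float,
    arc_step_px: float = 0.25,
) -> np.ndarray:
    """Count foreground intersections along concentric circles.

    For each radius (um, converted to pixels via ``pixel_um``) the circle is
    sampled at <= ``arc_step_px`` pixel arc increments and the count is the
    number of maximal contiguous foreground runs along the (circular)
    sampled path — the convention of the standard Sholl plug-in.  Circle
    portions outside the image are treated as background, with a clipping
    warning.
    """
    binary = np.asarray(binary, dtype=bool)
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ConfigError("radii must be non-empty")
    if np.any(np.diff(radii) <= 0) or np.any(radii <= 0):
        raise ConfigError("radii must be strictly increasing and positive")
    cx, cy = float(center[0]), float(center[1])
    h, w = binary.shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise InputError("center lies outside the image")
    counts = np.zeros(radii.size, dtype=int)
    clipped = False
    for i, r_um in enumerate(radii):
        r_px = r_um / pixel_um
        n = max(int(np.ceil(2 * np.pi * r_px / arc_step_px)), 8)
        theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        xs = np.round(cx + r_px * np.cos(theta)).astype(int)
        ys = np.round(cy + r_px * np.sin(theta)).astype(int)
        inside = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        if not inside.all():
            clipped = True
        fg = np.zeros(n, dtype=bool)
        fg[inside] = binary[ys[inside], xs[inside]]
        if not fg.any():
            continue
        if fg.all():
            counts[i] = 1
            continue
        # number of runs on a circular sequence = number of 0->1 transitions
        counts[i] = int(np.sum(fg & ~np.roll(fg, 1)))
    if clipped:
        warnings.warn(
            "some radii extend beyond the image; counts computed on the "
            "in-bounds arc",
            stacklevel=2,
        )
    return counts


def normalized_arbor_score(counts: Sequence[int], n_neurons: int) -> float:
    """Summed intersection count divided by the number of neurons."""
    if n_neurons < 1:
        raise InputError("n_neurons must be >= 1")
    return float(np.sum(counts)) / n_neurons


def _centroid(binary: np.ndarray, image: np.ndarray) -> tuple[float, float]:
    """Intensity centroid of the foreground, (x, y) pixels."""
    weights = np.where(binary, image.astype(float), 0.0)
    total = weights.sum()
    if total == 0:
        h, w = binary.shape
        return (w / 2.0, h / 2.0)
    ys, xs = np.mgrid[0 : binary.shape[0], 0 : binary.shape[1]]
    return (float((xs * weights).sum() / total), float((ys * weights).sum() / total))


def sholl_pipeline(stack: ImageStack, cfg: ShollConfig) -> ShollResult:
    """filter -> project -> binarize -> intersect -> normalize."""
    filtered = median_filter_3d(stack, cfg.median_kernel)
    proj = z_project_max(filtered)
    if np.all(proj == proj.flat[0]) and isinstance(cfg.threshold, str):
        # empty / constant stack: nothing to count
        radii = np.array([cfg.radius_step_um])
        return ShollResult(
            radii=radii,
            counts=np.zeros(1, dtype=int),
            n_neurons=cfg.n_neurons,
            center_px=(proj.shape[1] / 2.0, proj.shape[0] / 2.0),
        )
    binary = binarize(proj, cfg.threshold)
    if cfg.center == "centroid":
        center = _centroid(binary, proj)
    else:
        center = (float(cfg.center[0]), float(cfg.center[1]))
    h, w = binary.shape
    max_r = cfg.max_radius_um
    if max_r is None:
        edge_px = min(center[0], w - 1 - center[0], center[1], h - 1 - center[1])
        max_r = edge_px * stack.pixel_um
    radii = np.arange(cfg.radius_step_um, max_r + 1e-9, cfg.radius_step_um)
    if radii.size == 0:
        radii = np.array([cfg.radius_step_um])
    counts = sholl_intersections(binary, center, radii, stack.pixel_um)
    return ShollResult(
        radii=radii, counts=counts, n_neurons=cfg.n_neurons, center_px=center
    )


def detect_somata(
    binary: np.ndarray, min_area_px: int = 20
) -> int:
    """Advisory soma counter: connected bright blobs above a size threshold.

    This helper is a rough aid only; ``n_neurons`` for normalization should
    come from the experimenter's count.
    """
    labels = cc_label(binary)
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.sum(sizes >= min_area_px))
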