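"""Fluorescence quantification: z-stack projection and ROI intensity ratios.

Confocal z-stacks are reduced by maximum-intensity projection, and the
relative fluorescence of a region of interest (ROI, e.g. the Kenyon-cell
bodies of the mushroom body) is the ratio of the ROI's mean pixel intensity to
the whole-brain mean on the projected image. Masks are supplied (ROIs were
drawn manually in the original workflow); no segmentation is attempted and no
background subtraction is applied unless an explicit constant offset is given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ImageStack",
    "max_project",
    "relative_intensity",
    "load_stack",
    "load_mask",
]


@dataclass
class ImageStack:
    """A z x y x x fluorescence stack with named 2-D boolean masks."""

    voxels: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("stack must be a z x y x x array with z >= 1")
        if (self.voxels < 0).any():
            raise ValueError("fluorescence intensities must be non-negative")
        plane = self.voxels.shape[1:]
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != plane:
                raise ValueError(
                    f"mask {name!r} shape {m.shape} != image plane {plane}"
                )
            if not m.any():
                raise ValueError(f"mask {name!r} has no true pixels")
            self.masks[name] = m


def max_project(stack: ImageStack | np.ndarray) -> np.ndarray:
    """Per-pixel maximum over z."""
    voxels = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack, dtype=float)
    if voxels.ndim != 3 or voxels.shape[0] < 1:
        raise ValueError("max_project expects a non-empty z x y x x stack")
    return voxels.max(axis=0)


def relative_intensity(
    image: np.ndarray,
    roi_mask: np.ndarray,
    reference_mask: np.ndarray,
    background: float = 0.0,
) -> float:
    """Mean intensity in the ROI divided by the mean in the reference mask.

    ``background`` is an optional constant offset subtracted from both means
    before the ratio (default 0: no background correction).
    """
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    ref = np.asarray(reference_mask, dtype=bool)
    if roi.shape != image.shape or ref.shape != image.shape:
        raise ValueError("masks must match the image shape")
    if not roi.any() or not ref.any():
        raise ValueError("masks must contain at least one true pixel")
    ref_mean = image[ref].mean() - background
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    return float((image[roi].mean() - background) / ref_mean)


def load_stack(path) -> np.ndarray:
    """Load a stack from .npz/.npy (array 'stack' or first array), .tif, or
    a CSV holding a single 2-D slice."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".npz":
        with np.load(p) as data:
            key = "stack" if "stack" in data else list(data.keys())[0]
            arr = data[key]
    elif suffix == ".npy":
        arr = np.load(p)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(p)
    elif suffix == ".csv":
        arr = np.loadtxt(p, delimiter=",")
    else:
        raise ValueError(f"unsupported stack format {suffix!r}")
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return arr


def load_mask(path) -> np.ndarray:
    """Load a boolean mask from a PNG (non-zero pixels) or CSV (non-zero)."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".png":
        import imageio.v3 as iio

        img = np.asarray(iio.imread(p))
        if img.ndim == 3:
            img = img[..., :3].max(axis=-1)
        return img > 0
    if suffix == ".csv":
        return np.loadtxt(p, delimiter=",") > 0
    raise ValueError(f"unsupported mask format {suffix!r}")
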