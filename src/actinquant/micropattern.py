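"""Micropattern reference-cell pipeline.

Mirrors the normalisation macro used for crossbow-micropatterned
fibroblasts: Gaussian filtering and automatic thresholding, centring each
cell on the pattern, automatic exclusion of multinucleate / mitotic /
off-pattern cells, translational alignment of channel stacks, and
aggregation of many centred cells into a per-channel frequency map on a
0-255 intensity scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops
from skimage.registration import phase_cross_correlation

from .thresholds import huang_threshold, max_entropy_threshold, median_threshold

__all__ = [
    "CellImageSet",
    "FrequencyMap",
    "NucleusQCParams",
    "preprocess",
    "qc_cell",
    "center_on_pattern",
    "register_stack",
    "build_frequency_map",
]

QC_PASSED = "passed"
QC_MULTI = "excluded_multinucleate"
QC_MITOTIC = "excluded_mitotic"
QC_OFFPATTERN = "excluded_offpattern"


@dataclass
class CellImageSet:
    """Channels of one micropatterned cell, with QC status and the
    centring translation that has been applied to every channel."""

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0
    qc_status: str = QC_PASSED
    centring_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class FrequencyMap:
    """Pixel-wise projection over cells, min-max rescaled to 0-255."""

    channel: str
    map: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


_THRESHOLDS = {
    "huang_dark": huang_threshold,
    "max_entropy": max_entropy_threshold,
    "median": median_threshold,
}


def preprocess(
    image: np.ndarray,
    gaussian_sigma: float = 1.0,
    threshold_method: str = "huang_dark",
    median_size: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-blur then auto-threshold one channel.

    ``median_size`` optionally applies a median pre-filter before the blur
    (the macro's "Median" step).  Returns the filtered image and the binary
    mask of pixels above the automatic threshold ("dark" = dark background,
    bright objects).  ``gaussian_sigma=0`` leaves intensities untouched.
    A constant image has no defined threshold: an empty mask is returned
    with a warning.
    """
    if gaussian_sigma < 0:
        raise ValueError("gaussian_sigma must be >= 0")
    img = np.asarray(image, dtype=float)
    if median_size:
        img = ndi.median_filter(img, size=median_size)
    if gaussian_sigma > 0:
        img = gaussian(img, sigma=gaussian_sigma, preserve_range=True)
    try:
        thresh = _THRESHOLDS[threshold_method]
    except KeyError:
        raise ValueError(f"unknown threshold_method {threshold_method!r}") from None
    if img.max() <= img.min():
        warnings.warn("constant image: threshold undefined, returning empty mask")
        return img, np.zeros(img.shape, dtype=bool)
    t = thresh(img)
    return img, img > t


@dataclass(frozen=True)
class NucleusQCParams:
    """Nucleus-counting parameters for cell QC.

    A mitotic cell is flagged as a single condensed nucleus: area below
    ``mitotic_area_frac`` of the cohort-median nucleus area
    (``reference_area``; skip the check when unknown) with solidity above
    ``mitotic_solidity``.
    """

    min_area: float = 40.0
    mitotic_area_frac: float = 0.5
    mitotic_solidity: float = 0.95
    reference_area: Optional[float] = None
    threshold: Optional[float] = None


def qc_cell(dapi_image: np.ndarray, params: NucleusQCParams = NucleusQCParams()) -> str:
    """Classify a cell from its DAPI channel: exactly one normal nucleus
    passes; zero nuclei, multiple nuclei, or condensed (mitotic) chromatin
    are excluded."""
    img = np.asarray(dapi_image, dtype=float)
    if img.max() <= img.min():
        return QC_OFFPATTERN
    t = params.threshold if params.threshold is not None else threshold_otsu(img)
    lab = label(img > t, connectivity=2)
    regions = [r for r in regionprops(lab) if r.area >= params.min_area]
    if not regions:
        return QC_OFFPATTERN
    if len(regions) >= 2:
        return QC_MULTI
    r = regions[0]
    if (
        params.reference_area is not None
        and r.area < params.mitotic_area_frac * params.reference_area
        and r.solidity > params.mitotic_solidity
    ):
        return QC_MITOTIC
    return QC_PASSED


def _integer_shift(image: np.ndarray, shift_rc: tuple[int, int]) -> np.ndarray:
    return np.roll(np.roll(image, shift_rc[0], axis=0), shift_rc[1], axis=1)


def center_on_pattern(
    cell: CellImageSet,
    pattern_template: np.ndarray,
    channel: Optional[str] = None,
    min_overlap: float = 0.05,
) -> CellImageSet:
    """Translate all channels so the cell sits on the pattern template.

    The integer-pixel translation maximising the cross-correlation between
    the chosen channel (default: sum of channels) and the template is
    applied identically to every channel and recorded as
    ``centring_offset`` (dx, dy).  A cell whose post-shift overlap with the
    template stays below ``min_overlap`` is marked off-pattern.
    Already-centred input yields an offset of (0, 0) within one pixel.
    """
    template = np.asarray(pattern_template, dtype=float)
    if channel is None:
        ref = np.sum([np.asarray(c, float) for c in cell.channels.values()], axis=0)
    else:
        ref = np.asarray(cell.channels[channel], dtype=float)
    if template.shape != ref.shape:
        raise ValueError("template must match image dimensions")
    if ref.max() <= ref.min():
        return replace(cell, qc_status=QC_OFFPATTERN)
    shift, _, _ = phase_cross_correlation(template, ref, normalization=None)
    drow, dcol = int(round(shift[0])), int(round(shift[1]))
    shifted = {k: _integer_shift(np.asarray(v, float), (drow, dcol)) for k, v in cell.channels.items()}
    moved = _integer_shift(ref, (drow, dcol))
    tmask = template > 0.5 * (template.max() + template.min()) if template.max() > template.min() else template > 0
    sig = moved - moved.min()
    inside = sig[tmask].sum() / max(sig.sum(), 1e-12)
    status = cell.qc_status if inside >= min_overlap else QC_OFFPATTERN
    prev = cell.centring_offset
    return CellImageSet(
        channels=shifted,
        pixel_size=cell.pixel_size,
        qc_status=status,
        centring_offset=(prev[0] + dcol, prev[1] + drow),
    )


def register_stack(images: Sequence[np.ndarray]) -> tuple[list[np.ndarray], list[tuple[int, int]]]:
    """Translation-only registration of a stack to its first image.

    Returns the aligned images and the applied (dx, dy) integer shifts.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    ref = np.asarray(images[0], dtype=float)
    aligned = [ref]
    shifts: list[tuple[int, int]] = [(0, 0)]
    for img in images[1:]:
        img = np.asarray(img, dtype=float)
        if img.shape != ref.shape:
            raise ValueError("all images must share dimensions")
        shift, _, _ = phase_cross_correlation(ref, img, normalization=None)
        drow, dcol = int(round(shift[0])), int(round(shift[1]))
        aligned.append(_integer_shift(img, (drow, dcol)))
        shifts.append((dcol, drow))
    return aligned, shifts


def build_frequency_map(
    cells: Sequence[CellImageSet],
    channel: str,
    projection: str = "mean",
) -> FrequencyMap:
    """Project one channel across QC-passed, centred cells and rescale the
    projection to 0-255 integers (the reference-cell frequency map)."""
    if len(cells) == 0:
        raise ValueError("no cells to aggregate")
    bad = [i for i, c in enumerate(cells) if c.qc_status != QC_PASSED]
    if bad:
        raise ValueError(f"cells {bad} have not passed QC")
    stack = np.stack([np.asarray(c.channels[channel], dtype=float) for c in cells])
    if projection == "mean":
        proj = stack.mean(axis=0)
    elif projection == "max":
        proj = stack.max(axis=0)
    else:
        raise ValueError(f"unknown projection {projection!r}")
    lo, hi = proj.min(), proj.max()
    if hi <= lo:
        warnings.warn("flat projection: frequency map is all zeros")
        scaled = np.zeros_like(proj)
    else:
        scaled = (proj - lo) / (hi - lo) * 255.0
    return FrequencyMap(channel=channel, map=np.rint(scaled).astype(np.uint8), n_cells=len(cells))
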