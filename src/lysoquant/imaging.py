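"""Per-cell lysosomal clustering ratio and control-normalised clustering values.

The measurement follows the standard perinuclear-clustering readout for
fixed-cell immunofluorescence: z-stacks are flattened, a background threshold
is applied to the lysosome-marker channel, a circular ROI of radius 2 um is
centred on the MTOC-marker spot, and the clustering ratio is the thresholded
lysosome intensity inside the ROI (intersected with the cell) divided by the
whole-cell thresholded intensity.  Group "clustering values" are those ratios
expressed relative to the control-group mean, so the control group averages
to 1 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

ThresholdMethod = Union[str, tuple[str, float]]  # "otsu" or ("fixed", value)


@dataclass
class FieldImage:
    """Named non-negative intensity grids sharing one shape.

    Channels are 2-D planes or 3-D (z, rows, cols) stacks; ``pixel_size_um``
    converts pixel geometry to physical distances.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    field_id: str = "field"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels of {self.field_id} differ in shape: {shapes}")


@dataclass(frozen=True)
class QuantConfig:
    roi_radius_um: float = 2.0
    projection: str = "max"
    threshold_method: ThresholdMethod = "otsu"
    mtoc_smooth_sigma_um: float = 0.2
    min_cells_per_field: int = 10
    aggregation: str = "per_cell"
    lysosome_channel: str = "lysosome"
    mtoc_channel: str = "mtoc"

    def __post_init__(self) -> None:
        if self.roi_radius_um <= 0:
            raise ValueError("roi_radius_um must be > 0")
        if self.projection not in ("max", "sum"):
            raise ValueError(f"unknown projection {self.projection!r}")
        if self.aggregation not in ("per_cell", "per_field"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class CellQuant:
    field_id: str
    cell_id: int
    mtoc_position: tuple[int, int]
    roi_intensity: float
    cell_intensity: float

    @property
    def ratio(self) -> float:
        return self.roi_intensity / self.cell_intensity


@dataclass
class FieldQuant:
    field_id: str
    cells: list[CellQuant]
    low_cell_count: bool
    skipped: list[tuple[int, str]] = field(default_factory=list)
    threshold_value: float = 0.0


def project_stack(stack: np.ndarray, method: str = "max") -> np.ndarray:
    """Flatten a z-stack to one plane; a 2-D input is returned unchanged."""
    arr = np.asarray(stack)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D plane or 3-D stack, got shape {arr.shape}")
    if method == "max":
        return arr.max(axis=0)
    if method == "sum":
        return arr.sum(axis=0)
    raise ValueError(f"unknown projection method {method!r}")


def otsu_threshold(grid: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold on the histogram of *nonzero* intensities.

    Exhaustively scans the ``nbins`` candidate bin edges maximising the
    between-class variance.  A constant (or empty) nonzero population has no
    background/foreground split; every pixel is kept and a warning is logged.
    """
    values = np.asarray(grid, dtype=float).ravel()
    values = values[values > 0]
    if values.size == 0 or values.min() == values.max():
        logger.warning("otsu: constant image; keeping all pixels as foreground")
        return 0.0
    counts, edges = np.histogram(values, bins=nbins)
    counts = counts.astype(float)
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    mu_cum = np.cumsum(p * centers)
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    k = int(np.argmax(between[:-1]))  # split after bin k
    return float(edges[k + 1])


def apply_threshold(grid: np.ndarray, method: ThresholdMethod = "otsu") -> tuple[np.ndarray, np.ndarray, float]:
    """Zero sub-threshold pixels; return (masked grid, foreground mask, value)."""
    arr = np.asarray(grid, dtype=float)
    if np.any(arr < 0):
        raise ValueError("apply_threshold expects a non-negative grid")
    if method == "otsu":
        value = otsu_threshold(arr)
    elif isinstance(method, tuple) and len(method) == 2 and method[0] == "fixed":
        value = float(method[1])
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    out = np.where(arr >= value, arr, 0.0)
    mask = (arr >= value) & (arr > 0)  # all-zero input -> empty mask
    return out, mask, value


def detect_mtoc(mtoc_channel: np.ndarray, cell_mask: np.ndarray,
                smooth_sigma_px: float = 2.0) -> tuple[int, int]:
    """Locate the MTOC spot inside ``cell_mask``.

    Position of the global maximum of the Gaussian-smoothed channel within
    the mask; ties broken by the smallest (row, col) lexicographically.
    """
    if not np.any(cell_mask):
        raise ValueError("cell_mask is empty")
    if not np.any(np.asarray(mtoc_channel)[cell_mask] > 0):
        raise ValueError("no MTOC signal inside the cell mask")
    smoothed = gaussian_filter(np.asarray(mtoc_channel, dtype=float), smooth_sigma_px) if smooth_sigma_px > 0 else np.asarray(mtoc_channel, dtype=float)
    masked = np.where(cell_mask, smoothed, -np.inf)
    idx = int(np.argmax(masked))  # row-major argmax -> lexicographically smallest tie
    return tuple(int(v) for v in np.unravel_index(idx, masked.shape))


def circular_roi_mask(center: tuple[int, int], radius_um: float, pixel_size_um: float,
                      shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centre lies within ``radius_um`` of ``center``, border-clipped."""
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    r0, c0 = center
    if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
        raise ValueError(f"ROI centre {center} outside image of shape {shape}")
    half = int(np.ceil(radius_um / pixel_size_um))
    mask = np.zeros(shape, dtype=bool)
    rlo, rhi = max(0, r0 - half), min(shape[0], r0 + half + 1)
    clo, chi = max(0, c0 - half), min(shape[1], c0 + half + 1)
    rr = np.arange(rlo, rhi)[:, None]
    cc = np.arange(clo, chi)[None, :]
    # centre-in rule, evaluated in um^2 so physical and oracle comparisons agree
    mask[rlo:rhi, clo:chi] = ((rr - r0) ** 2 + (cc - c0) ** 2) * pixel_size_um**2 <= radius_um**2
    return mask


def _quantify_prepared(field_id: str, cell_id: int, lyso: np.ndarray,
                       mtoc_smoothed: np.ndarray, cell_mask: np.ndarray,
                       pixel_size_um: float, config: QuantConfig) -> CellQuant:
    masked = np.where(cell_mask, mtoc_smoothed, -np.inf)
    if not np.any(np.isfinite(masked) & (masked > 0)):
        raise ValueError("no MTOC signal inside the cell mask")
    pos = tuple(int(v) for v in np.unravel_index(int(np.argmax(masked)), masked.shape))
    cell_intensity = float(lyso[cell_mask].sum())
    if cell_intensity <= 0:
        raise ValueError("zero cell intensity after thresholding")
    roi = circular_roi_mask(pos, config.roi_radius_um, pixel_size_um, lyso.shape)
    roi_intensity = float(lyso[roi & cell_mask].sum())
    return CellQuant(field_id=field_id, cell_id=cell_id, mtoc_position=pos,
                     roi_intensity=roi_intensity, cell_intensity=cell_intensity)


def quantify_cell(field: FieldImage, cell_mask: np.ndarray, config: QuantConfig = QuantConfig(),
                  cell_id: int = 0) -> CellQuant:
    """Clustering ratio for one cell: projection, thresholding, MTOC ROI, sums."""
    lyso = project_stack(field.channels[config.lysosome_channel], config.projection)
    lyso, _, _ = apply_threshold(lyso, config.threshold_method)
    mtoc = project_stack(field.channels[config.mtoc_channel], config.projection)
    sigma_px = config.mtoc_smooth_sigma_um / field.pixel_size_um
    smoothed = gaussian_filter(np.asarray(mtoc, dtype=float), sigma_px) if sigma_px > 0 else np.asarray(mtoc, dtype=float)
    return _quantify_prepared(field.field_id, cell_id, lyso, smoothed, cell_mask,
                              field.pixel_size_um, config)


def masks_from_labels(label_image: np.ndarray) -> dict[int, np.ndarray]:
    """Cell masks from a labelled image (0 = background)."""
    labels = np.unique(label_image)
    return {int(l): label_image == l for l in labels if l != 0}


def quantify_field(field: FieldImage, cell_masks: Mapping[int, np.ndarray],
                   config: QuantConfig = QuantConfig()) -> FieldQuant:
    """One CellQuant per usable cell.

    Cells whose thresholded lysosome intensity is zero, or with no MTOC
    signal, are skipped with a logged reason.  The field is flagged (flag
    only) when fewer than ``min_cells_per_field`` usable cells remain.
    """
    lyso = project_stack(field.channels[config.lysosome_channel], config.projection)
    lyso, _, thr = apply_threshold(lyso, config.threshold_method)
    mtoc = project_stack(field.channels[config.mtoc_channel], config.projection)
    sigma_px = config.mtoc_smooth_sigma_um / field.pixel_size_um
    smoothed = gaussian_filter(np.asarray(mtoc, dtype=float), sigma_px) if sigma_px > 0 else np.asarray(mtoc, dtype=float)

    cells: list[CellQuant] = []
    skipped: list[tuple[int, str]] = []
    for cell_id, mask in cell_masks.items():
        try:
            cells.append(_quantify_prepared(field.field_id, cell_id, lyso, smoothed,
                                            mask, field.pixel_size_um, config))
        except ValueError as exc:
            logger.warning("field %s cell %s skipped: %s", field.field_id, cell_id, exc)
            skipped.append((cell_id, str(exc)))
    low = len(cells) < config.min_cells_per_field
    if low:
        logger.warning("field %s: only %d usable cells (< %d)", field.field_id,
                       len(cells), config.min_cells_per_field)
    return FieldQuant(field_id=field.field_id, cells=cells, low_cell_count=low,
                      skipped=skipped, threshold_value=thr)


def per_field_ratio(cells: Sequence[CellQuant]) -> float:
    """Field-level aggregate: summed ROI intensity over summed cell intensity.

    Equals the intensity-weighted mean of the per-cell ratios.
    """
    if not cells:
        raise ValueError("no cells")
    num = sum(c.roi_intensity for c in cells)
    den = sum(c.cell_intensity for c in cells)
    return num / den


def clustering_values(ratios_by_group: Mapping[str, Sequence[float]],
                      control_label: str) -> dict[str, np.ndarray]:
    """Each observation's ratio divided by the control-group mean ratio.

    The control group's clustering values average to 1 by construction.
    """
    if control_label not in ratios_by_group:
        raise ValueError(f"control group {control_label!r} missing")
    control = np.asarray(ratios_by_group[control_label], dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    cmean = control.mean()
    if cmean == 0:
        raise ValueError("control-group mean ratio is zero")
    return {label: np.asarray(vals, dtype=float) / cmean
            for label, vals in ratios_by_group.items()}
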