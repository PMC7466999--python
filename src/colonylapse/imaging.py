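"""Time-lapse plate-image quantification.

Converts a series of grayscale plate photographs into per-colony,
per-frame summed pixel intensities: Perona-Malik smoothing, half-mode-max
colony segmentation restricted to the central connected component, and a
two-stage multiplicative spatial correction (border rescale + moving-
median surface flattening).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PlateImage",
    "GridSpec",
    "ColonyMeasurement",
    "PlateMeasurementGrid",
    "InvalidGridError",
    "SeriesInconsistencyError",
    "fit_grid",
    "smooth_image",
    "segment_colony",
    "measure_colony",
    "quantify_plate",
    "spatial_correct",
]


class InvalidGridError(ValueError):
    """Grid anchors outside the crop or implied spacing too small."""


class SeriesInconsistencyError(ValueError):
    """Frames of one series disagree on crop dimensions."""


@dataclass(frozen=True)
class PlateImage:
    """One grayscale frame.  frame 1 is t = 0; frames are 5 minutes apart.

    ``crop_rect`` is (row0, row1, col0, col1), half-open, 0-based.
    """

    pixels: np.ndarray
    frame_index: int = 1
    crop_rect: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D raster")
        if np.any(px < 0):
            raise ValueError("pixel values must be nonnegative")
        if self.frame_index < 1:
            raise ValueError("frame_index starts at 1")
        if self.crop_rect is None:
            object.__setattr__(self, "crop_rect", (0, px.shape[0], 0, px.shape[1]))
        r0, r1, c0, c1 = self.crop_rect
        if not (0 <= r0 < r1 <= px.shape[0] and 0 <= c0 < c1 <= px.shape[1]):
            raise ValueError(f"crop_rect {self.crop_rect} outside raster {px.shape}")

    def cropped(self) -> np.ndarray:
        r0, r1, c0, c1 = self.crop_rect
        return self.pixels[r0:r1, c0:c1]


@dataclass(frozen=True)
class GridSpec:
    """Colony grid: bilinear lattice of centers between four corner anchors."""

    n_rows: int
    n_cols: int
    corner_anchors: tuple[tuple[float, float], ...]  # TL, TR, BL, BR in crop coords
    centers: np.ndarray                              # (n_rows, n_cols, 2)
    window_radius: int


@dataclass(frozen=True)
class ColonyMeasurement:
    row: int
    col: int
    area: int
    intensity: float

    def __post_init__(self) -> None:
        if self.area < 0 or self.intensity < 0:
            raise ValueError("area and intensity must be nonnegative")
        if (self.area == 0) != (self.intensity == 0):
            raise ValueError("intensity must be 0 exactly when area is 0")


@dataclass
class PlateMeasurementGrid:
    """Per-frame matrices of summed colony intensities for one plate."""

    plate_id: str
    condition: str
    frames: list[int]
    intensities: list[np.ndarray]     # one (n_rows, n_cols) matrix per frame
    areas: list[np.ndarray]
    corrected: bool = False


def fit_grid(
    image: PlateImage,
    n_rows: int,
    n_cols: int,
    corner_anchors: tuple[tuple[float, float], ...],
    window_radius: int | None = None,
) -> GridSpec:
    """Bilinear colony-center lattice from four corner anchors.

    Anchors are (row, col) in crop coordinates, ordered top-left, top-right,
    bottom-left, bottom-right.  The returned grid is reusable across every
    frame of the series (the camera and plate do not move).
    """
    if n_rows < 1 or n_cols < 1:
        raise InvalidGridError("grid dimensions must be positive")
    if len(corner_anchors) != 4:
        raise InvalidGridError("need exactly 4 corner anchors (TL, TR, BL, BR)")
    crop = image.cropped()
    h, w = crop.shape
    tl, tr, bl, br = (np.asarray(a, dtype=float) for a in corner_anchors)
    for a in (tl, tr, bl, br):
        if not (0 <= a[0] <= h - 1 and 0 <= a[1] <= w - 1):
            raise InvalidGridError(f"anchor {tuple(a)} outside crop {h}x{w}")
    u = np.linspace(0.0, 1.0, n_rows)[:, None, None] if n_rows > 1 else np.zeros((1, 1, 1))
    v = np.linspace(0.0, 1.0, n_cols)[None, :, None] if n_cols > 1 else np.zeros((1, 1, 1))
    centers = ((1 - u) * (1 - v) * tl + (1 - u) * v * tr
               + u * (1 - v) * bl + u * v * br)
    spacings = []
    if n_cols > 1:
        spacings.append(np.linalg.norm(np.diff(centers, axis=1), axis=2).min())
    if n_rows > 1:
        spacings.append(np.linalg.norm(np.diff(centers, axis=0), axis=2).min())
    min_spacing = min(spacings) if spacings else min(h, w)
    if min_spacing < 2.0:
        raise InvalidGridError(f"implied colony spacing {min_spacing:.2f}px < 2px")
    if window_radius is None:
        window_radius = max(1, int(np.floor(min_spacing / 2.0)) - 1)
    if window_radius >= min_spacing / 2.0 + 1:
        raise InvalidGridError("window_radius must be below half the center spacing")
    return GridSpec(n_rows, n_cols, tuple(map(tuple, (tl, tr, bl, br))),
                    centers, int(window_radius))


def smooth_image(image: PlateImage, n_iter: int = 5, conduction_percentile: float = 90.0) -> PlateImage:
    """Perona-Malik anisotropic diffusion (exponential conduction).

    The gradient threshold is the ``conduction_percentile`` of the input's
    neighbor-difference magnitudes, fixed across iterations.  The flux-form
    update with replicated borders conserves the image sum.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    img = image.pixels.copy()
    if n_iter == 0:
        return image
    dn = np.diff(img, axis=0)
    de = np.diff(img, axis=1)
    grads = np.concatenate([np.abs(dn).ravel(), np.abs(de).ravel()])
    grads = grads[grads > 0]  # sparse scenes: scale from actual edges only
    kappa = float(np.percentile(grads, conduction_percentile)) if grads.size else 0.0
    if kappa <= 0:
        return image  # flat image: zero flux everywhere
    lam = 0.25
    for _ in range(n_iter):
        ds = np.diff(img, axis=0)               # I[r+1] - I[r]
        dc = np.diff(img, axis=1)
        flux_s = np.exp(-(ds / kappa) ** 2) * ds
        flux_c = np.exp(-(dc / kappa) ** 2) * dc
        upd = np.zeros_like(img)
        upd[:-1, :] += flux_s
        upd[1:, :] -= flux_s
        upd[:, :-1] += flux_c
        upd[:, 1:] -= flux_c
        img = img + lam * upd
    return PlateImage(np.clip(img, 0.0, None), image.frame_index, image.crop_rect)


def _background_mode(window: np.ndarray) -> float:
    """Mode of the integer-binned intensity histogram."""
    binned = np.floor(window).astype(np.int64)
    counts = np.bincount(binned.ravel() - binned.min())
    return float(np.argmax(counts) + binned.min())


def segment_colony(window: np.ndarray) -> np.ndarray:
    """Half-mode-max segmentation of one colony window.

    Threshold T = background mode + (max - mode)/2; the mask keeps pixels
    above T belonging to the connected component containing (or nearest to)
    the window center.  Flat windows give an empty mask.  Equidistant
    components tie-break to the larger area.
    """
    window = np.asarray(window, dtype=float)
    mode = _background_mode(window)
    wmax = float(window.max())
    if wmax <= mode:
        return np.zeros(window.shape, dtype=bool)
    threshold = mode + (wmax - mode) / 2.0
    above = window > threshold
    if not above.any():
        return np.zeros(window.shape, dtype=bool)
    lab, n = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    center = ((window.shape[0] - 1) // 2, (window.shape[1] - 1) // 2)
    if lab[center] > 0:
        return lab == lab[center]
    # Nearest component to the center; ties go to the larger component.
    best, best_key = 0, None
    yy, xx = np.nonzero(above)
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    for comp in range(1, n + 1):
        sel = lab[yy, xx] == comp
        key = (d2[sel].min(), -int(sel.sum()))
        if best_key is None or key < best_key:
            best, best_key = comp, key
    return lab == best


def measure_colony(window: np.ndarray, mask: np.ndarray, row: int = 0, col: int = 0,
                   background: float = 0.0) -> ColonyMeasurement:
    """Area (pixel count) and summed intensity of the masked colony.

    ``background`` (the window's background level, e.g. its histogram mode)
    is subtracted per member pixel so the reported intensity is the
    colony's own signal, not the pedestal under it.
    """
    window = np.asarray(window, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != window.shape:
        raise ValueError("mask shape must match window shape")
    area = int(mask.sum())
    intensity = float(np.clip(window[mask] - background, 0.0, None).sum()) if area else 0.0
    if intensity == 0.0:
        area = 0
    return ColonyMeasurement(row=row, col=col, area=area, intensity=intensity)


def quantify_plate(
    series: list[PlateImage],
    grid: GridSpec,
    *,
    plate_id: str = "",
    condition: str = "untreated",
    n_iter: int = 5,
) -> PlateMeasurementGrid:
    """Smooth, segment and measure every colony in every frame."""
    if not series:
        raise SeriesInconsistencyError("empty frame series")
    shapes = {img.cropped().shape for img in series}
    if len(shapes) != 1:
        raise SeriesInconsistencyError(f"frames disagree on crop shape: {sorted(shapes)}")
    r = grid.window_radius
    intensities, areas, frames = [], [], []
    for img in sorted(series, key=lambda im: im.frame_index):
        smoothed = smooth_image(PlateImage(img.cropped(), img.frame_index), n_iter=n_iter)
        px = smoothed.pixels
        mat = np.zeros((grid.n_rows, grid.n_cols))
        amat = np.zeros((grid.n_rows, grid.n_cols))
        for i in range(grid.n_rows):
            for j in range(grid.n_cols):
                cy, cx = grid.centers[i, j]
                cy, cx = int(round(cy)), int(round(cx))
                y0, y1 = max(cy - r, 0), min(cy + r + 1, px.shape[0])
                x0, x1 = max(cx - r, 0), min(cx + r + 1, px.shape[1])
                window = px[y0:y1, x0:x1]
                mask = segment_colony(window)
                m = measure_colony(window, mask, i, j,
                                   background=_background_mode(window))
                mat[i, j] = m.intensity
                amat[i, j] = m.area
        intensities.append(mat)
        areas.append(amat)
        frames.append(img.frame_index)
    return PlateMeasurementGrid(plate_id, condition, frames, intensities, areas, corrected=False)


def _moving_median(mat: np.ndarray, size: int = 9) -> np.ndarray:
    """Edge-truncated moving-window median over grid positions."""
    half = size // 2
    padded = np.pad(mat.astype(float), half, mode="constant", constant_values=np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded, (size, size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(win.reshape(*mat.shape, -1), axis=-1)


def spatial_correct(
    grid_values: np.ndarray,
    *,
    border_width: int = 2,
    window: int = 9,
) -> np.ndarray:
    """Two-stage multiplicative spatial correction of a colony-intensity matrix.

    Border stage: the outermost ``border_width`` rows/columns (which overgrow
    from extra nutrient access) are rescaled so their median matches the
    interior median.  Spatial stage: a smooth surface S — the edge-truncated
    ``window`` x ``window`` moving median of the border-adjusted matrix — is
    divided out, normalized to the plate median of S.  A final rescale
    restores the original plate median exactly.
    """
    mat = np.asarray(grid_values, dtype=float)
    if mat.ndim != 2:
        raise ValueError("expected a 2-D intensity matrix")
    if not np.all(np.isfinite(mat)) or np.any(mat < 0):
        raise ValueError("matrix entries must be finite and nonnegative")
    if not mat.any():
        warnings.warn("all-zero plate: spatial correction skipped", stacklevel=2)
        return mat.copy()
    original_median = float(np.median(mat))
    out = mat.copy()
    b = border_width
    if min(mat.shape) > 2 * b:
        border_mask = np.zeros(mat.shape, dtype=bool)
        border_mask[:b, :] = border_mask[-b:, :] = True
        border_mask[:, :b] = border_mask[:, -b:] = True
        border_med = np.median(out[border_mask])
        interior_med = np.median(out[~border_mask])
        if border_med > 0:
            out[border_mask] *= interior_med / border_med
    surface = _moving_median(out, window)
    surface_med = float(np.median(surface))
    factor = np.where(surface > 0, surface_med / np.where(surface > 0, surface, 1.0), 1.0)
    out = out * factor
    out_med = float(np.median(out))
    if out_med > 0:
        out *= original_median / out_med
    return out
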