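"""Rasterising per-channel values into topography-preserving square images.

Scattered electrode values on the projected plane are interpolated with the
Clough-Tocher scheme (C1 piecewise cubic on the Delaunay triangulation) onto a
uniform square grid, giving one H x W image per window and band -- by default a
32 x 32 x 5 stack.  Pixels outside the electrode convex hull take a fill value
(default 0), and images can be min-max standardized to [0, 1].

Image orientation: row 0 is the front of the head (nasion, +y on the projected
plane) and column 0 is the subject's left (-x); i.e. the usual "nose up" scalp
view.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator
from scipy.spatial import Delaunay, QhullError

from .features import DEFeatures
from .montage import Montage

__all__ = ["TopoImages", "render_topomap", "render_image_stack", "minmax_standardize"]


@dataclass
class TopoImages:
    """A stack of square scalp images [n_windows, H, W, n_bands]."""

    images: np.ndarray
    extent: tuple[float, float, float, float]   # (xmin, xmax, ymin, ymax) on the plane
    mask: np.ndarray                            # [H, W] bool, True inside the hull
    bands: tuple[str, ...]
    labels: np.ndarray
    domains: np.ndarray
    fill: float = 0.0
    normalized: str | None = None               # None | per_image_band | per_band_global

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 4:
            raise ValueError("images must be [n_windows, H, W, n_bands]")
        if self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be square (H == W)")
        self.labels = np.asarray(self.labels, dtype=int)
        self.domains = np.asarray(self.domains, dtype=int)

    @property
    def n_windows(self) -> int:
        return self.images.shape[0]

    @property
    def resolution(self) -> int:
        return self.images.shape[1]

    def to_network_input(self) -> np.ndarray:
        """Channel-first view for the CNN: [n_windows, n_bands, H, W]."""
        return np.ascontiguousarray(np.moveaxis(self.images, -1, 1))


def _square_grid(pos2d: np.ndarray, resolution: int, margin: float):
    """Uniform square grid spanning the electrode bounding square (plus a
    relative margin), symmetric about the projection center."""
    half = float(np.max(np.abs(pos2d))) * (1.0 + margin)
    axis = np.linspace(-half, half, resolution)
    # row 0 = front of head = +y; columns run left (-x) to right (+x)
    gx, gy = np.meshgrid(axis, axis[::-1])
    extent = (-half, half, -half, half)
    return gx, gy, extent


def render_topomap(
    values: np.ndarray,
    pos2d: np.ndarray,
    resolution: int = 32,
    fill: float = 0.0,
    margin: float = 0.05,
) -> np.ndarray:
    """Clough-Tocher interpolation of per-channel values onto a square grid.

    `values` may be [n_channels] for a single image or [n_channels, k] to
    render k images sharing the triangulation in one call.  Out-of-hull pixels
    are set to `fill`; there is no extrapolation.
    """
    pos2d = np.asarray(pos2d, dtype=float)
    values = np.asarray(values, dtype=float)
    if pos2d.ndim != 2 or pos2d.shape[1] != 2:
        raise ValueError("pos2d must be [n_channels, 2]")
    if values.shape[0] != pos2d.shape[0]:
        raise ValueError("values and pos2d disagree on n_channels")
    if pos2d.shape[0] < 4:
        raise ValueError("need at least 4 electrodes to interpolate")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    try:
        tri = Delaunay(pos2d)
    except QhullError as err:
        raise ValueError(
            "electrode positions do not span the plane (collinear or duplicated "
            f"points): {err}"
        ) from err
    gx, gy, _ = _square_grid(pos2d, resolution, margin)
    grid_pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = tri.find_simplex(grid_pts) >= 0
    interp = CloughTocher2DInterpolator(tri, values)
    raw = interp(grid_pts)
    flat = np.where(np.isfinite(raw), raw, fill)
    flat[~inside] = fill
    if values.ndim == 1:
        return flat.reshape(resolution, resolution)
    return flat.reshape(resolution, resolution, values.shape[1])


def hull_mask(pos2d: np.ndarray, resolution: int = 32, margin: float = 0.05) -> np.ndarray:
    """Boolean [H, W] mask of grid pixels inside the electrode convex hull."""
    tri = Delaunay(np.asarray(pos2d, dtype=float))
    gx, gy, _ = _square_grid(pos2d, resolution, margin)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return (tri.find_simplex(pts) >= 0).reshape(resolution, resolution)


def render_image_stack(
    features: DEFeatures,
    montage: Montage,
    resolution: int = 32,
    fill: float = 0.0,
    margin: float = 0.05,
) -> TopoImages:
    """Render every window x band DE slice of `features` into images.

    The feature channel order must match the montage channel order
    (case-insensitive); all slices share one triangulation.
    """
    if montage.pos2d is None:
        raise ValueError("montage has no 2D positions; call azimuthal_project first")
    feat_names = [n.lower() for n in features.channel_names]
    mont_names = [n.lower() for n in montage.names]
    if feat_names != mont_names:
        offenders = [
            f"{f!r} vs {m!r} at index {i}"
            for i, (f, m) in enumerate(
                zip(features.channel_names, montage.names))
            if f.lower() != m.lower()
        ] or [f"length {len(feat_names)} vs {len(mont_names)}"]
        raise ValueError("feature/montage channel mismatch: " + "; ".join(offenders))
    n_win, n_ch, n_bands = features.values.shape
    # [n_ch, n_win * n_bands]: one interpolation call for the whole stack
    cols = features.values.transpose(1, 0, 2).reshape(n_ch, n_win * n_bands)
    imgs = render_topomap(cols, montage.pos2d, resolution=resolution, fill=fill, margin=margin)
    images = imgs.reshape(resolution, resolution, n_win, n_bands).transpose(2, 0, 1, 3)
    _, _, extent = _square_grid(montage.pos2d, resolution, margin)
    return TopoImages(
        images=np.ascontiguousarray(images),
        extent=extent,
        mask=hull_mask(montage.pos2d, resolution, margin),
        bands=tuple(b.name for b in features.bands),
        labels=features.labels.copy(),
        domains=features.domains.copy(),
        fill=fill,
    )


def export_png(topo: TopoImages, path, window: int = 0, cmap: str = "viridis") -> None:
    """Write one window's band slices side by side as a PNG (inspection aid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_bands = topo.images.shape[-1]
    fig, axes = plt.subplots(1, n_bands, figsize=(2.2 * n_bands, 2.4))
    for b, ax in enumerate(np.atleast_1d(axes)):
        ax.imshow(topo.images[window, :, :, b], cmap=cmap)
        ax.set_title(topo.bands[b], fontsize=9)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def minmax_standardize(topo: TopoImages, scope: str = "per_image_band") -> TopoImages:
    """Affinely map in-mask values to [0, 1] (min -> 0, max -> 1).

    scope='per_image_band' normalizes each H x W slice independently;
    scope='per_band_global' pools all windows of a band.  A degenerate group
    (max == min) maps to all zeros.  Out-of-hull pixels are reset to the fill
    value afterwards.
    """
    if scope not in ("per_image_band", "per_band_global"):
        raise ValueError(f"unknown scope {scope!r}")
    if not topo.mask.any():
        raise ValueError("empty hull mask: nothing to standardize")
    images = topo.images.copy()
    masked = images[:, topo.mask, :]               # [n_windows, n_in, n_bands]
    if scope == "per_image_band":
        lo = masked.min(axis=1)[:, None, None, :]  # [n_windows, 1, 1, n_bands]
        hi = masked.max(axis=1)[:, None, None, :]
    else:
        lo = masked.min(axis=(0, 1))[None, None, None, :]
        hi = masked.max(axis=(0, 1))[None, None, None, :]
    span = hi - lo
    out = np.where(span > 0, (images - lo) / np.where(span > 0, span, 1.0), 0.0)
    out[:, ~topo.mask, :] = topo.fill
    return replace(topo, images=out, normalized=scope)
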