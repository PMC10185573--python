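"""Pixel-wise chemical images: turn a hyperspectral cube into pH / pO2 maps.

Each pixel's spectrum is pushed through the trained cascade independently —
no spatial coupling or smoothing is introduced — so the image prediction is
exactly the flattened batch prediction reshaped.  Pixels whose predicted pH
falls outside the sensing layer's 5-9 dynamic range are flagged invalid and
exported as NaN in numeric maps / a dedicated sentinel colour in previews.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ChemicalImage", "predict_image", "export_maps", "median_smooth"]


def median_smooth(arr: np.ndarray, size: int = 3) -> np.ndarray:
    """Sliding-window median filter with edge padding (NaN-aware).

    ``size`` must be odd; NaN pixels are ignored inside each window and a
    window of all-NaN stays NaN.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError(f"filter size must be a positive odd integer, got {size}")
    if size == 1:
        return np.asarray(arr, dtype=float).copy()
    arr = np.asarray(arr, dtype=float)
    pad = size // 2
    padded = np.pad(arr, pad, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (size, size))
    flat = windows.reshape(arr.shape[0], arr.shape[1], size * size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        return np.nanmedian(flat, axis=2)


@dataclass
class ChemicalImage:
    """Per-pixel pH map, pO2 map (hPa) and validity mask."""

    ph_map: np.ndarray
    po2_map: np.ndarray
    valid_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ph_map = np.asarray(self.ph_map, dtype=float)
        self.po2_map = np.asarray(self.po2_map, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not (self.ph_map.shape == self.po2_map.shape == self.valid_mask.shape):
            raise ValueError(
                "ph_map, po2_map and valid_mask must share one shape; got "
                f"{self.ph_map.shape}, {self.po2_map.shape}, {self.valid_mask.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.ph_map.shape

    def masked_maps(self) -> tuple[np.ndarray, np.ndarray]:
        """Copies of the maps with invalid pixels set to NaN (the sentinel)."""
        ph = self.ph_map.copy()
        po2 = self.po2_map.copy()
        ph[~self.valid_mask] = np.nan
        po2[~self.valid_mask] = np.nan
        return ph, po2


def predict_image(model, cube, median_filter: int = 0) -> ChemicalImage:
    """Apply a trained cascade to every pixel of a cube.

    Equivalent, bit for bit, to flattening the cube row-major, running
    :func:`optodeml.cascade.predict_samples`, and reshaping.  Optional
    spatial smoothing: ``median_filter`` > 0 applies an odd-sized median
    filter to the predicted maps afterwards (off by default — predictions
    are strictly per pixel; the validity mask is never smoothed).
    """
    from .cascade import predict_samples

    cube_wl = np.asarray(cube.wavelengths, dtype=float)
    model_wl = np.asarray(model.wavelengths, dtype=float)
    if cube_wl.size != model_wl.size or not np.allclose(cube_wl, model_wl):
        raise ValueError(
            "cube wavelength axis does not match the model's: "
            f"cube has {cube_wl.size} bands "
            f"[{cube_wl[0] if cube_wl.size else '-'}..{cube_wl[-1] if cube_wl.size else '-'}], "
            f"model has {model_wl.size} bands "
            f"[{model_wl[0] if model_wl.size else '-'}..{model_wl[-1] if model_wl.size else '-'}]"
        )
    h, w, b = cube.data.shape
    pred = predict_samples(model, cube.data.reshape(h * w, b))
    ph_map = pred.ph.reshape(h, w)
    po2_map = pred.po2_refined.reshape(h, w)
    if median_filter:
        ph_map = median_smooth(ph_map, median_filter)
        po2_map = median_smooth(po2_map, median_filter)
    return ChemicalImage(
        ph_map=ph_map,
        po2_map=po2_map,
        valid_mask=pred.valid.reshape(h, w),
        provenance={
            "model": "optodeml-cascade-v1",
            "cube": dict(cube.metadata),
            "median_filter": int(median_filter),
        },
    )


def export_maps(
    img: ChemicalImage,
    outdir,
    ph_range: tuple[float, float] = (5.0, 9.0),
    o2_range: tuple[float, float] = (0.0, 195.0),
    cmap: str = "viridis",
    invalid_color: str = "magenta",
) -> dict:
    """Export numeric maps and rendered previews.

    Numeric maps are written losslessly as float64 TIFF with invalid pixels
    as NaN; previews are 8-bit PNGs with fixed colourbar limits (recorded in
    ``metadata.json``) and invalid pixels in a dedicated sentinel colour.
    Returns the paths written.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ph_nan, po2_nan = img.masked_maps()
    paths = {
        "ph_tiff": outdir / "ph_map.tif",
        "po2_tiff": outdir / "po2_map.tif",
        "valid_tiff": outdir / "valid_mask.tif",
        "ph_png": outdir / "ph_map.png",
        "po2_png": outdir / "po2_map.png",
        "metadata": outdir / "metadata.json",
    }
    tifffile.imwrite(paths["ph_tiff"], ph_nan)
    tifffile.imwrite(paths["po2_tiff"], po2_nan)
    tifffile.imwrite(paths["valid_tiff"], img.valid_mask.astype(np.uint8))

    for key, arr, (vmin, vmax), label in (
        ("ph_png", ph_nan, ph_range, "pH"),
        ("po2_png", po2_nan, o2_range, "pO2 / hPa"),
    ):
        colormap = matplotlib.colormaps[cmap].copy()
        colormap.set_bad(invalid_color)
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(np.ma.masked_invalid(arr), cmap=colormap, vmin=vmin, vmax=vmax)
        fig.colorbar(im, ax=ax, label=label)
        ax.set_xlabel("column / px")
        ax.set_ylabel("row / px")
        fig.savefig(paths[key], dpi=150, bbox_inches="tight")
        plt.close(fig)

    meta = {
        "ph_range": [float(ph_range[0]), float(ph_range[1])],
        "o2_range_hPa": [float(o2_range[0]), float(o2_range[1])],
        "colormap": cmap,
        "invalid_color": invalid_color,
        "invalid_sentinel_numeric": "NaN",
        "provenance": img.provenance,
    }
    paths["metadata"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in paths.items()}
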