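"""Calibration data preparation: RoI tiling, outlier cleaning, balancing.

A labeled calibration cube is reduced to one sample per 5x5-pixel region of
interest: within each RoI, each band's 25 intensities are cleaned with a
Tukey interquartile-range fence (factor 1.5 by default, applied once per RoI
per band) and the per-band median of the survivors becomes the RoI spectrum.
Calibration campaigns dwell unevenly across (pH, pO2) points, so the table
is then balanced: every group's count is reduced toward the median per-point
count by partitioning oversized groups (in stable stored order) and
averaging each partition into one row.  Finally the table is split randomly
into training and validation subsets (80:20 by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cube_io import CalibrationTable, SpectralCube

__all__ = [
    "RoI",
    "BalanceReport",
    "tile_grid",
    "tile_rois",
    "iqr_clean",
    "roi_median_spectrum",
    "extract_calibration_samples",
    "balance_table",
    "split_table",
]


@dataclass
class RoI:
    """One tile of pixels: origin (row, col), square size, member spectra."""

    row: int
    col: int
    size: int
    pixels: np.ndarray  # (size, size, B)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("RoI size must be >= 1")
        if self.pixels.shape[:2] != (self.size, self.size):
            raise ValueError(
                f"pixel block shape {self.pixels.shape[:2]} does not match "
                f"tile size {self.size}"
            )


@dataclass
class BalanceReport:
    """Per-calibration-point sample counts before and after balancing."""

    before: dict = field(default_factory=dict)
    after: dict = field(default_factory=dict)
    target: int = 0

    def __post_init__(self) -> None:
        for key, n_after in self.after.items():
            n_before = self.before.get(key, 0)
            if n_after > n_before:
                raise ValueError(f"group {key} grew during balancing")
            if n_before > self.target and n_after > self.target:
                raise ValueError(f"reduced group {key} still exceeds the target")

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "before": {str(k): v for k, v in self.before.items()},
            "after": {str(k): v for k, v in self.after.items()},
        }


def tile_grid(
    shape: tuple[int, int],
    region: tuple[int, int, int, int] | None = None,
    tile: int = 5,
) -> list[tuple[int, int]]:
    """Origins of the non-overlapping tiles covering a region's tile-aligned grid.

    ``region`` is (row0, col0, height, width); defaults to the full frame.
    Partial edge tiles are discarded.
    """
    if tile < 1:
        raise ValueError("tile size must be >= 1")
    h, w = shape
    r0, c0, rh, rw = region if region is not None else (0, 0, h, w)
    if r0 < 0 or c0 < 0 or r0 + rh > h or c0 + rw > w:
        raise ValueError(f"region {region} extends outside the {h}x{w} frame")
    n_r, n_c = rh // tile, rw // tile
    if n_r == 0 or n_c == 0:
        raise ValueError(
            f"region of {rh}x{rw} px is smaller than one {tile}x{tile} tile"
        )
    return [
        (r0 + i * tile, c0 + j * tile) for i in range(n_r) for j in range(n_c)
    ]


def tile_rois(
    cube: SpectralCube,
    region: tuple[int, int, int, int] | None = None,
    tile: int = 5,
) -> list[RoI]:
    """Cut a cube (or a sub-rectangle of it) into non-overlapping square RoIs."""
    origins = tile_grid(cube.data.shape[:2], region, tile)
    return [
        RoI(row=r, col=c, size=tile, pixels=cube.data[r : r + tile, c : c + tile, :])
        for r, c in origins
    ]


def iqr_clean(values, factor: float = 1.5) -> np.ndarray:
    """Keep values inside the Tukey fence [Q1 - f*IQR, Q3 + f*IQR].

    Quantiles use linear interpolation between order statistics.  Fewer than
    4 values cannot support a quartile estimate: passed through with a
    warning.  Applied exactly once per sample — the fence always derives
    from the original input.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 4:
        warnings.warn(
            f"iqr_clean needs >= 4 values, got {values.size}; passing through"
        )
        return values.copy()
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    return values[(values >= lo) & (values <= hi)]


def roi_median_spectrum(roi: RoI, factor: float = 1.5) -> np.ndarray:
    """Per-band median of the RoI's IQR-cleaned member pixels.

    Cleaning runs independently per band.  If cleaning ever removed every
    pixel at some band, that band falls back to the uncleaned median with a
    warning (the Tukey fence always contains the inter-quartile half of the
    data, so this is defensive only).
    """
    px = roi.pixels.reshape(-1, roi.pixels.shape[2]).astype(float)  # (n, B)
    n, n_bands = px.shape
    if n == 0:
        raise ValueError("RoI has no pixels")
    if n < 4:
        warnings.warn(
            f"RoI at ({roi.row},{roi.col}) has only {n} pixels; "
            "skipping IQR cleaning"
        )
        return np.median(px, axis=0)
    q1, q3 = np.percentile(px, [25.0, 75.0], axis=0)
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    keep = (px >= lo) & (px <= hi)
    empty = ~keep.any(axis=0)
    if empty.any():
        warnings.warn(
            f"IQR cleaning removed all pixels at {int(empty.sum())} band(s); "
            "falling back to the uncleaned median there"
        )
        keep[:, empty] = True
    masked = np.where(keep, px, np.nan)
    return np.nanmedian(masked, axis=0)


def extract_calibration_samples(
    labeled_cubes,
    region: tuple[int, int, int, int] | None = None,
    tile: int = 5,
    iqr_factor: float = 1.5,
) -> CalibrationTable:
    """Reduce labeled cubes to one calibration row per RoI.

    ``labeled_cubes`` is an iterable of cubes whose metadata carries 'ph'
    and 'po2', or of (cube, ph, po2) tuples.  Row count equals the total
    tile count across cubes.
    """
    spectra, phs, po2s, prov = [], [], [], []
    wavelengths = None
    count = 0
    for item in labeled_cubes:
        if isinstance(item, SpectralCube):
            cube = item
            if "ph" not in cube.metadata or "po2" not in cube.metadata:
                raise ValueError(
                    "unlabeled cube: metadata must carry 'ph' and 'po2' "
                    "(or pass (cube, ph, po2) tuples)"
                )
            ph, po2 = float(cube.metadata["ph"]), float(cube.metadata["po2"])
        else:
            cube, ph, po2 = item
            ph, po2 = float(ph), float(po2)
        if wavelengths is None:
            wavelengths = np.asarray(cube.wavelengths, dtype=float)
        elif not np.array_equal(wavelengths, np.asarray(cube.wavelengths)):
            raise ValueError("all cubes must share one wavelength axis")
        for roi in tile_rois(cube, region, tile):
            spectra.append(roi_median_spectrum(roi, iqr_factor))
            phs.append(ph)
            po2s.append(po2)
            prov.append(f"cube{count}:roi({roi.row},{roi.col})")
        count += 1
    if wavelengths is None:
        raise ValueError("no cubes given")
    return CalibrationTable(
        spectra=np.vstack(spectra),
        wavelengths=wavelengths,
        ph=np.asarray(phs),
        po2=np.asarray(po2s),
        provenance=np.asarray(prov, dtype=object),
    )


def _group_key(ph: float, po2: float) -> tuple[float, float]:
    # Calibration-point identity: pH to 0.1, pO2 to 1 hPa.
    return (round(float(ph), 1), float(round(float(po2))))


def balance_table(
    table: CalibrationTable,
) -> tuple[CalibrationTable, BalanceReport]:
    """Reduce over-represented calibration points to the median group count.

    Groups (calibration points) are keyed by the rounded (pH, pO2) label
    pair.  The target count is the median of per-group counts (floored if
    half-integral).  A group with n > target rows is partitioned, in stable
    stored order, into target chunks of near-equal size; each chunk is
    replaced by its per-band mean spectrum and mean labels.  Groups at or
    below the target pass through unchanged.  Deterministic: no shuffling,
    no seed.
    """
    n = len(table)
    if n == 0:
        raise ValueError("cannot balance an empty table")
    keys = [_group_key(p, o) for p, o in zip(table.ph, table.po2)]
    groups: dict[tuple[float, float], list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)
    before = {k: len(v) for k, v in groups.items()}
    target = int(math.floor(np.median(list(before.values()))))

    spectra, phs, po2s, prov = [], [], [], []
    after = {}
    for key, idx in groups.items():
        if len(idx) <= target:
            for i in idx:
                spectra.append(table.spectra[i])
                phs.append(table.ph[i])
                po2s.append(table.po2[i])
                prov.append(
                    table.provenance[i] if table.provenance is not None else ""
                )
            after[key] = len(idx)
        else:
            chunks = np.array_split(np.asarray(idx), target)
            for j, chunk in enumerate(chunks):
                spectra.append(table.spectra[chunk].mean(axis=0))
                phs.append(table.ph[chunk].mean())
                po2s.append(table.po2[chunk].mean())
                prov.append(f"balanced:pH{key[0]:g}:pO2{key[1]:g}:{j}")
            after[key] = len(chunks)
    report = BalanceReport(before=before, after=after, target=target)
    balanced = CalibrationTable(
        spectra=np.vstack(spectra),
        wavelengths=table.wavelengths,
        ph=np.asarray(phs),
        po2=np.asarray(po2s),
        provenance=np.asarray(prov, dtype=object),
    )
    return balanced, report


def split_table(
    table: CalibrationTable, ratio: float = 0.8, seed: int = 0
) -> tuple[CalibrationTable, CalibrationTable]:
    """Random disjoint train/validation split; |train| = round(ratio * N)."""
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(round(ratio * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    val_idx = np.sort(perm[n_train:])
    return table.subset(train_idx), table.subset(val_idx)
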