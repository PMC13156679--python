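"""MSI preprocessing: TIC normalization, peak picking, alignment, cell pixels.

Turns raw per-pixel spectra into a TIC-normalized, peak-picked, aligned
pixel x feature table, partitions pixels into cell / background by
spatially smoothed k-means, and selects cell-specific peaks with the 5x
signal ratio filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

logger = logging.getLogger(__name__)

__all__ = [
    "MSIDataset",
    "PeakTable",
    "PixelPartition",
    "tic_normalize",
    "estimate_noise",
    "pick_peaks",
    "align_peaks",
    "peak_table_from_dataset",
    "spatial_kmeans",
    "cell_specific_peaks",
    "mean_spectrum",
    "read_imzml",
    "write_imzml",
]


@dataclass
class MSIDataset:
    """Per-pixel mass spectra on a rectangular acquisition grid.

    ``mzs`` and ``intensities`` are parallel lists of per-pixel arrays
    (processed/centroided data may have different axes per pixel; profile
    data shares one axis).  Intensities are non-negative and each m/z axis
    is strictly increasing.
    """

    coords: np.ndarray  # (n, 2) int, 0-based (row, col)
    mzs: list
    intensities: list
    sample_id: str = "S1"
    treatment: str = "CTR"
    pair_id: str = "P1"
    pixel_um: float = 10.0
    grid_shape: tuple[int, int] | None = None
    zero_tic: np.ndarray | None = None  # flagged by tic_normalize
    raw_tic: np.ndarray | None = None  # pre-normalization TIC, kept by tic_normalize

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        if len({tuple(c) for c in self.coords}) != len(self.coords):
            raise ValueError("pixel coordinates must be unique")
        if self.grid_shape is None:
            self.grid_shape = (int(self.coords[:, 0].max()) + 1, int(self.coords[:, 1].max()) + 1)

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def tic(self) -> np.ndarray:
        return np.array([float(np.sum(i)) for i in self.intensities])


@dataclass
class PeakTable:
    """Aligned pixels x features intensity matrix with consensus m/z centers."""

    features: np.ndarray  # (f,) consensus m/z, ascending
    matrix: np.ndarray  # (n, f) intensities
    tic: np.ndarray  # per-pixel raw TIC (before normalization)
    coords: np.ndarray  # (n, 2)
    pixel_um: float = 10.0
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.features) < 0):
            raise ValueError("feature m/z must be sorted ascending")
        if np.any(self.matrix < 0):
            raise ValueError("intensities must be non-negative")
        if self.grid_shape is None and len(self.coords):
            self.grid_shape = (
                int(self.coords[:, 0].max()) + 1,
                int(self.coords[:, 1].max()) + 1,
            )


@dataclass
class PixelPartition:
    """Cell / background pixel labels from spatial k-means."""

    labels: np.ndarray  # (n,) cluster index
    cell_label: int
    coords: np.ndarray
    grid_shape: tuple[int, int]
    pixel_um: float = 10.0

    @property
    def is_cell(self) -> np.ndarray:
        return self.labels == self.cell_label


# ---------------------------------------------------------------------------
# normalization


def tic_normalize(ds: MSIDataset) -> MSIDataset:
    """Scale each spectrum so its total intensity equals the mean raw TIC.

    Targeting the dataset mean (rather than 1) preserves the intensity
    scale, which the downstream 5x cell-specificity ratio relies on.
    Zero-TIC pixels are left at zero and flagged in ``zero_tic``.
    """
    tics = ds.tic()
    nz = tics > 0
    if not nz.any():
        raise ValueError("all-zero dataset: no pixel with TIC > 0")
    target = float(tics.mean())
    scaled = []
    for inten, t in zip(ds.intensities, tics):
        scaled.append(np.asarray(inten, dtype=float) * (target / t) if t > 0 else np.asarray(inten, dtype=float))
    out = replace(ds, intensities=scaled, zero_tic=~nz, raw_tic=tics)
    return out


# ---------------------------------------------------------------------------
# peak picking


def estimate_noise(spectrum: np.ndarray, window: int = 101) -> float:
    """Robust noise scale: 1.4826 x MAD of the median-detrended baseline.

    The spectrum is detrended with a running median (window clipped to the
    spectrum length) so that real peaks and slow baseline drift do not
    inflate the estimate.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size < 16:
        raise ValueError("spectrum too short for noise estimation (need >= 16)")
    w = min(window, 2 * (x.size // 2) - 1)
    if w < 3:
        w = 3
    baseline = ndimage.median_filter(x, size=w, mode="nearest")
    resid = x - baseline
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(1.4826 * mad)


def pick_peaks(
    mz: np.ndarray,
    intensity: np.ndarray,
    snr_min: float = 6.0,
) -> list[tuple[float, float]]:
    """Local maxima above ``snr_min`` x noise, centroided by 3-point parabola.

    Signal-to-noise uses :func:`estimate_noise`; on an exactly flat
    spectrum (noise 0) only strictly positive maxima are reported.
    """
    mz = np.asarray(mz, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if y.size < 3:
        return []
    noise = estimate_noise(y) if y.size >= 16 else float(np.std(y))
    height = snr_min * noise if noise > 0 else np.finfo(float).tiny
    idx, _ = signal.find_peaks(y, height=height)
    peaks = []
    for i in idx:
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            step = (mz[min(i + 1, y.size - 1)] - mz[max(i - 1, 0)]) / 2.0
            center = mz[i] + delta * step
        else:
            center = mz[i]
        peaks.append((float(center), float(y[i])))
    return peaks


# ---------------------------------------------------------------------------
# alignment


def align_peaks(
    peak_lists: list[list[tuple[float, float]]],
    tol_da: float = 0.1,
    min_frac: float = 0.01,
    coords: np.ndarray | None = None,
    tic: np.ndarray | None = None,
    pixel_um: float = 10.0,
    grid_shape: tuple[int, int] | None = None,
) -> PeakTable:
    """Greedy 1-D clustering of pooled peak m/z into consensus features.

    Pooled peaks are sorted by m/z; a new feature opens whenever the gap to
    the previous peak exceeds ``tol_da``.  Per-pixel feature intensity is
    the sum of that pixel's peaks assigned to the feature.  Features seen
    in fewer than ``min_frac`` of pixels are dropped.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be > 0")
    n = len(peak_lists)
    all_mz, all_int, all_pix = [], [], []
    for p, plist in enumerate(peak_lists):
        for m, i in plist:
            all_mz.append(m)
            all_int.append(i)
            all_pix.append(p)
    if coords is None:
        coords = np.stack([np.zeros(n, dtype=int), np.arange(n)], axis=1)
    if tic is None:
        tic = np.array(
            [float(sum(i for _, i in plist)) for plist in peak_lists]
        )
    if not all_mz:
        return PeakTable(
            features=np.empty(0),
            matrix=np.zeros((n, 0)),
            tic=tic,
            coords=coords,
            pixel_um=pixel_um,
            grid_shape=grid_shape,
        )
    all_mz = np.asarray(all_mz)
    all_int = np.asarray(all_int)
    all_pix = np.asarray(all_pix)
    order = np.argsort(all_mz, kind="stable")
    smz = all_mz[order]
    cluster_id = np.concatenate([[0], np.cumsum(np.diff(smz) > tol_da)])
    n_feat = int(cluster_id[-1]) + 1
    centers = np.zeros(n_feat)
    np.add.at(centers, cluster_id, smz)
    counts = np.bincount(cluster_id, minlength=n_feat)
    centers /= counts
    matrix = np.zeros((n, n_feat))
    np.add.at(matrix, (all_pix[order], cluster_id), all_int[order])
    observed = np.zeros((n, n_feat), dtype=bool)
    observed[all_pix[order], cluster_id] = True
    keep = observed.sum(axis=0) >= max(1, math.ceil(min_frac * n))
    return PeakTable(
        features=centers[keep],
        matrix=matrix[:, keep],
        tic=tic,
        coords=np.asarray(coords),
        pixel_um=pixel_um,
        grid_shape=grid_shape,
    )


def peak_table_from_dataset(ds: MSIDataset, tol_da: float = 0.1, min_frac: float = 0.01) -> PeakTable:
    """Align an already-centroided dataset's per-pixel peak lists."""
    raw_tic = ds.raw_tic if ds.raw_tic is not None else ds.tic()
    peak_lists = [list(zip(m, i)) for m, i in zip(ds.mzs, ds.intensities)]
    return align_peaks(
        peak_lists,
        tol_da=tol_da,
        min_frac=min_frac,
        coords=ds.coords,
        tic=raw_tic,
        pixel_um=ds.pixel_um,
        grid_shape=ds.grid_shape,
    )


# ---------------------------------------------------------------------------
# cell-pixel detection


def _neighborhood_means(pt: PeakTable, r_px: float) -> np.ndarray:
    """Gaussian-weighted neighborhood mean of each pixel's feature vector."""
    rows, cols = pt.grid_shape
    n, f = pt.matrix.shape
    grid = np.zeros((rows, cols, f))
    mask = np.zeros((rows, cols))
    grid[pt.coords[:, 0], pt.coords[:, 1]] = pt.matrix
    mask[pt.coords[:, 0], pt.coords[:, 1]] = 1.0
    rad = max(1, int(math.ceil(2 * r_px)))
    offs = np.arange(-rad, rad + 1)
    kernel = np.exp(-(offs[:, None] ** 2 + offs[None, :] ** 2) / (2.0 * r_px**2))
    num = ndimage.convolve(grid, kernel[:, :, None], mode="constant")
    den = ndimage.convolve(mask, kernel, mode="constant")
    sm = num / np.maximum(den, 1e-300)[:, :, None]
    return sm[pt.coords[:, 0], pt.coords[:, 1]]


def spatial_kmeans(
    pt: PeakTable,
    k: int = 2,
    r_px: float = 1.0,
    seed: int = 0,
) -> PixelPartition:
    """Spatially smoothed k-means partition of pixels; cells = high-TIC cluster.

    Each pixel's feature vector is augmented with the Gaussian-weighted
    mean of its neighborhood (radius ``r_px``), approximating spatially
    aware k-means.  Pixels are processed in canonical (row, col) order so
    the partition is invariant to input pixel ordering.  The cell cluster
    is the one with the highest mean raw TIC (ties broken by size).
    """
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("k must be >= 2")
    if pt.matrix.shape[0] < k:
        raise ValueError("fewer pixels than clusters")
    order = np.lexsort((pt.coords[:, 1], pt.coords[:, 0]))
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    smooth = _neighborhood_means(pt, r_px)
    X = np.hstack([pt.matrix, smooth])[order]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels_sorted = km.fit_predict(X)
    labels = labels_sorted[inv]
    mean_tic = np.array(
        [pt.tic[labels == c].mean() if (labels == c).any() else -np.inf for c in range(k)]
    )
    sizes = np.bincount(labels, minlength=k)
    cell_label = int(np.lexsort((sizes, mean_tic))[-1])
    return PixelPartition(
        labels=labels,
        cell_label=cell_label,
        coords=pt.coords,
        grid_shape=pt.grid_shape,
        pixel_um=pt.pixel_um,
    )


def cell_specific_peaks(
    pt: PeakTable,
    part: PixelPartition,
    ratio_min: float = 5.0,
) -> np.ndarray:
    """Features whose mean cell signal is >= ``ratio_min`` x background mean.

    The boundary is inclusive ("minimum 5 times stronger").  A feature
    absent from the background (mean 0) but present in cells is retained.
    """
    is_cell = part.is_cell
    if not is_cell.any():
        raise ValueError("no cell pixels in partition")
    if is_cell.all():
        raise ValueError("no background pixels in partition")
    cell_mean = pt.matrix[is_cell].mean(axis=0)
    bg_mean = pt.matrix[~is_cell].mean(axis=0)
    keep = np.where(bg_mean > 0, cell_mean >= ratio_min * bg_mean, cell_mean > 0)
    return np.where(keep)[0]


def mean_spectrum(pt: PeakTable, pixel_idx: np.ndarray) -> np.ndarray:
    """Arithmetic per-feature mean over a pixel subset."""
    pixel_idx = np.asarray(pixel_idx)
    if pixel_idx.dtype == bool:
        if not pixel_idx.any():
            raise ValueError("empty pixel subset")
        return pt.matrix[pixel_idx].mean(axis=0)
    if pixel_idx.size == 0:
        raise ValueError("empty pixel subset")
    return pt.matrix[pixel_idx].mean(axis=0)


# ---------------------------------------------------------------------------
# imzML I/O


def write_imzml(ds: MSIDataset, path) -> None:
    """Write a dataset as processed-mode imzML (one m/z axis per pixel)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="processed") as w:
        for (r, c), mz, inten in zip(ds.coords, ds.mzs, ds.intensities):
            # imzML coordinates are 1-based (x, y)
            w.addSpectrum(np.asarray(mz, float), np.asarray(inten, float), (int(c) + 1, int(r) + 1, 1))


def read_imzml(
    path,
    sample_id: str = "S1",
    treatment: str = "CTR",
    pair_id: str = "P1",
    pixel_um: float = 10.0,
) -> MSIDataset:
    """Read continuous- or processed-mode imzML into an :class:`MSIDataset`."""
    from pyimzml.ImzMLParser import ImzMLParser

    p = ImzMLParser(str(path))
    coords, mzs, intens = [], [], []
    for i, (x, y, _z) in enumerate(p.coordinates):
        mz, inten = p.getspectrum(i)
        coords.append((int(y) - 1, int(x) - 1))
        mzs.append(np.asarray(mz, dtype=float))
        intens.append(np.asarray(inten, dtype=float))
    return MSIDataset(
        coords=np.asarray(coords, dtype=int),
        mzs=mzs,
        intensities=intens,
        sample_id=sample_id,
        treatment=treatment,
        pair_id=pair_id,
        pixel_um=pixel_um,
    )
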