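"""Brightfield segmentation and dispersed/cohesive cell assignment.

Classifies cell-containing MSI pixels as dispersed single cells or
cohesive groups using the co-registered brightfield micrograph: Gaussian
blur + Otsu threshold, contour detection, single-cell filtering by area
(100-2500 μm²) and bounding-box aspect ratio (0.75-1.25), projection onto
the MSI grid, flood-fill completion, and the component rule that a cell id
is dispersed iff it owns one whole connected component of cell pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .preprocess import PixelPartition

logger = logging.getLogger(__name__)

__all__ = [
    "BrightfieldImage",
    "ContourSet",
    "CellAssignment",
    "blur_and_threshold",
    "find_contours",
    "filter_single_cell_contours",
    "assign_pixels",
    "population_summary",
    "group_cell_shares",
]

DISPERSED, COHESIVE, NONE = "dispersed", "cohesive", "none"


@dataclass
class BrightfieldImage:
    """Grayscale micrograph co-registered to the MSI grid.

    Registration is an axis-aligned scale + translation (+ optional
    flips); the MSI pixel covering brightfield position (y, x) in μm is
    ``floor((y + origin_offset_um) / msi_pixel_um)``.
    """

    pixels: np.ndarray
    um_per_px: float
    origin_offset_um: tuple[float, float] = (0.0, 0.0)
    flip_y: bool = False
    flip_x: bool = False
    polarity: str = "dark"  # cells darker than background

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size == 0:
            raise ValueError("brightfield image is empty")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")


@dataclass
class ContourSet:
    """Detected object boundaries with per-contour geometry and accept flags."""

    contours: list  # closed boundary polygons, (m, 2) float arrays
    footprints: list  # per-contour (k, 2) int pixel coordinates
    table: pd.DataFrame  # area_um2, bbox_*, aspect_ratio, accepted
    um_per_px: float

    def accepted_indices(self) -> np.ndarray:
        return np.where(self.table["accepted"].to_numpy())[0]


@dataclass
class CellAssignment:
    """Per-MSI-pixel cell identity and organization labels."""

    is_cell: np.ndarray  # (rows, cols) bool
    cell_id: np.ndarray  # (rows, cols) int, 0 = unassigned cell area
    organization: np.ndarray  # (rows, cols) object: dispersed|cohesive|none
    pixel_um: float = 10.0
    sample_id: str = "S1"

    def organization_of(self, cid: int) -> str:
        sel = self.cell_id == cid
        if not sel.any():
            raise KeyError(cid)
        return str(self.organization[sel][0])

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.is_cell)
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "cell_id": self.cell_id[rows, cols],
                "organization": self.organization[rows, cols],
            }
        )


# ---------------------------------------------------------------------------


def blur_and_threshold(img: BrightfieldImage, sigma_px: float = 5.0) -> np.ndarray:
    """Gaussian blur (reflective borders) then Otsu binarization.

    The Otsu threshold maximizes between-class variance on a 256-bin
    histogram of the blurred image; the foreground (cell) side is chosen
    by the image's polarity flag (cells are darker by default).
    """
    x = img.pixels.astype(float)
    if np.all(x == x.flat[0]):
        raise ValueError("constant image: cannot threshold")
    blurred = ndimage.gaussian_filter(x, sigma=sigma_px, mode="reflect")
    thr = threshold_otsu(blurred, nbins=256)
    mask = blurred <= thr if img.polarity == "dark" else blurred > thr
    return mask


def find_contours(mask: np.ndarray, um_per_px: float = 1.0) -> ContourSet:
    """External boundaries of 8-connected foreground components.

    Area is the component pixel count x ``um_per_px``²; holes inside a
    component are ignored.  The bounding-box aspect ratio is width/height.
    """
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    contours, footprints, recs = [], [], []
    for i in range(1, n + 1):
        comp = lab == i
        rows, cols = np.nonzero(comp)
        footprints.append(np.stack([rows, cols], axis=1))
        r0, r1 = rows.min(), rows.max()
        c0, c1 = cols.min(), cols.max()
        height = (r1 - r0 + 1) * um_per_px
        width = (c1 - c0 + 1) * um_per_px
        # boundary polygon of the filled component (holes ignored)
        filled = ndimage.binary_fill_holes(comp)
        padded = np.pad(filled.astype(float), 1)
        polys = measure.find_contours(padded, 0.5)
        poly = max(polys, key=len) - 1.0 if polys else np.empty((0, 2))
        contours.append(poly)
        recs.append(
            {
                "area_um2": float(comp.sum()) * um_per_px**2,
                "bbox_row0": int(r0),
                "bbox_col0": int(c0),
                "bbox_row1": int(r1),
                "bbox_col1": int(c1),
                "aspect_ratio": width / height,
                "accepted": True,
            }
        )
    table = pd.DataFrame(recs, columns=[
        "area_um2", "bbox_row0", "bbox_col0", "bbox_row1", "bbox_col1",
        "aspect_ratio", "accepted",
    ])
    return ContourSet(contours=contours, footprints=footprints, table=table, um_per_px=um_per_px)


def filter_single_cell_contours(
    cs: ContourSet,
    area_range: tuple[float, float] = (100.0, 2500.0),
    aspect_range: tuple[float, float] = (0.75, 1.25),
) -> ContourSet:
    """Accept contours with in-range area and bounding-box aspect ratio.

    Both intervals are inclusive on both ends; the operation only updates
    the ``accepted`` flags and is idempotent.
    """
    area = cs.table["area_um2"].to_numpy()
    aspect = cs.table["aspect_ratio"].to_numpy()
    ok = (
        (area >= area_range[0])
        & (area <= area_range[1])
        & (aspect >= aspect_range[0])
        & (aspect <= aspect_range[1])
    )
    table = cs.table.copy()
    table["accepted"] = ok
    return ContourSet(contours=cs.contours, footprints=cs.footprints, table=table, um_per_px=cs.um_per_px)


# ---------------------------------------------------------------------------


def _bf_to_msi(footprint: np.ndarray, img: BrightfieldImage, pixel_um: float, grid_shape) -> np.ndarray:
    """Map brightfield pixel coordinates to MSI pixel indices."""
    if pixel_um <= 0 or img.um_per_px <= 0:
        raise ValueError("degenerate registration transform")
    rows_bf, cols_bf = img.pixels.shape
    r = footprint[:, 0].astype(float)
    c = footprint[:, 1].astype(float)
    if img.flip_y:
        r = rows_bf - 1 - r
    if img.flip_x:
        c = cols_bf - 1 - c
    y_um = (r + 0.5) * img.um_per_px + img.origin_offset_um[0]
    x_um = (c + 0.5) * img.um_per_px + img.origin_offset_um[1]
    msi = np.stack([np.floor(y_um / pixel_um), np.floor(x_um / pixel_um)], axis=1).astype(int)
    rows, cols = grid_shape
    ok = (msi[:, 0] >= 0) & (msi[:, 0] < rows) & (msi[:, 1] >= 0) & (msi[:, 1] < cols)
    return np.unique(msi[ok], axis=0)


def assign_pixels(
    cs: ContourSet,
    part: PixelPartition,
    img: BrightfieldImage,
    connectivity: int = 4,
    overrides: dict[int, str] | None = None,
) -> CellAssignment:
    """Assign single-cell ids to MSI cell pixels and label organization.

    Accepted contours are projected through the registration transform to
    the MSI grid; cell pixels covered by exactly one accepted contour get
    its id, remaining cell pixels are flood-filled (4-connected by
    default) from uniquely adjacent ids.  A cell id is dispersed iff its
    pixels make up one whole connected component of the cell mask and that
    component received exactly one id; every other cell pixel is cohesive.

    ``overrides`` (cell id -> organization) records what would otherwise
    be manual curation; it is applied last and wins over the rules.
    """
    rows, cols = part.grid_shape
    is_cell = np.zeros((rows, cols), dtype=bool)
    is_cell[part.coords[part.is_cell, 0], part.coords[part.is_cell, 1]] = True

    cover_count = np.zeros((rows, cols), dtype=int)
    cover_id = np.zeros((rows, cols), dtype=int)
    for rank, ci in enumerate(cs.accepted_indices(), start=1):
        msi_px = _bf_to_msi(cs.footprints[ci], img, part.pixel_um, (rows, cols))
        if len(msi_px) == 0:
            continue
        cover_count[msi_px[:, 0], msi_px[:, 1]] += 1
        cover_id[msi_px[:, 0], msi_px[:, 1]] = rank

    cell_id = np.where(is_cell & (cover_count == 1), cover_id, 0)

    # iterative flood fill: unassigned cell pixels adjacent to exactly one id
    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
    else:
        structure = np.ones((3, 3), dtype=bool)
        structure[1, 1] = False
    offsets = np.argwhere(structure) - 1
    changed = True
    while changed:
        changed = False
        unassigned = is_cell & (cell_id == 0)
        if not unassigned.any():
            break
        cand = np.zeros((rows, cols), dtype=int)
        conflict = np.zeros((rows, cols), dtype=bool)
        for dr, dc in offsets:
            shifted = np.zeros((rows, cols), dtype=int)
            src = cell_id
            r0, r1 = max(dr, 0), rows + min(dr, 0)
            c0, c1 = max(dc, 0), cols + min(dc, 0)
            shifted[r0:r1, c0:c1] = src[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
            new = unassigned & (shifted > 0)
            conflict |= new & (cand > 0) & (cand != shifted)
            cand = np.where(new & (cand == 0), shifted, cand)
        grow = unassigned & (cand > 0) & ~conflict
        if grow.any():
            cell_id[grow] = cand[grow]
            changed = True

    # organization by the component rule
    conn_struct = (
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)
        if connectivity == 4
        else np.ones((3, 3), dtype=int)
    )
    comp, n_comp = ndimage.label(is_cell, structure=conn_struct)
    organization = np.full((rows, cols), NONE, dtype=object)
    organization[is_cell] = COHESIVE
    id_comp: dict[int, set] = {}
    for cid in np.unique(cell_id[cell_id > 0]):
        id_comp[int(cid)] = set(np.unique(comp[cell_id == cid]).tolist())
    for ci in range(1, n_comp + 1):
        sel = comp == ci
        ids = np.unique(cell_id[sel])
        ids = ids[ids > 0]
        fully = sel & (cell_id > 0)
        if (
            len(ids) == 1
            and fully.sum() == sel.sum()  # whole component carries the id
            and id_comp.get(int(ids[0])) == {ci}  # id confined to this component
        ):
            organization[sel] = DISPERSED
    if overrides:
        for cid, org in overrides.items():
            if org not in (DISPERSED, COHESIVE):
                raise ValueError(f"invalid organization override {org!r}")
            organization[cell_id == cid] = org
    return CellAssignment(
        is_cell=is_cell,
        cell_id=cell_id,
        organization=organization,
        pixel_um=part.pixel_um,
    )


# ---------------------------------------------------------------------------


def population_summary(assignments: dict[str, CellAssignment], meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample cell-pixel and dispersed percentages.

    ``meta`` (indexed by sample id) may carry treatment labels for group
    comparisons done downstream with :func:`scmsi.stats.two_sample_t_test`.
    """
    recs = []
    for sid, ca in assignments.items():
        total = ca.is_cell.size
        n_cell = int(ca.is_cell.sum())
        n_disp = int((ca.organization == DISPERSED).sum())
        rec = {
            "sample_id": sid,
            "pct_cell_pixels": 100.0 * n_cell / total,
            "pct_dispersed": 100.0 * n_disp / n_cell if n_cell else np.nan,
            "n_cell_pixels": n_cell,
            "n_dispersed_pixels": n_disp,
        }
        if meta is not None and sid in meta.index:
            rec.update(meta.loc[sid].to_dict())
        recs.append(rec)
    return pd.DataFrame(recs).set_index("sample_id")


def group_cell_shares(counts: dict[str, int]) -> dict[str, float]:
    """Share (%) of pooled analyzed cells contributed by each group."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no cells")
    return {g: 100.0 * n / total for g, n in counts.items()}
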