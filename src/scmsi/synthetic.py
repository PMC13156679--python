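"""Synthetic MALDI-MSI experiments with known ground truth.

Emulates the data structure of a single-cell lipid imaging experiment on
cultured cells: a rectangular MSI acquisition grid (10 μm pitch) holding
spatially contiguous cell colonies and isolated single cells on a
matrix-covered background, a co-registered brightfield micrograph, and a
lipid feature panel (~46 m/z peaks in m/z 500-1000) with class-structured
treatment effects, per-sample (matrix-application) batch factors, and
planted single-cell subpopulations.

Every generator is deterministic given its configuration (including the
seed), and returns a :class:`SimTruth` carrying the ground truth needed to
close the test loop of every downstream stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import MSIDataset
from .segment import BrightfieldImage

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_feature_classes",
    "default_effect_map",
    "default_subpop_spec",
    "simulate_experiment",
    "simulate_single_cell_matrix",
    "simulate_profile_spectrum",
]

# Lipid head-group classes used to structure treatment effects.  The panel
# mirrors a negative-mode glycerophospholipid acquisition: PI dominates,
# PA/PS/PG are sparse, one lyso species, a few matrix-derived peaks and
# unidentified cellular peaks.
_CLASS_PLAN = (
    ("PA", 2),
    ("PS", 3),
    ("PE", 6),
    ("PI", 14),
    ("PG", 3),
    ("LPI", 1),
    ("other", 11),
    ("matrix", 6),
)

# Per-class log2 treatment effect plan: EMT induction lowers PA/PS/PE/PI
# species and raises PG species and the lyso-PI.  Counts give 21 affected
# features at the default panel size.
_EFFECT_PLAN = {
    "PA": (2, -0.6),
    "PS": (2, -0.6),
    "PE": (4, -0.6),
    "PI": (10, -0.6),
    "PG": (2, +0.6),
    "LPI": (1, +0.6),
}


def default_feature_classes(n_features: int = 46) -> list[str]:
    """Assign a lipid class label to each feature index."""
    classes: list[str] = []
    for name, count in _CLASS_PLAN:
        classes.extend([name] * count)
    if n_features <= len(classes):
        # Keep at least two matrix features so the background is non-empty.
        kept = classes[: max(n_features - 2, 0)]
        kept += ["matrix"] * (n_features - len(kept))
        return kept
    return classes + ["other"] * (n_features - len(classes))


def default_effect_map(n_features: int = 46) -> dict[int, float]:
    """Class-structured log2 treatment effects (21 affected features at n=46)."""
    classes = default_feature_classes(n_features)
    effects: dict[int, float] = {}
    remaining = {k: v[0] for k, v in _EFFECT_PLAN.items()}
    for i, c in enumerate(classes):
        if c in remaining and remaining[c] > 0:
            effects[i] = _EFFECT_PLAN[c][1]
            remaining[c] -= 1
    return effects


def default_subpop_spec(
    n_features: int = 46,
    n_subpops: int = 7,
    separation: float = 4.0,
    noise_cv: float = 0.2,
    block: int = 5,
) -> list[tuple[float, np.ndarray]]:
    """Subpopulation spec: (fraction, per-feature log2 shift vector).

    Each subpopulation shifts a disjoint block of ``block`` features by
    ``separation`` times the log2-scale noise SD, giving orthogonal
    centroids whose per-feature displacement / noise ratio equals
    ``separation``.
    """
    sigma_log2 = math.sqrt(math.log(1.0 + noise_cv**2)) / math.log(2.0)
    if sigma_log2 == 0:
        sigma_log2 = 0.25  # shift still needs a scale when noise-free
    if n_subpops * block > n_features:
        raise ValueError("not enough features for disjoint subpopulation blocks")
    fractions = np.array([0.15, 0.12, 0.19, 0.08, 0.06, 0.23, 0.17])
    if n_subpops != 7:
        fractions = np.full(n_subpops, 1.0 / n_subpops)
    fractions = fractions / fractions.sum()
    spec = []
    for j in range(n_subpops):
        shift = np.zeros(n_features)
        shift[j * block : (j + 1) * block] = separation * sigma_log2
        spec.append((float(fractions[j]), shift))
    return spec


@dataclass
class SimConfig:
    """Study conditions for one synthetic sample.

    Pixel pitch (10 μm) and m/z range (500-1000 Da) follow the acquisition
    settings of the emulated assay; colony/singleton geometry is chosen so
    the single-cell area filter (100-2500 μm²) and the dispersed/cohesive
    distinction are both exercised.
    """

    grid_shape: tuple[int, int] = (200, 200)
    pixel_um: float = 10.0
    n_features: int = 46
    mz_range: tuple[float, float] = (500.0, 1000.0)
    n_colonies: int = 12
    n_singletons: int = 60
    colony_radius_px: tuple[float, float] = (3.0, 4.5)
    treatment: str = "CTR"
    pair_id: str = "P1"
    sample_id: str = "S1"
    batch_scale: float = 1.0
    effect_map: dict[int, float] | None = None
    subpop_spec: list[tuple[float, np.ndarray]] | None = None
    noise_cv: float = 0.2
    bf_um_per_px: float = 1.0
    mz_jitter: float = 0.01
    seed: int = 0
    panel_seed: int = 0  # lipid panel (m/z, base levels) shared across samples

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError("mz_range low must be < high")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.subpop_spec is not None:
            total = sum(f for f, _ in self.subpop_spec)
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError("subpop_spec fractions must sum to 1")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimTruth:
    """Ground truth accompanying a synthetic sample."""

    cell_mask: np.ndarray  # (rows, cols) bool
    cell_id_map: np.ndarray  # (rows, cols) int, 0 = background
    organization_map: dict[int, str]  # cell id -> dispersed | cohesive
    cell_specific_features: np.ndarray  # sorted feature indices
    subpop_labels: dict[int, int]  # cell id -> subpopulation
    batch_factors: dict[str, float]
    feature_mz: np.ndarray = field(default=None)  # type: ignore[assignment]
    feature_classes: list[str] = field(default_factory=list)
    cell_centers_um: dict[int, tuple[float, float]] = field(default_factory=dict)


def _feature_mz(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.mz_range
    # Evenly spread centers with random offsets; enforced minimum spacing
    # keeps alignment unambiguous at the default 0.1 Da tolerance.
    base = np.linspace(lo + 5, hi - 5, config.n_features)
    jitter = rng.uniform(-1.5, 1.5, size=config.n_features)
    mz = np.sort(base + jitter)
    return mz


def _base_levels(config: SimConfig, rng: np.random.Generator):
    """Per-feature cellular and background intensity levels.

    Matrix-derived peaks are present everywhere at similar level (they are
    what the 5x cell-specificity filter must reject); cellular lipid peaks
    leak into the background at 1/150 of their cellular level on a random
    half of the panel, so the ratio computation is exercised on non-zero
    backgrounds.  The leak is kept far below 1/5 of the cellular level
    because TIC normalization scales background spectra up by the cell/
    background TIC contrast (~5-10x in this design), which eats into the
    measured ratio.
    """
    classes = default_feature_classes(config.n_features)
    is_matrix = np.array([c == "matrix" for c in classes])
    cell_level = np.where(
        is_matrix,
        0.0,
        np.exp(rng.uniform(np.log(60.0), np.log(400.0), config.n_features)),
    )
    matrix_level = np.where(
        is_matrix,
        np.exp(rng.uniform(np.log(150.0), np.log(500.0), config.n_features)),
        0.0,
    )
    leak = rng.random(config.n_features) < 0.5
    bg_level = matrix_level + np.where(~is_matrix & leak, cell_level / 150.0, 0.0)
    cell_total = cell_level + matrix_level
    return classes, cell_total, bg_level


def _place_objects(config: SimConfig, rng: np.random.Generator):
    """Place singleton discs and colony disc-unions in μm coordinates.

    Returns a list of objects ``(kind, discs)`` where each disc is
    ``(y_um, x_um, r_um)``.  Objects are separated so that distinct
    connected components stay >= 2 background pixels apart; an object that
    cannot be placed without wrapping outside the grid raises ValueError.
    """
    rows, cols = config.grid_shape
    h_um, w_um = rows * config.pixel_um, cols * config.pixel_um
    sep_um = 2.5 * config.pixel_um
    placed: list[tuple[float, float, float]] = []  # bounding circles
    objects = []

    def fits(y, x, r):
        if y - r < 0.5 or x - r < 0.5 or y + r > h_um - 0.5 or x + r > w_um - 0.5:
            return False
        for py, px, pr in placed:
            if math.hypot(y - py, x - px) < r + pr + sep_um:
                return False
        return True

    def place(kind, make_discs, max_tries=4000):
        for _ in range(max_tries):
            discs = make_discs()
            ys = [d[0] for d in discs]
            xs = [d[1] for d in discs]
            rs = [d[2] for d in discs]
            cy, cx = float(np.mean(ys)), float(np.mean(xs))
            br = max(
                math.hypot(y - cy, x - cx) + r for y, x, r in discs
            )
            if fits(cy, cx, br):
                placed.append((cy, cx, br))
                objects.append((kind, discs))
                return
        raise ValueError(
            f"could not place {kind} in grid {config.grid_shape} without "
            "wrapping; reduce object count or enlarge the grid"
        )

    for _ in range(config.n_colonies):

        def make_colony():
            n_discs = int(rng.integers(2, 5))
            r_lo, r_hi = config.colony_radius_px
            r0 = rng.uniform(r_lo, r_hi) * config.pixel_um
            y = rng.uniform(r0 + 1, h_um - r0 - 1)
            x = rng.uniform(r0 + 1, w_um - r0 - 1)
            discs = [(y, x, r0)]
            for _ in range(n_discs - 1):
                r = rng.uniform(r_lo, r_hi) * config.pixel_um
                ang = rng.uniform(0, 2 * math.pi)
                step = rng.uniform(0.6, 1.0) * (discs[-1][2] + r) / 2 * 1.2
                discs.append(
                    (discs[-1][0] + step * math.sin(ang), discs[-1][1] + step * math.cos(ang), r)
                )
            return discs

        place("cohesive", make_colony)

    for _ in range(config.n_singletons):

        def make_singleton():
            # single-cell areas well inside the 100-2500 μm² filter: blur +
            # thresholding erodes the rendered footprint of the smallest
            # cells, so the draw starts at 250 μm² (~18 μm diameter)
            area = rng.uniform(250.0, 1200.0)
            r = math.sqrt(area / math.pi)
            # snap the center to an MSI pixel center so >= 1 pixel is covered
            ri = int(rng.integers(1, rows - 1))
            ci = int(rng.integers(1, cols - 1))
            return [((ri + 0.5) * config.pixel_um, (ci + 0.5) * config.pixel_um, r)]

        place("dispersed", make_singleton)

    return objects


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=shape))


def simulate_experiment(config: SimConfig):
    """Render one synthetic sample: MSI dataset, brightfield image, truth.

    Background pixels carry only matrix-like peaks (log-normal noise);
    cell pixels add cellular lipid peaks at >= 5x their background leak,
    with the treatment effect map applied multiplicatively on EGF samples,
    per-cell subpopulation shifts, and the sample's batch factor applied to
    all intensities.  The brightfield image renders cells as dark blobs on
    a bright background at ``bf_um_per_px``.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    panel_rng = np.random.default_rng(config.panel_seed)
    mz = _feature_mz(config, panel_rng)
    classes, cell_level, bg_level = _base_levels(config, panel_rng)
    effect_map = config.effect_map if config.effect_map is not None else default_effect_map(config.n_features)
    subpop_spec = config.subpop_spec if config.subpop_spec is not None else default_subpop_spec(
        config.n_features, noise_cv=config.noise_cv
    )

    objects = _place_objects(config, rng)

    cell_mask = np.zeros((rows, cols), dtype=bool)
    cell_id_map = np.zeros((rows, cols), dtype=int)
    organization_map: dict[int, str] = {}
    subpop_labels: dict[int, int] = {}
    cell_centers: dict[int, tuple[float, float]] = {}

    yy = (np.arange(rows) + 0.5) * config.pixel_um
    xx = (np.arange(cols) + 0.5) * config.pixel_um
    fractions = np.array([f for f, _ in subpop_spec])
    shifts = np.array([s for _, s in subpop_spec])

    for idx, (kind, discs) in enumerate(objects, start=1):
        inside = np.zeros((rows, cols), dtype=bool)
        for y, x, r in discs:
            inside |= (yy[:, None] - y) ** 2 + (xx[None, :] - x) ** 2 <= r**2
        cell_mask |= inside
        cell_id_map[inside] = idx
        organization_map[idx] = kind
        subpop_labels[idx] = int(rng.choice(len(subpop_spec), p=fractions))
        cy = float(np.mean([d[0] for d in discs]))
        cx = float(np.mean([d[1] for d in discs]))
        cell_centers[idx] = (cy, cx)

    # --- intensities (centroided peak heights) -------------------------
    n_pix = rows * cols
    flat_id = cell_id_map.ravel()
    flat_cell = cell_mask.ravel()

    # background pixels: matrix peaks + delocalized analyte leak; cell
    # pixels: cellular signal plus the same matrix peaks, no leak term
    is_matrix_feat = np.array([c == "matrix" for c in classes])
    matrix_only = np.where(is_matrix_feat, bg_level, 0.0)
    cell_part = np.tile(cell_level + matrix_only, (n_pix, 1))
    # treatment effect acts on cellular signal of treated samples only
    if config.treatment == "EGF" and effect_map:
        fx = np.ones(config.n_features)
        for f, log2fc in effect_map.items():
            fx[f] = 2.0**log2fc
        cell_part = cell_part * fx
    # per-cell subpopulation shift (log2 scale)
    if len(shifts):
        shift_per_pixel = np.zeros((n_pix, config.n_features))
        for cid, sp in subpop_labels.items():
            shift_per_pixel[flat_id == cid] = shifts[sp]
        cell_part = cell_part * np.where(flat_cell[:, None], 2.0**shift_per_pixel, 1.0)
    intens = np.where(flat_cell[:, None], cell_part, bg_level[None, :])

    intens *= _lognormal_noise(rng, config.noise_cv, intens.shape)
    intens *= _lognormal_noise(rng, config.noise_cv, (n_pix, 1))  # per-pixel gain
    intens *= config.batch_scale

    coords = np.stack(np.unravel_index(np.arange(n_pix), (rows, cols)), axis=1)
    if config.mz_jitter > 0:
        mz_per_pixel = mz[None, :] + rng.normal(0.0, config.mz_jitter, size=intens.shape)
    else:
        mz_per_pixel = np.tile(mz, (n_pix, 1))
    mzs, ints = [], []
    for i in range(n_pix):
        keep = intens[i] > 0
        order = np.argsort(mz_per_pixel[i, keep], kind="stable")
        mzs.append(mz_per_pixel[i, keep][order])
        ints.append(intens[i, keep][order])

    ds = MSIDataset(
        coords=coords,
        mzs=mzs,
        intensities=ints,
        sample_id=config.sample_id,
        treatment=config.treatment,
        pair_id=config.pair_id,
        pixel_um=config.pixel_um,
        grid_shape=(rows, cols),
    )

    # --- brightfield ---------------------------------------------------
    bf_rows = int(round(rows * config.pixel_um / config.bf_um_per_px))
    bf_cols = int(round(cols * config.pixel_um / config.bf_um_per_px))
    bf = np.full((bf_rows, bf_cols), 30000.0)
    bff_y = (np.arange(bf_rows) + 0.5) * config.bf_um_per_px
    bff_x = (np.arange(bf_cols) + 0.5) * config.bf_um_per_px
    for kind, discs in objects:
        for y, x, r in discs:
            r0 = max(int((y - r) / config.bf_um_per_px) - 2, 0)
            r1 = min(int((y + r) / config.bf_um_per_px) + 3, bf_rows)
            c0 = max(int((x - r) / config.bf_um_per_px) - 2, 0)
            c1 = min(int((x + r) / config.bf_um_per_px) + 3, bf_cols)
            sub_y = bff_y[r0:r1][:, None]
            sub_x = bff_x[c0:c1][None, :]
            inside = (sub_y - y) ** 2 + (sub_x - x) ** 2 <= r**2
            patch = bf[r0:r1, c0:c1]
            patch[inside] = 12000.0
    bf += rng.normal(0.0, 250.0, size=bf.shape)
    bf_img = BrightfieldImage(
        pixels=np.clip(bf, 0, 65535).astype(np.uint16),
        um_per_px=config.bf_um_per_px,
    )

    is_matrix = np.array([c == "matrix" for c in classes])
    specific = np.where(~is_matrix & (cell_level >= 5 * np.maximum(bg_level, 1e-300)))[0]
    truth = SimTruth(
        cell_mask=cell_mask,
        cell_id_map=cell_id_map,
        organization_map=organization_map,
        cell_specific_features=specific,
        subpop_labels=subpop_labels,
        batch_factors={config.pair_id: config.batch_scale},
        feature_mz=mz,
        feature_classes=classes,
        cell_centers_um=cell_centers,
    )
    return ds, bf_img, truth


def simulate_single_cell_matrix(
    config: SimConfig,
    n_cells: int,
    n_batches: int = 3,
    batch_log_scale: float = 1.0,
):
    """Directly generate a single-cell feature matrix with planted subpopulations.

    Bypasses the imaging stages: each row is one dispersed cell, drawn from
    the configured subpopulation mixture, with per-batch multiplicative
    location factors (spread set by ``batch_scale``) and optional per-batch
    scale inflation of the log-intensity noise (``batch_log_scale``).
    Returns ``(CellFeatureMatrix, SimTruth)`` with per-cell subpopulation
    labels in the truth.
    """
    from .quant import CellFeatureMatrix
    import pandas as pd

    subpop_spec = config.subpop_spec if config.subpop_spec is not None else default_subpop_spec(
        config.n_features, noise_cv=config.noise_cv
    )
    if not subpop_spec:
        raise ValueError("subpop_spec must be non-empty")
    if n_cells < len(subpop_spec):
        raise ValueError("n_cells must be >= number of subpopulations")

    rng = np.random.default_rng(config.seed)
    panel_rng = np.random.default_rng(config.panel_seed)
    mz = _feature_mz(config, panel_rng)
    classes, cell_level, _ = _base_levels(config, panel_rng)
    level = np.where(cell_level > 0, cell_level, 1.0)

    fractions = np.array([f for f, _ in subpop_spec])
    shifts = np.array([s for _, s in subpop_spec])
    labels = rng.choice(len(subpop_spec), size=n_cells, p=fractions)

    if n_batches > 1:
        batch_factors = config.batch_scale ** np.linspace(-1.0, 1.0, n_batches)
    else:
        batch_factors = np.array([1.0])
    batch_idx = np.arange(n_cells) % n_batches

    log_vals = np.log(level)[None, :] + shifts[labels] * math.log(2.0)
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2)) if config.noise_cv > 0 else 0.0
    noise = rng.normal(0.0, 1.0, size=(n_cells, config.n_features)) * sigma
    if batch_log_scale != 1.0 and n_batches > 1:
        scale_per_batch = batch_log_scale ** np.linspace(-1.0, 1.0, n_batches)
        noise = noise * scale_per_batch[batch_idx][:, None]
    values = np.exp(log_vals + noise) * batch_factors[batch_idx][:, None]

    # treatment composition emulating an induction experiment: the first
    # four subpopulations are treated-majority, the next two control, the
    # last mixed (80/20)
    n_sub = len(subpop_spec)
    treatment = np.empty(n_cells, dtype=object)
    for i in range(n_cells):
        sp = labels[i]
        if n_sub >= 7:
            if sp <= 3:
                treatment[i] = "EGF"
            elif sp <= 5:
                treatment[i] = "CTR"
            else:
                treatment[i] = "EGF" if rng.random() < 0.8 else "CTR"
        else:
            treatment[i] = "EGF" if sp % 2 == 0 else "CTR"

    cols = [f"mz_{m:.4f}" for m in mz]
    obs = pd.DataFrame(
        {
            "sample_id": [f"S{b + 1}" for b in batch_idx],
            "treatment": treatment,
            "pair_id": [f"B{b + 1}" for b in batch_idx],
            "organization": "dispersed",
        },
        index=[f"cell_{i}" for i in range(n_cells)],
    )
    cfm = CellFeatureMatrix(
        values=pd.DataFrame(values, index=obs.index, columns=cols),
        obs=obs,
    )
    truth = SimTruth(
        cell_mask=np.zeros((1, 1), dtype=bool),
        cell_id_map=np.zeros((1, 1), dtype=int),
        organization_map={},
        cell_specific_features=np.arange(config.n_features),
        subpop_labels={i: int(l) for i, l in enumerate(labels)},
        batch_factors={f"B{b + 1}": float(batch_factors[b]) for b in range(n_batches)},
        feature_mz=mz,
        feature_classes=classes,
    )
    return cfm, truth


def simulate_profile_spectrum(
    mz_axis: np.ndarray,
    peaks: list[tuple[float, float]],
    fwhm: float = 0.3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Profile-mode spectrum: Gaussian peak shapes plus i.i.d. noise.

    Used only to exercise the peak picker; the imaging generator emits
    centroided peak heights directly.
    """
    rng = np.random.default_rng(seed)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    y = np.zeros_like(mz_axis, dtype=float)
    for center, height in peaks:
        y += height * np.exp(-0.5 * ((mz_axis - center) / sigma) ** 2)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=mz_axis.shape)
    return y
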